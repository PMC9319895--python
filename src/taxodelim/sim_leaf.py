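"""Synthetic pinnately lobed leaf silhouettes with known straight truth.

A leaf is built in a canonical frame (base at the origin, midvein along
+x, pixel units, y down) from a smooth half-width profile modulated by a
lobe term controlling dissection, then bent by a constant-curvature arc
map of the axis.  Constant curvature is not how real leaves bend, but it
has an exact inverse, so the unbent silhouette is available as ground
truth for the straightening stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .leaf.annotations import LeafAnnotation


@dataclass
class LeafModel:
    """Conditions for one simulated leaf.

    Parameters
    ----------
    length
        Base-to-tip length in pixels.
    n_lobes
        Number of lobe pairs along the margin (0 = entire margin).
    dissection
        Non-negative lobe-depth control; the margin dips to a fraction
        1/(1+dissection) of the smooth profile, so 0 means no lobing.
    bend_curvature
        Signed curvature (1/pixels) of the arc the midvein is bent along.
    contour_points
        Number of contour vertices (>= 64).
    width
        Maximum half-width in pixels (default length/5).
    noise
        Standard deviation of a smooth multiplicative margin perturbation
        (log scale); introduces individual variation.
    """

    length: float = 400.0
    n_lobes: int = 5
    dissection: float = 1.0
    bend_curvature: float = 0.0
    contour_points: int = 256
    width: float | None = None
    noise: float = 0.0
    n_midvein: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_lobes < 0:
            raise ValueError("n_lobes must be non-negative")
        if self.dissection < 0:
            raise ValueError("dissection must be >= 0")
        if self.contour_points < 64:
            raise ValueError("need at least 64 contour points")
        if self.n_midvein < 2:
            raise ValueError("need at least two midvein vertices")

    @property
    def half_width(self) -> float:
        return self.width if self.width is not None else self.length / 5.0


def _margin(model: LeafModel, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Half-width profile over u in (0, 1), smooth base x lobing x noise.

    The smooth profile is skewed toward the base (leaves taper toward
    the tip), which also makes the basal end identifiable from local
    contour width alone.
    """
    base = np.sin(np.pi * u) ** 0.8 * (1.0 - 0.35 * u)
    depth = model.dissection / (1.0 + model.dissection)
    lobes = 1.0 - depth * np.sin(np.pi * model.n_lobes * u) ** 2
    if model.noise > 0:
        coeff = rng.normal(0.0, model.noise, size=4)
        wave = sum(
            coeff[k] * np.sin(np.pi * (k + 1) * u) / (k + 1) for k in range(4)
        )
        lobes = lobes * np.exp(wave)
    return model.half_width * base * lobes


def _arc_map(points: np.ndarray, kappa: float) -> np.ndarray:
    """Constant-curvature bend of the axis: (x, y) -> arc frame.

    x is arc length along the bent axis and y the signed offset, so the
    midvein (y = 0) keeps its arc length exactly.
    """
    if abs(kappa) < 1e-12:
        return points.copy()
    r = 1.0 / kappa
    phi = points[:, 0] * kappa
    rad = r - points[:, 1]
    return np.column_stack([rad * np.sin(phi), r - rad * np.cos(phi)])


def _bend_midvein(midvein: np.ndarray, kappa: float) -> np.ndarray:
    """Place midvein vertices on the bent axis with chord-exact spacing.

    Consecutive angular steps are chosen so every polyline segment keeps
    its straight-frame Euclidean length exactly, making the cumulative
    polyline arc length of the bent and straight midveins identical.
    """
    if abs(kappa) < 1e-12:
        return midvein.copy()
    r = 1.0 / kappa
    seg = np.linalg.norm(np.diff(midvein, axis=0), axis=1)
    half = np.clip(seg * abs(kappa) / 2.0, 0.0, 1.0)
    steps = 2.0 * np.arcsin(half) * np.sign(kappa)
    phi = midvein[0, 0] * kappa + np.concatenate([[0.0], np.cumsum(steps)])
    return np.column_stack([r * np.sin(phi), r - r * np.cos(phi)])


def simulate_leaf(model: LeafModel) -> tuple[LeafAnnotation, LeafAnnotation]:
    """Generate (bent, straight_truth) annotations for one leaf.

    Both share vertex counts and midvein arc length; curvature large
    enough to self-intersect the contour is rejected.
    """
    model.validate()
    rng = np.random.default_rng(model.seed)
    n_side = model.contour_points // 2
    u = np.linspace(0.0, 1.0, n_side + 1)
    w = _margin(model, u, rng)
    w[0] = w[-1] = 0.0
    x = u * model.length
    upper = np.column_stack([x, -w])  # y-down: upper margin at negative y
    lower = np.column_stack([x[::-1][1:-1], w[::-1][1:-1]])
    contour = np.vstack([upper, lower])
    # midvein strictly interior: annotated midveins stop short of the
    # base and tip apices, and the bent chord-exact vertices must stay
    # inside the tapering outline
    mid_x = np.linspace(0.01 * model.length, 0.99 * model.length, model.n_midvein)
    midvein = np.column_stack([mid_x, np.zeros_like(mid_x)])

    straight = LeafAnnotation(
        contour.copy(), midvein.copy(), specimen_id=f"synthetic_{model.seed}"
    )
    straight.validate()

    kappa = model.bend_curvature
    if abs(kappa) * w.max() >= 0.95:
        raise ValueError(
            f"curvature {kappa} too large for half-width {w.max():.1f}: "
            "the bent contour would self-intersect"
        )
    bent_contour = _arc_map(contour, kappa)
    bent_mid = _bend_midvein(midvein, kappa)
    if not Polygon(bent_contour).is_valid:
        raise ValueError(
            f"curvature {kappa} bends the leaf onto itself; reduce it"
        )
    bent = LeafAnnotation(
        bent_contour, bent_mid, specimen_id=f"synthetic_{model.seed}"
    )
    bent.validate()
    return bent, straight


def simulate_leaf_population(
    n: int,
    model: LeafModel,
    dissection_sd: float = 0.15,
    curvature_sd: float = 0.0008,
    seed: int = 0,
    taxon: str = "",
) -> list[tuple[LeafAnnotation, LeafAnnotation]]:
    """A population of leaves varying around a common archetype.

    Per-leaf dissection is the archetype value plus Gaussian noise
    (clipped at 0), curvature is drawn around the archetype value, and
    the margin-noise seed varies, emulating individual variation within
    one taxon.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        m = LeafModel(
            length=model.length,
            n_lobes=model.n_lobes,
            dissection=max(0.0, model.dissection + rng.normal(0.0, dissection_sd)),
            bend_curvature=model.bend_curvature + rng.normal(0.0, curvature_sd),
            contour_points=model.contour_points,
            width=model.width,
            noise=model.noise if model.noise > 0 else 0.03,
            n_midvein=model.n_midvein,
            seed=int(rng.integers(2**31)),
        )
        bent, straight = simulate_leaf(m)
        bent.taxon = straight.taxon = taxon
        bent.specimen_id = straight.specimen_id = f"{taxon or 'leaf'}_{i:03d}"
        out.append((bent, straight))
    return out
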