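"""Synthetic landscapes: smooth env layers, Gaussian niches, occurrences.

Environmental layers are sums of random Gaussian bumps over a lon/lat
grid; the first two layers additionally carry west-east and north-south
gradients so that positions in environmental space map to coherent
regions in geographic space.  Each taxon's true suitability is a Gaussian
response around its niche center in layer space, and occurrences are
sampled without replacement from cells with probability proportional to
suitability.  The scenario controls niche-center placement: sympatric
taxa share one center, parapatric centers sit adjacent, allopatric
centers are taken from opposite grid corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geo import OccurrenceSet, Raster

SCENARIOS = ("sympatric", "parapatric", "allopatric")


@dataclass
class LandscapeModel:
    """Conditions for one simulated landscape.

    ``niche_centers``/``niche_widths`` (per taxon, in layer space) may be
    left None: the scenario then places them automatically.
    """

    n_rows: int = 40
    n_cols: int = 40
    n_layers: int = 3
    smoothness: float = 8.0  # Gaussian-bump width in cells
    n_bumps: int = 25
    taxa: tuple[str, ...] = ("A", "B")
    niche_centers: dict[str, np.ndarray] | None = None
    niche_widths: dict[str, np.ndarray] | None = None
    niche_width_scale: float = 1.0
    n_occurrences: int | dict[str, int] = 60
    scenario: str = "sympatric"
    x_origin: float = -10.0
    y_origin: float = 52.0
    cell_size: float = 0.1
    seed: int = 0

    def n_occ(self, taxon: str) -> int:
        if isinstance(self.n_occurrences, dict):
            return self.n_occurrences[taxon]
        return int(self.n_occurrences)

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.n_layers < 1 or self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid too small")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


@dataclass
class Landscape:
    layers: list[Raster]
    true_suitability: dict[str, Raster]
    occurrences: dict[str, OccurrenceSet]
    model: LandscapeModel = field(repr=False, default=None)


def _bump_layer(model: LandscapeModel, rng: np.random.Generator) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(model.n_rows), np.arange(model.n_cols), indexing="ij"
    )
    vals = np.zeros((model.n_rows, model.n_cols))
    for _ in range(model.n_bumps):
        r0 = rng.uniform(0, model.n_rows)
        c0 = rng.uniform(0, model.n_cols)
        amp = rng.normal(0.0, 1.0)
        width = model.smoothness * rng.uniform(0.6, 1.4)
        vals += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2))
    return vals


def simulate_landscape(model: LandscapeModel) -> Landscape:
    """Generate layers, per-taxon true suitability and occurrence sets."""
    model.validate()
    rng = np.random.default_rng(model.seed)
    nr, nc = model.n_rows, model.n_cols
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")

    layer_vals = []
    for li in range(model.n_layers):
        vals = _bump_layer(model, rng)
        if li == 0:  # west-east gradient dominates layer 1
            vals = 0.5 * vals + 3.0 * (cc / (nc - 1) - 0.5)
        elif li == 1:  # north-south gradient dominates layer 2
            vals = 0.5 * vals + 3.0 * (rr / (nr - 1) - 0.5)
        vals = (vals - vals.mean()) / max(vals.std(), 1e-9)
        layer_vals.append(vals)

    layers = [
        Raster(
            v,
            x_origin=model.x_origin,
            y_origin=model.y_origin,
            cell_size=model.cell_size,
        )
        for v in layer_vals
    ]
    env = np.stack(layer_vals)  # (L, nr, nc)

    centers = dict(model.niche_centers or {})
    widths = dict(model.niche_widths or {})
    if not centers:
        centers = _scenario_centers(model, env)
    for t in model.taxa:
        widths.setdefault(
            t, np.full(model.n_layers, 0.6 * model.niche_width_scale)
        )

    true_suit: dict[str, Raster] = {}
    occs: dict[str, OccurrenceSet] = {}
    for t in model.taxa:
        z = (env - np.asarray(centers[t])[:, None, None]) / np.asarray(widths[t])[
            :, None, None
        ]
        s = np.exp(-0.5 * (z**2).sum(axis=0))
        s = s / s.max()
        suit = Raster(
            s,
            x_origin=model.x_origin,
            y_origin=model.y_origin,
            cell_size=model.cell_size,
        )
        true_suit[t] = suit

        flat = s.ravel()
        positive = np.where(flat > 0)[0]
        n_occ = model.n_occ(t)
        if n_occ > positive.size:
            raise ValueError(
                f"taxon {t!r}: {n_occ} occurrences requested but only "
                f"{positive.size} cells have positive suitability"
            )
        probs = flat[positive] / flat[positive].sum()
        chosen = rng.choice(positive, size=n_occ, replace=False, p=probs)
        pts = []
        for idx in chosen:
            r, c = divmod(int(idx), nc)
            lon, lat = suit.center_of(r, c)
            # jitter inside the cell so points are not exactly co-located
            lon += rng.uniform(-0.45, 0.45) * model.cell_size
            lat += rng.uniform(-0.45, 0.45) * model.cell_size
            pts.append((lon, lat))
        occs[t] = OccurrenceSet(t, np.asarray(pts)).assign_cells(suit)

    return Landscape(layers, true_suit, occs, model)


def _scenario_centers(
    model: LandscapeModel, env: np.ndarray
) -> dict[str, np.ndarray]:
    """Niche centers implied by the scenario, read off the env grid."""
    nr, nc = model.n_rows, model.n_cols
    m = max(2, min(nr, nc) // 8)  # corner patch size

    def patch_mean(rows: slice, cols: slice) -> np.ndarray:
        return env[:, rows, cols].reshape(env.shape[0], -1).mean(axis=1)

    center_mid = patch_mean(
        slice(nr // 2 - m, nr // 2 + m), slice(nc // 2 - m, nc // 2 + m)
    )
    corner_nw = patch_mean(slice(0, m), slice(0, m))
    corner_se = patch_mean(slice(nr - m, nr), slice(nc - m, nc))

    out: dict[str, np.ndarray] = {}
    for i, t in enumerate(model.taxa):
        if model.scenario == "sympatric":
            out[t] = center_mid
        elif model.scenario == "allopatric":
            out[t] = corner_nw if i % 2 == 0 else corner_se
        else:  # parapatric: adjacent centers straddling the middle
            shift = (i - (len(model.taxa) - 1) / 2) * 2 * m
            col = int(np.clip(nc // 2 + shift, m, nc - m))
            out[t] = patch_mean(
                slice(nr // 2 - m, nr // 2 + m), slice(col - m, col + m)
            )
    return out
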