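"""Assembly-parameter scoring and knee-point model selection.

Candidate RADseq assemblies (one per clustering-threshold ct /
min-samples-per-locus msl combination) are ranked by a score combining
in-vitro replicate error rates with a soft target for the missing-data
percentage:

    score = (1 - EL) * (1 - ES) * exp(-(MS - mu)^2 / (2 sigma^2)),

with EL the mean locus error rate, ES the mean SNP error rate, MS the
percent missing data, and mu = sigma = 50 by default.  The Gaussian factor
is an unnormalized kernel (1 at MS = mu), so the score lives in [0, 1] and
higher is better.  Note the deliberate consequence of centering at 50%:
assemblies with *less* missing data than mu score lower, all else equal.

The knee (elbow) of a model-fit-versus-complexity curve -- e.g. marginal
likelihood against the number of species groups -- is located with the
Kneedle algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AssemblyMetrics:
    """Replicate-error and missing-data summary of one finished assembly."""

    ct: float
    msl: int
    EL: float
    ES: float
    MS: float
    score: float = np.nan


def replicate_error_rates(
    loci_a: dict, loci_b: dict, pairs: list[tuple[str, str]] | None = None
) -> tuple[float, float]:
    """Locus and SNP error rates from in-vitro replicate pairs.

    ``loci_a`` / ``loci_b`` map, per replicate sample, locus id ->
    genotype-call sequence (any equal-length sequences).  When ``pairs``
    is None, ``loci_a`` and ``loci_b`` are taken to be the two members of
    a single replicate pair (locus id -> calls directly).

    Per pair: locus error = loci recovered in exactly one replicate /
    loci recovered in at least one; SNP error = mismatching genotype calls
    / calls compared at loci shared by both.  EL and ES are means over
    pairs; a pair sharing zero loci has undefined SNP error and is
    excluded from ES with a warning.
    """
    import warnings

    if pairs is None:
        pair_data = [(loci_a, loci_b)]
    else:
        pair_data = [(loci_a[a], loci_b[b]) for a, b in pairs]
    el_values, es_values = [], []
    for la, lb in pair_data:
        keys_a, keys_b = set(la), set(lb)
        union = keys_a | keys_b
        if not union:
            raise ValueError("replicate pair recovered no loci at all")
        shared = keys_a & keys_b
        el_values.append(len(union - shared) / len(union))
        if not shared:
            warnings.warn(
                "replicate pair shares no loci; SNP error undefined for it",
                stacklevel=2,
            )
            continue
        mism = compared = 0
        for key in shared:
            ca, cb = la[key], lb[key]
            if len(ca) != len(cb):
                raise ValueError(f"locus {key!r}: call sequences differ in length")
            compared += len(ca)
            mism += sum(1 for x, y in zip(ca, cb) if x != y)
        es_values.append(mism / compared if compared else 0.0)
    EL = float(np.mean(el_values))
    ES = float(np.mean(es_values)) if es_values else float("nan")
    return EL, ES


def assembly_score(
    EL: float, ES: float, MS: float, mu: float = 50.0, sigma: float = 50.0
) -> float:
    """(1-EL)(1-ES) * Gaussian kernel of the missing-data percentage."""
    if not (0.0 <= EL <= 1.0 and 0.0 <= ES <= 1.0):
        raise ValueError("EL and ES must lie in [0, 1]")
    if not (0.0 <= MS <= 100.0):
        raise ValueError("MS is a percentage in [0, 100]")
    g = np.exp(-((MS - mu) ** 2) / (2.0 * sigma**2))
    return float((1.0 - EL) * (1.0 - ES) * g)


def grid_select(
    rows: list[AssemblyMetrics], mu: float = 50.0, sigma: float = 50.0
) -> tuple[AssemblyMetrics, list[AssemblyMetrics]]:
    """Best assembly by score; ties broken by lower EL, lower ES, MS near mu.

    Returns the winner and the full table ranked best-first (scores filled
    in place).
    """
    if not rows:
        raise ValueError("no assemblies to rank")
    for r in rows:
        r.score = assembly_score(r.EL, r.ES, r.MS, mu, sigma)
    ranked = sorted(rows, key=lambda r: (-r.score, r.EL, r.ES, abs(r.MS - mu)))
    return ranked[0], ranked


@dataclass
class Curve:
    """Model fit against model complexity, x strictly increasing."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length vectors")
        if len(self.x) < 3:
            raise ValueError("knee detection needs at least three points")
        if not (np.diff(self.x) > 0).all():
            raise ValueError("x must be strictly increasing")


def kneedle(
    curve: Curve, sensitivity: float = 1.0, shape: str = "concave-increasing"
) -> float | None:
    """Knee of a curve per the Kneedle algorithm.

    x and y are min-max normalized, the difference curve
    ``y_d = y_n - x_n`` is formed (after orienting the curve to
    concave-increasing), and each local maximum of ``y_d`` is a knee
    candidate, accepted when the difference curve drops below the
    threshold ``T = y_d(max) - S * mean(dx_n)`` before the next local
    maximum.  Returns the x of the first accepted knee, or None.

    ``shape='auto'`` flips a convex or decreasing curve into the concave-
    increasing orientation first; ``'concave-increasing'`` requires that
    orientation and returns None if the curve is convex.
    """
    x, y = curve.x, curve.y
    xn = (x - x.min()) / (x.max() - x.min())
    yspan = y.max() - y.min()
    if yspan == 0:
        return None
    yn = (y - y.min()) / yspan

    flipped = False
    if yn[-1] < yn[0]:  # decreasing: mirror in x, preserving concavity
        if shape != "auto":
            return None
        xn, yn, flipped = 1.0 - xn[::-1], yn[::-1], True
    ydiff = yn - xn
    if ydiff.sum() < 0:  # convex under the concave orientation
        if shape != "auto":
            return None
        ydiff = -ydiff
    if np.allclose(ydiff, 0.0):
        return None
    x_oriented = x[::-1] if flipped else x

    maxima = [
        i
        for i in range(1, len(ydiff) - 1)
        if ydiff[i] >= ydiff[i - 1] and ydiff[i] > ydiff[i + 1]
    ]
    if not maxima:
        return None
    threshold_drop = sensitivity * float(np.mean(np.diff(xn)))
    for mi, i in enumerate(maxima):
        t = ydiff[i] - threshold_drop
        stop = maxima[mi + 1] if mi + 1 < len(maxima) else len(ydiff)
        for j in range(i + 1, stop):
            if ydiff[j] < t:
                return float(x_oriented[i])
    return None


def max_distance_knee(curve: Curve) -> float:
    """Brute-force knee: point farthest above the chord between endpoints."""
    x, y = curve.x, curve.y
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / (y.max() - y.min())
    chord = yn[0] + (yn[-1] - yn[0]) * xn
    return float(x[int(np.argmax(yn - chord))])
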