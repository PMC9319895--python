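"""Pairwise genetic distances on SNP matrices and principal coordinates.

Two distances feed the clustering stage: the Kimura two-parameter (K2P)
distance on the concatenated SNP characters (pairwise deletion of missing
or ambiguous calls) and Nei's standard genetic distance computed on
per-individual allele-frequency vectors at each SNP.  Pairs for which a
distance is mathematically undefined (no shared sites, or a non-positive
log argument) are flagged, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .snp import IUPAC_PAIRS, MISSING, SnpMatrix

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with explicit undefined cells."""

    labels: list[str]
    d: np.ndarray
    undefined: np.ndarray  # boolean mask, True where the distance is undefined

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        n = len(self.labels)
        if self.d.shape != (n, n) or self.undefined.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_undefined(self) -> bool:
        return bool(self.undefined.any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.undefined[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out

    def drop_undefined_samples(self) -> "DistanceMatrix":
        """Greedily drop samples involved in undefined pairs (most first)."""
        und = self.undefined.copy()
        np.fill_diagonal(und, False)
        keep = np.ones(self.n, dtype=bool)
        while und[np.ix_(keep, keep)].any():
            counts = np.where(keep, und[:, keep].sum(axis=1), -1)
            keep[int(np.argmax(counts))] = False
        idx = np.where(keep)[0]
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            self.d[np.ix_(idx, idx)],
            und[np.ix_(idx, idx)],
        )

    def to_dataframe(self):
        import pandas as pd

        d = self.d.copy()
        d[self.undefined] = np.nan
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def write_phylip(self, path) -> None:
        """PHYLIP square-matrix format; undefined cells written as nan."""
        d = self.d.copy()
        d[self.undefined] = np.nan
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, d):
                vals = " ".join(f"{v:.10f}" for v in row)
                fh.write(f"{label}  {vals}\n")

    @classmethod
    def read_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split()
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        d = np.asarray(rows)
        if d.shape != (n, n):
            raise ValueError(f"header promises {n}x{n}, file has {d.shape}")
        und = np.isnan(d)
        return cls(labels, np.where(und, 0.0, d), und)


def _haploid_ints(matrix: SnpMatrix) -> np.ndarray:
    """Codes as ints: A,C,G,T = 0..3; missing/ambiguous = -1."""
    lut = {c: -1 for c in MISSING | set(IUPAC_PAIRS)}
    lut.update({"A": 0, "C": 1, "G": 2, "T": 3})
    out = np.empty(matrix.codes.shape, dtype=np.int8)
    for code, val in lut.items():
        out[matrix.codes == code] = val
    return out


def k2p_distance(matrix: SnpMatrix, het_as_missing: bool = True) -> DistanceMatrix:
    """Kimura two-parameter distance with pairwise deletion.

    For each pair, sites where either call is missing (or heterozygous,
    since the K2P model is defined on haploid bases; see
    ``het_as_missing``) are deleted.  With transition fraction P and
    transversion fraction Q over the retained sites,

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

    ``het_as_missing=False`` splits each diploid call into two haploid
    alleles and compares the per-pair expected fractions instead.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    n = matrix.n_samples
    d = np.zeros((n, n))
    und = np.zeros((n, n), dtype=bool)
    if het_as_missing:
        ints = _haploid_ints(matrix)
        valid = ints >= 0
        purine = (ints == 0) | (ints == 2)
        for i in range(n):
            for j in range(i + 1, n):
                shared = valid[i] & valid[j]
                m = int(shared.sum())
                if m == 0:
                    und[i, j] = und[j, i] = True
                    continue
                diff = shared & (ints[i] != ints[j])
                ts = diff & (purine[i] == purine[j])
                P = ts.sum() / m
                Q = (diff.sum() - ts.sum()) / m
                d[i, j] = d[j, i] = _k2p_formula(P, Q, und, i, j)
    else:
        dos = matrix.dosage()
        ref, alt = matrix.site_alleles()
        pur = np.isin(ref, ["A", "G"]) == np.isin(alt, ["A", "G"])
        for i in range(n):
            for j in range(i + 1, n):
                shared = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
                m = int(shared.sum())
                if m == 0:
                    und[i, j] = und[j, i] = True
                    continue
                # expected fraction of differing allele draws per site
                fi, fj = dos[i, shared] / 2.0, dos[j, shared] / 2.0
                pdiff = fi * (1 - fj) + (1 - fi) * fj
                ts_mask = pur[shared]
                P = float(pdiff[ts_mask].sum()) / m
                Q = float(pdiff[~ts_mask].sum()) / m
                d[i, j] = d[j, i] = _k2p_formula(P, Q, und, i, j)
    return DistanceMatrix(list(matrix.sample_ids), d, und)


def _k2p_formula(P: float, Q: float, und: np.ndarray, i: int, j: int) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        und[i, j] = und[j, i] = True
        return 0.0
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def nei_snp_distance(matrix: SnpMatrix) -> DistanceMatrix:
    """Nei's standard genetic distance on per-individual SNP frequencies.

    Each genotype is an allele-frequency vector over the site's two
    alleles ((1,0), (.5,.5) or (0,1)); with per-pair means over shared
    sites J_xy, J_x, J_y of the allele-frequency inner products,
    I = J_xy / sqrt(J_x J_y) and d = -ln I.  I <= 0 is flagged undefined.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    dos = matrix.dosage()
    n = matrix.n_samples
    f_alt = dos / 2.0
    f_ref = 1.0 - f_alt
    self_j = f_ref**2 + f_alt**2  # per-site J of each individual
    d = np.zeros((n, n))
    und = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            if not shared.any():
                und[i, j] = und[j, i] = True
                continue
            jxy = float(
                np.mean(
                    f_ref[i, shared] * f_ref[j, shared]
                    + f_alt[i, shared] * f_alt[j, shared]
                )
            )
            jx = float(np.mean(self_j[i, shared]))
            jy = float(np.mean(self_j[j, shared]))
            identity = jxy / np.sqrt(jx * jy)
            if identity <= 0.0:
                und[i, j] = und[j, i] = True
            else:
                d[i, j] = d[j, i] = -np.log(min(identity, 1.0))
    return DistanceMatrix(list(matrix.sample_ids), d, und)


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of a distance matrix."""

    coords: np.ndarray  # samples x positive-eigenvalue axes, scaled by sqrt(eig)
    eigenvalues: np.ndarray  # non-increasing, positive only
    retained_axes: int
    variance_explained: np.ndarray  # fractions of the positive-eigenvalue total
    labels: list[str]

    @property
    def retained(self) -> np.ndarray:
        """Coordinates restricted to the retained axes."""
        return self.coords[:, : self.retained_axes]


def pcoa(dist: DistanceMatrix, variance_threshold: float = 0.8) -> PcoaResult:
    """Classical (Gower) principal coordinates analysis.

    Negative eigenvalues are dropped from both the coordinates and the
    variance denominator; the retained axes are the smallest prefix whose
    cumulative variance fraction reaches ``variance_threshold``.
    """
    if dist.has_undefined():
        pairs = dist.undefined_pairs()
        raise ValueError(
            "distance matrix contains undefined cells; impute or drop samples "
            f"first (offending pairs: {pairs})"
        )
    d = dist.d
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval).max(initial=1.0), 0.0)
    if not pos.any():
        # fully degenerate (e.g. all-zero distances): one axis of zeros
        return PcoaResult(
            np.zeros((n, 1)), np.zeros(1), 1, np.array([1.0]), list(dist.labels)
        )
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    coords = eigvec * np.sqrt(eigval)
    frac = eigval / eigval.sum()
    retained = int(np.searchsorted(np.cumsum(frac), variance_threshold - 1e-12) + 1)
    retained = min(retained, coords.shape[1])
    return PcoaResult(coords, eigval, retained, frac, list(dist.labels))
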