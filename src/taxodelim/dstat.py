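"""Patterson's D (ABBA-BABA) screening of individuals for hybrid origin.

For a triplet (P1, P2, P3) plus an outgroup, site patterns where P2 and P3
share a derived allele against P1 (ABBA) are balanced against patterns
where P1 and P3 share it (BABA) under incomplete lineage sorting alone;
an excess of one class signals introgression into P2 (or P1).  Derived
allele frequencies of diploid individuals take values 0, 0.5, 1, and the
frequency-weighted pattern sums are

    abba = sum (1-p1) p2 p3 (1-p4),   baba = sum p1 (1-p2) p3 (1-p4),

with D = (abba - baba) / (abba + baba).  Significance comes from a site
(or locus) bootstrap: Z = D / sd(D_boot), two-sided normal p, Bonferroni
corrected over the executed tests of a screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .snp import SnpMatrix


@dataclass
class DTestSpec:
    """One ABBA-BABA test: three sample ids plus an outgroup taxon."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ValueError("the four roles must be distinct")


@dataclass
class DStatResult:
    spec: DTestSpec
    abba: float
    baba: float
    D: float
    bootstrap_sd: float
    Z: float
    p: float
    p_corrected: float = np.nan  # uncapped Bonferroni product
    p_corrected_capped: float = np.nan
    undefined: bool = False
    n_sites: int = 0


def _outgroup_consensus(matrix: SnpMatrix, outgroup: str) -> np.ndarray:
    """Per-site majority allele of the outgroup taxon as alt-dosage 0/2.

    Returns the consensus alt-allele frequency (0.0 or 1.0) per site, nan
    where the consensus is tied or entirely missing.
    """
    samples = matrix.samples_of(outgroup)
    if not samples:
        raise ValueError(f"outgroup taxon {outgroup!r} has no samples")
    dos = matrix.dosage()
    idx = [matrix.row(s) for s in samples]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(dos[idx], axis=0) / 2.0
    cons = np.full(matrix.n_sites, np.nan)
    cons[mean < 0.5] = 0.0
    cons[mean > 0.5] = 1.0
    return cons


def pattersons_d(matrix: SnpMatrix, spec: DTestSpec) -> DStatResult:
    """Patterson's D for one triplet, bootstrap significance included.

    The outgroup role is the majority consensus of a taxon (``spec.outgroup``
    names a taxon label; a plain sample id works too and acts as a
    single-member taxon).  Sites with missing data in any role, or a tied
    outgroup consensus, are excluded.  The bootstrap resamples loci when
    ``matrix.locus_ids`` is present, sites otherwise; identical per-unit
    (abba, baba) contributions are aggregated so the resampling is a small
    multinomial draw.
    """
    dos = matrix.dosage()
    if spec.outgroup in matrix.sample_ids:
        og = dos[matrix.row(spec.outgroup)] / 2.0
        og = np.where(og == 0.5, np.nan, np.round(og))
    else:
        og = _outgroup_consensus(matrix, spec.outgroup)

    rows = [matrix.row(s) for s in (spec.p1, spec.p2, spec.p3)]
    p = dos[rows] / 2.0
    keep = ~np.isnan(p).any(axis=0) & ~np.isnan(og)
    if not keep.any():
        return DStatResult(spec, 0.0, 0.0, np.nan, np.nan, np.nan, 1.0,
                           undefined=True)
    p = p[:, keep]
    p4 = og[keep]
    # polarize so the outgroup consensus is ancestral (frequency 0)
    flip = p4 == 1.0
    p = np.where(flip, 1.0 - p, p)
    abba_i = (1.0 - p[0]) * p[1] * p[2]
    baba_i = p[0] * (1.0 - p[1]) * p[2]
    abba, baba = float(abba_i.sum()), float(baba_i.sum())
    n_used = int(keep.sum())
    if abba + baba == 0.0:
        return DStatResult(spec, abba, baba, np.nan, np.nan, np.nan, 1.0,
                           undefined=True, n_sites=n_used)
    D = (abba - baba) / (abba + baba)

    if matrix.locus_ids is not None:
        units = matrix.locus_ids[keep]
        uniq, inv = np.unique(units, return_inverse=True)
        ua = np.bincount(inv, weights=abba_i)
        ub = np.bincount(inv, weights=baba_i)
    else:
        ua, ub = abba_i, baba_i
    # aggregate identical (abba, baba) unit contributions -> multinomial
    pat = np.round(np.column_stack([ua, ub]), 12)
    upat, counts = np.unique(pat, axis=0, return_counts=True)
    n_units = int(counts.sum())
    rng = np.random.default_rng(spec.seed)
    w = rng.multinomial(n_units, counts / n_units, size=spec.n_bootstrap)
    ab = w @ upat[:, 0]
    bb = w @ upat[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        d_boot = (ab - bb) / (ab + bb)
    d_boot = d_boot[np.isfinite(d_boot)]
    sd = float(d_boot.std(ddof=1)) if d_boot.size > 1 else np.nan
    if not np.isfinite(sd) or sd == 0.0:
        z = np.inf if D != 0 else 0.0
    else:
        z = D / sd
    pval = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return DStatResult(spec, abba, baba, D, sd, z, pval, n_sites=n_used)


def enumerate_triplets(
    taxon_labels: dict[str, str],
    focal_taxa: list[str],
    outgroup: str,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[DTestSpec]:
    """All within-pair/across-taxon triplets for a hybrid screen.

    For every unordered focal-taxon pair (A, B): every unordered pair of
    distinct individuals of A fills (P1, P2) with each individual of B as
    P3, plus the mirrored specs with the pair drawn from B and P3 from A.
    The outgroup role is the designated outgroup taxon (consensus).
    """
    if outgroup in focal_taxa:
        raise ValueError("outgroup must be disjoint from the focal taxa")
    members = {t: [s for s, lb in taxon_labels.items() if lb == t] for t in focal_taxa}
    specs: list[DTestSpec] = []
    for ai in range(len(focal_taxa)):
        for bi in range(ai + 1, len(focal_taxa)):
            for pair_taxon, p3_taxon in (
                (focal_taxa[ai], focal_taxa[bi]),
                (focal_taxa[bi], focal_taxa[ai]),
            ):
                pool = members[pair_taxon]
                for i in range(len(pool)):
                    for j in range(i + 1, len(pool)):
                        for p3 in members[p3_taxon]:
                            specs.append(
                                DTestSpec(
                                    pool[i], pool[j], p3, outgroup,
                                    n_bootstrap=n_bootstrap,
                                    seed=int(
                                        np.random.SeedSequence(
                                            (seed, len(specs))
                                        ).generate_state(1)[0] % (2**31)
                                    ),
                                )
                            )
    return specs


@dataclass
class ScreenResult:
    results: list[DStatResult]
    hybrid_flags: list[str]
    n_tests: int
    alpha: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "p1": [r.spec.p1 for r in self.results],
                "p2": [r.spec.p2 for r in self.results],
                "p3": [r.spec.p3 for r in self.results],
                "outgroup": [r.spec.outgroup for r in self.results],
                "abba": [r.abba for r in self.results],
                "baba": [r.baba for r in self.results],
                "D": [r.D for r in self.results],
                "Z": [r.Z for r in self.results],
                "p": [r.p for r in self.results],
                "p_corrected": [r.p_corrected for r in self.results],
                "p_corrected_capped": [r.p_corrected_capped for r in self.results],
                "undefined": [r.undefined for r in self.results],
            }
        )


def dstat_screen(
    matrix: SnpMatrix,
    focal_taxa: list[str],
    outgroup: str,
    alpha: float = 0.01,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """Bonferroni-corrected ABBA-BABA screen over all enumerated triplets.

    A sample is flagged as a putative hybrid when it is the introgressed
    candidate of a significant test: the P2 role when D > 0, the P1 role
    when D < 0 (swapping P1 and P2 merely negates D, and each unordered
    pair is enumerated once).  Both the raw Bonferroni product and its
    truncation at 1.0 are stored.
    """
    specs = enumerate_triplets(
        matrix.taxon_labels, focal_taxa, outgroup, n_bootstrap=n_bootstrap, seed=seed
    )
    if not specs:
        return ScreenResult([], [], 0, alpha)
    results = [pattersons_d(matrix, s) for s in specs]
    m = len(results)
    flags: list[str] = []
    for r in results:
        r.p_corrected = r.p * m
        r.p_corrected_capped = min(1.0, r.p_corrected)
        if not r.undefined and r.p_corrected_capped < alpha:
            candidate = r.spec.p2 if r.D >= 0 else r.spec.p1
            if candidate not in flags:
                flags.append(candidate)
    return ScreenResult(results, flags, m, alpha)
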