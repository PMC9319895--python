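"""Synthetic diploid SNP matrices with hierarchical population structure.

Allele frequencies drift down a population tree under the Balding-Nichols
model: a branch with drift parameter ``F`` transforms the parental
frequency ``p`` into ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, so ``F`` plays the
role of the expected fixation index between parent and child.  Diploid
genotypes are then binomial draws from the tip frequency, encoded in the
one-character convention of :mod:`taxodelim.snp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .snp import BASES, PAIR_TO_IUPAC, SnpMatrix


@dataclass
class PopNode:
    """Node of the population-split hierarchy.

    ``f`` is the drift parameter of the branch leading *into* this node
    (ignored at the root).  Tips carry a label; internal nodes carry
    children.
    """

    label: str | None = None
    f: float | None = None
    children: list["PopNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["PopNode"]:
        if self.is_tip:
            return [self]
        out: list[PopNode] = []
        for c in self.children:
            out.extend(c.tips())
        return out


def star_tree(labels: list[str], f: float) -> PopNode:
    """Star phylogeny: every population splits from the root with drift f."""
    return PopNode(children=[PopNode(label=lb, f=f) for lb in labels])


@dataclass
class SpeciesModel:
    """Conditions for one simulated SNP dataset.

    Parameters
    ----------
    tree
        Rooted hierarchy of population splits, drift ``F`` in (0, 1) on
        every non-root branch.
    n_individuals
        Diploid individuals per tip (single int, or map tip label -> int).
    n_sites
        Number of unlinked biallelic SNPs.
    missing_rate
        Per-call independent missing probability in [0, 1).
    seed
        Seed for the generator; the simulation is a pure function of it.
    """

    tree: PopNode
    n_individuals: int | dict[str, int] = 6
    n_sites: int = 1000
    missing_rate: float = 0.0
    seed: int = 0

    def n_for(self, label: str) -> int:
        if isinstance(self.n_individuals, dict):
            return self.n_individuals[label]
        return int(self.n_individuals)

    def validate(self) -> None:
        tips = self.tree.tips()
        labels = [t.label for t in tips]
        if len(set(labels)) != len(labels) or None in labels:
            raise ValueError("tips must carry unique labels")
        for node, parent in _walk(self.tree):
            if parent is None:
                continue
            if node.f is None or not (0.0 < node.f < 1.0):
                name = node.label or "<internal>"
                raise ValueError(
                    f"branch into {name!r}: drift F={node.f!r} must lie strictly "
                    "inside (0, 1), otherwise the Beta drift parameters are "
                    "non-finite"
                )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        for lb in labels:
            if self.n_for(lb) < 1:
                raise ValueError(f"tip {lb!r} needs at least one individual")


def _walk(node: PopNode, parent: PopNode | None = None):
    yield node, parent
    for c in node.children:
        yield from _walk(c, node)


def _drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    q = rng.beta(a, b)
    return np.clip(q, 1e-9, 1.0 - 1e-9)


def simulate_snp_matrix(model: SpeciesModel) -> tuple[SnpMatrix, dict[str, str]]:
    """Simulate genotypes under the drift model.

    Returns the matrix and the true sample -> population map (identical to
    the matrix's ``taxon_labels``; returned separately so callers can
    relabel samples without losing the truth).
    """
    model.validate()
    rng = np.random.default_rng(model.seed)
    m = model.n_sites

    anc = rng.uniform(0.05, 0.95, size=m)

    # ref/alt letters per site, distinct
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref = np.array(list(BASES))[ref_idx]
    alt = np.array(list(BASES))[alt_idx]

    tip_freq: dict[str, np.ndarray] = {}

    def descend(node: PopNode, p: np.ndarray) -> None:
        for child in node.children:
            q = _drift(rng, p, child.f)
            if child.is_tip:
                tip_freq[child.label] = q
            else:
                descend(child, q)

    if model.tree.is_tip:
        tip_freq[model.tree.label] = anc
    else:
        descend(model.tree, anc)

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    rows: list[np.ndarray] = []
    het = np.array(
        [PAIR_TO_IUPAC[frozenset((r, a))] for r, a in zip(ref, alt)], dtype="U1"
    )
    for tip in model.tree.tips():
        lb = tip.label
        for i in range(model.n_for(lb)):
            sid = f"{lb}_{i:02d}"
            dos = rng.binomial(2, tip_freq[lb])
            codes = np.where(dos == 0, ref, np.where(dos == 2, alt, het))
            if model.missing_rate > 0:
                mask = rng.random(m) < model.missing_rate
                codes = np.where(mask, "N", codes)
            sample_ids.append(sid)
            labels[sid] = lb
            rows.append(codes)

    matrix = SnpMatrix(sample_ids, dict(labels), np.asarray(rows, dtype="U1"))
    return matrix, labels


def inject_hybrid(
    matrix: SnpMatrix,
    parent_a: str,
    parent_b: str,
    label: str = "hybrid",
    seed: int = 0,
    backcross_fraction: float = 0.5,
    taxon: str | None = None,
) -> SnpMatrix:
    """Append an F1-like hybrid between two taxa.

    At every site one allele is drawn from each parent taxon's empirical
    allele frequencies.  ``backcross_fraction`` is the expected fraction
    of the hybrid's alleles that come from ``parent_b``: 0.5 (default)
    is a strict F1 (exactly one allele per parent per site), 0.25 an
    F1 x parent_a backcross, 1.0 a pure ``parent_b`` genotype.  Existing
    samples are untouched.  The new sample is filed under ``taxon``
    (default: ``parent_a``), mimicking a hybrid individual hiding inside
    a morpho-species.
    """
    for t in (parent_a, parent_b):
        if not matrix.samples_of(t):
            raise ValueError(f"unknown parent taxon {t!r}")
    rng = np.random.default_rng(seed)
    ref, alt, dos = matrix._dosage()

    def taxon_freq(taxon: str) -> np.ndarray:
        idx = [matrix.row(s) for s in matrix.samples_of(taxon)]
        with np.errstate(invalid="ignore"):
            f = np.nanmean(dos[idx], axis=0) / 2.0
        return np.nan_to_num(f, nan=0.0)

    fa, fb = taxon_freq(parent_a), taxon_freq(parent_b)
    m_sites = matrix.n_sites
    # per-site parental origin of the two allele slots; at 0.5 the second
    # slot always comes from parent_b and the first never does (strict F1)
    f = float(backcross_fraction)
    slot1_b = rng.random(m_sites) < max(0.0, 2.0 * f - 1.0)
    slot2_b = rng.random(m_sites) < min(1.0, 2.0 * f)
    allele_1 = rng.random(m_sites) < np.where(slot1_b, fb, fa)
    allele_2 = rng.random(m_sites) < np.where(slot2_b, fb, fa)
    n_alt = allele_1.astype(int) + allele_2.astype(int)

    het = np.array(
        [
            PAIR_TO_IUPAC[frozenset((r, a))] if a != r else r
            for r, a in zip(ref, alt)
        ],
        dtype="U1",
    )
    codes = np.where(n_alt == 0, ref, np.where(n_alt == 2, alt, het))
    codes = np.where(ref == "N", "N", codes)

    new_codes = np.vstack([matrix.codes, codes[None, :]])
    ids = list(matrix.sample_ids) + [label]
    labels = dict(matrix.taxon_labels)
    labels[label] = taxon if taxon is not None else parent_a
    return SnpMatrix(ids, labels, new_codes, matrix.locus_ids)
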