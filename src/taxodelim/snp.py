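"""Diploid SNP matrices in one-character-per-genotype encoding.

Genotypes are stored the way concatenated-SNP assembler output encodes
them: a homozygote is the plain base (``A C G T``), a heterozygote is the
two-base IUPAC ambiguity code (``R Y S W K M``), and a missing call is
``N`` or ``-``.  One row per sample, one column per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: IUPAC two-base ambiguity codes -> unordered base pair.
IUPAC_PAIRS: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
#: base pair -> ambiguity code
PAIR_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_PAIRS.items()}

MISSING = frozenset("N-?")
BASES = "ACGT"
ALPHABET = frozenset(BASES) | frozenset(IUPAC_PAIRS) | MISSING


@dataclass
class SnpMatrix:
    """Samples x biallelic-SNP genotype codes with taxon labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``codes``.
    taxon_labels
        Mapping sample id -> taxon name.
    codes
        ``(n_samples, n_sites)`` array of single characters from the
        genotype alphabet.
    locus_ids
        Optional per-site locus identifiers (RAD locus of origin); used
        as the bootstrap resampling unit when present.
    """

    sample_ids: list[str]
    taxon_labels: dict[str, str]
    codes: np.ndarray
    locus_ids: np.ndarray | None = None
    _dosage_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="U1")
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x sites)")
        if len(self.sample_ids) != self.codes.shape[0]:
            raise ValueError("row count must equal number of sample ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = set(np.unique(self.codes)) - set(ALPHABET)
        if bad:
            raise ValueError(f"codes outside genotype alphabet: {sorted(bad)}")
        missing = np.isin(self.codes, list(MISSING))
        if self.codes.shape[1] and missing.all(axis=1).any():
            i = int(np.where(missing.all(axis=1))[0][0])
            raise ValueError(f"sample {self.sample_ids[i]!r} has no non-missing call")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def taxa(self) -> list[str]:
        """Distinct taxon labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.taxon_labels[s], None)
        return list(seen)

    def samples_of(self, taxon: str) -> list[str]:
        return [s for s in self.sample_ids if self.taxon_labels[s] == taxon]

    def row(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset(self, keep: list[str]) -> "SnpMatrix":
        idx = [self.row(s) for s in keep]
        return SnpMatrix(
            list(keep),
            {s: self.taxon_labels[s] for s in keep},
            self.codes[idx],
            self.locus_ids,
        )

    def drop_samples(self, drop: list[str]) -> "SnpMatrix":
        return self.subset([s for s in self.sample_ids if s not in set(drop)])

    def site_alleles(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference/alternative allele per site, inferred from the data.

        The two alleles observed at a site (from homozygote and ambiguity
        codes) in lexicographic order.  Monomorphic sites get alt == ref;
        sites with more than two alleles raise.
        """
        ref, alt, _ = self._dosage()
        return ref, alt

    def dosage(self) -> np.ndarray:
        """Per-sample count of the alternative allele, ``nan`` = missing."""
        return self._dosage()[2]

    def _dosage(self):
        if self._dosage_cache is not None:
            return self._dosage_cache
        n, m = self.codes.shape
        ref = np.empty(m, dtype="U1")
        alt = np.empty(m, dtype="U1")
        dos = np.full((n, m), np.nan)
        for j in range(m):
            col = self.codes[:, j]
            alleles: set[str] = set()
            for c in col:
                if c in MISSING:
                    continue
                alleles |= IUPAC_PAIRS.get(c, frozenset(c))
            if len(alleles) > 2:
                raise ValueError(f"site {j} has {len(alleles)} alleles; expected <= 2")
            if not alleles:
                ref[j] = alt[j] = "N"
                continue
            pair = sorted(alleles)
            ref[j] = pair[0]
            alt[j] = pair[-1]
            het = PAIR_TO_IUPAC.get(frozenset(pair)) if len(pair) == 2 else None
            dos[col == ref[j], j] = 0.0
            if len(pair) == 2:
                dos[col == alt[j], j] = 2.0
                if het is not None:
                    dos[col == het, j] = 1.0
        object.__setattr__(self, "_dosage_cache", (ref, alt, dos))
        return ref, alt, dos


def encode_genotype(ref: str, alt: str, n_alt: int) -> str:
    """One-character genotype code from an alt-allele count (0, 1 or 2)."""
    if n_alt == 0:
        return ref
    if n_alt == 2:
        return alt
    return PAIR_TO_IUPAC[frozenset((ref, alt))]


# ---------------------------------------------------------------------------
# readers / writers


def write_phylip(matrix: SnpMatrix, path) -> None:
    """Concatenated-SNP matrix in relaxed PHYLIP form (``id  codes``)."""
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_samples} {matrix.n_sites}\n")
        for i, s in enumerate(matrix.sample_ids):
            fh.write(f"{s}  {''.join(matrix.codes[i])}\n")


def read_phylip(path, taxon_labels: dict[str, str] | None = None) -> SnpMatrix:
    """Read a relaxed-PHYLIP concatenated-SNP matrix.

    ``taxon_labels`` maps sample id -> taxon; samples absent from the map
    get their own id as taxon.
    """
    with open(path) as fh:
        header = fh.readline().split()
        n, m = int(header[0]), int(header[1])
        ids, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.strip().replace(" ", "")
            ids.append(name)
            rows.append(list(seq.upper()))
    codes = np.asarray(rows, dtype="U1")
    if codes.shape != (n, m):
        raise ValueError(f"header promises {(n, m)}, file contains {codes.shape}")
    labels = {s: (taxon_labels or {}).get(s, s) for s in ids}
    return SnpMatrix(ids, labels, codes)


def write_vcf(matrix: SnpMatrix, path, chrom: str = "1") -> None:
    """Minimal VCF 4.2 with GT fields only (biallelic rows)."""
    ref, alt, dos = matrix._dosage()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={matrix.n_sites + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(matrix.n_sites):
            if ref[j] == "N":
                continue
            a = alt[j] if alt[j] != ref[j] else "."
            gts = [
                "./." if np.isnan(dos[i, j]) else gt_map[dos[i, j]]
                for i in range(matrix.n_samples)
            ]
            fh.write(
                f"{chrom}\t{j + 1}\tsnp{j}\t{ref[j]}\t{a}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path, taxon_labels: dict[str, str] | None = None) -> SnpMatrix:
    """Read a GT-only VCF with single-base biallelic rows (via cyvcf2)."""
    from cyvcf2 import VCF

    reader = VCF(str(path))
    ids = list(reader.samples)
    cols: list[list[str]] = []
    for var in reader:
        ref = var.REF
        alt = var.ALT[0] if var.ALT else ref
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError("only single-base biallelic rows are supported")
        col = []
        for a1, a2, *_ in var.genotypes:
            if a1 < 0 or a2 < 0:
                col.append("N")
            else:
                col.append(encode_genotype(ref, alt, a1 + a2) if alt != ref else ref)
        cols.append(col)
    codes = np.asarray(cols, dtype="U1").T
    labels = {s: (taxon_labels or {}).get(s, s) for s in ids}
    return SnpMatrix(ids, labels, codes)
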