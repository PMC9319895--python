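"""Per-pair evidence integration and taxonomic rank decisions.

Each candidate taxon pair carries Bonferroni-corrected p-values from four
evidence layers -- niche overlap (Schoener's D equivalency test), overall
leaf shape (EFA permutation test), leaf dissection (Welch test on LDI),
and geography (sympatry permutation test) -- plus a genealogical
distinctness flag from the clustering stage.  The ranking follows a
morpho-geographical species concept: genealogically distinct lineages
are species when sympatric (cryptic species if not morphologically
distinct), or when allopatric but ecologically distinct; allopatric
ecologically similar lineages are subspecies; without genealogical
distinctness, ecological differentiation at best marks an ecotype, and
its absence argues for merging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("niche", "efa", "ldi", "geo")

VERDICTS = (
    "species",
    "cryptic-species",
    "subspecies",
    "ecotype",
    "merge",
    "undecided",
)


@dataclass
class EvidenceTable:
    """Machine twin of a per-pair significance table."""

    rows: pd.DataFrame  # index: "taxonA|taxonB"; columns per layer
    bonferroni_m: int
    alpha: float = 0.05

    def pair_flags(self, pair: str) -> dict[str, bool | None]:
        """Significance flags at alpha from the capped corrected p-values."""
        row = self.rows.loc[pair]
        flags: dict[str, bool | None] = {}
        for layer in LAYERS:
            p = row[f"p_{layer}_capped"]
            flags[layer] = None if pd.isna(p) else bool(p < self.alpha)
        return flags


def pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def build_evidence_table(
    results: dict[str, dict[str, float]],
    bonferroni_m: int,
    alpha: float = 0.05,
) -> EvidenceTable:
    """Assemble the evidence table from raw per-layer p-values.

    ``results`` maps pair key -> {layer: raw p}; missing layers are
    recorded as NaN and flagged unknown.  All layers share one Bonferroni
    multiplier; the uncapped product and its truncation at 1.0 are both
    stored.
    """
    records = {}
    for pair, layer_p in results.items():
        if pair in records:
            raise ValueError(f"duplicate pair {pair!r}")
        rec = {}
        for layer in LAYERS:
            raw = layer_p.get(layer, np.nan)
            rec[f"p_{layer}_raw"] = raw
            if np.isnan(raw):  # stage not run: stays an explicit gap
                rec[f"p_{layer}_corrected"] = np.nan
                rec[f"p_{layer}_capped"] = np.nan
            else:
                rec[f"p_{layer}_corrected"] = raw * bonferroni_m
                rec[f"p_{layer}_capped"] = min(1.0, raw * bonferroni_m)
        records[pair] = rec
    df = pd.DataFrame.from_dict(records, orient="index")
    return EvidenceTable(df, bonferroni_m, alpha)


@dataclass
class RankDecision:
    pair: str
    genealogically_distinct: bool | None
    sympatric: bool | None
    eco_distinct: bool | None
    morpho_distinct: bool | None
    verdict: str
    rationale: str


def rank_decision(
    pair: str,
    genealogically_distinct: bool | None,
    sympatric: bool | None,
    eco_distinct: bool | None,
    morpho_distinct: bool | None,
) -> RankDecision:
    """Map evidence flags to a rank verdict via the rule table.

    sympatric means the geographic test did NOT reject sympatry (absence
    of a significant allopatry signal).  Unknown (None) inputs needed by
    the applicable rule yield ``undecided`` with the gaps listed.
    """

    def decide() -> tuple[str, str]:
        if genealogically_distinct is None:
            return "undecided", "genealogical distinctness unknown"
        if genealogically_distinct:
            if sympatric is None:
                return "undecided", "geographic overlap unknown"
            if sympatric:
                if morpho_distinct is None:
                    return (
                        "species",
                        "distinct lineage, sympatric; morphology unknown so "
                        "cryptic status unresolved",
                    )
                if morpho_distinct:
                    return (
                        "species",
                        "genealogically distinct and sympatric, morphologically "
                        "appreciable",
                    )
                return (
                    "cryptic-species",
                    "genealogically distinct and sympatric but morphologically "
                    "inseparable",
                )
            if eco_distinct is None:
                return "undecided", "allopatric; ecological distinctness unknown"
            if eco_distinct:
                return (
                    "species",
                    "allopatric but ecologically distinct: reproductive "
                    "isolation expected in potential sympatry",
                )
            return (
                "subspecies",
                "allopatric and ecologically similar: geographic race of one "
                "species",
            )
        # not genealogically distinct
        if eco_distinct is None:
            return "undecided", "no lineage separation; ecology unknown"
        if eco_distinct:
            return (
                "ecotype",
                "no genealogical independence; ecological deviation marks an "
                "ecotype, at best a subspecies",
            )
        return "merge", "no genealogical, ecological or geographic independence"

    verdict, why = decide()
    return RankDecision(
        pair, genealogically_distinct, sympatric, eco_distinct, morpho_distinct,
        verdict, why,
    )


def decide_all(
    table: EvidenceTable, genealogical: dict[str, bool | None]
) -> list[RankDecision]:
    """Rank every pair of the evidence table.

    Ecological distinctness comes from the niche layer, morphological
    distinctness from EFA or LDI (either significant), sympatry from the
    geographic layer NOT rejecting sympatry.
    """
    out = []
    for pair in table.rows.index:
        flags = table.pair_flags(pair)
        morpho: bool | None
        if flags["efa"] is None and flags["ldi"] is None:
            morpho = None
        else:
            morpho = bool(flags["efa"]) or bool(flags["ldi"])
        sym = None if flags["geo"] is None else not flags["geo"]
        out.append(
            rank_decision(
                pair,
                genealogical.get(pair),
                sym,
                flags["niche"],
                morpho,
            )
        )
    return out


@dataclass
class PipelineReport:
    evidence: EvidenceTable
    decisions: list[RankDecision]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "bonferroni_m": self.evidence.bonferroni_m,
            "alpha": self.evidence.alpha,
            "evidence": json.loads(
                self.evidence.rows.replace({np.nan: None}).to_json(orient="index")
            ),
            "decisions": [
                {
                    "pair": d.pair,
                    "genealogically_distinct": d.genealogically_distinct,
                    "sympatric": d.sympatric,
                    "eco_distinct": d.eco_distinct,
                    "morpho_distinct": d.morpho_distinct,
                    "verdict": d.verdict,
                    "rationale": d.rationale,
                }
                for d in self.decisions
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(config: dict) -> PipelineReport:
    """Run the bundled synthetic three-scenario study end to end.

    The demo builds three taxon pairs on synthetic landscapes and leaves:

    * a sympatric, genealogically distinct, morphologically distinct pair
      (expected verdict: species),
    * an allopatric, genealogically distinct, ecologically distinct pair
      (expected verdict: species),
    * an undifferentiated pair (expected verdict: merge).

    ``config`` keys (all optional): seed, alpha, n_perm_geo, n_perm_niche,
    n_perm_shape, n_occurrences, grid, stages (iterable subset of
    {"niche", "geo", "shape"}).
    """
    from .geo import niche_equivalency_test, sympatry_test
    from .leaf.efa import efa, efa_pca
    from .leaf.stats import ldi, ldi_welch_test, shape_permutation_test
    from .sim_landscape import LandscapeModel, simulate_landscape
    from .sim_leaf import LeafModel, simulate_leaf_population

    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    n_geo = int(config.get("n_perm_geo", 199))
    n_niche = int(config.get("n_perm_niche", 199))
    n_shape = int(config.get("n_perm_shape", 999))
    n_occ = int(config.get("n_occurrences", 50))
    grid = int(config.get("grid", 36))
    stages = set(config.get("stages", {"niche", "geo", "shape"}))

    scenarios = {
        "sympatric_distinct": dict(
            scenario="sympatric", genealogical=True, dissection=(0.3, 2.5)
        ),
        "allopatric_eco": dict(
            scenario="allopatric", genealogical=True, dissection=(1.0, 1.0)
        ),
        "undifferentiated": dict(
            scenario="sympatric", genealogical=False, dissection=(1.0, 1.0)
        ),
    }
    m = len(scenarios) * 2  # correction shared across pairs and sides
    results: dict[str, dict[str, float]] = {}
    genealogical: dict[str, bool | None] = {}
    for i, (name, sc) in enumerate(scenarios.items()):
        ta, tb = f"{name}_A", f"{name}_B"
        pair = pair_key(ta, tb)
        genealogical[pair] = sc["genealogical"]
        layer_p: dict[str, float] = {}

        model = LandscapeModel(
            n_rows=grid,
            n_cols=grid,
            taxa=(ta, tb),
            scenario=sc["scenario"],
            n_occurrences=n_occ,
            seed=seed * 101 + i,
        )
        land = simulate_landscape(model)
        if "niche" in stages:
            res = niche_equivalency_test(
                land.occurrences[ta],
                land.occurrences[tb],
                land.layers,
                n_perm=n_niche,
                seed=seed * 919 + i,
            )
            layer_p["niche"] = res.p
        if "geo" in stages:
            res = sympatry_test(
                land.occurrences[ta],
                land.occurrences[tb],
                land.layers,
                n_perm=n_geo,
                seed=seed * 577 + i,
            )
            layer_p["geo"] = res.p
        if "shape" in stages:
            da, db = sc["dissection"]
            leaves_a = simulate_leaf_population(
                12, LeafModel(dissection=da), seed=seed * 31 + i, taxon=ta
            )
            leaves_b = simulate_leaf_population(
                12, LeafModel(dissection=db), seed=seed * 67 + i, taxon=tb
            )
            desc = [efa(s.contour) for _, s in leaves_a + leaves_b]
            scores, _, _ = efa_pca(desc)
            res = shape_permutation_test(
                scores[: len(leaves_a), :2],
                scores[len(leaves_a):, :2],
                n_perm=n_shape,
                seed=seed * 13 + i,
            )
            layer_p["efa"] = res.p
            ldi_a = [ldi(s.contour) for _, s in leaves_a]
            ldi_b = [ldi(s.contour) for _, s in leaves_b]
            p_ldi, _, _ = ldi_welch_test(ldi_a, ldi_b)
            layer_p["ldi"] = p_ldi
        results[pair] = layer_p

    table = build_evidence_table(results, bonferroni_m=m, alpha=alpha)
    decisions = decide_all(table, genealogical)
    return PipelineReport(
        table,
        decisions,
        metadata={
            "seed": seed,
            "alpha": alpha,
            "stages": sorted(stages),
            "bonferroni_m": m,
        },
    )
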