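"""Pairwise genetic distances and ordination of the synthetic SNP matrix.

Reads results/data/snps.phy, computes K2P (pairwise deletion) and
SNP-level Nei distances, embeds the K2P matrix by principal coordinates
(retaining the axes that explain 80% of the variance), and writes tidy
CSV outputs for the clustering stage.
"""

import json
from pathlib import Path

import pandas as pd

import taxodelim as td

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    labels = json.loads((ROOT / "data" / "taxon_map.json").read_text())
    matrix = td.read_phylip(ROOT / "data" / "snps.phy", labels)

    k2p = td.k2p_distance(matrix)
    nei = td.nei_snp_distance(matrix)
    k2p.to_dataframe().to_csv(ROOT / "dist_k2p.csv")
    nei.to_dataframe().to_csv(ROOT / "dist_nei.csv")
    print(
        f"K2P: mean off-diagonal {k2p.d[k2p.d > 0].mean():.4f}, "
        f"{len(k2p.undefined_pairs())} undefined pairs; "
        f"Nei: mean {nei.d[nei.d > 0].mean():.4f}"
    )

    coords = td.pcoa(k2p, variance_threshold=0.8)
    df = pd.DataFrame(
        coords.retained,
        index=coords.labels,
        columns=[f"PCo{i + 1}" for i in range(coords.retained_axes)],
    )
    df.to_csv(ROOT / "pcoa_coords.csv")
    frac = coords.variance_explained[: coords.retained_axes].sum()
    print(
        f"PCoA: {coords.retained_axes} axes retained, explaining "
        f"{100 * frac:.1f}% of the positive-eigenvalue variance "
        "-> pcoa_coords.csv"
    )


if __name__ == "__main__":
    main()
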