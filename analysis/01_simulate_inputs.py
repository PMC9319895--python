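"""Generate the synthetic study inputs and write them in field formats.

Products (under results/data/): a structured SNP matrix with one injected
F1 hybrid (PHYLIP + VCF + taxon map), leaf annotations for two shape
archetypes (CVAT XML), and a two-taxon landscape (ESRI ASCII grids,
GeoTIFF, occurrence CSV).  Everything downstream reads these files or
regenerates the same objects from the shared seed.
"""

import json
from pathlib import Path

import taxodelim as td
from taxodelim.geo import write_ascii_grid, write_geotiff, write_occurrences
from taxodelim.leaf import write_cvat

SEED = 20220719
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- genetic layer: 5 populations + outgroup, one hidden F1 hybrid
    taxa = [f"pop{i}" for i in range(1, 6)] + ["outgroup"]
    model = td.SpeciesModel(
        td.star_tree(taxa, 0.4), n_individuals=6, n_sites=4000,
        missing_rate=0.05, seed=SEED,
    )
    matrix, truth = td.simulate_snp_matrix(model)
    matrix = td.inject_hybrid(
        matrix, "pop1", "pop2", label="pop1_hyb", seed=SEED, taxon="pop1"
    )
    td.write_phylip(matrix, OUT / "snps.phy")
    td.write_vcf(matrix, OUT / "snps.vcf")
    (OUT / "taxon_map.json").write_text(
        json.dumps(matrix.taxon_labels, indent=1, sort_keys=True)
    )
    print(
        f"SNP matrix: {matrix.n_samples} samples x {matrix.n_sites} sites, "
        "one injected F1 (pop1_hyb) -> snps.phy / snps.vcf"
    )

    # --- morphological layer: two archetypes differing in dissection
    leaves = []
    for taxon, dissection, seed in (("taxA", 0.4, 1), ("taxB", 2.2, 2)):
        pop = td.simulate_leaf_population(
            15, td.LeafModel(dissection=dissection, bend_curvature=0.0012),
            seed=SEED + seed, taxon=taxon,
        )
        leaves += [bent for bent, _ in pop]
    write_cvat(leaves, OUT / "leaves_cvat.xml")
    print(f"Leaf annotations: {len(leaves)} bent leaves -> leaves_cvat.xml")

    # --- ecological/geographic layer: parapatric two-taxon landscape
    land = td.simulate_landscape(
        td.LandscapeModel(
            n_rows=40, n_cols=40, scenario="parapatric",
            taxa=("taxA", "taxB"), n_occurrences=60, seed=SEED,
        )
    )
    for i, layer in enumerate(land.layers):
        write_ascii_grid(layer, OUT / f"env_{i}.asc")
    write_geotiff(land.layers[0], OUT / "env_0.tif")
    write_occurrences(list(land.occurrences.values()), OUT / "occurrences.csv")
    print(
        f"Landscape: {len(land.layers)} env layers (ASCII + GeoTIFF), "
        f"{sum(len(o.points) for o in land.occurrences.values())} occurrence "
        "points -> env_*.asc / occurrences.csv"
    )


if __name__ == "__main__":
    main()
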