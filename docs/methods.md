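# Methods

`taxodelim` implements an integrative species-delimitation workflow for
closely related plant lineages: genetic *discovery* of clusters from SNP
data, a hybrid screen to remove introgressed individuals, and then three
independent evidence layers — leaf-shape morphometrics, ecological niche
comparison, and geographic overlap — integrated into a per-pair rank
decision under a morpho-geographical species concept.  This note records
the models, the parameter choices, and the places where the design was
genuinely open.

## Synthetic data

All stages are exercised on generated data with known structure; nothing
in the pipeline depends on downloads.

**Genotypes.** Allele frequencies drift down a population tree under the
Balding–Nichols model: a branch with drift parameter `F ∈ (0, 1)`
replaces the parental frequency `p` by a draw from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `F` is the expected fixation index
between parent and child.  Ancestral frequencies are uniform on
[0.05, 0.95]; diploid genotypes are `Binomial(2, p_tip)` and encoded in
the one-character concatenated-SNP convention (plain base = homozygote,
IUPAC two-base code = heterozygote, `N`/`-` = missing), so synthetic and
assembler-produced matrices share one reader.  Calls are masked missing
independently at the configured rate.  Defaults used across the bundled
study: 4–6 diploids per population, `F = 0.4` between well-separated
populations, 2 000–5 000 unlinked SNPs — enough drift and data that a
competent method should resolve the structure, without making the
problem trivial.  Hybrids are injected as strict F1s (one allele drawn
from each parent taxon's empirical frequencies per site); a
`backcross_fraction` parameter generalizes this (0.5 = F1).  What the
generator does *not* emulate: linkage within RAD loci, allele dropout,
coverage-dependent genotyping error, and gene-tree discordance beyond
drift.  Passing tests therefore certify the statistics, not robustness
to every artifact of real RADseq data.

**Leaves.** A silhouette is built in a canonical frame (base at the
origin, midvein along +x, y down, pixel units) from a smooth half-width
profile `W·sin(πu)^0.8·(1 − 0.35u)` — skewed toward the base, as real
leaves are — modulated by a lobe term whose depth is
`dissection/(1+dissection)`, with an optional smooth log-normal margin
perturbation for individual variation.  Bending maps the axis through a
constant-curvature arc; midvein vertices are placed chord-exactly on
the arc so the bent and straight polylines have identical cumulative
length, giving an analytic ground truth for the straightening stage.
Real leaves bend irregularly; constant curvature is used because it has
an exact inverse.  The midvein spans 1–99 % of the length: annotated
midveins stop short of the apices, and the chord-exact bent vertices
must stay inside the tapering outline.

**Landscapes.** Environmental layers are sums of seeded Gaussian bumps
on a lon/lat grid; the first two layers carry west–east and north–south
gradients so that environmental positions map to coherent regions.  A
taxon's true suitability is a Gaussian response around its niche center
in layer space, and occurrences are sampled without replacement with
probability proportional to suitability (with sub-cell jitter).  The
scenario places niche centers: identical (sympatric), adjacent
(parapatric), or read off opposite grid corners (allopatric).

## Genetic discovery

**Distances.** K2P uses pairwise deletion; heterozygous IUPAC calls are
treated as missing by default because the model is defined on haploid
bases (a `split-alleles` mode compares expected per-site allele draws
instead).  Pairs with no shared sites or a non-positive log argument are
flagged undefined — never silently zero — and principal coordinates
refuses to run until the caller imputes or drops samples (a greedy
drop-samples helper is provided).  The SNP-level Nei distance treats
each genotype as an allele-frequency vector ((1,0), (½,½), (0,1)) and
takes `d = −ln I` with `I = J_xy/√(J_x J_y)` over shared sites.

**Ordination.** Classical (Gower) PCoA; negative eigenvalues are dropped
from both the coordinates and the variance denominator (no Cailliez
correction), and the retained axes are the smallest prefix reaching 80 %
cumulative variance.  This is the simplest defensible reading of an
"axes explaining at least 80 % of the variance" rule.

**Consensus K-means.** Per replicate, ⌈0.8·n⌉ observations and ⌈0.8·p⌉
features are drawn without replacement and K-means (k-means++, one
initialization, Lloyd capped at 50 iterations) is run; co-clustering
counts over co-sampled pairs form the consensus matrix.  The replicate
engine is a small vectorized k-means so thousands of replicates on tens
of samples stay cheap and fully seed-controlled.  Final labels come from
average-linkage agglomeration of (1 − consensus) cut at k — the linkage
is configurable because the convention is not fixed by the method
itself.  Validity indices (silhouette with the contribute-zero singleton
rule; standard Davies–Bouldin, returning infinity for duplicated
centroids) are computed on the retained PCo coordinates with the
consensus-derived labels; using (1 − consensus) as the distance is
available behind a flag.  The scan reports the silhouette maximum, the
DB minimum, and DB local optima, and never arbitrates when they
disagree.  The default replicate count is 5 000; the bundled study and
tests use 500–1 000, where the indices have long stabilized at these
sample sizes.

## Hybrid screening

Patterson's D with derived-allele frequencies (0, ½, 1 per diploid
individual), polarized by the per-site majority consensus of a
designated outgroup taxon (tied or missing consensus drops the site).
Significance is a bootstrap over loci when locus ids exist, else over
sites; identical per-unit (abba, baba) contributions are aggregated so
the resampling is a single small multinomial draw — exactly the site
bootstrap, orders of magnitude faster.  `Z = D/sd`, two-sided normal p,
Bonferroni over the executed tests of the screen (uncapped product and
its truncation at 1.0 both stored).  Enumeration: for each unordered
focal-taxon pair, every within-taxon individual pair fills (P1, P2) with
every individual of the other taxon as P3, mirrored across the pair.
Because swapping P1 and P2 only negates D, each unordered pair is
enumerated once and the flagged hybrid candidate is P2 when D > 0 and
P1 when D < 0.  Exact |Z| preservation under a role swap is not
guaranteed bitwise (the bootstrap's category order changes); D negation
is exact and Z agrees within bootstrap noise.

## Assembly scoring and knee detection

The assembly score is `(1−EL)(1−ES)·exp(−(MS−μ)²/(2σ²))` with μ = σ =
50 by default, EL/ES the replicate-based locus and SNP error rates
(loci recovered in exactly one replicate over loci in at least one;
mismatching calls over calls compared at shared loci), and MS the
percent missing data.  The Gaussian factor is an unnormalized kernel
(1 at MS = μ), keeping the score in [0, 1]; the expression is treated
as a score to maximize.  Note the deliberate consequence of centering
at 50 %: an assembly with *less* missing data than μ scores lower, all
else equal.  Ties break by lower EL, then lower ES, then MS nearest μ.
Running the assembler itself is out of scope; the scorer consumes a
metrics table.

Kneedle: min–max normalize, form the difference curve `y_n − x_n` after
orienting to concave-increasing (decreasing curves are mirrored in x,
convex curves flipped — only under `shape='auto'`; the default rejects
non-concave input), take local maxima as candidates, and accept the
first whose difference curve drops below
`y_d(max) − S·mean(Δx_n)` before the next maximum (sensitivity S = 1).
The knee is invariant to affine rescaling of either axis.

## Leaf straightening and morphometrics

The contour polygon is split along the midvein (extended along its end
tangents to the contour where needed) into two half-polygons, each
triangulated by constrained Delaunay triangulation (GEOS, no Steiner
points) and merged; uniform 1-to-4 midpoint subdivision refines until no
triangle exceeds `max_triangle_area`, preserving triangle quality and
every constrained chain.  Straightening places the midvein chain on the
+x axis anchored at its basal vertex with consecutive spacing equal to
the original Euclidean spacing (arc length conserved exactly), and
solves the remaining vertices as-rigid-as-possibly: local step fits a
per-vertex rotation (closed form in 2-D:
`θ_i = atan2(Σ w e⁰×e¹, Σ w e⁰·e¹)`), global step solves the cotangent
Laplacian with the midvein as hard constraints; weights are clamped at
zero.  Iterations start from the rigid motion best aligning the midvein
to its target and stop when the maximum per-iteration displacement falls
below 1e-6 px; the cap is 400 iterations — local–global ARAP converges
linearly and typically needs 150–250 iterations at this tolerance on
the ~2 500-vertex meshes used here.  Texture transfer samples each
output pixel through shared barycentric coordinates with bilinear
interpolation.

Elliptic Fourier descriptors (Kuhl–Giardina, 15 harmonics) are
normalized for size, rotation and starting point via the first-harmonic
ellipse; the phase formula's quarter- and half-period ambiguities are
resolved deterministically from the geometry (minor-axis starts are
discarded by the |d1| > 1 criterion, the remaining pair by
lexicographic order), making the descriptors exactly invariant to input
rotation and starting vertex.  The DC terms are excluded; PCA of the
remaining coefficients is centered and unscaled (covariance PCA — the
coefficients share units, so correlation scaling would inflate the
noise harmonics).  The group test is a label permutation on the first
two PC scores with the mean cross-group pairwise Euclidean distance as
statistic (centroid distance available behind a flag), one-sided with
the +1 correction, so p is never 0.  LDI is
`perimeter/(2√(π·area))` on the straightened polygon (the deformed
polygon is used directly; no mask re-extraction), compared by Welch's
t test.  The straightened contour is taken from the deformed input
polygon vertices, not from a rasterized mask boundary.

## Niche and geography

Environmental stacks are z-scored per layer over valid cells and reduced
by PCA across cells; the no-data mask (union over layers) propagates.
Depth triplets of edaphic variables are averaged cell-wise ignoring
no-data.  The built-in niche model is an independent Gaussian envelope
per layer fitted on occurrence-cell values, with the suitability product
rescaled to max 1; an external suitability raster (e.g. exported from a
MaxEnt run) can be passed through instead after range validation, with
background-sampling parameters (1 000 points, 20 km radius, 50 km range)
recorded in provenance for models that need them (the Gaussian model
does not).

The approximate species distribution is a thresholded flood fill from
occurrence cells: cells reachable through suitability ≥ 0.25 keep their
value, unvisited cells become 0, occurrence cells become exactly 1.
Connectivity is 8-neighborhood by default (diagonal adjacency matters
at coarse cells); 4-neighborhood is available.  Visited cells are *not*
binarized — the downstream overlap multiplies the two rasters,
re-thresholds the product at 0.25, counts non-zero cells and divides by
the non-zero cell count of the smaller-ranged species, exactly in that
order.  A consequence worth knowing: the self-overlap of a non-binary
distribution raster is below 1, because squaring drops cells with
suitability < 0.5 at the product-threshold step.

Both permutation tests pool the occurrences, reassign them to groups of
the original sizes, and redo their full chain: Schoener's
`D = 1 − ½Σ|p_a − p_b|` on normalized suitability surfaces for niche
equivalency, the overlap statistic for sympatry.  Both are one-sided
toward the lower tail (similarity lower / overlap lower than expected
under label exchange) with the +1 correction, and both are exactly
symmetric in their two arguments under a fixed seed (inputs are
canonically ordered before permuting).  The geographic chain appends
longitude and latitude rasters as predictors; the niche chain does not.

## Integration and ranking

The evidence table stores, per unordered taxon pair, the raw p-value of
each layer (niche D, EFA permutation, LDI Welch, geographic overlap),
the Bonferroni product with a shared multiplier m (uncapped and capped
at 1.0 — corrected values above 1 are reported as their truncation), and
significance flags at α = 0.05 (the hybrid screen uses α = 0.01).
m = 6 covers the six pairwise comparisons of two three-taxon clusters
analyzed jointly; it is configurable.  The rule table: genealogically
distinct ∧ sympatric → species (cryptic-species if not morphologically
distinct); distinct ∧ allopatric ∧ eco-distinct → species; distinct ∧
allopatric ∧ eco-similar → subspecies; not distinct ∧ eco-distinct →
ecotype (at best a subspecies); neither → merge; any pivotal unknown →
undecided with the gaps listed.  "Sympatric" is operationalized as
failure to reject sympatry at α — an absence-of-evidence caveat the
report records.  Genealogical distinctness is an input flag (from the
clustering stage or an external coalescent validation); it is not
recomputed here.

## Problem sizes

The bundled study and test suite run at desk scale: 30–37 samples ×
2 000–5 000 SNPs, 500–1 000 consensus replicates over k = 2…9, 100-seed
recovery and calibration loops, 20–30 leaves at ~2 500 mesh vertices,
36×36 landscape grids with 99–400 permutations.  These sizes were
chosen so each stage's statistical behaviour (recovery rates ≥ 90 %,
type-I error at nominal level) is measurable in minutes; all are
parameters, not limits.

## Known limitations

* The drift simulator has no linkage or genotyping-error model, so the
  locus-bootstrap path is exercised only when locus ids are supplied.
* The built-in Gaussian niche model is deliberately simple; skewed or
  multimodal niches need the external-raster route.
* ARAP minimizes distortion but cannot undo folds: curvature beyond
  `κ·width ≈ 1` self-intersects and is rejected at generation time.
* The ranking rule table encodes one reading of a morpho-geographical
  species concept; conflicting genealogical flags (e.g. discovery and
  validation methods disagreeing) are surfaced, not resolved.
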