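"""Environmental rasters, niche models, range approximation and overlap.

Gridded environmental layers (unprojected lon/lat, row-major with cell
(0, 0) at the top-left) are reduced by PCA, turned into habitat
suitability via a pluggable niche model, filtered to approximate species
distributions by a thresholded flood fill from the occurrence cells, and
compared by Schoener's D and a distribution-overlap statistic, each with
a permutation test (niche equivalency, and deviation from sympatry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Raster:
    """Single-layer raster with an affine lon/lat transform.

    ``values`` may contain nan only where ``mask`` (no-data) is True.
    ``x_origin``/``y_origin`` are the coordinates of the top-left corner
    of cell (0, 0); rows run south as latitude decreases.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
        if not np.isfinite(self.values[~self.mask]).all():
            raise ValueError("non-finite value outside the no-data mask")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
            and math.isclose(self.cell_size, other.cell_size)
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing (lon, lat); half-open intervals."""
        col = int(np.floor((lon - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - lat) / self.cell_size))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def with_values(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class OccurrenceSet:
    """Collection points of one taxon with derived raster cells."""

    taxon: str
    points: np.ndarray  # (n, 2) lon, lat
    cells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def assign_cells(self, raster: Raster) -> "OccurrenceSet":
        cells = sorted({raster.cell_of(lon, lat) for lon, lat in self.points})
        return OccurrenceSet(self.taxon, self.points, cells)


@dataclass
class DistributionRaster:
    """DFS-filtered approximate species range in [0, 1]."""

    raster: Raster
    threshold: float
    connectivity: int
    source: str = "suitability"


# ---------------------------------------------------------------------------
# raster preparation


def _check_stack(stack: list[Raster]) -> None:
    if not stack:
        raise ValueError("empty raster stack")
    for r in stack[1:]:
        if not r.same_grid(stack[0]):
            raise ValueError("rasters are not co-registered")


def raster_pca(stack: list[Raster], n_keep: int = 3):
    """PCA across cells of z-scored layers; top components as rasters.

    Returns ``(component_rasters, variance_fractions)``.  The common
    no-data mask (union over layers) propagates to the outputs.
    """
    _check_stack(stack)
    if len(stack) < n_keep:
        raise ValueError("fewer layers than components requested")
    mask = np.zeros(stack[0].shape, dtype=bool)
    for r in stack:
        mask |= r.mask
    valid = ~mask
    X = np.column_stack([r.values[valid] for r in stack])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    cov = np.cov(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    frac = eigval / eigval.sum() if eigval.sum() > 0 else eigval
    scores = X @ eigvec[:, :n_keep]
    out = []
    for k in range(n_keep):
        vals = np.full(stack[0].shape, np.nan)
        vals[valid] = scores[:, k]
        out.append(replace(stack[0], values=vals, mask=mask.copy()))
    return out, frac[:n_keep]


def depth_average(stacks: list[list[Raster]]) -> list[Raster]:
    """Cell-wise mean of each triplet of depth layers, ignoring no-data."""
    out = []
    for layers in stacks:
        _check_stack(layers)
        vals = np.stack([np.where(r.mask, np.nan, r.values) for r in layers])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(vals, axis=0)
        mask = np.isnan(mean)
        out.append(replace(layers[0], values=mean, mask=mask))
    return out


def add_lonlat_layers(stack: list[Raster]) -> list[Raster]:
    """Append longitude and latitude rasters (geographic predictors)."""
    _check_stack(stack)
    base = stack[0]
    nr, nc = base.shape
    lon = base.x_origin + (np.arange(nc) + 0.5) * base.cell_size
    lat = base.y_origin - (np.arange(nr) + 0.5) * base.cell_size
    lon_grid = np.broadcast_to(lon, (nr, nc)).copy()
    lat_grid = np.broadcast_to(lat[:, None], (nr, nc)).copy()
    mask = base.mask.copy()
    lon_grid[mask] = np.nan
    lat_grid[mask] = np.nan
    return list(stack) + [
        replace(base, values=lon_grid, mask=mask.copy()),
        replace(base, values=lat_grid, mask=mask.copy()),
    ]


# ---------------------------------------------------------------------------
# niche models


def fit_enm(
    occ: OccurrenceSet,
    env: list[Raster],
    model: str = "builtin-gaussian",
    external: Raster | None = None,
    min_occurrences: int = 5,
) -> Raster:
    """Habitat suitability in [0, 1] from occurrences and env layers.

    ``builtin-gaussian`` fits an independent Gaussian envelope per layer
    on the occurrence-cell values (suitability = product of per-axis
    Gaussians, rescaled to max 1).  ``external-raster`` passes through a
    user-supplied suitability raster (e.g. an exported MaxEnt surface)
    after validating its range.
    """
    _check_stack(env)
    if model == "external-raster":
        if external is None:
            raise ValueError("external-raster model needs a raster")
        vals = external.values[~external.mask]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("external suitability must lie in [0, 1]")
        return external
    if model != "builtin-gaussian":
        raise ValueError(f"unknown niche model {model!r}")
    occ = occ.assign_cells(env[0])
    if len(occ.cells) < min_occurrences:
        raise ValueError(
            f"builtin niche model needs >= {min_occurrences} occurrence cells, "
            f"got {len(occ.cells)}"
        )
    rows = np.array([c[0] for c in occ.cells])
    cols = np.array([c[1] for c in occ.cells])
    log_s = np.zeros(env[0].shape)
    for layer in env:
        v = layer.values[rows, cols]
        mu = np.nanmean(v)
        sd = np.nanstd(v)
        sd = max(sd, 1e-6 * max(abs(mu), 1.0))
        z = (layer.values - mu) / sd
        log_s = log_s - 0.5 * z**2
    log_s = log_s - np.nanmax(log_s)
    suit = np.exp(log_s)
    mask = np.zeros(env[0].shape, dtype=bool)
    for layer in env:
        mask |= layer.mask
    suit[mask] = np.nan
    return replace(env[0], values=suit, mask=mask)


# ---------------------------------------------------------------------------
# distribution approximation and overlap


def approximate_distribution(
    suit: Raster,
    occ: OccurrenceSet,
    threshold: float = 0.25,
    connectivity: int = 8,
) -> DistributionRaster:
    """Thresholded flood fill from occurrence cells.

    Cells reachable from an occurrence cell through cells with
    suitability >= threshold keep their suitability value, unvisited
    cells become 0.0, and occurrence cells are set to 1.0 (even when
    their own suitability is below the threshold).
    """
    from scipy.ndimage import binary_dilation, label

    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    occ = occ.assign_cells(suit)
    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    )
    passable = np.where(suit.mask, False, suit.values >= threshold)
    labels, _ = label(passable, structure=structure)
    seeds = np.zeros(suit.shape, dtype=bool)
    for r, c in occ.cells:
        seeds[r, c] = True
    # a component is visited when it contains or touches a seed cell
    reach = binary_dilation(seeds, structure=structure) | seeds
    kept = np.unique(labels[reach & passable])
    kept = kept[kept > 0]
    visited = np.isin(labels, kept)
    out = np.where(visited, suit.values, 0.0)
    out[seeds] = 1.0
    out = np.where(suit.mask, 0.0, out)
    return DistributionRaster(
        suit.with_values(out), threshold, connectivity
    )


def pairwise_overlap(
    da: DistributionRaster, db: DistributionRaster, threshold: float = 0.25
) -> float:
    """Distribution overlap: thresholded product over the smaller range.

    (1) multiply the two approximate distribution rasters, (2) threshold
    the product at ``threshold``, (3) count its non-zero cells, (4)
    divide by the non-zero cell count of the species with the smaller
    distribution area.  Undefined (ValueError) when a species has no
    non-zero cells.
    """
    ra, rb = da.raster, db.raster
    if not ra.same_grid(rb):
        raise ValueError("distribution rasters are not co-registered")
    prod = ra.values * rb.values
    prod = np.where(prod >= threshold, prod, 0.0)
    numerator = int((prod > 0).sum())
    na = int((ra.values > 0).sum())
    nb = int((rb.values > 0).sum())
    if na == 0 or nb == 0:
        raise ValueError("a species has an empty distribution; overlap undefined")
    return numerator / min(na, nb)


def schoener_d(sa: Raster, sb: Raster) -> float:
    """Schoener's D between two suitability surfaces.

    Each surface is normalized to sum 1 over its valid cells;
    D = 1 - 0.5 * sum |p_a - p_b|, in [0, 1].
    """
    if not sa.same_grid(sb):
        raise ValueError("rasters are not co-registered")
    a = np.where(sa.mask, 0.0, sa.values)
    b = np.where(sb.mask, 0.0, sb.values)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("zero-sum suitability raster")
    pa = a / a.sum()
    pb = b / b.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


# ---------------------------------------------------------------------------
# permutation tests


@dataclass
class OverlapResult:
    overlap: float
    p: float
    p_corrected: float
    p_corrected_capped: float
    n_permutations: int
    null_values: np.ndarray


def _split_labels(
    rng: np.random.Generator, pooled: np.ndarray, na: int
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(len(pooled))
    return pooled[perm[:na]], pooled[perm[na:]]


def sympatry_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    env: list[Raster],
    enm_model: str = "builtin-gaussian",
    n_perm: int = 400,
    threshold: float = 0.25,
    seed: int = 0,
    bonferroni_m: int = 1,
    include_lonlat: bool = True,
) -> OverlapResult:
    """Permutation test for deviation from sympatry.

    The observed overlap runs the full chain (niche model -> thresholded
    flood fill -> overlap statistic); the null swaps taxon labels over
    the pooled occurrence points preserving group sizes and redoes the
    chain.  One-sided toward *lower* overlap:
    p = (1 + #{null <= observed}) / (n_perm + 1), so a small p signals
    allopatry beyond what label exchange explains.  The geographic chain
    includes longitude/latitude predictor layers by default.

    The statistic and the pooling are symmetric in the two taxa, so the
    argument order does not matter (inputs are canonically ordered before
    permuting).
    """
    occ_a, occ_b = sorted(
        (occ_a, occ_b), key=lambda o: (o.taxon, len(o.points))
    )
    layers = add_lonlat_layers(env) if include_lonlat else list(env)

    def chain(pa: np.ndarray, pb: np.ndarray) -> float:
        oa = OccurrenceSet(occ_a.taxon, pa)
        ob = OccurrenceSet(occ_b.taxon, pb)
        da = approximate_distribution(
            fit_enm(oa, layers, enm_model), oa, threshold
        )
        db = approximate_distribution(
            fit_enm(ob, layers, enm_model), ob, threshold
        )
        return pairwise_overlap(da, db, threshold)

    observed = chain(occ_a.points, occ_b.points)
    pooled = np.vstack([occ_a.points, occ_b.points])
    na = len(occ_a.points)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa, pb = _split_labels(rng, pooled, na)
        null[i] = chain(pa, pb)
    p = (1.0 + float((null <= observed).sum())) / (n_perm + 1.0)
    return OverlapResult(
        observed, p, p * bonferroni_m, min(1.0, p * bonferroni_m), n_perm, null
    )


def niche_equivalency_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    env: list[Raster],
    enm_model: str = "builtin-gaussian",
    n_perm: int = 200,
    seed: int = 0,
    bonferroni_m: int = 1,
    background: dict | None = None,
) -> OverlapResult:
    """Niche-equivalency permutation test on Schoener's D.

    The observed D compares the two fitted suitability surfaces; the null
    pools the occurrences, reassigns them to groups of the original
    sizes, refits both models and recomputes D.  One-sided lower tail:
    p = (1 + #{null_D <= observed_D}) / (n_perm + 1).  ``background``
    (n_points / radius_km / range_km) is recorded for niche models that
    need background sampling; the builtin Gaussian model ignores it.
    Symmetric in the two taxa under a fixed seed.
    """
    occ_a, occ_b = sorted(
        (occ_a, occ_b), key=lambda o: (o.taxon, len(o.points))
    )
    background = background or {"n_points": 1000, "radius_km": 20, "range_km": 50}

    def fit_pair(pa: np.ndarray, pb: np.ndarray) -> float:
        sa = fit_enm(OccurrenceSet(occ_a.taxon, pa), env, enm_model)
        sb = fit_enm(OccurrenceSet(occ_b.taxon, pb), env, enm_model)
        return schoener_d(sa, sb)

    observed = fit_pair(occ_a.points, occ_b.points)
    pooled = np.vstack([occ_a.points, occ_b.points])
    na = len(occ_a.points)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa, pb = _split_labels(rng, pooled, na)
        null[i] = fit_pair(pa, pb)
    p = (1.0 + float((null <= observed).sum())) / (n_perm + 1.0)
    return OverlapResult(
        observed, p, p * bonferroni_m, min(1.0, p * bonferroni_m), n_perm, null
    )


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in kilometers on the spherical Earth."""
    r = 6371.0088
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


# ---------------------------------------------------------------------------
# raster IO


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid writer (plain text)."""
    nr, nc = raster.shape
    vals = np.where(raster.mask, nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {raster.x_origin}\n")
        fh.write(f"yllcorner {raster.y_origin - nr * raster.cell_size}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.asarray(rows)
    nodata = header.get("nodata_value", -9999.0)
    mask = vals == nodata
    vals = np.where(mask, np.nan, vals)
    nr = int(header["nrows"])
    cs = header["cellsize"]
    return Raster(
        vals,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nr * cs,
        cell_size=cs,
        mask=mask,
    )


def write_geotiff(raster: Raster, path, nodata: float = -9999.0) -> None:
    """Minimal GeoTIFF via tifffile: pixel scale + tiepoint tags."""
    import tifffile

    vals = np.where(raster.mask, nodata, raster.values).astype(np.float32)
    scale = (raster.cell_size, raster.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, raster.x_origin, raster.y_origin, 0.0)
    tifffile.imwrite(
        str(path),
        vals,
        extratags=[
            (33550, "d", 3, scale),  # ModelPixelScaleTag
            (33922, "d", 6, tiepoint),  # ModelTiepointTag
            (42113, "s", 0, str(nodata)),  # GDAL_NODATA
        ],
    )


def read_geotiff(path) -> Raster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        scale = tags[33550].value
        tiepoint = tags[33922].value
        nodata = float(tags[42113].value) if 42113 in tags else np.nan
    mask = vals == nodata
    vals = np.where(mask, np.nan, vals)
    return Raster(
        vals,
        x_origin=float(tiepoint[3]),
        y_origin=float(tiepoint[4]),
        cell_size=float(scale[0]),
        mask=mask,
    )


def write_occurrences(occs: list[OccurrenceSet], path) -> None:
    """Occurrence CSV (taxon, lon, lat)."""
    import pandas as pd

    rows = [
        {"taxon": o.taxon, "lon": lon, "lat": lat}
        for o in occs
        for lon, lat in o.points
    ]
    pd.DataFrame(rows, columns=["taxon", "lon", "lat"]).to_csv(path, index=False)


def read_occurrences(path) -> list[OccurrenceSet]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for taxon, grp in df.groupby("taxon", sort=False):
        out.append(OccurrenceSet(str(taxon), grp[["lon", "lat"]].to_numpy()))
    return out
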