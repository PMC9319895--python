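"""Consensus K-means species discovery on ordination coordinates.

Repeated K-means on random subsamples of observations and features yields
a co-clustering consensus matrix; average-linkage agglomeration of
(1 - consensus) gives the final partition, and silhouette / Davies-Bouldin
indices over a range of k select the number of clusters.  The replicate
engine is a small vectorized k-means++/Lloyd loop so that thousands of
replicates on tens of samples stay cheap and fully seed-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .distances import PcoaResult


@dataclass
class CkmConfig:
    """Consensus K-means settings.

    5000 replicates at 0.8/0.8 observation/feature portions are the
    defaults; tests and the bundled study use fewer replicates where noted.
    """

    k_range: tuple[int, int] = (2, 10)
    replicates: int = 5000
    observation_fraction: float = 0.8
    feature_fraction: float = 0.8
    seed: int = 0
    kmeans_max_iter: int = 50

    def validate(self, n_samples: int) -> None:
        lo, hi = self.k_range
        if not (2 <= lo <= hi):
            raise ValueError("k_range must satisfy 2 <= lo <= hi")
        if hi >= n_samples:
            raise ValueError("max k must be smaller than the sample count")
        for frac in (self.observation_fraction, self.feature_fraction):
            if not (0.0 < frac <= 1.0):
                raise ValueError("fractions must lie in (0, 1]")
        if int(np.ceil(self.observation_fraction * n_samples)) < hi:
            raise ValueError("observation fraction samples fewer points than k")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class ConsensusResult:
    """Consensus matrix, per-k labels, and validity indices."""

    consensus: dict[int, np.ndarray]
    cooccurrence_counts: dict[int, np.ndarray]
    cosample_counts: dict[int, np.ndarray]
    labels_per_k: dict[int, np.ndarray]
    sil_per_k: dict[int, float]
    db_per_k: dict[int, float]
    best_k_sil: int
    best_k_db: int
    db_local_optima: list[int] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int) -> np.ndarray:
    """k-means++ seeded Lloyd iteration; returns labels."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c:] = X[rng.integers(0, n, size=k - c)]
            break
        centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    labels = np.zeros(n, dtype=np.int32)
    for _ in range(max_iter):
        dist2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist2.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                centers[c] = X[dist2.min(axis=1).argmax()]
    return labels


def ckm_run(
    coords: PcoaResult | np.ndarray, k: int, cfg: CkmConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One consensus K-means pass at a fixed k.

    Returns ``(consensus, co_cluster_counts, co_sample_counts, labels)``.
    Per replicate, ceil(frac*n) observations and ceil(frac*p) features are
    drawn without replacement, K-means (k-means++ init, one initialization)
    is run, and co-clustering is recorded for the co-sampled pairs.  The
    final partition is average-linkage agglomerative clustering of
    (1 - consensus) cut at k clusters.
    """
    X, _ = _coords_array(coords)
    n, p = X.shape
    for frac in (cfg.observation_fraction, cfg.feature_fraction):
        if not (0.0 < frac <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
    if cfg.replicates < 1:
        raise ValueError("need at least one replicate")
    n_obs = int(np.ceil(cfg.observation_fraction * n))
    n_feat = max(1, int(np.ceil(cfg.feature_fraction * p)))
    if k > n_obs:
        raise ValueError(f"k={k} exceeds the {n_obs} sampled observations")
    rng = np.random.default_rng((cfg.seed, k))
    co_cluster = np.zeros((n, n), dtype=np.int64)
    co_sample = np.zeros((n, n), dtype=np.int64)
    for _ in range(cfg.replicates):
        obs = rng.choice(n, size=n_obs, replace=False)
        feats = rng.choice(p, size=n_feat, replace=False)
        labels = _kmeans(X[np.ix_(obs, feats)], k, rng, cfg.kmeans_max_iter)
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(obs, obs)] += 1
        co_cluster[np.ix_(obs, obs)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    z = linkage(squareform(1.0 - consensus, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    return consensus, co_cluster, co_sample, labels


def silhouette_index(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width with Euclidean distances.

    Members of singleton clusters contribute 0, following the usual
    convention.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    d = cdist(coords, coords)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def davies_bouldin(coords: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (lower is better).

    Mean over clusters of max_{j != i} (s_i + s_j) / d_ij with centroid
    dispersions s (mean Euclidean distance to the centroid) and centroid
    distances d.  Duplicated centroids make the index diverge; infinity
    is returned in that case.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin requires at least two clusters")
    centroids = np.array([coords[labels == c].mean(axis=0) for c in uniq])
    disp = np.array(
        [
            np.linalg.norm(coords[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(uniq)
        ]
    )
    dc = cdist(centroids, centroids)
    ratios = np.full((len(uniq), len(uniq)), -np.inf)
    for i in range(len(uniq)):
        for j in range(len(uniq)):
            if i == j:
                continue
            if dc[i, j] == 0.0:
                return float("inf")
            ratios[i, j] = (disp[i] + disp[j]) / dc[i, j]
    return float(ratios.max(axis=1).mean())


def ckm_scan(
    coords: PcoaResult | np.ndarray,
    cfg: CkmConfig,
    exclude: list[str] | None = None,
) -> ConsensusResult:
    """Consensus K-means over the configured k range.

    Validity indices are computed in the retained ordination space on the
    consensus-derived labels.  Reports the global silhouette maximum and
    Davies-Bouldin minimum, plus any DB local optima (sign change of the
    discrete difference); no arbitration between the two indices.
    ``exclude`` drops samples (e.g. flagged hybrids) before scanning.
    """
    X, ids = _coords_array(coords)
    if exclude:
        keep = [i for i, s in enumerate(ids) if s not in set(exclude)]
        X, ids = X[keep], [ids[i] for i in keep]
    cfg.validate(len(ids))
    lo, hi = cfg.k_range
    consensus, cooc, cosamp, labels_k = {}, {}, {}, {}
    sil, db = {}, {}
    for k in range(lo, hi + 1):
        cons, cc, cs, labels = ckm_run(X, k, cfg)
        consensus[k], cooc[k], cosamp[k], labels_k[k] = cons, cc, cs, labels
        sil[k] = silhouette_index(X, labels)
        db[k] = davies_bouldin(X, labels)
    ks = sorted(sil)
    best_sil = max(ks, key=lambda k: sil[k])
    best_db = min(ks, key=lambda k: db[k])
    local = []
    for idx in range(1, len(ks) - 1):
        k = ks[idx]
        if db[k] < db[ks[idx - 1]] and db[k] < db[ks[idx + 1]]:
            local.append(k)
    return ConsensusResult(
        consensus, cooc, cosamp, labels_k, sil, db, best_sil, best_db, local, ids
    )


def _coords_array(coords) -> tuple[np.ndarray, list[str]]:
    if isinstance(coords, PcoaResult):
        return np.asarray(coords.retained, dtype=float), list(coords.labels)
    arr = np.asarray(coords, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def plot_consensus(result: ConsensusResult, k: int, path) -> None:
    """Heat map of the consensus matrix at k, samples ordered by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(result.labels_per_k[k], kind="stable")
    mat = result.consensus[k][np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    ax.set_title(f"Consensus matrix, k = {k}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
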