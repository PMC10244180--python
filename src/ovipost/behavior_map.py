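"""Unsupervised behavior mapping from the 17-feature matrix.

The z-scored feature matrix is embedded into two dimensions with t-SNE
trained on a frame subsample; the remaining frames are placed at the
embedding coordinate of their nearest training neighbor in feature space.
A Gaussian kernel density over the embedding is segmented into basins by a
watershed on the negative density, giving per-frame cluster labels.
Clusters are then scored for egg-expulsion-locked expression: the
egg-out-aligned occupancy time course, its peak time, and a significance
p-value against a null of circular time shifts of the label stream within
each event (shifts preserve each event's label composition and
autocorrelation).  Finally, clusters are matched to the manual behavior
categories by frame-wise F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .ethogram import LABELS, Ethogram
from .features import FeatureMatrix


@dataclass
class EmbeddingMap:
    """2-D embedding of every frame, with training-subsample provenance."""

    points: np.ndarray            # (n_frames, 2)
    training_subsample: np.ndarray  # indices of frames the embedding was fit on
    seed: int
    method_params: dict = field(default_factory=dict)


@dataclass
class ClusterMap:
    """Watershed segmentation of the embedding density.

    ``labels`` assigns each frame a basin id (1..K; 0 = unassigned).
    """

    labels: np.ndarray            # (n_frames,)
    density: np.ndarray           # (grid, grid)
    basins: np.ndarray            # (grid, grid) watershed label image
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def _as_features(fm: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(fm, FeatureMatrix):
        return fm.zscored()
    return np.asarray(fm, dtype=float)


def embed_features(
    fm: Union[FeatureMatrix, np.ndarray],
    subsample: int = 30_000,
    seed: int = 0,
    perplexity: float = 30.0,
) -> EmbeddingMap:
    """t-SNE embedding trained on a subsample, nearest-neighbor placement.

    Arrays are taken as already z-scored; a :class:`FeatureMatrix` is
    z-scored column-wise first.  When the recording has fewer frames than
    ``subsample`` every frame is used for training.  Deterministic for a
    fixed seed.
    """
    X = _as_features(fm)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if n <= subsample:
        train_idx = np.arange(n)
    else:
        train_idx = np.sort(rng.choice(n, size=subsample, replace=False))
    Xt = X[train_idx]
    perp = min(perplexity, max(2.0, (len(train_idx) - 1) / 3.0))
    tsne = TSNE(n_components=2, perplexity=perp, init="pca", random_state=seed)
    emb_train = tsne.fit_transform(Xt)
    points = np.empty((n, 2))
    points[train_idx] = emb_train
    rest = np.setdiff1d(np.arange(n), train_idx, assume_unique=True)
    if rest.size:
        nn = NearestNeighbors(n_neighbors=1).fit(Xt)
        _, j = nn.kneighbors(X[rest])
        points[rest] = emb_train[j[:, 0]]
    return EmbeddingMap(
        points=points,
        training_subsample=train_idx,
        seed=seed,
        method_params={"perplexity": perp, "method": "tsne", "init": "pca"},
    )


def segment_density(
    em: EmbeddingMap,
    bandwidth: Optional[float] = None,
    grid: int = 512,
    min_occupancy: float = 0.005,
) -> ClusterMap:
    """Gaussian-KDE + watershed segmentation of the embedding.

    The density is a 2-D histogram smoothed with a Gaussian kernel
    (``bandwidth`` in embedding units; default Scott's rule on the training
    subsample).  Basins come from a watershed of the negative density seeded
    at density maxima; basins holding fewer than ``min_occupancy`` of all
    frames are merged into their dominant neighbor.
    """
    pts = em.points
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("degenerate embedding: all points identical")
    train = pts[em.training_subsample]
    if bandwidth is None:
        # Scott's rule, averaged over the two embedding axes
        bandwidth = float(train.std(axis=0).mean() * len(train) ** (-1.0 / 6.0))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    margin = 3.0 * bandwidth
    xmin, ymin = pts.min(axis=0) - margin
    xmax, ymax = pts.max(axis=0) + margin
    hist, xedges, yedges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=grid, range=[[xmin, xmax], [ymin, ymax]]
    )
    cell = ((xmax - xmin) / grid + (ymax - ymin) / grid) / 2.0
    density = ndimage.gaussian_filter(hist, sigma=bandwidth / cell)

    peaks = peak_local_max(
        density, min_distance=max(1, int(bandwidth / cell)), exclude_border=False
    )
    markers = np.zeros_like(density, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers[np.unravel_index(np.argmax(density), density.shape)] = 1
    basins = watershed(-density, markers=markers)

    ix = np.clip(np.searchsorted(xedges, pts[:, 0], side="right") - 1, 0, grid - 1)
    iy = np.clip(np.searchsorted(yedges, pts[:, 1], side="right") - 1, 0, grid - 1)
    labels = basins[ix, iy].astype(np.int64)

    labels, basins = _merge_small_basins(labels, basins, density, min_occupancy)
    return ClusterMap(labels=labels, density=density, basins=basins, extent=(xmin, xmax, ymin, ymax))


def _merge_small_basins(
    labels: np.ndarray, basins: np.ndarray, density: np.ndarray, min_occupancy: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge under-occupied basins into the neighbor sharing the most border."""
    n = labels.size
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        occ = dict(zip(ids.tolist(), (counts / n).tolist()))
        small = [i for i in ids if occ[i] < min_occupancy and len(ids) > 1]
        if not small:
            break
        b = min(small, key=lambda i: occ[i])
        mask = basins == b
        grown = ndimage.binary_dilation(mask)
        neighbor_ids = np.unique(basins[grown & ~mask])
        neighbor_ids = neighbor_ids[neighbor_ids != b]
        if neighbor_ids.size == 0:
            break
        border_len = [(basins[grown & ~mask] == nb).sum() for nb in neighbor_ids]
        target = int(neighbor_ids[int(np.argmax(border_len))])
        basins = np.where(mask, target, basins)
        labels = np.where(labels == b, target, labels)
    # relabel densely 1..K
    ids = np.unique(basins)
    remap = {old: new for new, old in enumerate(ids, start=1)}
    basins = np.vectorize(remap.get)(basins)
    labels = np.vectorize(lambda v: remap.get(v, 0))(labels)
    return labels.astype(np.int64), basins.astype(np.int32)


# ---------------------------------------------------------------------------
# Egg-out-aligned cluster significance
# ---------------------------------------------------------------------------

def cluster_significance(
    labels_by_event: Sequence[np.ndarray],
    egg_out_frames: Sequence[int],
    fps: float,
    window_s: float = 20.0,
    n_shift: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    course_window_s: float = 60.0,
    smooth_s: float = 0.5,
) -> pd.DataFrame:
    """Expulsion-locked cluster statistics with a circular-shift null.

    For each cluster the observed statistic is the peak of the egg-out
    aligned occupancy (fraction of events expressing the cluster) within
    ±``window_s``; the null redraws it after circularly shifting each
    event's label stream by an independent uniform offset, and
    ``p = (1 + #{null peak >= observed}) / (1 + n_shift)``.  A cluster is
    significant if additionally the peak of its wider time course
    (±``course_window_s``) falls inside ±``window_s``.  Alignment uses
    circular indexing within each event, matching the null's geometry.

    Occupancy courses (observed and null alike) are smoothed with a
    ``smooth_s`` Gaussian along the time axis before the peak is taken:
    the raw per-frame occupancy is a count over events, and a peak of tied
    integer counts would make the permutation p-value needlessly
    conservative; smoothing makes the statistic effectively continuous.
    """
    if len(labels_by_event) == 0 or len(labels_by_event) != len(egg_out_frames):
        raise ValueError("need matching label arrays and egg_out anchors")
    if any(f is None for f in egg_out_frames):
        raise ValueError("every event needs an egg_out anchor")
    rng = np.random.default_rng(seed)
    w = int(round(window_s * fps))
    cw = int(round(course_window_s * fps))
    rel_w = np.arange(-w, w + 1)
    rel_c = np.arange(-cw, cw + 1)
    clusters = np.unique(np.concatenate([np.unique(a) for a in labels_by_event]))
    clusters = clusters[clusters > 0]
    n_events = len(labels_by_event)

    shifts = [rng.integers(0, len(a), size=n_shift) for a in labels_by_event]
    rows = []
    courses = {}
    for k in clusters:
        obs_w = np.zeros(rel_w.size)
        obs_c = np.zeros(rel_c.size)
        cover_c = np.zeros(rel_c.size)
        null = np.zeros((n_shift, rel_w.size))
        occupancy = 0.0
        for a, egg, s in zip(labels_by_event, egg_out_frames, shifts):
            ind = (a == k)
            L = len(a)
            occupancy += ind.mean() / n_events
            obs_w += ind[(egg + rel_w) % L]
            # the wide course is coverage-based (no wrap): frames outside the
            # event simply do not contribute
            idx_c = egg + rel_c
            ok = (idx_c >= 0) & (idx_c < L)
            obs_c[ok] += ind[idx_c[ok]]
            cover_c += ok
            null += ind[(egg + rel_w[None, :] - s[:, None]) % L]
        obs_w /= n_events
        obs_c = np.divide(obs_c, cover_c, out=np.zeros_like(obs_c), where=cover_c > 0)
        null /= n_events
        sig = smooth_s * fps
        if sig > 0:
            obs_w = ndimage.gaussian_filter1d(obs_w, sig)
            obs_c = ndimage.gaussian_filter1d(obs_c, sig)
            null = ndimage.gaussian_filter1d(null, sig, axis=1)
        obs_peak = obs_w.max()
        p = (1.0 + np.sum(null.max(axis=1) >= obs_peak)) / (1.0 + n_shift)
        peak_time = rel_c[int(np.argmax(obs_c))] / fps
        rows.append({
            "cluster": int(k),
            "occupancy": occupancy,
            "peak_occupancy": obs_peak,
            "peak_time_s": peak_time,
            "p": p,
            "significant": bool(p < alpha and abs(peak_time) <= window_s),
        })
        courses[int(k)] = obs_c
    df = pd.DataFrame(rows).sort_values("peak_time_s").reset_index(drop=True)
    df.attrs["course_times_s"] = rel_c / fps
    df.attrs["courses"] = courses
    return df


def cluster_correspondence(
    labels: np.ndarray, ethograms: Sequence[Ethogram]
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Frame-wise F1 between each cluster and each manual behavior.

    ``labels`` covers the concatenated frames of ``ethograms``.  Each
    cluster is assigned its argmax-F1 behavior; exact ties break toward the
    rarer behavior.
    """
    activity = np.concatenate([e.activity for e in ethograms], axis=0)
    if activity.shape[0] != len(labels):
        raise ValueError("label stream and ethogram frames must match")
    clusters = np.unique(labels)
    clusters = clusters[clusters > 0]
    behavior_counts = activity.sum(axis=0)
    f1 = np.zeros((clusters.size, len(LABELS)))
    for i, k in enumerate(clusters):
        pred = labels == k
        npred = pred.sum()
        for j in range(len(LABELS)):
            tp = (pred & activity[:, j]).sum()
            denom = npred + behavior_counts[j]
            f1[i, j] = 2.0 * tp / denom if denom else 0.0
    table = pd.DataFrame(f1, index=[int(k) for k in clusters], columns=list(LABELS))
    assignment: dict[int, str] = {}
    for i, k in enumerate(clusters):
        best = np.flatnonzero(f1[i] == f1[i].max())
        if best.size > 1:  # tie: prefer the rarer behavior
            best = best[np.argsort(behavior_counts[best])]
        assignment[int(k)] = LABELS[int(best[0])]
    return table, assignment
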