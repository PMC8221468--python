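"""ISODATA clustering of pre-intervention index trajectories.

Pixels inside the thicket mask are described by the multi-temporal
trajectory of one spectral index over the pre-intervention scene archive
(ten acquisitions in the reference application). ISODATA — k-means style
assignment/update extended with cluster splitting and merging under
variance/size thresholds — partitions these trajectories into K vegetation
clusters (default 5) that act as the control-matching strata.

The original desktop implementation's internals are proprietary; this is a
textbook ISODATA with explicit, configurable defaults:

* initialization: K centroids spread along the first principal axis;
* minimum cluster size: max(10, 0.1 m / K);
* split threshold: overall per-feature standard deviation of the data;
* merge threshold: half the median inter-centroid distance;
* convergence: stop when the fraction of pixels keeping their label
  reaches the convergence limit (1.0 = fully stable), or at max_iter.

After convergence clusters are renumbered 1..K by decreasing mean centroid
value, so cluster 1 is the densest vegetation (for a vegetation index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import compute_index
from .rasterdata import SceneStack


@dataclass
class TrajectoryMatrix:
    """m pixel trajectories over T pre-intervention dates."""

    pixels: np.ndarray  # (m, 2) row/col
    features: np.ndarray  # (m, T)
    index: str
    dates: list

    def __post_init__(self):
        if not np.all(np.isfinite(self.features)):
            raise ValueError("trajectory features must be finite")
        if self.pixels.shape[0] != self.features.shape[0]:
            raise ValueError("pixel list and feature matrix disagree")


@dataclass
class ClusterMap:
    """Per-pixel cluster labels 1..K (0 = unclustered) plus centroids."""

    labels: np.ndarray  # 2D int grid
    centroids: np.ndarray  # (K, T)
    counts: np.ndarray  # (K,)
    index: str
    n_iter: int
    converged: bool

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def build_trajectories(
    stack: SceneStack,
    index_name: str,
    mask: np.ndarray,
    policy: str = "drop",
    coeffs: dict | None = None,
) -> TrajectoryMatrix:
    """One row per masked pixel; columns are the index at each date.

    ``policy`` for pixels invalid at any date: ``"drop"`` excludes the row
    (default — mirrors an archive of cloud-free acquisitions), ``"impute"``
    fills with that date's mean over valid masked pixels.
    """
    if len(stack.scenes) < 2:
        raise ValueError("need at least 2 pre-intervention dates")
    if not mask.any():
        raise ValueError("empty trajectory mask")
    layers, valids = [], []
    for scene in stack.scenes:
        ir = compute_index(scene, index_name, coeffs)
        layers.append(ir.values)
        valids.append(ir.valid_mask)
    cube = np.stack(layers, axis=-1)  # (rows, cols, T)
    ok = np.stack(valids, axis=-1)
    rows, cols = np.nonzero(mask)
    feats = cube[rows, cols, :]
    valid = ok[rows, cols, :]
    if policy == "drop":
        keep = valid.all(axis=1)
        rows, cols, feats = rows[keep], cols[keep], feats[keep]
    elif policy == "impute":
        for t in range(feats.shape[1]):
            col = feats[:, t]
            bad = ~valid[:, t]
            if bad.any():
                col[bad] = np.nanmean(col[~bad]) if (~bad).any() else 0.0
    else:
        raise ValueError(f"unknown missing-data policy {policy!r}")
    if feats.shape[0] == 0:
        raise ValueError("no complete trajectories under the mask")
    return TrajectoryMatrix(
        pixels=np.column_stack([rows, cols]),
        features=np.asarray(feats, dtype=np.float64),
        index=index_name,
        dates=stack.dates,
    )


def _assign(X, centroids):
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def isodata_cluster(
    traj: TrajectoryMatrix,
    k: int = 5,
    max_iter: int = 50,
    convergence: float = 1.0,
    min_size: int | None = None,
    split_threshold: float | None = None,
    merge_threshold: float | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int] | None = None,
) -> ClusterMap:
    """Cluster trajectories with ISODATA; final label count <= k.

    Assignment/update iterations never increase the total within-cluster
    sum of squares; split and merge steps are exempt and logged through the
    iteration trace. Deterministic for a given seed.
    """
    X = traj.features
    m, T = X.shape
    if m < k:
        raise ValueError(f"m={m} trajectories < k={k} clusters")
    rng = np.random.default_rng(seed)
    if min_size is None:
        min_size = max(10, int(0.1 * m / k))
    min_size = min(min_size, max(1, m // k))
    if split_threshold is None:
        split_threshold = float(X.std(axis=0).mean())
    # initialization: spread along the first principal axis
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ vt[0]
    qs = np.quantile(proj, np.linspace(0.05, 0.95, k))
    centroids = X.mean(axis=0)[None, :] + qs[:, None] * vt[0][None, :]

    labels = _assign(X, centroids)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # update
        centroids = np.stack(
            [X[labels == c].mean(axis=0) if (labels == c).any() else centroids[c]
             for c in range(centroids.shape[0])]
        )
        # discard undersized clusters: members reassigned to remaining centroids
        counts = np.bincount(labels, minlength=centroids.shape[0])
        keep = counts >= min_size
        if keep.sum() >= 1 and not keep.all():
            centroids = centroids[keep]
        # merge close centroid pairs
        if centroids.shape[0] > 1:
            dmat = np.linalg.norm(
                centroids[:, None, :] - centroids[None, :, :], axis=2
            )
            thr = merge_threshold
            if thr is None:
                # default: typical pixel-to-centroid scatter, so duplicate
                # centroids merge but separated clusters never do
                tmp = _assign(X, centroids)
                thr = float(
                    np.mean(np.linalg.norm(X - centroids[tmp], axis=1))
                )
            merged = np.ones(centroids.shape[0], dtype=bool)
            for i in range(centroids.shape[0]):
                for j in range(i + 1, centroids.shape[0]):
                    if merged[i] and merged[j] and dmat[i, j] < thr:
                        centroids[i] = (centroids[i] + centroids[j]) / 2
                        merged[j] = False
            centroids = centroids[merged]
        # split the most dispersed cluster while below k
        while centroids.shape[0] < k:
            tmp = _assign(X, centroids)
            stds = np.array(
                [X[tmp == c].std(axis=0).max() if (tmp == c).sum() > 1 else 0.0
                 for c in range(centroids.shape[0])]
            )
            c = int(np.argmax(stds))
            if stds[c] <= split_threshold and centroids.shape[0] > 1:
                break
            members = X[tmp == c]
            if members.shape[0] < 2:
                break
            axis = int(np.argmax(members.std(axis=0)))
            offset = np.zeros(T)
            offset[axis] = max(members[:, axis].std(), 1e-9)
            centroids = np.vstack([centroids, centroids[c] + offset])
            centroids[c] = centroids[c] - offset
        new_labels = _assign(X, centroids)
        if labels.shape == new_labels.shape:
            stable = float(np.mean(new_labels == labels))
        else:
            stable = 0.0
        labels = new_labels
        if stable >= convergence:
            converged = True
            break
    _ = rng  # randomness reserved for future tie-breaking; kept for API stability

    # relabel 1..K by decreasing mean centroid (densest vegetation first)
    order = np.argsort(-centroids.mean(axis=1), kind="stable")
    remap = np.empty(centroids.shape[0], dtype=int)
    remap[order] = np.arange(1, centroids.shape[0] + 1)
    final = remap[labels]
    centroids = centroids[order]
    counts = np.bincount(final, minlength=centroids.shape[0] + 1)[1:]

    if grid_shape is None:
        grid_shape = (int(traj.pixels[:, 0].max()) + 1, int(traj.pixels[:, 1].max()) + 1)
    grid = np.zeros(grid_shape, dtype=np.int16)
    grid[traj.pixels[:, 0], traj.pixels[:, 1]] = final
    return ClusterMap(
        labels=grid,
        centroids=centroids,
        counts=counts,
        index=traj.index,
        n_iter=n_iter,
        converged=converged,
    )
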