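"""PCA screening and k-means segmentation of NDE curves.

The per-pixel NDE curves of a node are clustered with k-means (k=2, the
minimum able to expose heterogeneity) on the raw curve vectors — no spatial
term enters the objective, so any anatomical structure in the label map is
an empirical finding, not an artifact of the method. A PCA variance screen
on the same curves justifies the two-cluster choice: when two components
already explain most of the variance, two enhancement patterns dominate.

Cluster roles are assigned operationally: the cluster whose averaged curve
has the larger AUC is "inner" (the strongly enhancing node core), the other
"outer". Ties fall back to the larger peak value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from nodedce.curve_params import auc as _auc
from nodedce.enhancement import NDECurveSet


class InsufficientDataError(ValueError):
    """Too few curves, or no variance, for the requested analysis."""


@dataclass
class PcaScreen:
    """Explained-variance screen of a curve set.

    explained_variance_pct : per-component percentages, descending.
    """

    explained_variance_pct: np.ndarray

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct)

    def n_components_for(self, threshold_pct: float) -> int:
        """Smallest number of leading components explaining >= threshold_pct."""
        return int(np.searchsorted(self.cumulative_pct, threshold_pct - 1e-12) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.explained_variance_pct.size + 1),
                "explained_pct": self.explained_variance_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )


@dataclass
class ClusterResult:
    """Outcome of segmenting one node's curves.

    labels : per-pixel assignment; integers after k-means, role strings
        ("inner"/"outer") after :func:`assign_cluster_roles`.
    label_map : image of assignments (-1 outside the node mask, cluster
        index inside; roles map inner=1, outer=0).
    cluster_curves : cluster-averaged NDE curve per cluster key.
    volume_pct : percentage of node pixels per cluster key.
    inertia : within-cluster sum of squared curve distances.
    """

    labels: np.ndarray
    coords: np.ndarray
    cluster_curves: dict
    volume_pct: dict
    inertia: float
    grid: tuple[int, int] | None = None
    tie_broken_by_peak: bool = False

    @property
    def label_map(self) -> np.ndarray:
        if self.grid is None:
            raise ValueError("no grid attached to this result")
        img = np.full(self.grid, -1, dtype=int)
        codes = {"outer": 0, "inner": 1}
        for (r, c), lab in zip(self.coords, self.labels):
            img[r, c] = codes.get(lab, lab) if isinstance(lab, str) else int(lab)
        return img


def pca_screen(curves: NDECurveSet | np.ndarray) -> PcaScreen:
    """Percentage of curve-set variance explained per principal component.

    Curves are centered; components are ordered by decreasing variance.
    Raises :class:`InsufficientDataError` for fewer than two curves or a
    zero-variance set.
    """
    X = curves.curves if isinstance(curves, NDECurveSet) else np.asarray(curves, dtype=float)
    if X.shape[0] < 2:
        raise InsufficientDataError("PCA screen needs at least 2 curves")
    if np.allclose(X, X[0], atol=0.0):
        raise InsufficientDataError("curve set has zero variance; PCA screen undefined")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    return PcaScreen(explained_variance_pct=pca.explained_variance_ratio_ * 100.0)


def kmeans_segment(
    curves: NDECurveSet | np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_init: int = 20,
    grid: tuple[int, int] | None = None,
) -> ClusterResult:
    """Segment pixels by k-means on their full NDE curves.

    Raw curve vectors are clustered (NDE is already muscle-normalized, so no
    further standardization is applied) with squared Euclidean distance and
    the best of ``n_init`` k-means++ restarts. Deterministic for a given
    seed.
    """
    if isinstance(curves, NDECurveSet):
        X = curves.curves
        coords = curves.coords
    else:
        X = np.asarray(curves, dtype=float)
        coords = np.zeros((X.shape[0], 2), dtype=int)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} invalid for {X.shape[0]} curves")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    inertia = float(km.inertia_)
    if k == 2 and X.shape[0] <= 12:
        # restarted Lloyd iterations can stall in a local optimum on such
        # tiny instances; the exact 2-partition optimum is cheap to enumerate
        labels, inertia = _exact_two_partition(X)
    n = X.shape[0]
    cluster_curves = {j: X[labels == j].mean(axis=0) for j in range(k)}
    volume_pct = {j: 100.0 * (labels == j).sum() / n for j in range(k)}
    return ClusterResult(
        labels=labels,
        coords=coords,
        cluster_curves=cluster_curves,
        volume_pct=volume_pct,
        inertia=inertia,
        grid=grid,
    )


def _exact_two_partition(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Globally optimal 2-partition by exhaustive enumeration (n <= 12)."""
    n = X.shape[0]
    codes = np.arange(1, 2 ** (n - 1))  # fix point 0 in cluster 0; skip empty split
    bits = (codes[:, None] >> np.arange(n)) & 1  # (n_partitions, n)
    best_sse, best = np.inf, None
    for row in bits:
        sse = 0.0
        for j in (0, 1):
            member = X[row == j]
            sse += ((member - member.mean(axis=0)) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, row
    return best.astype(int), float(best_sse)


def assign_cluster_roles(
    result: ClusterResult,
    frame_interval: float,
    n_baseline: int,
) -> ClusterResult:
    """Label the two clusters "inner"/"outer" by enhancement magnitude.

    The cluster whose averaged curve has the larger post-injection AUC is
    "inner"; an exact AUC tie is broken by the larger peak value. Spatial
    position plays no role, so the assignment is invariant to the arbitrary
    ordering of the k-means output.
    """
    keys = sorted(result.cluster_curves, key=str)
    if len(keys) != 2:
        raise ValueError("role assignment is defined for exactly 2 clusters")
    aucs = {j: _auc(result.cluster_curves[j], frame_interval, n_baseline) for j in keys}
    tie = aucs[keys[0]] == aucs[keys[1]]
    if tie:
        inner_key = max(keys, key=lambda j: result.cluster_curves[j].max())
    else:
        inner_key = max(keys, key=lambda j: aucs[j])
    outer_key = keys[0] if inner_key == keys[1] else keys[1]
    role_of = {inner_key: "inner", outer_key: "outer"}
    return ClusterResult(
        labels=np.array([role_of[j] for j in result.labels], dtype=object),
        coords=result.coords,
        cluster_curves={role_of[j]: result.cluster_curves[j] for j in keys},
        volume_pct={role_of[j]: result.volume_pct[j] for j in keys},
        inertia=result.inertia,
        grid=result.grid,
        tie_broken_by_peak=tie,
    )


def save_overlay(
    result: ClusterResult,
    background: np.ndarray,
    path: str | Path,
) -> None:
    """Write a color-coded segmentation overlay (inner red, outer green) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(background, cmap="gray", interpolation="nearest")
    overlay = np.zeros(background.shape + (4,))
    colors = {"inner": (1.0, 0.2, 0.2, 0.6), "outer": (0.2, 1.0, 0.2, 0.6)}
    for (r, c), lab in zip(result.coords, result.labels):
        overlay[r, c] = colors.get(lab, (0.2, 0.2, 1.0, 0.6))
    ax.imshow(overlay, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
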