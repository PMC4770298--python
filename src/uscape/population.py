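"""Well-population statistics and K-means typing of well sub-groups.

A scanned micro-well array yields one volume (and one half-depth area) per
well; array quality is summarized by the mean, sample standard deviation
and coefficient of variation (CoV = 100 * sd / mean).  Arrays deliberately
mixing several designed well types separate into clusters in the
volume-vs-half-depth-area plane; K-means assigns each well a type, and
accuracy against known design labels is the disagreement count under the
optimal cluster-to-type assignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "WellPopulation",
    "PopulationSummary",
    "summarize",
    "round_sig",
    "fit_gaussian",
    "GaussianFit",
    "WellTypeClassifier",
    "kmeans_classify",
    "misclassification_count",
    "flag_outliers",
]


class PopulationSummary(NamedTuple):
    """mean (nL), sample sd (nL), CoV (%), count."""

    mean: float
    sd: float
    cov_percent: float
    n: int


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (for report tables)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def summarize(volumes: Sequence[float]) -> PopulationSummary:
    """Mean, sample sd (n-1 denominator) and CoV in percent.

    Report tables conventionally print CoV to 2 significant figures
    (use :func:`round_sig`); the returned value is unrounded.
    """
    v = np.asarray(volumes, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values for a sample sd")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cov = 100.0 * sd / mean if mean != 0 else float("inf")
    return PopulationSummary(mean=mean, sd=sd, cov_percent=cov, n=int(v.size))


@dataclass
class GaussianFit:
    """Moment-based normal fit with a plotting histogram and normality check."""

    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    shapiro_p: float
    normal: bool  # diagnostic only (p >= 0.01); never enforced


def fit_gaussian(volumes: Sequence[float], alpha: float = 0.01) -> GaussianFit:
    """Fit N(mu, sd) by moments and report a Shapiro-Wilk diagnostic.

    The histogram uses Freedman-Diaconis binning for plotting.  Shapiro is
    evaluated on at most 5000 values (subsampled deterministically) since
    the test degenerates at very large n; the result is advisory.
    """
    v = np.asarray(volumes, dtype=np.float64)
    if v.size < 10:
        raise ValueError("need at least 10 values for a distribution fit")
    counts, edges = np.histogram(v, bins="fd")
    sub = v if v.size <= 5000 else v[:: v.size // 5000 + 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.shapiro(sub).pvalue)
    return GaussianFit(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        bin_edges=edges,
        counts=counts,
        shapiro_p=p,
        normal=p >= alpha,
    )


@dataclass
class WellPopulation:
    """Per-well records plus optional design labels and cluster labels."""

    volumes_nl: np.ndarray
    half_depth_areas_um2: np.ndarray | None = None
    centroids_um: np.ndarray | None = None
    true_labels: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volumes_nl = np.asarray(self.volumes_nl, dtype=np.float64)
        if self.volumes_nl.ndim != 1 or self.volumes_nl.size < 1:
            raise ValueError("need a 1-D, non-empty volume vector")
        for name in ("half_depth_areas_um2", "true_labels", "cluster_labels"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape[0] != self.volumes_nl.size:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WellPopulation":
        """Build from a morphometry measurement table (wells CSV)."""
        return cls(
            volumes_nl=df["volume_nL"].to_numpy(),
            half_depth_areas_um2=(
                df["half_depth_area_um2"].to_numpy()
                if "half_depth_area_um2" in df else None
            ),
            centroids_um=(
                df[["centroid_x_um", "centroid_y_um"]].to_numpy()
                if "centroid_x_um" in df else None
            ),
            true_labels=(df["true_label"].to_numpy()
                         if "true_label" in df else None),
        )

    def features(self) -> np.ndarray:
        """(n, 2) volume + half-depth-area matrix, or (n, 1) volume only."""
        if self.half_depth_areas_um2 is not None:
            return np.column_stack(
                [self.volumes_nl, self.half_depth_areas_um2.astype(np.float64)]
            )
        return self.volumes_nl[:, None]

    def summary(self) -> PopulationSummary:
        return summarize(self.volumes_nl)


class WellTypeClassifier(BaseEstimator, ClusterMixin):
    """K-means typing of wells on z-scored (volume, half-depth-area) features.

    Volume (nL) and area (um^2) differ by orders of magnitude, so each
    feature is standardized to zero mean / unit variance before Lloyd's
    algorithm with k-means++ initialization; the best of ``n_restarts``
    runs by within-cluster sum of squares is kept.  Deterministic under
    ``seed``.

    Attributes
    ----------
    labels_ : (n,) int
        Cluster assignment per well.
    cluster_centers_ : (k, p) float
        Centers in the original (unstandardized) feature units.
    inertia_ : float
        Within-cluster sum of squares in standardized units.
    """

    def __init__(self, n_clusters: int = 3, seed: int | None = None,
                 n_restarts: int = 10):
        self.n_clusters = n_clusters
        self.seed = seed
        self.n_restarts = n_restarts

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if X.shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters wells")
        n_distinct = np.unique(X, axis=0).shape[0]
        k = self.n_clusters
        if n_distinct < k:
            warnings.warn(
                f"only {n_distinct} distinct points; reducing k from {k}",
                stacklevel=2,
            )
            k = n_distinct
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        km = KMeans(n_clusters=k, init="k-means++", n_init=self.n_restarts,
                    random_state=self.seed).fit(Z)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_ * sd + mu
        self.inertia_ = float(km.inertia_)
        self.n_clusters_ = k
        self._scale = (mu, sd)
        self._km = km
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        mu, sd = self._scale
        return self._km.predict((X - mu) / sd)


def kmeans_classify(wells: WellPopulation, k: int = 3, seed: int | None = None,
                    n_restarts: int = 10) -> np.ndarray:
    """Cluster a well population into ``k`` types; stores and returns labels."""
    clf = WellTypeClassifier(n_clusters=k, seed=seed, n_restarts=n_restarts)
    labels = clf.fit(wells.features()).labels_
    wells.cluster_labels = labels
    return labels


def misclassification_count(labels: Sequence[int],
                            true_labels: Sequence[int]) -> int:
    """Disagreements under the optimal cluster-to-type mapping.

    Cluster ids are arbitrary, so clusters are first matched to designed
    types by the permutation maximizing agreement (Hungarian assignment on
    the confusion matrix); the count of wells still mismatched under that
    mapping is returned.  Invariant to any relabeling of either argument.
    """
    a = np.asarray(labels)
    b = np.asarray(true_labels)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    ua, ub = np.unique(a), np.unique(b)
    if ua.size != ub.size:
        raise ValueError(
            f"label sets differ in cardinality ({ua.size} vs {ub.size})"
        )
    confusion = np.zeros((ua.size, ub.size), dtype=np.int64)
    ia = np.searchsorted(ua, a)
    ib = np.searchsorted(ub, b)
    np.add.at(confusion, (ia, ib), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return int(a.size - confusion[rows, cols].sum())


def flag_outliers(wells: WellPopulation, z_threshold: float = 3.0) -> np.ndarray:
    """Indices of wells whose volume deviates more than z sd from the mean.

    When cluster labels exist the z-score is computed within each cluster,
    so a mixed-type array does not flag an entire minority type.  A zero
    sd (all volumes identical) flags nothing, with a warning.
    """
    v = wells.volumes_nl
    if v.size < 10:
        raise ValueError("need at least 10 wells for outlier statistics")
    groups = (wells.cluster_labels if wells.cluster_labels is not None
              else np.zeros(v.size, dtype=int))
    flagged = []
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        mu = v[idx].mean()
        sd = v[idx].std(ddof=1) if idx.size > 1 else 0.0
        # constant volumes give sd at rounding-noise level, not exactly 0
        if sd <= 1e-12 * max(abs(mu), 1e-300):
            warnings.warn(f"group {g}: zero volume sd; nothing flagged",
                          stacklevel=2)
            continue
        flagged.append(idx[np.abs(v[idx] - mu) / sd > z_threshold])
    if not flagged:
        return np.array([], dtype=int)
    return np.sort(np.concatenate(flagged))


def plot_histogram(wells: WellPopulation, path) -> None:
    """Save a volume histogram with the moment Gaussian overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = fit_gaussian(wells.volumes_nl)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = 0.5 * (fit.bin_edges[:-1] + fit.bin_edges[1:])
    width = np.diff(fit.bin_edges)
    ax.bar(centers, fit.counts, width=width, color="#7697c6",
           edgecolor="white")
    xs = np.linspace(fit.bin_edges[0], fit.bin_edges[-1], 200)
    scale = wells.volumes_nl.size * width.mean()
    ax.plot(xs, scale * stats.norm.pdf(xs, fit.mean, fit.sd), "k-")
    ax.set_xlabel("well volume (nL)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(wells: WellPopulation, path) -> None:
    """Save the volume vs half-depth-area scatter colored by cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if wells.half_depth_areas_um2 is None:
        raise ValueError("scatter plot needs half-depth areas")
    labels = (wells.cluster_labels if wells.cluster_labels is not None
              else np.zeros(wells.volumes_nl.size, dtype=int))
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(wells.volumes_nl, wells.half_depth_areas_um2, c=labels,
                    s=6, cmap="viridis")
    ax.set_xlabel("well volume (nL)")
    ax.set_ylabel("half-depth area (um$^2$)")
    if wells.cluster_labels is not None:
        fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
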