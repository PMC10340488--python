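"""Logit-space cluster separability analysis.

A 3-class classifier maps each test sample to a logit triple (L1, L2, L3).
Projecting these onto the top two principal components gives a 2-D cloud per
true class; how far apart the class centroids sit relative to the spread
within each class summarizes how separable the classifier's representation
is.  The headline statistic is the Dist/SD ratio,

    ratio = 3 * (sum of pairwise centroid distances) / (total intra-class SD),

where the total SD combines per-cluster spreads by root-sum-of-squares and
each cluster's spread combines the SDs of its PC1 and PC2 coordinates the
same way.  Larger ratios mean tighter, better-separated clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (DegenerateCovarianceError, InsufficientDataError,
                         ZeroSpreadError)

#: weight of the distance term in the Dist/SD ratio ("3-1 weighted ratio")
DIST_WEIGHT = 3.0


@dataclass
class LogitSet:
    """Per-sample 3-D logits with true class labels in {1, 2, 3}."""

    logits: np.ndarray          # (n, 3)
    labels: np.ndarray          # (n,)

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.logits.ndim != 2 or self.logits.shape[1] != 3:
            raise ValueError(f"logits must be (n, 3), got {self.logits.shape}")
        if self.labels.shape != (self.logits.shape[0],):
            raise ValueError("labels must have one entry per sample")
        for c in np.unique(self.labels):
            if np.count_nonzero(self.labels == c) < 2:
                raise InsufficientDataError(f"class {c} has fewer than 2 samples")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LogitSet":
        """Read a CSV with columns L1, L2, L3, label."""
        df = pd.read_csv(path)
        return cls(df[["L1", "L2", "L3"]].to_numpy(), df["label"].to_numpy())


@dataclass
class ClusterSummary:
    """Per-class centroids, pairwise distances, spreads, and the Dist/SD ratio."""

    centroids: dict[int, np.ndarray]
    pairwise_dists: dict[tuple[int, int], float]
    dist_total: float
    sd_per_cluster: dict[int, float]
    sd_total: float
    ratio: float
    sd_components: dict[int, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "centroids": {str(k): list(v) for k, v in self.centroids.items()},
            "pairwise_dists": {f"{a}-{b}": d for (a, b), d in self.pairwise_dists.items()},
            "dist_total": self.dist_total,
            "sd_per_cluster": {str(k): v for k, v in self.sd_per_cluster.items()},
            "sd_total": self.sd_total,
            "ratio": self.ratio,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def project_logits(logits: LogitSet | np.ndarray) -> np.ndarray:
    """Project centered 3-D logits onto their top two principal components.

    Uses the sample covariance (divisor n-1).  The sign of each component is
    fixed by making its largest-magnitude loading positive, so repeated runs
    produce identical (not merely mirrored) projections.
    """
    x = logits.logits if isinstance(logits, LogitSet) else np.asarray(logits, float)
    if x.shape[0] < 3:
        raise InsufficientDataError("need at least 3 samples for a 2-D projection")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 1e-15:
        raise DegenerateCovarianceError("all samples identical: covariance is zero")
    components = evecs[:, :2]
    for j in range(2):
        i_max = np.argmax(np.abs(components[:, j]))
        if components[i_max, j] < 0:
            components[:, j] = -components[:, j]
    return centered @ components


def summarize_clusters(points: np.ndarray, labels: np.ndarray) -> ClusterSummary:
    """Centroids, pairwise centroid distances, per-cluster spreads, and totals.

    ``points`` are 2-D (PC1, PC2) coordinates.  Per-cluster spread is
    sqrt(SD_PC1^2 + SD_PC2^2) with sample SDs (ddof=1); the total spread is
    the root-sum-of-squares over clusters; dist_total is the plain sum of
    pairwise centroid distances; ratio = 3 * dist_total / sd_total.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    classes = sorted(int(c) for c in np.unique(labels))
    centroids, sd_per_cluster, sd_components = {}, {}, {}
    for c in classes:
        pts = points[labels == c]
        if pts.shape[0] < 2:
            raise InsufficientDataError(f"class {c} has fewer than 2 points")
        centroids[c] = pts.mean(axis=0)
        sd1, sd2 = pts.std(axis=0, ddof=1)
        sd_components[c] = (float(sd1), float(sd2))
        sd_per_cluster[c] = float(np.hypot(sd1, sd2))
    pairwise = {(a, b): float(np.linalg.norm(centroids[a] - centroids[b]))
                for a, b in combinations(classes, 2)}
    dist_total = float(sum(pairwise.values()))
    sd_total = float(np.sqrt(sum(v ** 2 for v in sd_per_cluster.values())))
    if sd_total == 0:
        raise ZeroSpreadError("all clusters have zero spread; ratio undefined")
    ratio = DIST_WEIGHT * dist_total / sd_total
    return ClusterSummary(centroids, pairwise, dist_total, sd_per_cluster,
                          sd_total, float(ratio), sd_components)


def summary_from_components(
    pairwise_dists: tuple[float, float, float],
    sd_per_cluster: tuple[float, float, float],
) -> ClusterSummary:
    """Build a summary from already-computed pairwise distances and cluster SDs.

    Useful for recomputing totals and the ratio from tabulated per-pair /
    per-cluster values.  Distances are (d12, d23, d13); SDs per class 1..3.
    """
    d12, d23, d13 = (float(d) for d in pairwise_dists)
    sds = {c: float(s) for c, s in zip((1, 2, 3), sd_per_cluster)}
    dist_total = d12 + d23 + d13
    sd_total = float(np.sqrt(sum(s ** 2 for s in sds.values())))
    if sd_total == 0:
        raise ZeroSpreadError("zero total spread; ratio undefined")
    return ClusterSummary(
        centroids={}, pairwise_dists={(1, 2): d12, (2, 3): d23, (1, 3): d13},
        dist_total=dist_total, sd_per_cluster=sds, sd_total=sd_total,
        ratio=DIST_WEIGHT * dist_total / sd_total)


def dist_sd_ratio(summary: ClusterSummary) -> float:
    """The 3:1-weighted distance-to-spread ratio of a cluster summary."""
    if summary.sd_total == 0:
        raise ZeroSpreadError("zero total spread; ratio undefined")
    return DIST_WEIGHT * summary.dist_total / summary.sd_total


def analyze_logits(logits: LogitSet) -> ClusterSummary:
    """Full analysis: PCA projection followed by cluster summarization."""
    return summarize_clusters(project_logits(logits), logits.labels)


def plot_clusters(points: np.ndarray, labels: np.ndarray, path: str | Path) -> None:
    """Optional 2-D scatter of the projected clusters (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in np.unique(labels):
        pts = points[labels == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=f"class {c}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
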