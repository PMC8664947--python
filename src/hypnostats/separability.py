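"""Cluster-separability measures in hyper-parameter space.

Two scalar measures quantify how well labeled point clusters separate
in a D-dimensional embedding (here: per-epoch (STD, KUR, SKE) vectors
grouped by sleep stage):

* **GDV** (General Discrimination Value).  After each dimension is
  z-scored with the pooled population mean/std and multiplied by 1/2,

      GDV = (1/sqrt(D)) * [ mean_l intra(C_l)
                            - (2 / (L(L-1))) * sum_{l<m} inter(C_l, C_m) ],

  where intra is the mean pairwise Euclidean distance within a class
  and inter the mean distance between two classes.  More *negative* =
  better separated; the 1/sqrt(D) factor makes it dimension-invariant.

* **CSI** (Cluster Separation Index).  On the raw coordinates,

      CSI = < ln( d_min_other / d_min_same ) >_n,

  the mean over points of the log-ratio of the nearest-neighbor
  distance to any *other*-class point over the nearest *same*-class
  neighbor.  More *positive* = better separated.  Unlike the GDV, which
  averages all pairwise distances and therefore penalizes elongated
  clusters, the CSI considers two dense parallel line-like clusters as
  well separated.  It is invariant under translation and scaling by
  construction and requires all nearest-neighbor distances to be
  non-zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .epochs import STAGES, Hypnogram

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledPointSet",
    "zscore_half",
    "gdv",
    "csi",
    "stage_distance_matrix",
    "DuplicatePointError",
    "DegenerateInputError",
]


class DuplicatePointError(ValueError):
    """A nearest-neighbor distance is zero; the CSI log-ratio is undefined."""


class DegenerateInputError(ValueError):
    """The point set carries no usable variance."""


@dataclass
class LabeledPointSet:
    """N points in D dimensions with a class label each."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim == 2 and self.points.shape[0] == 1 \
                and len(np.atleast_1d(self.labels)) > 1:
            self.points = self.points.T
        self.labels = np.asarray(self.labels)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points and labels disagree in length")
        if self.points.shape[0] < 2:
            raise ValueError("need at least 2 points")

    @property
    def classes(self) -> list:
        seen: list = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def zscore_half(point_set: LabeledPointSet) -> LabeledPointSet:
    """Z-score each dimension with the pooled population std, then halve.

    ``s = (x - mu_d) / (2 * sigma_d)`` per dimension; constant dimensions
    (sigma = 0) are dropped with a warning, reducing D.
    """
    x = point_set.points
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)        # population (divide by N)
    keep = sigma > 0
    if not keep.any():
        raise DegenerateInputError("all dimensions are constant")
    if not keep.all():
        logger.warning("dropping %d constant dimension(s) before rescaling",
                       int((~keep).sum()))
    s = 0.5 * (x[:, keep] - mu[keep]) / sigma[keep]
    return LabeledPointSet(s, point_set.labels.copy())


def gdv(point_set: LabeledPointSet) -> float:
    """General Discrimination Value of a labeled point set.

    Applies the z-score-and-halve rescaling internally.  Every class
    needs at least 2 points (the mean intra-class distance is undefined
    otherwise).  Negative values indicate separation.
    """
    rescaled = zscore_half(point_set)
    x = rescaled.points
    labels = rescaled.labels
    classes = rescaled.classes
    d_dim = x.shape[1]
    n_cls = len(classes)
    if n_cls < 2:
        raise ValueError("need at least 2 classes")

    groups = {c: x[labels == c] for c in classes}
    for c, g in groups.items():
        if g.shape[0] < 2:
            raise ValueError(
                f"class {c!r} has {g.shape[0]} point(s); mean intra-class "
                f"distance undefined")

    intra = np.mean([pdist(groups[c]).mean() for c in classes])
    inter_sum = 0.0
    for i in range(n_cls):
        for j in range(i + 1, n_cls):
            inter_sum += cdist(groups[classes[i]], groups[classes[j]]).mean()
    inter = 2.0 / (n_cls * (n_cls - 1)) * inter_sum
    return float((intra - inter) / np.sqrt(d_dim))


def csi(point_set: LabeledPointSet, jitter: float = 0.0, seed: int = 0) -> float:
    """Cluster Separation Index of a labeled point set (raw coordinates).

    Parameters
    ----------
    jitter : float
        If positive and duplicate points make a nearest-neighbor
        distance zero, coordinates are perturbed by uniform noise of
        ``jitter`` × the pooled coordinate scale (documented escape
        hatch); with the default 0 a zero distance raises
        :class:`DuplicatePointError`.
    """
    x = point_set.points
    labels = point_set.labels
    classes = point_set.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(
                f"class {c!r} needs >= 2 points for a same-class neighbor")

    dist = cdist(x, x)
    np.fill_diagonal(dist, np.inf)
    same = labels[:, None] == labels[None, :]
    d_same = np.where(same, dist, np.inf).min(axis=1)
    d_other = np.where(~same, dist, np.inf).min(axis=1)
    if np.any(d_same == 0) or np.any(d_other == 0):
        if jitter > 0:
            scale = np.abs(x).max() or 1.0
            rng = np.random.default_rng(seed)
            noisy = x + rng.uniform(-1, 1, x.shape) * jitter * scale
            return csi(LabeledPointSet(noisy, labels), jitter=0.0)
        raise DuplicatePointError(
            "zero nearest-neighbor distance (duplicate points); pass "
            "jitter > 0 to perturb")
    return float(np.mean(np.log(d_other / d_same)))


def stage_distance_matrix(
    table: pd.DataFrame,
    hypnogram: Hypnogram | None = None,
    measure: str = "gdv",
    hyper_names: Sequence[str] = ("STD", "KUR", "SKE"),
    channel_policy: str = "average",
) -> pd.DataFrame:
    """Pairwise stage dissimilarity in hyper-parameter space.

    For every pair of stages the per-epoch hyper-parameter vectors of
    the two stages form a two-class point set and the chosen measure is
    evaluated: ``measure="gdv"`` reports the magnitude |GDV| (so larger
    = more separated, like the CSI), ``measure="csi"`` the CSI.  Epochs
    are channel-averaged; artifact epochs and epochs with undefined
    hyper-parameters are excluded.  Stage pairs with fewer than 2 usable
    epochs on either side are reported as NaN.

    Returns a symmetric 5×5 DataFrame with zero diagonal.
    """
    if measure not in ("gdv", "csi"):
        raise ValueError(f"unknown measure {measure!r}")
    if channel_policy != "average":
        raise ValueError(f"unknown channel_policy {channel_policy!r}")
    clean = table[~table["artifact"].astype(bool)]
    per_epoch = clean.groupby(["stage", "epoch"], sort=False)[
        list(hyper_names)].mean().dropna()

    points: dict[str, np.ndarray] = {}
    for stage in STAGES:
        if stage in per_epoch.index.get_level_values("stage"):
            points[stage] = per_epoch.loc[stage].to_numpy(dtype=float)

    out = pd.DataFrame(np.zeros((5, 5)), index=STAGES, columns=STAGES)
    for i, a in enumerate(STAGES):
        for j in range(i + 1, 5):
            b = STAGES[j]
            if a not in points or b not in points \
                    or len(points[a]) < 2 or len(points[b]) < 2:
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            pts = np.vstack([points[a], points[b]])
            labs = np.array([a] * len(points[a]) + [b] * len(points[b]),
                            dtype=object)
            ps = LabeledPointSet(pts, labs)
            if measure == "gdv":
                val = abs(gdv(ps))
            else:
                val = csi(ps, jitter=1e-9)
            out.loc[a, b] = out.loc[b, a] = val
    return out
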