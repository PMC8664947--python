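"""Stage-conditional hyper-parameter distributions and likelihoods.

For every sleep stage ``s`` and hyper-parameter ``h`` (STD, KUR, SKE,
ACF300) a continuous, strictly positive likelihood ``q(h | s)`` is built
from the pooled per-epoch samples.  The default construction is a
histogram on a range shared across stages (so stages are directly
comparable), evaluated by *log-linear interpolation* between bin centers
and extended beyond the outermost non-empty bins by linear log-density
extrapolation, floored at a small positive density ``floor``.

Log-linear interpolation plus a log-linear tail keeps the evaluator
strictly positive everywhere — a requirement of the Bayesian update,
which an unconstrained spline fit of the histogram would violate.  A
Gaussian kernel-density alternative is available via ``method="kde"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .epochs import HYPER_NAMES, STAGES

logger = logging.getLogger(__name__)

__all__ = [
    "StageLikelihoodModel",
    "fit_stage_likelihoods",
    "evaluate_likelihood",
    "MissingStageError",
]

#: Default density floor (in the hyper-parameter's density units).
DENSITY_FLOOR = 1e-12


class MissingStageError(ValueError):
    """A stage has no samples to fit a likelihood from."""


@dataclass
class _HistDensity:
    """One histogram-based density with log-linear interpolation."""

    edges: np.ndarray
    densities: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        c = 0.5 * (self.edges[:-1] + self.edges[1:])
        self._centers = c
        logf = float(np.log(self.floor))
        self._logd = np.log(np.clip(self.densities, self.floor, None))
        nz = np.nonzero(self.densities > 0)[0]
        if nz.size == 0:
            raise ValueError("histogram has no occupied bins")
        self._i0, self._i1 = int(nz[0]), int(nz[-1])
        # tail slopes from the two outermost non-empty bins, clamped so
        # the extrapolated density never grows with distance from the
        # support (monotone-tail contract)
        width = float(self.edges[1] - self.edges[0])
        # fallback tail: decay from the edge density to the floor within
        # one bin width; used when fewer than two occupied bins exist or
        # when the empirical two-bin slope does not decay outward (the
        # tail must be non-increasing away from the support)
        fall_lo = (self._logd[self._i0] - logf) / width
        fall_hi = (self._logd[self._i1] - logf) / width
        self._slope_lo = fall_lo
        self._slope_hi = -fall_hi
        if nz.size >= 2:
            lo2 = int(nz[1])
            hi2 = int(nz[-2])
            s_lo = (self._logd[self._i0] - self._logd[lo2]) / (
                c[self._i0] - c[lo2])
            s_hi = (self._logd[self._i1] - self._logd[hi2]) / (
                c[self._i1] - c[hi2])
            if s_lo > 0:      # density falls moving below the support
                self._slope_lo = s_lo
            if s_hi < 0:      # density falls moving above the support
                self._slope_hi = s_hi
        self._logfloor = logf

    def __call__(self, values) -> np.ndarray:
        v = np.atleast_1d(np.asarray(values, dtype=float))
        c = self._centers
        i0, i1 = self._i0, self._i1
        # inside the occupied support: log-linear between bin centers,
        # constant across the outer half of the two edge bins (np.interp
        # clamps); outside the occupied bin edges: linear log tails
        out = np.interp(v, c[i0:i1 + 1], self._logd[i0:i1 + 1])
        lo_edge = self.edges[i0]
        hi_edge = self.edges[i1 + 1]
        below = v < lo_edge
        above = v > hi_edge
        out[below] = self._logd[i0] + self._slope_lo * (v[below] - lo_edge)
        out[above] = self._logd[i1] + self._slope_hi * (v[above] - hi_edge)
        np.clip(out, self._logfloor, None, out=out)
        return np.exp(out)


@dataclass
class _KdeDensity:
    """Gaussian KDE density, floored."""

    samples: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        s = self.samples
        if s.size < 2 or np.ptp(s) == 0:
            # degenerate sample: narrow Gaussian around the single value
            center = float(s[0])
            width = max(abs(center) * 1e-3, 1e-3)
            self._kde = None
            self._center, self._width = center, width
        else:
            self._kde = gaussian_kde(s)

    def __call__(self, values) -> np.ndarray:
        v = np.atleast_1d(np.asarray(values, dtype=float))
        if self._kde is None:
            d = np.exp(-0.5 * ((v - self._center) / self._width) ** 2) / (
                np.sqrt(2 * np.pi) * self._width)
        else:
            d = self._kde(v)
        return np.clip(d, self.floor, None)


@dataclass
class StageLikelihoodModel:
    """Continuous positive likelihoods ``q(h | s)`` for all stages.

    Built by :func:`fit_stage_likelihoods`; evaluated through
    :meth:`evaluate` (vectorized over values).  Serializable to a single
    JSON document so classifier runs are reproducible without refitting.
    """

    hyper_names: tuple[str, ...]
    stage_names: tuple[str, ...]
    floor: float
    method: str
    edges: dict[str, np.ndarray]
    densities: dict[str, dict[str, np.ndarray]]
    _evaluators: dict[tuple[str, str], object] = field(
        default_factory=dict, repr=False)

    def _build_evaluators(self,
                          samples: Mapping[str, Mapping[str, np.ndarray]]
                          | None = None) -> None:
        self._evaluators = {}
        for h in self.hyper_names:
            for s in self.stage_names:
                if self.method == "kde":
                    self._evaluators[(s, h)] = _KdeDensity(
                        np.asarray(samples[s][h]), self.floor)
                else:
                    self._evaluators[(s, h)] = _HistDensity(
                        self.edges[h], self.densities[h][s], self.floor)

    def evaluate(self, hyper_name: str, values, stage: str) -> np.ndarray:
        """Density of ``values`` under ``q(hyper_name | stage)`` (> 0)."""
        key = (stage, hyper_name)
        if key not in self._evaluators:
            raise LookupError(
                f"no likelihood for stage={stage!r}, hyper={hyper_name!r}; "
                f"model covers stages {self.stage_names} and hypers "
                f"{self.hyper_names}"
            )
        return self._evaluators[key](values)

    def integral(self, hyper_name: str, stage: str,
                 pad_bins: int = 10, n_points: int = 20001) -> float:
        """Numerical integral of the evaluator over the padded support."""
        e = self.edges[hyper_name]
        width = e[1] - e[0]
        grid = np.linspace(e[0] - pad_bins * width, e[-1] + pad_bins * width,
                           n_points)
        return float(np.trapezoid(self.evaluate(hyper_name, grid, stage),
                                  grid))

    # -- JSON round-trip ------------------------------------------------
    def to_json(self) -> str:
        if self.method == "kde":
            raise NotImplementedError(
                "kde models are not serializable; use the histogram method")
        doc = {
            "format": "hypnostats-stage-likelihoods",
            "version": 1,
            "method": self.method,
            "floor": self.floor,
            "hyper_names": list(self.hyper_names),
            "stage_names": list(self.stage_names),
            "edges": {h: self.edges[h].tolist() for h in self.hyper_names},
            "densities": {
                h: {s: self.densities[h][s].tolist()
                    for s in self.stage_names}
                for h in self.hyper_names
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StageLikelihoodModel":
        doc = json.loads(text)
        model = cls(
            hyper_names=tuple(doc["hyper_names"]),
            stage_names=tuple(doc["stage_names"]),
            floor=float(doc["floor"]),
            method=doc["method"],
            edges={h: np.asarray(v, dtype=float)
                   for h, v in doc["edges"].items()},
            densities={h: {s: np.asarray(d, dtype=float)
                           for s, d in sd.items()}
                       for h, sd in doc["densities"].items()},
        )
        model._build_evaluators()
        return model


def fit_stage_likelihoods(
    pooled_samples: Mapping[str, Mapping[str, Sequence[float]]],
    n_bins: int = 50,
    floor: float = DENSITY_FLOOR,
    method: str = "histogram",
    hyper_names: Sequence[str] | None = None,
) -> StageLikelihoodModel:
    """Fit per-stage likelihoods from pooled hyper-parameter samples.

    Parameters
    ----------
    pooled_samples : mapping ``{stage: {hyper_name: samples}}``
        As produced by :func:`hypnostats.epochs.pool_hyperparameters`.
    n_bins : int
        Histogram bins per hyper-parameter.  The bin range is shared
        across stages: the pooled [0.5th, 99.5th] percentile span.  If a
        stage has fewer than 30 samples, fewer (wider) bins are used for
        all stages of that hyper-parameter (with a warning).
    floor : float
        Strictly positive density floor.
    method : {"histogram", "kde"}
        Histogram with log-linear interpolation/extrapolation (default,
        serializable) or Gaussian KDE (not serializable).
    """
    if method not in ("histogram", "kde"):
        raise ValueError(f"unknown method {method!r}")
    stages = tuple(s for s in STAGES if s in pooled_samples)
    if not stages:
        raise MissingStageError("no stages in pooled samples")
    if hyper_names is None:
        hyper_names = tuple(next(iter(pooled_samples.values())).keys())
    hyper_names = tuple(hyper_names)

    samples: dict[str, dict[str, np.ndarray]] = {}
    for s in stages:
        samples[s] = {}
        for h in hyper_names:
            arr = np.asarray(pooled_samples[s][h], dtype=float)
            arr = arr[np.isfinite(arr)]
            if arr.size == 0:
                raise MissingStageError(
                    f"stage {s!r} has no finite samples for {h!r}")
            samples[s][h] = arr

    edges: dict[str, np.ndarray] = {}
    densities: dict[str, dict[str, np.ndarray]] = {}
    for h in hyper_names:
        pooled = np.concatenate([samples[s][h] for s in stages])
        lo, hi = np.percentile(pooled, [0.5, 99.5])
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        min_n = min(samples[s][h].size for s in stages)
        bins = n_bins
        if min_n < 30:
            bins = max(4, min(n_bins, min_n))
            logger.warning(
                "only %d samples for hyper %s in the smallest stage; "
                "widening bins to %d", min_n, h, bins)
        edges[h] = np.linspace(lo, hi, bins + 1)
        densities[h] = {}
        for s in stages:
            clipped = np.clip(samples[s][h], lo, hi)
            d, _ = np.histogram(clipped, bins=edges[h], density=True)
            densities[h][s] = d

    model = StageLikelihoodModel(
        hyper_names=hyper_names,
        stage_names=stages,
        floor=floor,
        method=method,
        edges=edges,
        densities=densities,
    )
    model._build_evaluators(samples if method == "kde" else None)
    return model


def evaluate_likelihood(model: StageLikelihoodModel, hyper_name: str,
                        value, stage: str) -> np.ndarray:
    """Functional alias for :meth:`StageLikelihoodModel.evaluate`."""
    return model.evaluate(hyper_name, value, stage)
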