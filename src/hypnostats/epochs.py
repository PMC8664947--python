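"""Per-epoch statistics of raw EEG signals.

The raw signal of every channel is cut into non-overlapping 30-s epochs
(7680 samples at 256 Hz) and each epoch is summarized by

* its amplitude distribution (histogram on a common bin grid),
* its autocorrelation function (ACF) and, between channel pairs, the
  cross-correlation function (CCF), and
* four scalar *hyper-parameters*: the standard deviation (STD, in µV),
  the excess kurtosis (KUR), the skewness (SKE) and the ACF value at a
  lag of 300 ms (ACF300).

All moments use the population convention (divide by N, no small-sample
correction) and the ACF uses the biased estimator (the lagged sum is
divided by the full segment length), which guarantees ACF(0) = 1 and
keeps the curve bounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed sleep-stage alphabet; this order is used in every vector and matrix.
STAGES: tuple[str, ...] = ("Wake", "REM", "N1", "N2", "N3")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Names of the per-epoch hyper-parameters, in canonical order.
HYPER_NAMES: tuple[str, ...] = ("STD", "KUR", "SKE", "ACF300")


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


_STAGE_LOOKUP = {s.lower(): s for s in STAGES}


def canonical_stage(label: str) -> str:
    """Map a case-insensitive stage label onto the canonical alphabet."""
    key = str(label).strip().lower()
    if key not in _STAGE_LOOKUP:
        raise ValueError(
            f"unknown sleep stage label {label!r}; expected one of {STAGES}"
        )
    return _STAGE_LOOKUP[key]


@dataclass
class Recording:
    """Multi-channel raw EEG signal.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Raw amplitudes in µV.
    sampling_rate : float
        Samples per second (Hz).
    channel_labels : sequence of str
        One label per channel, e.g. ``["F4-M1", "C4-M1", "O2-M1"]``.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signals.shape[0]} signal rows"
            )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels with an optional artifact mask."""

    stages: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.stages = np.asarray(
            [canonical_stage(s) for s in np.asarray(self.stages, dtype=object)],
            dtype=object,
        )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.stages), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.artifact_mask) != len(self.stages):
            raise ValueError("artifact_mask length must equal number of epochs")

    def __len__(self) -> int:
        return len(self.stages)


def epoch_length_samples(sampling_rate: float, epoch_seconds: float) -> int:
    """Number of samples per epoch; must be an integer (e.g. 256 Hz × 30 s = 7680)."""
    n = sampling_rate * epoch_seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"epoch length {epoch_seconds} s at {sampling_rate} Hz is not an "
            f"integer number of samples"
        )
    return int(round(n))


def segment_epochs(recording: Recording, epoch_seconds: float = 30.0) -> np.ndarray:
    """Cut a recording into non-overlapping epochs.

    Epochs are half-open sample windows ``[n*L, (n+1)*L)``; a trailing
    partial epoch is dropped.

    Returns
    -------
    ndarray, shape (n_channels, n_epochs, epoch_len)
    """
    length = epoch_length_samples(recording.sampling_rate, epoch_seconds)
    n_epochs = recording.n_samples // length
    if n_epochs == 0:
        logger.warning(
            "recording of %d samples is shorter than one epoch (%d samples)",
            recording.n_samples, length,
        )
    used = n_epochs * length
    if used < recording.n_samples:
        logger.info("dropping trailing partial epoch: %d samples discarded",
                    recording.n_samples - used)
    return recording.signals[:, :used].reshape(
        recording.n_channels, n_epochs, length
    )


def autocorrelation(segment: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation function of one epoch segment.

    ``A(l) = sum_t (y_t - ybar)(y_{t+l} - ybar) / (N * sigma^2)`` with the
    population variance sigma^2; ``A(0) = 1`` exactly.

    Raises
    ------
    UndefinedStatisticError
        If the segment has zero variance.
    """
    y = np.asarray(segment, dtype=float)
    n = y.size
    if n <= max_lag:
        raise ValueError(f"segment of {n} samples cannot support lag {max_lag}")
    d = y - y.mean()
    var = np.dot(d, d) / n
    if var == 0.0:
        raise UndefinedStatisticError("zero-variance segment: ACF undefined")
    # FFT autocovariance (zero-padded to avoid circular wrap-around)
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(d, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    return acov / var


def crosscorrelation(
    segment_1: np.ndarray,
    segment_2: np.ndarray,
    lags: Sequence[int],
) -> np.ndarray:
    """Biased cross-correlation between two equal-length segments.

    ``C(l) = sum_t (y1_t - ybar1)(y2_{t+l} - ybar2) / (N * sigma1 * sigma2)``;
    negative lags shift channel 2 backwards.
    """
    y1 = np.asarray(segment_1, dtype=float)
    y2 = np.asarray(segment_2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("segments must have equal length")
    n = y1.size
    d1 = y1 - y1.mean()
    d2 = y2 - y2.mean()
    s1 = np.sqrt(np.dot(d1, d1) / n)
    s2 = np.sqrt(np.dot(d2, d2) / n)
    if s1 == 0.0 or s2 == 0.0:
        raise UndefinedStatisticError("zero-variance segment: CCF undefined")
    out = np.empty(len(lags), dtype=float)
    for i, lag in enumerate(lags):
        lag = int(lag)
        if abs(lag) >= n:
            out[i] = 0.0
            continue
        if lag >= 0:
            out[i] = np.dot(d1[: n - lag], d2[lag:])
        else:
            out[i] = np.dot(d1[-lag:], d2[: n + lag])
    return out / (n * s1 * s2)


def acf_lag_samples(acf_lag_ms: float, sampling_rate: float) -> int:
    """Nearest integer sample lag for a lag expressed in milliseconds.

    300 ms at 256 Hz is 76.8 samples, which is not an integer; the nearest
    lag (77 samples ≈ 300.8 ms) is used and reported via this helper.
    """
    return int(round(acf_lag_ms / 1000.0 * sampling_rate))


def hyperparameters(
    segment: np.ndarray,
    acf_lag_ms: float = 300.0,
    sampling_rate: float = 256.0,
) -> tuple[float, float, float, float]:
    """Per-epoch hyper-parameters (STD, KUR, SKE, ACF300) of one segment.

    STD is the population standard deviation in signal units; KUR the
    excess kurtosis (Gaussian → 0); SKE the skewness; ACF300 the biased
    ACF evaluated at the integer lag nearest to ``acf_lag_ms``.

    A constant segment returns ``(0.0, nan, nan, nan)``: the STD is zero
    and the standardized moments are undefined.
    """
    y = np.asarray(segment, dtype=float)
    if y.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    d = y - y.mean()
    var = np.dot(d, d) / y.size
    std = np.sqrt(var)
    if std == 0.0:
        return 0.0, np.nan, np.nan, np.nan
    z = d / std
    kur = float(np.mean(z**4) - 3.0)
    ske = float(np.mean(z**3))
    lag = acf_lag_samples(acf_lag_ms, sampling_rate)
    if lag >= y.size:
        acf = np.nan   # segment too short to support the requested lag
    else:
        acf = float(np.dot(d[: y.size - lag], d[lag:]) / (y.size * var))
    return float(std), kur, ske, acf


def hyperparameter_table(
    recording: Recording,
    hypnogram: Hypnogram,
    epoch_seconds: float = 30.0,
    acf_lag_ms: float = 300.0,
) -> pd.DataFrame:
    """Compute the per-(epoch, channel) hyper-parameter table.

    Returns a DataFrame with columns ``epoch, channel, stage, STD, KUR,
    SKE, ACF300, artifact``.  Statistics of artifact epochs are computed
    anyway (rows are flagged, not removed) so downstream code can decide
    how to treat them.
    """
    epochs = segment_epochs(recording, epoch_seconds)
    n_ch, n_ep, length = epochs.shape
    if len(hypnogram) != n_ep:
        raise ValueError(
            f"hypnogram covers {len(hypnogram)} epochs but the recording "
            f"contains {n_ep}"
        )
    lag = acf_lag_samples(acf_lag_ms, recording.sampling_rate)
    d = epochs - epochs.mean(axis=2, keepdims=True)
    var = np.mean(d**2, axis=2)
    std = np.sqrt(var)
    ok = std > 0
    safe = np.where(ok, std, 1.0)
    z = d / safe[:, :, None]
    kur = np.mean(z**4, axis=2) - 3.0
    ske = np.mean(z**3, axis=2)
    acf = np.einsum("cet,cet->ce", d[:, :, : length - lag], d[:, :, lag:]) / (
        length * np.where(ok, var, 1.0)
    )
    kur[~ok] = np.nan
    ske[~ok] = np.nan
    acf[~ok] = np.nan
    std[~ok] = 0.0

    rows = {
        "epoch": np.repeat(np.arange(n_ep), n_ch),
        "channel": np.tile(np.arange(n_ch), n_ep),
        "stage": np.repeat(hypnogram.stages, n_ch),
        "STD": std.T.ravel(),
        "KUR": kur.T.ravel(),
        "SKE": ske.T.ravel(),
        "ACF300": acf.T.ravel(),
        "artifact": np.repeat(hypnogram.artifact_mask, n_ch),
    }
    return pd.DataFrame(rows)


def amplitude_histograms(
    epochs: np.ndarray,
    n_bins: int = 201,
    amplitude_range: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch amplitude densities on a shared symmetric bin grid.

    The grid spans ±``amplitude_range``; when not given, the range is the
    99.99th percentile of the pooled absolute amplitudes, so all epochs of
    a recording share one axis.

    Returns
    -------
    hist : ndarray, shape (n_channels, n_epochs, n_bins)
        Probability densities (each epoch's histogram integrates to 1).
    edges : ndarray, shape (n_bins + 1,)
    """
    if amplitude_range is None:
        amplitude_range = float(np.percentile(np.abs(epochs), 99.99))
    if amplitude_range <= 0:
        raise UndefinedStatisticError("all amplitudes zero: histogram undefined")
    edges = np.linspace(-amplitude_range, amplitude_range, n_bins + 1)
    n_ch, n_ep, _ = epochs.shape
    hist = np.empty((n_ch, n_ep, n_bins), dtype=float)
    for c in range(n_ch):
        for e in range(n_ep):
            h, _ = np.histogram(np.clip(epochs[c, e], edges[0], edges[-1]),
                                bins=edges, density=True)
            hist[c, e] = h
    return hist, edges


def pool_by_stage(
    curves: np.ndarray,
    hypnogram: Hypnogram,
) -> dict[str, np.ndarray]:
    """Average per-epoch curves (histograms, ACFs, CCFs) by sleep stage.

    ``curves`` has shape (n_channels, n_epochs, m) or (n_epochs, m); every
    unmasked (epoch, channel) pair enters the average of its stage with
    equal weight.  Stages absent from the hypnogram are omitted (logged).
    """
    arr = np.asarray(curves, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    n_ch, n_ep = arr.shape[:2]
    if n_ep != len(hypnogram):
        raise ValueError("curves and hypnogram cover different epoch counts")
    keep = ~hypnogram.artifact_mask
    out: dict[str, np.ndarray] = {}
    for stage in STAGES:
        sel = keep & (hypnogram.stages == stage)
        if not sel.any():
            logger.info("stage %s absent from hypnogram; omitted from pooling",
                        stage)
            continue
        out[stage] = arr[:, sel].reshape(-1, arr.shape[2]).mean(axis=0)
    return out


def pool_hyperparameters(
    table: pd.DataFrame,
    hyper_names: Sequence[str] = HYPER_NAMES,
) -> dict[str, dict[str, np.ndarray]]:
    """Pool (not average) hyper-parameter samples by stage.

    Artifact rows and undefined (NaN) values are excluded.  Returns
    ``{stage: {hyper_name: samples}}`` over the stages present.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    clean = table[~table["artifact"].astype(bool)]
    for stage, grp in clean.groupby("stage", sort=False):
        out[str(stage)] = {
            h: grp[h].dropna().to_numpy(dtype=float) for h in hyper_names
        }
    return {s: out[s] for s in STAGES if s in out}
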