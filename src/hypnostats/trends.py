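"""Within-phase linear trends of hyper-parameters.

A *sleep phase* is a maximal run of consecutive epochs with the same
stage label; phases tile the hypnogram.  Within each phase the time
series of a hyper-parameter is approximated by an ordinary least-squares
line ``f(n) ≈ a_J * n + b_J`` and the slopes ``a_J`` are averaged per
stage — with REM, N1 and N2 phases split into the *falling* part of the
sleep cycle (on the descent towards N3) and the *rising* part (on the
ascent towards Wake).

The falling/rising assignment scans the phase sequence forwards: a
REM/N1/N2 phase is *falling* if an N3 phase occurs ahead before any Wake
phase, and *rising* if Wake occurs first.  If neither extreme stage lies
ahead, the backward scan is used with the roles of Wake and N3 swapped
(a phase preceded most recently by Wake is falling, by N3 rising).
Phases that neither scan resolves get direction ``none`` and are
excluded from the directed aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .epochs import HYPER_NAMES, Hypnogram

logger = logging.getLogger(__name__)

__all__ = [
    "SleepPhase",
    "PhaseSlope",
    "segment_phases",
    "annotate_cycle_direction",
    "phase_slopes",
    "stage_mean_slopes",
    "DIRECTED_STAGE_ORDER",
]

#: Row order of the directed-stage trend table.
DIRECTED_STAGE_ORDER: tuple[str, ...] = (
    "Wake", "REM↓", "N1↓", "N2↓", "N3", "N2↑", "N1↑", "REM↑",
)


@dataclass
class SleepPhase:
    """Maximal same-stage run of epochs ``[t_beg, t_end]`` (inclusive)."""

    stage: str
    t_beg: int
    t_end: int
    cycle_direction: str = "none"   # "falling" | "rising" | "none"

    @property
    def n_epochs(self) -> int:
        return self.t_end - self.t_beg + 1

    @property
    def directed_stage(self) -> str:
        """Stage label with ↓/↑ arrow for directed REM/N1/N2 phases."""
        if self.cycle_direction == "falling":
            return self.stage + "↓"
        if self.cycle_direction == "rising":
            return self.stage + "↑"
        return self.stage


@dataclass
class PhaseSlope:
    """OLS trend of one hyper-parameter within one phase.

    ``slope`` is in hyper-parameter units per epoch; ``intercept`` is the
    fitted value at the first epoch of the phase.
    """

    phase: SleepPhase
    hyper_name: str
    slope: float
    intercept: float
    n_points: int


def segment_phases(hypnogram: Hypnogram | Sequence[str]) -> list[SleepPhase]:
    """Run-length encode a hypnogram into ordered sleep phases."""
    stages = (list(hypnogram.stages) if isinstance(hypnogram, Hypnogram)
              else list(hypnogram))
    if not stages:
        raise ValueError("empty hypnogram")
    phases: list[SleepPhase] = []
    start = 0
    for n in range(1, len(stages) + 1):
        if n == len(stages) or stages[n] != stages[start]:
            phases.append(SleepPhase(stages[start], start, n - 1))
            start = n
    return phases


def annotate_cycle_direction(phases: Sequence[SleepPhase]) -> list[SleepPhase]:
    """Assign falling/rising cycle direction to REM/N1/N2 phases.

    Wake and N3 phases (the cycle extremes) always get ``none``.  See
    the module docstring for the scanning rule.
    """
    labels = [p.stage for p in phases]

    def scan(start: int, step: int, falling_marker: str) -> str | None:
        rising_marker = "Wake" if falling_marker == "N3" else "N3"
        i = start + step
        while 0 <= i < len(labels):
            if labels[i] == falling_marker:
                return "falling"
            if labels[i] == rising_marker:
                return "rising"
            i += step
        return None

    out = []
    for i, p in enumerate(phases):
        direction = "none"
        if p.stage in ("REM", "N1", "N2"):
            # forward: heading to N3 = falling, to Wake = rising
            d = scan(i, +1, falling_marker="N3")
            if d is None:
                # backward with roles swapped: coming from Wake = falling
                d = scan(i, -1, falling_marker="Wake")
            direction = d or "none"
        out.append(SleepPhase(p.stage, p.t_beg, p.t_end, direction))
    return out


def phase_slopes(
    table: pd.DataFrame,
    phases: Sequence[SleepPhase],
    hyper_name: str,
    channel_policy: str = "average",
) -> list[PhaseSlope]:
    """OLS slope of one hyper-parameter within each phase.

    The hyper-parameter is averaged over channels per epoch first
    (``channel_policy="average"``, the only policy); artifact-masked
    epochs are dropped from the fit, but the regressor stays the epoch
    *index*, so gaps do not distort the time axis.  Phases with fewer
    than two usable epochs are skipped (logged).
    """
    if channel_policy != "average":
        raise ValueError(f"unknown channel_policy {channel_policy!r}")
    if hyper_name not in table.columns:
        raise LookupError(f"hyper-parameter {hyper_name!r} not in table")
    clean = table[~table["artifact"].astype(bool)]
    per_epoch = clean.groupby("epoch")[hyper_name].mean()

    out: list[PhaseSlope] = []
    for phase in phases:
        idx = per_epoch.index[(per_epoch.index >= phase.t_beg)
                              & (per_epoch.index <= phase.t_end)]
        vals = per_epoch.loc[idx].dropna()
        if len(vals) < 2:
            logger.info("phase %s [%d, %d] has %d usable epochs; skipped",
                        phase.stage, phase.t_beg, phase.t_end, len(vals))
            continue
        x = vals.index.to_numpy(dtype=float) - phase.t_beg
        slope, intercept = np.polyfit(x, vals.to_numpy(dtype=float), 1)
        out.append(PhaseSlope(phase, hyper_name, float(slope),
                              float(intercept), len(vals)))
    return out


def stage_mean_slopes(
    slopes: Iterable[PhaseSlope],
    directed: bool = True,
) -> pd.DataFrame:
    """Mean slope ± standard error per (directed) stage and hyper-parameter.

    Returns a DataFrame indexed by directed stage (rows ordered Wake,
    REM↓, N1↓, N2↓, N3, N2↑, N1↑, REM↑) with columns
    ``slope_<h>``, ``error_<h>``, ``n_<h>`` per hyper-parameter present.
    The error is the standard error of the mean over phases (NaN for a
    single phase); stages without any phase are reported as missing
    (NaN), not zero.
    """
    rows: dict[str, dict[str, float]] = {}
    grouped: dict[tuple[str, str], list[float]] = {}
    for ps in slopes:
        key = ps.phase.directed_stage if directed else ps.phase.stage
        if directed and ps.phase.stage in ("REM", "N1", "N2") \
                and ps.phase.cycle_direction == "none":
            continue   # unresolved cycle direction: excluded
        grouped.setdefault((key, ps.hyper_name), []).append(ps.slope)

    hyper_names = sorted({h for (_, h) in grouped},
                         key=lambda h: (HYPER_NAMES.index(h)
                                        if h in HYPER_NAMES else 99))
    order = DIRECTED_STAGE_ORDER if directed else \
        ("Wake", "REM", "N1", "N2", "N3")
    for stage_key in order:
        rows[stage_key] = {}
        for h in hyper_names:
            vals = grouped.get((stage_key, h))
            if not vals:
                rows[stage_key][f"slope_{h}"] = np.nan
                rows[stage_key][f"error_{h}"] = np.nan
                rows[stage_key][f"n_{h}"] = 0
                continue
            arr = np.asarray(vals, dtype=float)
            rows[stage_key][f"slope_{h}"] = float(arr.mean())
            rows[stage_key][f"error_{h}"] = (
                float(arr.std(ddof=1) / np.sqrt(arr.size))
                if arr.size > 1 else np.nan)
            rows[stage_key][f"n_{h}"] = int(arr.size)
    return pd.DataFrame.from_dict(rows, orient="index")
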