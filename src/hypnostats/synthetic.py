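"""Synthetic stage-labeled full-night EEG surrogate generator.

Real sleep EEG behaves like a *heterogeneous random walk*: within any
short window it is well described by a low-order autoregressive process,
but the parameters of that process (amplitude scale, tail weight,
correlation strength) drift with the sleep stage and within stages.
This module generates surrogate recordings with exactly that two-level
structure, with analytically known statistics, so that every downstream
estimator can be tested without clinical data:

* a first-order Markov chain over {Wake, REM, N1, N2, N3} produces the
  per-epoch stage sequence (the hypnogram);
* within each 30-s epoch the signal is an AR(1) process whose
  innovations are standardized Student-t (heavy tails), optionally
  skewed by a two-sided scale asymmetry, and whose innovation scale is
  modulated block-wise (0.25-s blocks) by independent log-normal
  factors — the super-statistical mechanism that produces the large
  excess kurtosis seen in real recordings;
* within each contiguous same-stage run the per-epoch scale multiplier
  evolves geometrically, emulating the slow within-phase amplitude
  trends of real sleep.

Closed forms used by the tests (all for ``variance_mod_sd = 0`` unless
stated):

* stationary AR(1) autocorrelation at lag l is ``phi**l``;
* an AR(1) process driven by innovations with excess kurtosis k_eps has
  signal excess kurtosis ``k_eps * (1 - phi**2) / (1 + phi**2)``;
* for ``phi = 0`` and Gaussian innovations with log-normal scale
  ``exp(tau * G)``, the signal excess kurtosis is ``3*(exp(4 tau^2)-1)``.

The generator makes no attempt at biophysically realistic rhythms
(spindles, K-complexes, alpha waves); it emulates the amplitude
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.special import gammaln

from .epochs import (
    STAGES,
    STAGE_INDEX,
    Hypnogram,
    Recording,
    epoch_length_samples,
)
from .markov import InvalidModelError, TransitionMatrix

__all__ = [
    "StageParams",
    "GeneratorConfig",
    "default_stage_params",
    "default_transition_matrix",
    "simulate_stage_sequence",
    "simulate_epoch_signal",
    "generate_recording",
]

#: Samples per variance-modulation block (0.25 s at 256 Hz).
VARIANCE_BLOCK_SAMPLES = 64

#: Artifact epochs are overwritten with a square burst at this multiple
#: of the stage's base scale.
ARTIFACT_BURST_FACTOR = 5.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class StageParams:
    """First-level (within-epoch) process parameters for one sleep stage.

    Parameters
    ----------
    stage : str
        Stage label this parameter set belongs to.
    ar_coefficient : float
        AR(1) coefficient phi, |phi| < 1.  Sets the ACF decay time.
    base_scale : float
        Innovation scale in µV (for phi = 0 and no modulation this is
        the stationary signal STD).
    tail_dof : float
        Degrees of freedom of the Student-t innovations (> 2 for a
        finite variance; > 4 needed for a finite kurtosis).
    skew_coefficient : float
        Two-sided scale asymmetry: positive/negative draws are scaled by
        ``exp(+-skew_coefficient)`` and the result re-standardized, so
        positive values give right-skewed innovations.  0 = symmetric.
    variance_mod_sd : float
        Standard deviation tau of the log innovation scale; each 0.25-s
        block gets an independent factor ``exp(tau * G)``, ``G ~ N(0,1)``.
    trend_per_epoch : float
        Fractional change of the scale multiplier per epoch within a
        contiguous same-stage phase (0 = no trend).
    """

    stage: str
    ar_coefficient: float = 0.95
    base_scale: float = 30.0
    tail_dof: float = 8.0
    skew_coefficient: float = 0.0
    variance_mod_sd: float = 0.2
    trend_per_epoch: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.ar_coefficient) < 1:
            raise InvalidModelError(
                f"ar_coefficient {self.ar_coefficient} is not stationary "
                f"(need |phi| < 1)"
            )
        if self.base_scale <= 0:
            raise InvalidModelError("base_scale must be positive")
        if self.tail_dof <= 2:
            raise InvalidModelError("tail_dof must exceed 2 (finite variance)")
        if self.variance_mod_sd < 0:
            raise InvalidModelError("variance_mod_sd must be >= 0")


def default_stage_params() -> dict[str, StageParams]:
    """Default per-stage generator presets.

    The amplitude scales increase monotonically from Wake to N3
    (10/25/60/140/300 µV), mirroring the physiological progression from
    low-amplitude desynchronized activity towards large slow waves, and
    keeping the stage clusters well separated in STD.  N3 gets the
    strongest temporal correlation, as in real recordings.  These values
    are conventions of this package, not estimates from clinical data.
    """
    spec = {
        "Wake": dict(ar_coefficient=0.95, base_scale=10.0, tail_dof=6.0,
                     skew_coefficient=0.10),
        "REM": dict(ar_coefficient=0.96, base_scale=25.0, tail_dof=6.0,
                    skew_coefficient=-0.05),
        "N1": dict(ar_coefficient=0.96, base_scale=60.0, tail_dof=8.0,
                   skew_coefficient=0.05),
        "N2": dict(ar_coefficient=0.97, base_scale=140.0, tail_dof=8.0,
                   skew_coefficient=0.0),
        "N3": dict(ar_coefficient=0.985, base_scale=300.0, tail_dof=10.0,
                   skew_coefficient=-0.10),
    }
    return {s: StageParams(stage=s, variance_mod_sd=0.2, **kw)
            for s, kw in spec.items()}


def default_transition_matrix() -> TransitionMatrix:
    """Default epoch-to-epoch transition matrix for simulated hypnograms.

    Diagonal-dominant (stages persist over many epochs) with the typical
    progression Wake → N1 → N2 → N3, N2↔N3 oscillations and REM entered
    mostly from N1/N2.  A convention of this package.
    """
    p = np.array([
        # Wake   REM    N1     N2     N3
        [0.920, 0.010, 0.060, 0.010, 0.000],   # Wake
        [0.020, 0.900, 0.050, 0.030, 0.000],   # REM
        [0.040, 0.030, 0.850, 0.080, 0.000],   # N1
        [0.010, 0.020, 0.040, 0.880, 0.050],   # N2
        [0.000, 0.000, 0.010, 0.060, 0.930],   # N3
    ])
    return TransitionMatrix(p)


@dataclass
class GeneratorConfig:
    """Configuration of a full surrogate recording."""

    n_epochs: int = 120
    sampling_rate: float = 256.0
    epoch_seconds: float = 30.0
    channels: Sequence[str] = ("F4-M1", "C4-M1", "O2-M1")
    transition_matrix: TransitionMatrix = field(
        default_factory=default_transition_matrix)
    initial_stage: str = "Wake"
    stage_params: Mapping[str, StageParams] = field(
        default_factory=default_stage_params)
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.initial_stage not in STAGE_INDEX:
            raise ValueError(f"unknown initial stage {self.initial_stage!r}")
        epoch_length_samples(self.sampling_rate, self.epoch_seconds)
        missing = [s for s in STAGES if s not in self.stage_params]
        if missing:
            raise ValueError(f"stage_params missing stages {missing}")


def simulate_stage_sequence(
    transition_matrix: TransitionMatrix,
    n_epochs: int,
    initial_stage: str = "Wake",
    seed=None,
) -> list[str]:
    """Sample a stage sequence from a first-order Markov chain.

    The first element is ``initial_stage``; each successor is drawn from
    the matrix row of its predecessor.  Reproducible for a fixed seed.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = _rng(seed)
    p = transition_matrix.probabilities
    state = STAGE_INDEX[initial_stage]
    out = [STAGES[state]]
    # cumulative rows + inverse-CDF draws; one uniform per epoch
    cum = np.cumsum(p, axis=1)
    u = rng.random(n_epochs - 1)
    for i in range(n_epochs - 1):
        if p[state].sum() == 0.0:
            raise InvalidModelError(
                f"no outgoing transition probabilities for stage "
                f"{STAGES[state]!r}"
            )
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 4)
        out.append(STAGES[state])
    return out


def _abs_moment_std_t(dof: float) -> float:
    """E|Z| for a Student-t standardized to unit variance."""
    if not np.isfinite(dof):
        return float(np.sqrt(2.0 / np.pi))
    # E|T_v| = 2 sqrt(v/pi) Gamma((v+1)/2) / ((v-1) Gamma(v/2)); divide by
    # the raw std sqrt(v/(v-2)) to standardize.
    log_e = (np.log(2.0) + 0.5 * np.log(dof / np.pi)
             + gammaln((dof + 1) / 2) - np.log(dof - 1) - gammaln(dof / 2))
    return float(np.exp(log_e) / np.sqrt(dof / (dof - 2)))


def _standardized_innovations(
    rng: np.random.Generator,
    n: int,
    tail_dof: float,
    skew_coefficient: float,
) -> np.ndarray:
    """Zero-mean unit-variance heavy-tailed, optionally skewed, draws.

    Symmetric part: Student-t(tail_dof) scaled to unit variance (plain
    normal for infinite dof).  Skewing multiplies positive draws by
    ``g = exp(skew_coefficient)`` and negative draws by ``1/g`` and then
    re-standardizes with the analytic mean and variance of the skewed
    variable, so the innovation scale contract is unaffected by skew.
    """
    if np.isfinite(tail_dof):
        z = rng.standard_t(tail_dof, size=n) / np.sqrt(
            tail_dof / (tail_dof - 2.0))
    else:
        z = rng.standard_normal(n)
    if skew_coefficient == 0.0:
        return z
    g = float(np.exp(skew_coefficient))
    w = np.where(z >= 0, z * g, z / g)
    e_abs = _abs_moment_std_t(tail_dof)
    mean_w = 0.5 * (g - 1.0 / g) * e_abs
    var_w = 0.5 * (g * g + 1.0 / (g * g)) - mean_w**2
    return (w - mean_w) / np.sqrt(var_w)


def simulate_epoch_signal(
    params: StageParams,
    n_samples: int,
    scale_multiplier: float = 1.0,
    seed=None,
    block_samples: int = VARIANCE_BLOCK_SAMPLES,
) -> np.ndarray:
    """Simulate one single-channel epoch segment.

    AR(1) recursion ``y_t = phi * y_{t-1} + eps_t`` where ``eps_t`` has
    scale ``base_scale * scale_multiplier * exp(tau * G_b)`` with one
    standard-normal ``G_b`` per 0.25-s block.  The recursion starts from
    a draw with the stationary scale of the first block, so per-epoch
    moments carry no startup transient.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(seed)
    phi = params.ar_coefficient
    n_blocks = -(-n_samples // block_samples)
    if params.variance_mod_sd > 0:
        factors = np.exp(params.variance_mod_sd * rng.standard_normal(n_blocks))
    else:
        factors = np.ones(n_blocks)
    scale = (params.base_scale * scale_multiplier
             * np.repeat(factors, block_samples)[:n_samples])
    eps = scale * _standardized_innovations(
        rng, n_samples, params.tail_dof, params.skew_coefficient)
    if phi == 0.0:
        return eps
    # stationary initial value: same innovation law, stationary scale
    y_prev = (scale[0] / np.sqrt(1.0 - phi * phi)) * _standardized_innovations(
        rng, 1, params.tail_dof, params.skew_coefficient)[0]
    y, _ = _signal.lfilter([1.0], [1.0, -phi], eps, zi=[phi * y_prev])
    return y


def _phase_scale_multipliers(stages: Sequence[str],
                             stage_params: Mapping[str, StageParams]
                             ) -> np.ndarray:
    """Per-epoch geometric scale multipliers, reset at each phase start."""
    mult = np.ones(len(stages))
    j = 0
    for n, s in enumerate(stages):
        if n > 0 and stages[n] == stages[n - 1]:
            j += 1
        else:
            j = 0
        mult[n] = (1.0 + stage_params[s].trend_per_epoch) ** j
    return mult


def _artifact_burst(n_samples: int, amplitude: float,
                    half_period: int = 128) -> np.ndarray:
    """Saturated square burst used to overwrite artifact epochs."""
    t = np.arange(n_samples)
    return amplitude * np.where((t // half_period) % 2 == 0, 1.0, -1.0)


def generate_recording(
    config: GeneratorConfig,
) -> tuple[Recording, Hypnogram, pd.DataFrame]:
    """Generate a full surrogate recording.

    Returns the multi-channel :class:`Recording`, the matching
    :class:`Hypnogram` (with artifact mask), and a ground-truth table
    with one row per epoch: ``epoch, stage, scale_multiplier, artifact``.
    All channels share the stage sequence and scale multipliers but have
    independent noise.  A single pseudo-random stream derived from
    ``config.seed`` drives everything, so output is bit-reproducible.
    """
    rng = _rng(config.seed)
    epoch_len = epoch_length_samples(config.sampling_rate, config.epoch_seconds)
    stages = simulate_stage_sequence(
        config.transition_matrix, config.n_epochs, config.initial_stage, rng)
    artifacts = rng.random(config.n_epochs) < config.artifact_rate
    mult = _phase_scale_multipliers(stages, config.stage_params)

    n_ch = len(config.channels)
    signals = np.empty((n_ch, config.n_epochs * epoch_len))
    for c in range(n_ch):
        for n, s in enumerate(stages):
            p = config.stage_params[s]
            seg = simulate_epoch_signal(p, epoch_len, mult[n], rng)
            if artifacts[n]:
                seg = _artifact_burst(
                    epoch_len, ARTIFACT_BURST_FACTOR * p.base_scale)
            signals[c, n * epoch_len:(n + 1) * epoch_len] = seg

    recording = Recording(signals, config.sampling_rate,
                          list(config.channels))
    hypnogram = Hypnogram(np.array(stages, dtype=object), artifacts)
    truth = pd.DataFrame({
        "epoch": np.arange(config.n_epochs),
        "stage": stages,
        "scale_multiplier": mult,
        "artifact": artifacts,
    })
    return recording, hypnogram, truth
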