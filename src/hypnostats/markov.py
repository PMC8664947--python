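"""Sleep-stage transition matrices.

The scored hypnogram is treated as a random walk over the discrete state
space {Wake, REM, N1, N2, N3}.  Two first-order descriptions are
estimated from one or more recordings:

* the epoch-to-epoch matrix ``M(s_{n+1} | s_n)``, whose diagonal is
  close to one because stages persist over many 30-s epochs, and
* the phase-to-phase matrix ``M(s_{J+1} | s_J)`` over maximal same-stage
  runs, whose diagonal is structurally zero.

Counts are pooled across recordings; a transition is never counted
across a recording boundary.  Artifact-masked epochs keep their scored
stage label and therefore still contribute transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .epochs import STAGES, STAGE_INDEX, Hypnogram

__all__ = [
    "TransitionMatrix",
    "epoch_transition_matrix",
    "phase_transition_matrix",
]


class NoDataError(ValueError):
    """No transitions observed in the input."""


class InvalidModelError(ValueError):
    """A stochastic-model object violates its defining constraints."""


@dataclass
class TransitionMatrix:
    """Row-stochastic 5x5 matrix over the fixed stage alphabet.

    ``probabilities[i, j]`` is the probability of moving from
    ``STAGES[i]`` to ``STAGES[j]``.  Rows without any observation are
    all-zero and listed in ``unobserved_rows``.  The raw transition
    counts are retained alongside the normalized probabilities.
    """

    probabilities: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (5, 5):
            raise InvalidModelError(f"expected a 5x5 matrix, got {p.shape}")
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-12):
            raise InvalidModelError("probabilities must lie in [0, 1]")
        rowsum = p.sum(axis=1)
        bad = ~(np.isclose(rowsum, 1.0, atol=1e-12) | (rowsum == 0.0))
        if bad.any():
            raise InvalidModelError(
                f"rows {np.nonzero(bad)[0].tolist()} do not sum to 1 "
                f"(sums {rowsum[bad].tolist()})"
            )
        self.probabilities = p
        if self.counts is None:
            self.counts = np.zeros((5, 5))
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def unobserved_rows(self) -> list[str]:
        return [STAGES[i] for i in range(5)
                if self.probabilities[i].sum() == 0.0]

    def row(self, stage: str) -> np.ndarray:
        return self.probabilities[STAGE_INDEX[stage]]

    @classmethod
    def from_counts(cls, counts: np.ndarray,
                    smoothing: float = 0.0) -> "TransitionMatrix":
        """Normalize a count matrix row-wise, with optional add-alpha smoothing."""
        c = np.asarray(counts, dtype=float)
        sm = c + smoothing
        rowsum = sm.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rowsum > 0, sm / np.where(rowsum > 0, rowsum, 1.0), 0.0)
        return cls(p, counts=c)


def _stage_labels(seq) -> list[str]:
    """Accept a Hypnogram, a list of stage labels, or a list of phase objects."""
    if isinstance(seq, Hypnogram):
        return list(seq.stages)
    out = []
    for item in seq:
        out.append(item.stage if hasattr(item, "stage") else str(item))
    return out


def epoch_transition_matrix(
    hypnograms: Iterable[Hypnogram | Sequence[str]],
    smoothing: float = 0.0,
) -> TransitionMatrix:
    """Estimate the epoch-to-epoch transition matrix from scored hypnograms.

    Counts are pooled over all recordings; rows are normalized to
    probabilities, optionally after adding the pseudo-count ``smoothing``
    to every cell (default 0: plain maximum likelihood).

    Raises
    ------
    NoDataError
        If no transition at all is observed.
    """
    counts = np.zeros((5, 5))
    total = 0
    for hyp in hypnograms:
        labels = _stage_labels(hyp)
        idx = np.array([STAGE_INDEX[s] for s in labels], dtype=int)
        for a, b in zip(idx[:-1], idx[1:]):
            counts[a, b] += 1
            total += 1
    if total == 0:
        raise NoDataError("no epoch-to-epoch transitions in input")
    tm = TransitionMatrix.from_counts(counts, smoothing=smoothing)
    if tm.unobserved_rows:
        import logging
        logging.getLogger(__name__).warning(
            "no transitions observed out of stages %s; rows left at zero",
            tm.unobserved_rows,
        )
    return tm


def phase_transition_matrix(
    phase_lists: Iterable[Sequence],
) -> TransitionMatrix:
    """Estimate the phase-to-phase transition matrix.

    ``phase_lists`` holds, per recording, the ordered sleep phases
    (``SleepPhase`` objects or plain stage labels).  Successive phases
    always differ in stage, so the diagonal is structurally zero.
    Recordings with fewer than two phases contribute nothing.
    """
    counts = np.zeros((5, 5))
    total = 0
    for phases in phase_lists:
        labels = _stage_labels(phases)
        idx = [STAGE_INDEX[s] for s in labels]
        for a, b in zip(idx[:-1], idx[1:]):
            if a == b:
                raise InvalidModelError(
                    "consecutive phases share a stage; input is not a "
                    "phase segmentation"
                )
            counts[a, b] += 1
            total += 1
    if total == 0:
        raise NoDataError("no phase-to-phase transitions in input")
    return TransitionMatrix.from_counts(counts)
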