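"""Bayesian sleep-stage inference from per-epoch hyper-parameters.

A forward (filter-style) Bayesian update over the five stages: the prior
for epoch ``n`` is the previous posterior propagated through the
epoch-to-epoch transition matrix,

    Pi(s_n) ∝ sum_{s_{n-1}} M(s_n | s_{n-1}) P(s_{n-1}),

and the posterior multiplies the prior with the global likelihood

    P(s_n) ∝ Q(D_n | s_n) Pi(s_n),
    Q(D_n | s_n) = prod_k q(h_kn | s_n),

the product running over the selected hyper-parameters (typically STD,
KUR, SKE).  All products are computed in the log domain; the likelihood
floor of the distribution model keeps them finite.  On artifact epochs
the update uses the prior only.  The filter starts from a point mass on
Wake (the subject is assumed awake at lights-off); a uniform start is
available.  No backward pass or Viterbi decoding is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distributions import StageLikelihoodModel, fit_stage_likelihoods
from .epochs import STAGES, STAGE_INDEX, Hypnogram, pool_hyperparameters
from .markov import TransitionMatrix, epoch_transition_matrix

__all__ = [
    "PosteriorSequence",
    "bayes_update",
    "infer_sequence",
    "accuracy",
    "accuracy_by_subset",
    "DegenerateModelError",
]


class DegenerateModelError(ValueError):
    """The propagated prior vanished; the model cannot continue."""


@dataclass
class PosteriorSequence:
    """Per-epoch posterior stage probabilities and MAP labels."""

    probabilities: np.ndarray        # (n_epochs, 5), rows sum to 1
    artifact: np.ndarray             # (n_epochs,) bool

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 5:
            raise ValueError("probabilities must have shape (n_epochs, 5)")
        if np.any(np.abs(self.probabilities.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("posterior rows must sum to 1 within 1e-9")

    @property
    def map_labels(self) -> np.ndarray:
        return np.asarray(
            [STAGES[i] for i in self.probabilities.argmax(axis=1)],
            dtype=object)

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities,
                          columns=[f"P_{s}" for s in STAGES])
        df.insert(0, "epoch", np.arange(len(self)))
        df["MAP"] = self.map_labels
        df["artifact"] = self.artifact
        return df


def bayes_update(
    prev_posterior: np.ndarray,
    transition_matrix: TransitionMatrix,
    likelihood_factors: np.ndarray | None,
    artifact: bool = False,
) -> np.ndarray:
    """One filter step: propagate, then (unless artifact) reweight.

    Parameters
    ----------
    prev_posterior : (5,) array
        Normalized posterior of the previous epoch.
    likelihood_factors : (5,) array or None
        Per-stage global likelihood ``Q(D_n | s)`` (strictly positive).
        ``None`` behaves like an artifact epoch (prior only).
    artifact : bool
        If true, the update returns the propagated prior unchanged.
    """
    prev = np.asarray(prev_posterior, dtype=float)
    prior = transition_matrix.probabilities.T @ prev
    total = prior.sum()
    if total <= 0:
        raise DegenerateModelError(
            "propagated prior is all zero (absorbing unobserved row?)")
    prior = prior / total
    if artifact or likelihood_factors is None:
        return prior
    q = np.asarray(likelihood_factors, dtype=float)
    if np.any(q <= 0):
        raise ValueError("likelihood factors must be strictly positive")
    return _posterior_from_log(np.log(q), prior)


def _posterior_from_log(log_q: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Normalized posterior ∝ exp(log_q)·prior; zero-prior stages stay zero."""
    support = prior > 0
    lp = np.full(prior.shape, -np.inf)
    lp[support] = log_q[support] + np.log(prior[support])
    lp -= lp[support].max()
    post = np.exp(lp)
    return post / post.sum()


def _epoch_hyper_values(
    table: pd.DataFrame,
    hyper_names: Sequence[str],
    channel_policy: str = "average",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch hyper-parameter values and artifact flags from the table."""
    if channel_policy != "average":
        raise ValueError(f"unknown channel_policy {channel_policy!r}")
    missing = [h for h in hyper_names if h not in table.columns]
    if missing:
        raise LookupError(f"hyper-parameters {missing} absent from table")
    grouped = table.groupby("epoch")
    values = grouped[list(hyper_names)].mean() if hyper_names else None
    artifact = grouped["artifact"].any()
    epochs = artifact.index.to_numpy()
    if not np.array_equal(epochs, np.arange(epochs.min(),
                                            epochs.min() + len(epochs))):
        raise ValueError("hyper table must cover contiguous epochs")
    vals = (values.to_numpy(dtype=float) if values is not None
            else np.empty((len(epochs), 0)))
    return epochs, vals, artifact.to_numpy(dtype=bool)


def infer_sequence(
    table: pd.DataFrame,
    model: StageLikelihoodModel,
    transition_matrix: TransitionMatrix,
    hyper_names: Sequence[str] = ("STD", "KUR", "SKE"),
    channel_policy: str = "average",
    initial: str = "wake-point-mass",
) -> PosteriorSequence:
    """Run the forward Bayesian filter over a whole recording.

    Hyper-parameters are averaged across channels per epoch before the
    likelihood lookup; the per-epoch global likelihood is the product of
    the selected factors (log-domain).  Epochs whose values are NaN (and
    artifact-flagged epochs) are updated with the prior only.

    ``initial`` is ``"wake-point-mass"`` (default: the filter starts
    certain of Wake) or ``"uniform"``.
    """
    for h in hyper_names:
        if h not in model.hyper_names:
            raise LookupError(
                f"hyper-parameter {h!r} not in likelihood model "
                f"({model.hyper_names})")
    epochs, vals, artifact = _epoch_hyper_values(
        table, hyper_names, channel_policy)
    n = len(epochs)

    # log-likelihood factors per epoch and stage, vectorized per stage
    log_q = np.zeros((n, 5))
    have_value = np.ones(n, dtype=bool)
    if hyper_names:
        have_value = np.all(np.isfinite(vals), axis=1)
        for j, s in enumerate(STAGES):
            if s not in model.stage_names:
                # stage unseen in training: fall back to the density floor
                log_q[:, j] = len(hyper_names) * np.log(model.floor)
                continue
            for k, h in enumerate(hyper_names):
                v = np.where(have_value, vals[:, k], 0.0)
                log_q[:, j] += np.log(model.evaluate(h, v, s))

    if initial == "wake-point-mass":
        posterior = np.zeros(5)
        posterior[STAGE_INDEX["Wake"]] = 1.0
    elif initial == "uniform":
        posterior = np.full(5, 0.2)
    else:
        raise ValueError(f"unknown initial condition {initial!r}")

    probs = np.empty((n, 5))
    for i in range(n):
        prior_only = artifact[i] or not have_value[i] or not hyper_names
        if i == 0:
            prior = posterior   # initial prior, already normalized
            if prior_only:
                posterior = prior
            else:
                posterior = _posterior_from_log(log_q[i], prior)
        else:
            factors = None if prior_only else np.exp(
                log_q[i] - log_q[i].max())
            posterior = bayes_update(posterior, transition_matrix, factors,
                                     artifact=prior_only)
        probs[i] = posterior
    return PosteriorSequence(probs, artifact)


def accuracy(predicted: Sequence[str], reference: Hypnogram | Sequence[str],
             ignore_masked: bool = True) -> float:
    """Fraction of correctly predicted stage labels.

    Artifact-masked epochs are excluded from the count by default.
    """
    if isinstance(reference, Hypnogram):
        ref = reference.stages
        mask = reference.artifact_mask if ignore_masked else \
            np.zeros(len(ref), dtype=bool)
    else:
        ref = np.asarray(list(reference), dtype=object)
        mask = np.zeros(len(ref), dtype=bool)
    pred = np.asarray(list(predicted), dtype=object)
    if len(pred) != len(ref):
        raise ValueError(
            f"length mismatch: {len(pred)} predictions vs {len(ref)} epochs")
    keep = ~mask
    if keep.sum() == 0:
        raise ValueError("no unmasked epochs to score")
    return float(np.mean(pred[keep] == ref[keep]))


def _all_subsets(hyper_names: Sequence[str]) -> list[tuple[str, ...]]:
    subsets = []
    for r in range(1, len(hyper_names) + 1):
        subsets.extend(combinations(hyper_names, r))
    return subsets


def accuracy_by_subset(
    recordings: Sequence[tuple[pd.DataFrame, Hypnogram]],
    subsets: Sequence[Sequence[str]] | None = None,
    transition_matrix: TransitionMatrix | None = None,
    n_bins: int = 50,
    cross_validate: bool = True,
) -> pd.DataFrame:
    """Per-recording staging accuracy for combinations of hyper-parameters.

    For each recording, the likelihood model (and, unless given, the
    transition matrix) is fitted on the *other* recordings
    (leave-one-recording-out, default) and the filter is scored against
    that recording's hypnogram.  With a single recording or
    ``cross_validate=False``, fitting uses all recordings (in-sample).

    Returns a tidy DataFrame with columns ``subset, recording, accuracy``
    plus a ``subset_size`` column; means per subset mirror the
    distribution summaries one would plot.
    """
    if subsets is None:
        subsets = _all_subsets(("STD", "KUR", "SKE"))
    subsets = [tuple(s) for s in subsets]
    rows = []
    n_rec = len(recordings)
    for i, (table, hyp) in enumerate(recordings):
        if cross_validate and n_rec > 1:
            train = [recordings[j] for j in range(n_rec) if j != i]
        else:
            train = list(recordings)
        pooled: dict[str, dict[str, list[float]]] = {}
        for t, _ in train:
            for stage, hs in pool_hyperparameters(t).items():
                dest = pooled.setdefault(stage, {})
                for h, v in hs.items():
                    dest.setdefault(h, []).append(v)
        pooled_cat = {s: {h: np.concatenate(v) for h, v in hs.items()}
                      for s, hs in pooled.items()}
        model = fit_stage_likelihoods(pooled_cat, n_bins=n_bins)
        tm = transition_matrix
        if tm is None:
            tm = epoch_transition_matrix([h for _, h in train],
                                         smoothing=0.5)
        for subset in subsets:
            post = infer_sequence(table, model, tm, hyper_names=subset)
            acc = accuracy(post.map_labels, hyp)
            rows.append({"subset": "+".join(subset),
                         "subset_size": len(subset),
                         "recording": i, "accuracy": acc})
    return pd.DataFrame(rows)
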