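"""File formats, pipeline configuration and the end-to-end runner.

Formats
-------
* **Recording**: EDF (read via :mod:`mne`, one signal per channel,
  physical unit µV) or delimited text — one column per channel, with
  optional ``# sampling_rate_hz:`` and ``# channels:`` header comments.
  Recordings are written as delimited text.
* **Hypnogram**: two-column text ``epoch_index stage``; indices must be
  contiguous and 0-based; stage labels are case-insensitive.
* **Artifact mask**: one-column 0/1 text.
* **Likelihood model**: single JSON document (see
  :mod:`hypnostats.distributions`).

All floating-point output uses 9 significant digits so regression tests
are byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import accuracy, infer_sequence
from .distributions import fit_stage_likelihoods
from .epochs import (
    HYPER_NAMES,
    STAGES,
    Hypnogram,
    Recording,
    canonical_stage,
    hyperparameter_table,
    pool_hyperparameters,
)
from .markov import TransitionMatrix, epoch_transition_matrix, \
    phase_transition_matrix
from .separability import stage_distance_matrix
from .synthetic import GeneratorConfig, generate_recording
from .trends import annotate_cycle_direction, phase_slopes, segment_phases, \
    stage_mean_slopes

logger = logging.getLogger(__name__)

#: Formatting of every floating-point number written by this module.
FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """A file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# recordings

def read_recording(
    path,
    fmt: str | None = None,
    sampling_rate: float = 256.0,
    channel_labels: Sequence[str] | None = None,
) -> Recording:
    """Read a multi-channel recording from EDF or delimited text.

    ``fmt`` is inferred from the suffix when omitted (``.edf`` → EDF).
    For text files, the sampling rate and channel labels come from the
    header comments when present, else from the arguments.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:   # pragma: no cover
            raise FormatError(
                f"reading {path}: EDF support requires the 'mne' package"
            ) from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                         list(raw.ch_names))
    if fmt != "text":
        raise FormatError(f"unknown recording format {fmt!r}")

    labels = None
    fs = None
    data_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("sampling_rate_hz:"):
                    fs = float(body.split(":", 1)[1])
                elif body.lower().startswith("channels:"):
                    labels = body.split(":", 1)[1].split()
                continue
            parts = line.replace(",", " ").split()
            try:
                data_lines.append([float(v) for v in parts])
            except ValueError:
                raise FormatError(
                    f"{path}, line {lineno}: non-numeric sample value")
    if not data_lines:
        raise FormatError(f"{path}: no sample rows found")
    widths = {len(r) for r in data_lines}
    if len(widths) != 1:
        raise FormatError(
            f"{path}: inconsistent column counts {sorted(widths)} "
            f"(truncated channel?)")
    signals = np.asarray(data_lines, dtype=float).T
    n_ch = signals.shape[0]
    if labels is None:
        labels = (list(channel_labels) if channel_labels is not None
                  else [f"ch{i}" for i in range(n_ch)])
    if len(labels) != n_ch:
        raise FormatError(
            f"{path}: {len(labels)} channel labels for {n_ch} columns")
    return Recording(signals, fs if fs is not None else sampling_rate, labels)


def write_recording(recording: Recording, path, fmt: str = "text") -> Path:
    """Write a recording as delimited text (µV, one column per channel).

    Only the text format is supported for writing; requesting ``edf``
    raises :class:`FormatError` naming the limitation.
    """
    if fmt == "edf":
        raise FormatError(
            "EDF output is not supported (no EDF writer available); "
            "recordings are written as delimited text")
    if fmt != "text":
        raise FormatError(f"unknown recording format {fmt!r}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {FLOAT_FMT % recording.sampling_rate}\n")
        fh.write("# channels: " + " ".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.signals.T, fmt=FLOAT_FMT, delimiter="\t")
    return path


# ---------------------------------------------------------------------------
# hypnograms and masks

def read_hypnogram(path, mask_path=None) -> Hypnogram:
    """Read a two-column ``epoch_index stage`` hypnogram (0-based, contiguous)."""
    stages = []
    expected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}, line {lineno}: expected 'epoch stage', got "
                    f"{line!r}")
            try:
                idx = int(parts[0])
            except ValueError:
                raise FormatError(
                    f"{path}, line {lineno}: non-integer epoch index "
                    f"{parts[0]!r}")
            if idx != expected:
                raise FormatError(
                    f"{path}, line {lineno}: epoch index {idx} breaks the "
                    f"contiguous 0-based sequence (expected {expected})")
            try:
                stages.append(canonical_stage(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}")
            expected += 1
    if not stages:
        raise FormatError(f"{path}: empty hypnogram")
    mask = read_mask(mask_path, len(stages)) if mask_path else None
    return Hypnogram(np.array(stages, dtype=object), mask)


def write_hypnogram(hypnogram: Hypnogram, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, s in enumerate(hypnogram.stages):
            fh.write(f"{i}\t{s}\n")
    return path


def read_mask(path, n_epochs: int | None = None) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line not in ("0", "1"):
                raise FormatError(
                    f"{path}, line {lineno}: mask entries must be 0 or 1")
            values.append(line == "1")
    if n_epochs is not None and len(values) != n_epochs:
        raise FormatError(
            f"{path}: mask covers {len(values)} epochs, expected {n_epochs}")
    return np.asarray(values, dtype=bool)


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for v in np.asarray(mask, dtype=bool):
            fh.write(f"{int(v)}\n")
    return path


# ---------------------------------------------------------------------------
# tables and matrices

def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """Write a DataFrame as tab-delimited text with 9-significant-digit floats."""
    path = Path(path)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_transition_matrix(tm: TransitionMatrix, path) -> Path:
    """Write probabilities and counts of a transition matrix as text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# probabilities (rows: from, cols: to); order "
                 + " ".join(STAGES) + "\n")
        np.savetxt(fh, tm.probabilities, fmt=FLOAT_FMT, delimiter="\t")
        fh.write("# counts\n")
        np.savetxt(fh, tm.counts, fmt=FLOAT_FMT, delimiter="\t")
    return path


def read_transition_matrix(path) -> TransitionMatrix:
    blocks: list[list[list[float]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                blocks.append([])
                continue
            if not blocks:
                blocks.append([])
            blocks[-1].append([float(v) for v in line.split()])
    if not blocks or len(blocks[0]) != 5:
        raise FormatError(f"{path}: expected a 5x5 probability block")
    probs = np.asarray(blocks[0], dtype=float)
    counts = (np.asarray(blocks[1], dtype=float)
              if len(blocks) > 1 and blocks[1] else None)
    return TransitionMatrix(probs, counts=counts)


# ---------------------------------------------------------------------------
# pipeline configuration and runner

@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic-data mode by default)."""

    epoch_seconds: float = 30.0
    sampling_rate: float = 256.0
    acf_lag_ms: float = 300.0
    n_bins: int = 50
    density_floor: float = 1e-12
    channel_policy: str = "average"
    smoothing: float = 0.5
    hyper_subset: tuple[str, ...] = ("STD", "KUR", "SKE")
    seed: int = 0
    n_epochs: int = 240
    n_train_recordings: int = 1
    artifact_rate: float = 0.02
    recording_path: str | None = None
    hypnogram_path: str | None = None
    mask_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("epoch_seconds", "sampling_rate", "acf_lag_ms",
                     "n_bins", "density_floor"):
            if float(getattr(self, name)) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.smoothing < 0:
            raise ValueError("smoothing pseudo-count must be non-negative")
        bad = [h for h in self.hyper_subset if h not in HYPER_NAMES]
        if bad:
            raise ValueError(
                f"unknown hyper-parameters {bad}; choose from {HYPER_NAMES}")
        self.hyper_subset = tuple(self.hyper_subset)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)


def run_pipeline(config: PipelineConfig, output_dir) -> dict[str, Path]:
    """Execute the full analysis chain and write all output artifacts.

    Synthetic mode (no ``recording_path``): a surrogate recording is
    generated with ``config.seed``, plus ``n_train_recordings``
    independent surrogate recordings used only to fit the likelihood
    model and the transition prior, keeping training and scoring data
    disjoint.  File mode: the recording/hypnogram at the configured
    paths is analyzed and the likelihoods are fitted in-sample (logged).

    Returns a name → path mapping of everything written, including a
    run manifest sufficient to reproduce the outputs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.recording_path:
        recording = read_recording(config.recording_path,
                                   sampling_rate=config.sampling_rate)
        hypnogram = read_hypnogram(config.hypnogram_path, config.mask_path)
        train: list[tuple[pd.DataFrame, Hypnogram]] = []
        logger.warning("file mode: likelihoods will be fitted in-sample")
    else:
        gen = GeneratorConfig(n_epochs=config.n_epochs,
                              sampling_rate=config.sampling_rate,
                              epoch_seconds=config.epoch_seconds,
                              artifact_rate=config.artifact_rate,
                              seed=config.seed)
        recording, hypnogram, truth = generate_recording(gen)
        paths["recording"] = write_recording(recording, out / "recording.txt")
        paths["hypnogram"] = write_hypnogram(hypnogram, out / "hypnogram.txt")
        paths["mask"] = write_mask(hypnogram.artifact_mask, out / "mask.txt")
        paths["ground_truth"] = write_table(truth, out / "ground_truth.tsv")
        train = []
        for j in range(config.n_train_recordings):
            tg = dataclasses.replace(gen, seed=config.seed + 1 + j)
            rec_j, hyp_j, _ = generate_recording(tg)
            tab_j = hyperparameter_table(rec_j, hyp_j, config.epoch_seconds,
                                         config.acf_lag_ms)
            train.append((tab_j, hyp_j))

    table = hyperparameter_table(recording, hypnogram, config.epoch_seconds,
                                 config.acf_lag_ms)
    paths["hyperparameters"] = write_table(table, out / "hyperparameters.tsv")

    # likelihood model (fitted on disjoint recordings when available)
    fit_tables = [t for t, _ in train] or [table]
    pooled: dict[str, dict[str, list[np.ndarray]]] = {}
    for t in fit_tables:
        for stage, hs in pool_hyperparameters(t).items():
            dest = pooled.setdefault(stage, {})
            for h, v in hs.items():
                dest.setdefault(h, []).append(v)
    pooled_cat = {s: {h: np.concatenate(v) for h, v in hs.items()}
                  for s, hs in pooled.items()}
    model = fit_stage_likelihoods(pooled_cat, n_bins=config.n_bins,
                                  floor=config.density_floor)
    paths["likelihoods"] = out / "likelihoods.json"
    paths["likelihoods"].write_text(model.to_json())

    # trends
    phases = annotate_cycle_direction(segment_phases(hypnogram))
    slopes = []
    for h in HYPER_NAMES:
        slopes.extend(phase_slopes(table, phases, h,
                                   channel_policy=config.channel_policy))
    paths["trends"] = write_table(
        stage_mean_slopes(slopes), out / "trends.tsv", index=True)

    # transition matrices
    fit_hyps = [h for _, h in train] or [hypnogram]
    tm_epoch = epoch_transition_matrix(fit_hyps, smoothing=config.smoothing)
    paths["transition_epoch"] = write_transition_matrix(
        tm_epoch, out / "transition_epoch.tsv")
    tm_phase = phase_transition_matrix(
        [segment_phases(h) for h in fit_hyps])
    paths["transition_phase"] = write_transition_matrix(
        tm_phase, out / "transition_phase.tsv")

    # Bayesian staging
    posterior = infer_sequence(table, model, tm_epoch,
                               hyper_names=config.hyper_subset,
                               channel_policy=config.channel_policy)
    post_df = posterior.to_frame()
    post_df["reference"] = hypnogram.stages
    paths["posteriors"] = write_table(post_df, out / "posteriors.tsv")
    acc = accuracy(posterior.map_labels, hypnogram)

    # separability
    for measure in ("gdv", "csi"):
        m = stage_distance_matrix(table, measure=measure,
                                  hyper_names=config.hyper_subset)
        paths[f"separability_{measure}"] = write_table(
            m, out / f"separability_{measure}.tsv", index=True)

    manifest = {
        "package": "hypnostats",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {f.name: _jsonable(getattr(config, f.name))
                   for f in dataclasses.fields(config)},
        "accuracy": acc,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v
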