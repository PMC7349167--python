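"""File formats, run configuration, and the end-to-end pipeline runner.

The preprocessed-DEAP distribution is treated as a documented array layout —
per subject a ``trials x channels x samples`` array plus a ``trials x 4``
ratings table (valence, arousal, dominance, liking) — stored in an HDF5
container rather than a language-specific pickle.  EDF recordings are read
through mne and mapped onto a montage by channel name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import yaml

from .montage import ElectrodeMontage, default_deap_montage, read_montage
from .streaming import (
    EEGTrial,
    StreamConfig,
    build_dataset,
    streams_to_arrays,
    task_classes,
)
from .training import TrainConfig, cross_validate, evaluate, train_model
from . import models

__all__ = [
    "save_deap_style",
    "load_deap_style_subject",
    "list_subjects",
    "load_edf",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: number of leading channels that are EEG in the DEAP layout (the rest are
#: peripheral physiology and are dropped on load)
N_EEG_CHANNELS = 32


def save_deap_style(path: Union[str, Path], trials: Sequence[EEGTrial]) -> None:
    """Write trials grouped by subject as /<subject>/data + /<subject>/labels."""
    by_subject: dict[str, list[EEGTrial]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    with h5py.File(path, "w") as f:
        for subject_id, subject_trials in by_subject.items():
            data = np.stack([t.signal for t in subject_trials])
            labels = np.array(
                [
                    [
                        t.valence if t.valence is not None else np.nan,
                        t.arousal if t.arousal is not None else np.nan,
                        t.dominance if t.dominance is not None else np.nan,
                        t.liking if t.liking is not None else np.nan,
                    ]
                    for t in subject_trials
                ]
            )
            g = f.create_group(subject_id)
            g.create_dataset("data", data=data)
            g.create_dataset("labels", data=labels)
            g.attrs["sampling_rate"] = subject_trials[0].sampling_rate


def list_subjects(path: Union[str, Path]) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f.keys())


def load_deap_style_subject(path: Union[str, Path], subject_id: str) -> list[EEGTrial]:
    """Load one subject's trials from the DEAP-style container.

    Keeps the first 32 channels (the EEG block of the 40-channel DEAP layout);
    ratings come from the trials x 4 table in valence, arousal, dominance,
    liking order.  The pre-trial baseline is NOT trimmed here — trimming is an
    explicit pipeline stage.
    """
    with h5py.File(path, "r") as f:
        if subject_id not in f:
            raise KeyError(f"subject {subject_id!r} not in {path}")
        g = f[subject_id]
        if "data" not in g or "labels" not in g:
            raise ValueError(
                f"subject group {subject_id!r} must hold 'data' "
                "(trials x channels x samples) and 'labels' (trials x 4)"
            )
        data = np.asarray(g["data"])
        labels = np.asarray(g["labels"])
        rate = float(g.attrs.get("sampling_rate", 128.0))
    if data.ndim != 3:
        raise ValueError(
            f"expected data of rank 3 (trials x channels x samples), got shape {data.shape}"
        )
    if labels.ndim != 2 or labels.shape[1] != 4 or labels.shape[0] != data.shape[0]:
        raise ValueError(
            f"expected labels of shape (n_trials, 4) matching {data.shape[0]} trials, "
            f"got {labels.shape}"
        )
    trials = []
    for i in range(data.shape[0]):
        val, aro, dom, lik = labels[i]
        trials.append(
            EEGTrial(
                signal=data[i, :N_EEG_CHANNELS],
                sampling_rate=rate,
                subject_id=subject_id,
                trial_id=f"{subject_id}_t{i + 1:02d}",
                valence=None if np.isnan(val) else float(val),
                arousal=None if np.isnan(aro) else float(aro),
                dominance=None if np.isnan(dom) else float(dom),
                liking=None if np.isnan(lik) else float(lik),
            )
        )
    return trials


def load_edf(
    path: Union[str, Path],
    montage: ElectrodeMontage,
    target_rate: float = 128.0,
) -> list[EEGTrial]:
    """Read an EDF recording and order its channels by montage name.

    Every montage electrode must have a name matching an EDF channel label;
    unmatched names raise with the offending list.  Recordings at other
    sampling rates are resampled to ``target_rate``.  Returns a single
    unlabeled trial fragment (no ratings).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = {name: i for i, name in enumerate(raw.ch_names)}
    wanted = [p.name for p in montage.by_channel()]
    missing = [n if n else f"<unnamed ch{p.channel}>" for n, p in
               zip(wanted, montage.by_channel()) if n is None or n not in available]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing}")
    if abs(raw.info["sfreq"] - target_rate) > 1e-9:
        raw = raw.resample(target_rate)
    data = raw.get_data()
    signal = np.stack([data[available[n]] for n in wanted])
    return [
        EEGTrial(
            signal=signal,
            sampling_rate=target_rate,
            subject_id=Path(path).stem,
            trial_id=f"{Path(path).stem}_t01",
        )
    ]


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    dataset_path: str
    out_dir: str
    montage: str = "deap-default"
    task: str = "valence"
    model: str = "r21d"  # c3d | r21d
    stream: StreamConfig = field(default_factory=StreamConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    model_overrides: dict = field(default_factory=dict)
    subjects: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.model not in ("c3d", "r21d"):
            raise ValueError("model must be 'c3d' or 'r21d'")
        task_classes(self.task)  # validates task name
        if self.stream.shape_param <= 0:
            raise ValueError("shape_param must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        stream = StreamConfig(**raw.pop("stream", {}))
        train = TrainConfig(**raw.pop("train", {}))
        return cls(stream=stream, train=train, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolve_montage(self) -> ElectrodeMontage:
        if self.montage == "deap-default":
            return default_deap_montage()
        p = Path(self.montage)
        if not p.exists():
            raise FileNotFoundError(f"montage table {p} does not exist")
        return read_montage(p)


def _build_model_factory(cfg: RunConfig, input_shape, num_classes):
    overrides = dict(cfg.model_overrides)
    mc_kwargs = dict(
        input_shape=tuple(input_shape), num_classes=num_classes, **overrides
    )
    mc = models.ModelConfig(**mc_kwargs)
    builder = models.build_c3d if cfg.model == "c3d" else models.build_r2plus1d
    return lambda seed: builder(mc, seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """load -> trim -> normalize -> frame -> stream -> cross-validate.

    Writes a config snapshot, per-fold results and a metrics summary under
    cfg.out_dir and returns the summary dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    montage = cfg.resolve_montage()
    t0 = time.perf_counter()
    subjects = cfg.subjects or list_subjects(cfg.dataset_path)
    trials = []
    for s in subjects:
        trials.extend(load_deap_style_subject(cfg.dataset_path, s))
    logger.info("loaded %d trials from %d subjects", len(trials), len(subjects))
    streams = build_dataset(trials, montage, cfg.stream)
    X, y = streams_to_arrays(streams, cfg.task)
    logger.info("built %d streams of shape %s", len(X), X.shape[1:])
    factory = _build_model_factory(cfg, X.shape[1:], len(task_classes(cfg.task)))
    mean_acc, folds = cross_validate(factory, X, y, cfg.train)
    summary = {
        "task": cfg.task,
        "model": cfg.model,
        "n_streams": int(len(X)),
        "mean_test_accuracy": mean_acc,
        "fold_test_accuracies": [f.test_accuracy for f in folds],
        "seconds": time.perf_counter() - t0,
    }
    (out / "metrics.json").write_text(json.dumps(summary, indent=2))
    with (out / "folds.csv").open("w") as fh:
        fh.write("fold,test_accuracy,n_train,n_test\n")
        for f in folds:
            fh.write(
                f"{f.fold_index},{f.test_accuracy},"
                f"{len(f.train_indices)},{len(f.test_indices)}\n"
            )
    logger.info("mean test accuracy %.4f", mean_acc)
    return summary
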