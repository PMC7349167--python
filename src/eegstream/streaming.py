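"""Trials, windows, 3D EEG streams, and emotion-label quantization.

A trial is a channels x samples recording with self-reported valence and
arousal ratings on the 1-9 scale.  The pipeline here:

1. trim the pre-trial baseline (first 3 s in the DEAP layout),
2. z-score each channel per subject over the retained samples,
3. cut each trial into non-overlapping windows of w samples (w = 128 at
   128 Hz, i.e. 1-s streams; a 60-s trial yields 60 of them),
4. densify every sample of a window into a 2D frame and stack the w frames
   along time into a rank-3 stream S_j of shape (w, size, size),
5. attach labels: each rating binarized at 5 (>= 5 is "high"), and the
   quadrant class (LALV/LAHV/HALV/HAHV) from the arousal/valence pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .framing import FrameMaker, InterpMode, normalize_subject
from .montage import ElectrodeMontage

__all__ = [
    "EEGTrial",
    "EEGStream",
    "LabeledStream",
    "StreamConfig",
    "trim_baseline",
    "window_trial",
    "build_stream",
    "quantize_binary",
    "quadrant_label",
    "build_dataset",
]

logger = logging.getLogger(__name__)


def _check_rating(value: Optional[float], name: str) -> None:
    if value is not None and not (1.0 <= value <= 9.0):
        raise ValueError(f"{name} rating {value} outside the 1-9 scale")


@dataclass
class EEGTrial:
    """One trial: channels x samples signal plus its emotion self-ratings.

    Dominance and liking are carried when present but never used for labels.
    Ratings may be None for unlabeled fragments (e.g. raw EDF recordings).
    """

    signal: np.ndarray
    sampling_rate: float
    subject_id: str
    trial_id: str
    valence: Optional[float] = None
    arousal: Optional[float] = None
    dominance: Optional[float] = None
    liking: Optional[float] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("trial signal must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("valence", "arousal", "dominance", "liking"):
            _check_rating(getattr(self, name), name)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EEGStream:
    """Rank-3 stack of consecutive dense frames: shape (w, size, size)."""

    frames: np.ndarray
    window_index: int
    subject_id: str
    trial_id: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("stream frames must be (length, height, width)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stream contains non-finite values")


@dataclass
class LabeledStream:
    """A stream with its binary valence/arousal labels and quadrant class."""

    stream: EEGStream
    valence_binary: str
    arousal_binary: str
    quadrant: str

    def __post_init__(self) -> None:
        expected = (
            ("L" if self.arousal_binary == "low" else "H") + "A"
            + ("L" if self.valence_binary == "low" else "H") + "V"
        )
        if self.quadrant != expected:
            raise ValueError(
                f"quadrant {self.quadrant} inconsistent with binary labels "
                f"({self.arousal_binary} arousal, {self.valence_binary} valence)"
            )


@dataclass
class StreamConfig:
    """How trials become labeled streams.

    window is in samples (128 = 1 s at 128 Hz); stride defaults to the window
    length, i.e. non-overlapping streams, which is what 60 streams per 60-s
    trial implies.  frame_size is the dense-frame resolution (64 default).
    """

    window: int = 128
    stride: Optional[int] = None
    baseline_seconds: float = 3.0
    frame_size: int = 64
    shape_param: float = 1.0
    interp_mode: InterpMode = "direct"
    ridge: float = 0.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1 sample")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1 sample")
        if self.baseline_seconds < 0:
            raise ValueError("baseline_seconds must be >= 0")

    @property
    def effective_stride(self) -> int:
        return self.window if self.stride is None else self.stride


def trim_baseline(trial: EEGTrial, baseline_seconds: float) -> EEGTrial:
    """Drop the first round(baseline_seconds * rate) samples of every channel."""
    n_drop = int(round(baseline_seconds * trial.sampling_rate))
    if trial.n_samples <= n_drop:
        raise ValueError(
            f"trial has {trial.n_samples} samples; needs more than {n_drop} "
            f"to trim a {baseline_seconds}-s baseline"
        )
    return replace(trial, signal=trial.signal[:, n_drop:])


def window_trial(trial: EEGTrial, w: int, stride: Optional[int] = None) -> list[np.ndarray]:
    """Cut a trial into consecutive channels x w segments.

    Windows start at sample 0 and advance by ``stride`` (default w, i.e.
    non-overlapping); the trailing remainder shorter than w is discarded.
    """
    if w < 1:
        raise ValueError("window length must be >= 1")
    stride = w if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = trial.n_samples
    starts = range(0, n - w + 1, stride)
    return [trial.signal[:, s : s + w] for s in starts]


def build_stream(
    segment: np.ndarray,
    montage: ElectrodeMontage,
    cfg: StreamConfig,
    window_index: int = 0,
    subject_id: str = "",
    trial_id: str = "",
    frame_maker: Optional[FrameMaker] = None,
) -> EEGStream:
    """Densify every time sample of a channels x w segment and stack in time order."""
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[0] != montage.n_electrodes:
        raise ValueError(
            f"segment must be ({montage.n_electrodes}, w), got {segment.shape}"
        )
    if frame_maker is None:
        frame_maker = FrameMaker(
            montage, cfg.shape_param, cfg.frame_size, cfg.interp_mode, cfg.ridge
        )
    frames = frame_maker.frames(segment).astype(cfg.dtype)
    return EEGStream(
        frames=frames,
        window_index=window_index,
        subject_id=subject_id,
        trial_id=trial_id,
    )


def quantize_binary(rating: float) -> str:
    """Binarize a 1-9 rating at 5: >= 5 is "high", below is "low"."""
    if rating is None or not (1.0 <= rating <= 9.0):
        raise ValueError(f"rating {rating} outside the 1-9 scale")
    return "high" if rating >= 5.0 else "low"


def quadrant_label(valence: float, arousal: float) -> str:
    """Quadrant class on the arousal-valence plane: {L,H}A x {L,H}V at threshold 5."""
    a = "H" if quantize_binary(arousal) == "high" else "L"
    v = "H" if quantize_binary(valence) == "high" else "L"
    return f"{a}A{v}V"


def label_stream(stream: EEGStream, valence: float, arousal: float) -> LabeledStream:
    return LabeledStream(
        stream=stream,
        valence_binary=quantize_binary(valence),
        arousal_binary=quantize_binary(arousal),
        quadrant=quadrant_label(valence, arousal),
    )


def build_dataset(
    trials: Sequence[EEGTrial],
    montage: ElectrodeMontage,
    cfg: StreamConfig,
) -> list[LabeledStream]:
    """Full pipeline over a set of rated trials, grouped by subject.

    Per subject: trim the baseline from every trial, z-score each channel over
    the subject's retained samples, then window each trial and build one
    labeled stream per window.  The total stream count is
    sum_trials floor(samples_after_trim / w) under the default stride.
    """
    if len(trials) == 0:
        raise ValueError("no trials given")
    frame_maker = FrameMaker(
        montage, cfg.shape_param, cfg.frame_size, cfg.interp_mode, cfg.ridge
    )
    by_subject: dict[str, list[EEGTrial]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    out: list[LabeledStream] = []
    for subject_id, subject_trials in by_subject.items():
        trimmed = [trim_baseline(t, cfg.baseline_seconds) for t in subject_trials]
        signals = normalize_subject([t.signal for t in trimmed])
        n_sub = 0
        for trial, signal in zip(trimmed, signals):
            if trial.valence is None or trial.arousal is None:
                raise ValueError(
                    f"trial {trial.trial_id} of subject {subject_id} lacks ratings"
                )
            segments = window_trial(replace(trial, signal=signal), cfg.window, cfg.stride)
            for j, seg in enumerate(segments):
                stream = build_stream(
                    seg,
                    montage,
                    cfg,
                    window_index=j,
                    subject_id=subject_id,
                    trial_id=trial.trial_id,
                    frame_maker=frame_maker,
                )
                out.append(label_stream(stream, trial.valence, trial.arousal))
            n_sub += len(segments)
        logger.info("subject %s: %d streams", subject_id, n_sub)
    return out


_TASK_CLASSES = {
    "valence": ("low", "high"),
    "arousal": ("low", "high"),
    "quadrant": ("LALV", "LAHV", "HALV", "HAHV"),
}


def streams_to_arrays(
    streams: Sequence[LabeledStream], task: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack labeled streams into (X, y) arrays for a classification task.

    X is (n, 1, w, size, size) float32 (the singleton axis is the input
    channel of the 3D networks); y holds integer class indices in the fixed
    class order of the task.
    """
    if task not in _TASK_CLASSES:
        raise ValueError(f"unknown task {task!r}; expected one of {list(_TASK_CLASSES)}")
    classes = _TASK_CLASSES[task]
    X = np.stack([s.stream.frames for s in streams]).astype(np.float32)[:, None]
    if task == "valence":
        labels = [s.valence_binary for s in streams]
    elif task == "arousal":
        labels = [s.arousal_binary for s in streams]
    else:
        labels = [s.quadrant for s in streams]
    y = np.array([classes.index(l) for l in labels], dtype=np.int64)
    return X, y


def task_classes(task: str) -> tuple[str, ...]:
    """Fixed class-name order used by :func:`streams_to_arrays`."""
    if task not in _TASK_CLASSES:
        raise ValueError(f"unknown task {task!r}; expected one of {list(_TASK_CLASSES)}")
    return _TASK_CLASSES[task]
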