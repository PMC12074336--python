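"""Stream capture and normalization: the bounded capture FIFO, the
mean-distance finder with previous/current feedback, the two baselines
("early" = empty bed, "encoded" = per-posture subject profile), six-bit
occupancy patterns, and the per-window feature vectors fed to the classifier.

Distances are integers in tenths of a millimetre throughout (a 20-bit word
covers the full 2 cm – 4 m sensor range at that resolution).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .simulate import CHANNELS, LABEL_KEYS, SENSOR_MAX, SENSOR_MIN, WORD_BITS

#: Default analysis window: 1 s of 4 Hz data.
WINDOW_FRAMES = 4

#: Per-channel feature layout of a window; M = 4 x 6 = 24 features total.
FEATURES_PER_CHANNEL: tuple[str, ...] = ("norm_mean", "mean", "var", "occupied")
N_FEATURES = len(FEATURES_PER_CHANNEL) * len(CHANNELS)


def feature_names() -> list[str]:
    """The 24 feature names in vector order (channel-major)."""
    return [f"{ch}_{feat}" for ch in CHANNELS for feat in FEATURES_PER_CHANNEL]


class CaptureFIFO:
    """Bounded capture buffer: 6 channels wide, 40 frames deep, 20-bit words.

    Models the fixed-size capture memory of the streaming front end: when a
    41st frame arrives the single oldest frame is evicted, everything else
    keeps its order.
    """

    WIDTH = len(CHANNELS)

    def __init__(self, depth: int = 40, word_bits: int = WORD_BITS) -> None:
        if depth < 1:
            raise ValueError("depth must be positive")
        self.depth = depth
        self.word_bits = word_bits
        self._max_word = (1 << word_bits) - 1
        self._frames: deque[tuple[int, ...]] = deque()
        self.pushes = 0
        self.evictions = 0

    def push(self, frame: Sequence[int]) -> tuple[int, ...] | None:
        """Append a frame; return the evicted frame if the buffer was full.

        The frame is validated *before* insertion: exactly six values, each
        representable in the word width.
        """
        values = tuple(int(v) for v in frame)
        if len(values) != self.WIDTH:
            raise ValueError(f"frame must carry {self.WIDTH} channel values")
        for v in values:
            if not 0 <= v <= self._max_word:
                raise ValueError(
                    f"distance {v} does not fit in a {self.word_bits}-bit word"
                )
        evicted = None
        if len(self._frames) == self.depth:
            evicted = self._frames.popleft()
            self.evictions += 1
        self._frames.append(values)
        self.pushes += 1
        return evicted

    @property
    def occupancy(self) -> int:
        return len(self._frames)

    def __len__(self) -> int:
        return len(self._frames)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        return iter(self._frames)

    def as_array(self) -> np.ndarray:
        """(occupancy, 6) array, oldest frame first."""
        return np.array(self._frames, dtype=np.int64).reshape(-1, self.WIDTH)


def mean_distance(
    window: np.ndarray,
    channel: int,
    previous_mean: float | None = None,
    drift_tolerance: float = 50.0,
) -> tuple[float, str | None]:
    """Mean distance of one channel over a window, with feedback flag.

    Returns ``(mean, flag)`` where flag is ``"stable"`` when the mean moved by
    at most ``drift_tolerance`` (tenths of mm, default 5 mm) since
    ``previous_mean``, ``"changed"`` otherwise, and ``None`` when there is no
    previous mean to compare against.
    """
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("mean_distance needs a non-empty window")
    mean = float(window.reshape(-1, len(CHANNELS))[:, channel].mean())
    if previous_mean is None:
        return mean, None
    flag = "stable" if abs(previous_mean - mean) <= drift_tolerance else "changed"
    return mean, flag


@dataclass
class Baseline:
    """The two normalization references.

    ``early`` is the per-channel empty-bed mean distance; ``encoded`` maps a
    posture label key to that posture's per-channel mean for the trained
    subject.  ``occupancy_margin`` (tenths of mm) is how much nearer than the
    empty-bed baseline a channel must read to count as occupied.
    """

    early: np.ndarray
    encoded: dict[str, np.ndarray] = field(default_factory=dict)
    occupancy_margin: float = 1000.0

    def __post_init__(self) -> None:
        self.early = np.asarray(self.early, dtype=float)
        if self.early.shape != (len(CHANNELS),):
            raise ValueError("early baseline must hold one value per channel")
        if not (SENSOR_MIN <= self.early).all() or not (self.early <= SENSOR_MAX).all():
            raise ValueError("early baseline outside the sensor range")
        if self.occupancy_margin <= 0:
            raise ValueError("occupancy_margin must be positive")
        self.encoded = {k: np.asarray(v, dtype=float) for k, v in self.encoded.items()}


@dataclass(frozen=True)
class BinaryPattern:
    """Six-bit occupancy code in canonical channel order (UBL first)."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(CHANNELS) or any(b not in (0, 1) for b in self.bits):
            raise ValueError("pattern must be six bits")

    @property
    def value(self) -> int:
        """Whole-number value; UBL is the most significant bit, so the code
        reads like the bit string (e.g. LLL+LLR occupied -> 0b000011 = 3)."""
        v = 0
        for b in self.bits:
            v = (v << 1) | b
        return v

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


def early_normalize(empty_frames: np.ndarray) -> np.ndarray:
    """Per-channel mean of an empty-bed stream (the early baseline)."""
    frames = np.asarray(empty_frames, dtype=float)
    if frames.size == 0:
        raise ValueError("early_normalize needs at least one frame")
    return frames.reshape(-1, len(CHANNELS)).mean(axis=0)


def encoded_normalize(
    frames: np.ndarray,
    labels: Sequence[str],
    required_labels: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-posture, per-channel mean over the frames carrying each label.

    ``labels`` gives one posture key per frame.  Raises if any required
    posture (default: all 12 classes) has no frames, naming the absent ones.
    """
    frames = np.asarray(frames, dtype=float).reshape(-1, len(CHANNELS))
    labels = list(labels)
    if len(labels) != len(frames):
        raise ValueError("one posture label per frame is required")
    required = list(required_labels) if required_labels is not None else list(LABEL_KEYS)
    present = set(labels)
    missing = [k for k in required if k not in present]
    if missing:
        raise ValueError(f"no training frames for posture(s): {', '.join(missing)}")
    out: dict[str, np.ndarray] = {}
    arr = np.asarray(labels)
    for key in dict.fromkeys(labels):  # first-seen order, deterministic
        out[key] = frames[arr == key].mean(axis=0)
    return out


def binarize(frame: Sequence[int], baseline: Baseline,
             margin: float | None = None) -> BinaryPattern:
    """Occupancy pattern: bit = 1 iff the channel reads at least ``margin``
    nearer than its empty-bed baseline."""
    m = baseline.occupancy_margin if margin is None else margin
    reading = np.asarray(frame, dtype=float)
    bits = tuple(int(d >= m) for d in baseline.early - reading)
    return BinaryPattern(bits)


@dataclass(frozen=True)
class FeatureVector:
    """M = 24 per-window features (channel-major: normalized mean, raw mean,
    population variance, occupancy bit) plus the window identifier."""

    values: np.ndarray
    window_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector must be finite")


def build_feature_vector(window: np.ndarray, baseline: Baseline,
                         window_id: int = 0) -> FeatureVector:
    """Feature vector of one full analysis window (4 frames = 1 s).

    Per channel: normalized mean (early baseline minus window mean), raw
    window mean, population variance (divide by n), occupancy bit at the
    baseline's margin.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != len(CHANNELS):
        raise ValueError("window must be (frames, 6)")
    if window.shape[0] < WINDOW_FRAMES:
        raise ValueError(f"window must hold at least {WINDOW_FRAMES} frames")
    means = window.mean(axis=0)
    variances = window.var(axis=0)  # population convention
    norm = baseline.early - means
    bits = (norm >= baseline.occupancy_margin).astype(float)
    values = np.column_stack([norm, means, variances, bits]).reshape(-1)
    return FeatureVector(values=values, window_id=window_id)


def iter_windows(frames: np.ndarray,
                 frames_per_window: int = WINDOW_FRAMES) -> Iterator[np.ndarray]:
    """Consecutive non-overlapping analysis windows of a 4 Hz stream."""
    frames = np.asarray(frames)
    n_windows = len(frames) // frames_per_window
    for w in range(n_windows):
        yield frames[w * frames_per_window:(w + 1) * frames_per_window]


def build_dataset(frames: np.ndarray, labels_per_second: Sequence[str],
                  baseline: Baseline) -> tuple[np.ndarray, list[str]]:
    """Window the stream and pair each window's features with its label.

    Returns ``(X, y)`` with X of shape (n_windows, 24) and y the posture key
    of each window.
    """
    windows = list(iter_windows(frames))
    if len(labels_per_second) < len(windows):
        raise ValueError("need one posture label per one-second window")
    X = np.stack([
        build_feature_vector(w, baseline, window_id=i).values
        for i, w in enumerate(windows)
    ])
    y = [labels_per_second[i] for i in range(len(windows))]
    return X, y


def calibrate(empty_frames: np.ndarray, subject_frames: np.ndarray,
              labels: Sequence[str],
              occupancy_margin: float = 1000.0,
              required_labels: Iterable[str] | None = None) -> Baseline:
    """Build a full Baseline from an empty-bed stream and a labelled session."""
    early = early_normalize(empty_frames)
    base = Baseline(early=early, occupancy_margin=occupancy_margin)
    base.encoded = encoded_normalize(subject_frames, labels,
                                     required_labels=required_labels)
    return base
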