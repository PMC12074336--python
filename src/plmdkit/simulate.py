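"""Seeded synthetic generator for six-channel ultrasonic sleep sessions.

Six ceiling-mounted rangers read the distance to whatever is below them four
times a second: the bare mattress when the bed is empty, the body surface when
it is occupied.  A session is therefore a (n_frames, 6) integer array of
distances in tenths of a millimetre, channel order ``UBL, UBR, MBL, MBR, LLL,
LLR`` (upper/middle/lower bed rows, left/right), clamped to the sensor's
2 cm – 4 m range.

The generator composes, per frame and channel:

* a posture-dependent baseline — the row's mounting height minus a
  pose-specific body-thickness offset over occupied channels;
* a slow sinusoidal body oscillation on occupied channels for the
  ``time_variant`` posture variants (static variants are flat);
* limb-movement episodes on the two lower-limb channels (``LLL``/``LLR``):
  during each in-motion second the limb toggles between its resting level and
  a dipped level ``magnitude_mm`` nearer the sensor, so the per-second window
  means keep changing for exactly the scheduled movement seconds;
* additive Gaussian sensor noise and a linear whole-session baseline drift.

Alongside the frames the generator emits the ground truth the detector is
later judged against: per-frame posture labels, per-second binary motion flags
for each lower limb, and the episode table itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BedGeometry

#: Canonical channel order; the two lower-limb channels come last.
CHANNELS: tuple[str, ...] = ("UBL", "UBR", "MBL", "MBR", "LLL", "LLR")
ROW_OF_CHANNEL: tuple[str, ...] = ("upper", "upper", "middle", "middle", "lower", "lower")
LLL, LLR = 4, 5

#: Sensor range 2 cm – 4 m, stored in tenths of a millimetre (20-bit safe).
SENSOR_MIN = 200
SENSOR_MAX = 40000
WORD_BITS = 20

BASE_POSES: tuple[str, ...] = (
    "supine", "prone", "fetal_left", "fetal_right", "log_left", "log_right",
)
VARIANTS: tuple[str, ...] = ("static", "time_variant")

# Body-thickness offsets (mm) per pose and channel.  Values are chosen so
# that every pose has a distinct six-bit occupancy pattern at the default
# 100 mm margin and every channel separates every pair of poses, which keeps
# the posture classes separable from any single distance feature.
POSE_OFFSETS_MM: dict[str, tuple[int, int, int, int, int, int]] = {
    "supine":      (250, 250, 250, 250, 200, 200),
    "prone":       (240, 240, 260, 260,  80,  80),
    "fetal_left":  (300,  50, 300,  50, 250,  50),
    "fetal_right": ( 50, 300,  50, 300,  50, 250),
    "log_left":    (280,  40, 280,  40, 220, 220),
    "log_right":   ( 40, 280,  40, 280, 230, 240),
}

#: Channels with offsets at or above this (mm) count as occupied by the body.
OCCUPIED_MIN_OFFSET_MM = 100

#: Time-variant body oscillation: amplitude (mm) and frequency (Hz).  Small
#: enough that consecutive one-second window means never differ by more than
#: the default limb-motion threshold.
OSCILLATION_AMP_MM = 20.0
OSCILLATION_FREQ_HZ = 0.5


@dataclass(frozen=True, order=True)
class PostureLabel:
    """One of the 6 poses x {static, time_variant} = 12 posture classes."""

    pose: str
    variant: str = "static"

    def __post_init__(self) -> None:
        if self.pose not in BASE_POSES:
            raise ValueError(f"unknown pose {self.pose!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def key(self) -> str:
        return f"{self.pose}-{self.variant}"

    @classmethod
    def from_key(cls, key: str) -> "PostureLabel":
        pose, _, variant = key.rpartition("-")
        return cls(pose=pose, variant=variant)


ALL_LABELS: tuple[PostureLabel, ...] = tuple(
    PostureLabel(pose, variant) for pose in BASE_POSES for variant in VARIANTS
)
LABEL_KEYS: tuple[str, ...] = tuple(lbl.key for lbl in ALL_LABELS)


@dataclass(frozen=True)
class PLMEpisodeSpec:
    """A periodic burst of limb movements on one limb (or both).

    ``movement_count`` movements of ``movement_duration_s`` seconds each,
    starting ``inter_movement_interval_s`` apart from movement onset to
    movement onset.  ``magnitude_mm`` is how much nearer the sensor the limb
    dips while moving.  Timing is whole seconds so that the per-second flag
    semantics are exact.
    """

    limb: str  # left | right | both
    onset_s: int
    movement_count: int
    movement_duration_s: int
    inter_movement_interval_s: int
    magnitude_mm: float

    def __post_init__(self) -> None:
        if self.limb not in ("left", "right", "both"):
            raise ValueError("limb must be left, right or both")
        for name in ("onset_s", "movement_duration_s", "inter_movement_interval_s"):
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"{name} must be a whole number of seconds")
        if self.onset_s < 1:
            raise ValueError("onset_s must be >= 1 s (second 0 has no prior window)")
        if self.movement_count < 1:
            raise ValueError("movement_count must be positive")
        if self.movement_duration_s < 1:
            raise ValueError("movement_duration_s must be positive")
        if self.movement_duration_s >= self.inter_movement_interval_s:
            raise ValueError("movement_duration_s must be < inter_movement_interval_s")
        if self.magnitude_mm <= 0:
            raise ValueError("magnitude_mm must be positive")

    @property
    def end_s(self) -> int:
        """First second after the last movement."""
        last_onset = self.onset_s + (self.movement_count - 1) * self.inter_movement_interval_s
        return int(last_onset + self.movement_duration_s)

    def movement_seconds(self) -> list[range]:
        """The per-movement second ranges, in order."""
        return [
            range(
                int(self.onset_s + k * self.inter_movement_interval_s),
                int(self.onset_s + k * self.inter_movement_interval_s
                    + self.movement_duration_s),
            )
            for k in range(self.movement_count)
        ]

    @property
    def channels(self) -> tuple[int, ...]:
        if self.limb == "left":
            return (LLL,)
        if self.limb == "right":
            return (LLR,)
        return (LLL, LLR)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic sleep session."""

    duration_s: float
    geometry: BedGeometry = field(default_factory=BedGeometry)
    sample_rate_hz: float = 4.0
    noise_sd_mm: float = 3.0
    baseline_drift_mm: float = 0.0
    posture_schedule: tuple[tuple[float, PostureLabel], ...] = (
        (0.0, PostureLabel("supine", "static")),
    )
    episodes: tuple[PLMEpisodeSpec, ...] = ()
    seed: int = 0
    subject_present: bool = True
    #: Tenths of mm; a posture transition flags a limb in the ground truth iff
    #: that limb channel's baseline changes by more than this.
    flag_threshold: float = 1000.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration_s and sample_rate_hz must be positive")
        if not float(self.duration_s).is_integer():
            raise ValueError("duration_s must be a whole number of seconds")
        n = self.sample_rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate_hz * duration_s must be a whole frame count")
        if self.noise_sd_mm < 0 or self.baseline_drift_mm < 0:
            raise ValueError("noise_sd_mm and baseline_drift_mm must be non-negative")
        if not self.posture_schedule:
            raise ValueError("posture_schedule must contain at least one entry")
        starts = [s for s, _ in self.posture_schedule]
        if starts[0] != 0:
            raise ValueError("posture_schedule must start at 0 s")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("posture_schedule start times must be strictly increasing")
        for s in starts:
            if not float(s).is_integer():
                raise ValueError("posture changes must fall on whole-second boundaries")
        if starts[-1] >= self.duration_s:
            raise ValueError("posture_schedule entry starts beyond the session end")
        self._validate_episodes()

    def _validate_episodes(self) -> None:
        per_channel: dict[int, set[int]] = {LLL: set(), LLR: set()}
        for ep in self.episodes:
            if ep.end_s > self.duration_s:
                raise ValueError(
                    f"episode ({ep.limb}, onset {ep.onset_s}s) runs past the session end"
                )
            secs = {s for rng in ep.movement_seconds() for s in rng}
            for ch in ep.channels:
                taken = per_channel[ch]
                # Runs on the same limb must be separated by >= 1 static second
                # so that ground-truth events are maximal runs.
                widened = secs | {s - 1 for s in secs} | {s + 1 for s in secs}
                if taken & widened:
                    raise ValueError(
                        "episodes sharing a limb overlap or touch; leave at least "
                        "one static second between movement runs"
                    )
                taken |= secs

    @property
    def n_frames(self) -> int:
        return int(round(self.sample_rate_hz * self.duration_s))

    @property
    def n_seconds(self) -> int:
        return int(round(self.duration_s))


@dataclass
class GroundTruth:
    """Everything the generator injected, in detector-comparable form."""

    #: Per-frame posture label keys, length n_frames.
    posture_per_frame: list[str]
    #: Per-second posture label keys, length n_seconds.
    posture_per_second: list[str]
    #: (n_seconds, 2) int8; columns LLL, LLR; 1 = limb in motion that second.
    flags: np.ndarray
    episodes: tuple[PLMEpisodeSpec, ...]
    #: Seconds at which the posture label changes (t > 0).
    transition_seconds: tuple[int, ...]

    def flag_total(self) -> int:
        """Total flagged limb-seconds, both limbs counted separately."""
        return int(self.flags.sum())


def empty_bed_profile(geometry: BedGeometry) -> np.ndarray:
    """Per-channel bare-mattress distance, tenths of mm."""
    heights = {
        "upper": geometry.sensor_to_target_m[0],
        "middle": geometry.sensor_to_target_m[1],
        "lower": geometry.sensor_to_target_m[2],
    }
    return np.array(
        [heights[row] * 10000.0 for row in ROW_OF_CHANNEL], dtype=float
    )


def posture_profile(label: PostureLabel, geometry: BedGeometry,
                    offsets_mm: dict[str, tuple[int, ...]] | None = None) -> np.ndarray:
    """Expected per-channel distance for a posture, tenths of mm.

    Mounting height minus the pose's body-thickness offset; the ``variant``
    field changes the dynamics only, never the baseline.
    """
    table = POSE_OFFSETS_MM if offsets_mm is None else offsets_mm
    offsets = np.asarray(table[label.pose], dtype=float) * 10.0
    return empty_bed_profile(geometry) - offsets


def _quantize(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), SENSOR_MIN, SENSOR_MAX).astype(np.int32)


def _schedule_index(config: SimConfig, t: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _ in config.posture_schedule], dtype=float)
    return np.searchsorted(starts, t, side="right") - 1


def _limb_dip_levels(config: SimConfig) -> np.ndarray:
    """(n_seconds, 2) dip level (tenths of mm) of each lower-limb channel.

    Each in-motion second toggles the limb between 0 (resting) and the
    episode magnitude, so consecutive window means always differ during a
    movement and never after it.
    """
    n_sec = config.n_seconds
    dip = np.zeros((n_sec, 2), dtype=float)
    for col, ch in ((0, LLL), (1, LLR)):
        movement: dict[int, float] = {}
        for ep in config.episodes:
            if ch in ep.channels:
                for rng in ep.movement_seconds():
                    for s in rng:
                        movement[s] = ep.magnitude_mm * 10.0
        level = 0.0
        for s in range(n_sec):
            if s in movement:
                level = movement[s] if level == 0.0 else 0.0
            dip[s, col] = level
    return dip


def _truth_flags(config: SimConfig) -> tuple[np.ndarray, tuple[int, ...]]:
    n_sec = config.n_seconds
    flags = np.zeros((n_sec, 2), dtype=np.int8)
    for ep in config.episodes:
        for col, ch in ((0, LLL), (1, LLR)):
            if ch in ep.channels:
                for rng in ep.movement_seconds():
                    flags[list(rng), col] = 1
    transitions = []
    for start, label in config.posture_schedule[1:]:
        s = int(start)
        prev_label = _label_at(config, s - 1)
        transitions.append(s)
        prev_prof = posture_profile(prev_label, config.geometry)
        cur_prof = posture_profile(label, config.geometry)
        for col, ch in ((0, LLL), (1, LLR)):
            if abs(cur_prof[ch] - prev_prof[ch]) > config.flag_threshold:
                flags[s, col] = 1
    return flags, tuple(transitions)


def _label_at(config: SimConfig, t_s: float) -> PostureLabel:
    label = config.posture_schedule[0][1]
    for start, lbl in config.posture_schedule:
        if start <= t_s:
            label = lbl
    return label


def simulate_session(config: SimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate one occupied-bed session.

    Returns ``(frames, truth)`` where ``frames`` is an (n_frames, 6) int32
    array of distances in tenths of mm.  Equal configs (including seed)
    produce bit-identical output.
    """
    n = config.n_frames
    rate = config.sample_rate_hz
    t = np.arange(n) / rate
    seg = _schedule_index(config, t)

    starts = np.array([s for s, _ in config.posture_schedule], dtype=float)
    labels = [lbl for _, lbl in config.posture_schedule]
    profiles = np.stack([posture_profile(lbl, config.geometry) for lbl in labels])
    base = profiles[seg]  # (n, 6)

    # Time-variant micro-oscillation of the body over occupied channels.
    occupied = np.stack([
        np.asarray(POSE_OFFSETS_MM[lbl.pose], dtype=float) >= OCCUPIED_MIN_OFFSET_MM
        for lbl in labels
    ])
    variant = np.array([lbl.variant == "time_variant" for lbl in labels])
    phase_t = t - starts[seg]
    osc = (OSCILLATION_AMP_MM * 10.0) * np.sin(
        2.0 * math.pi * OSCILLATION_FREQ_HZ * phase_t
    )
    mask = variant[seg][:, None] & occupied[seg]
    base = base - np.where(mask, osc[:, None], 0.0)

    # Limb-movement dips on LLL/LLR, constant within each second.
    dip_sec = _limb_dip_levels(config)
    frames_per_sec = int(round(rate))
    dip_frames = np.repeat(dip_sec, frames_per_sec, axis=0)[:n]
    base[:, [LLL, LLR]] -= dip_frames

    # Drift (all channels drift away from the sensor by drift_mm over the
    # session) and sensor noise.
    if n > 1 and config.baseline_drift_mm > 0:
        base += (np.arange(n) / (n - 1) * config.baseline_drift_mm * 10.0)[:, None]
    if config.noise_sd_mm > 0:
        rng = np.random.default_rng(config.seed)
        base = base + rng.normal(0.0, config.noise_sd_mm * 10.0, size=(n, 6))

    flags, transitions = _truth_flags(config)
    posture_per_frame = [labels[i].key for i in seg]
    sec_idx = _schedule_index(config, np.arange(config.n_seconds, dtype=float))
    posture_per_second = [labels[i].key for i in sec_idx]
    truth = GroundTruth(
        posture_per_frame=posture_per_frame,
        posture_per_second=posture_per_second,
        flags=flags,
        episodes=config.episodes,
        transition_seconds=transitions,
    )
    return _quantize(base), truth


def empty_bed_session(config: SimConfig) -> np.ndarray:
    """Generate a bare-mattress calibration stream (noise + drift only)."""
    n = config.n_frames
    base = np.tile(empty_bed_profile(config.geometry), (n, 1))
    if n > 1 and config.baseline_drift_mm > 0:
        base += (np.arange(n) / (n - 1) * config.baseline_drift_mm * 10.0)[:, None]
    if config.noise_sd_mm > 0:
        rng = np.random.default_rng(config.seed)
        base = base + rng.normal(0.0, config.noise_sd_mm * 10.0, size=(n, 6))
    return _quantize(base)


def training_schedule(segment_s: int = 20) -> tuple[tuple[float, PostureLabel], ...]:
    """A schedule visiting all 12 posture classes for ``segment_s`` each."""
    return tuple((float(i * segment_s), lbl) for i, lbl in enumerate(ALL_LABELS))


def training_session_config(seed: int = 0, segment_s: int = 20,
                            noise_sd_mm: float = 3.0,
                            geometry: BedGeometry | None = None) -> SimConfig:
    """Labelled session covering every posture class, for classifier training."""
    schedule = training_schedule(segment_s)
    return SimConfig(
        duration_s=float(segment_s * len(ALL_LABELS)),
        geometry=geometry or BedGeometry(),
        noise_sd_mm=noise_sd_mm,
        posture_schedule=schedule,
        seed=seed,
    )


def scenario_library(seed: int = 0, noise_sd_mm: float = 3.0) -> dict[str, SimConfig]:
    """Named presets spanning the limb-movement taxonomy.

    * ``exp1`` — both-limb and individual-limb movement series.
    * ``exp2`` — left-limb-only series (8 one-second movements, 10 s apart).
    * ``exp3`` — right-limb series plus a both-limb series.
    * ``exp4`` — one unbroken constant movement (non-periodic, hence non-PLMD).
    * ``pose_change`` — a single instantaneous both-limb posture change and
      nothing else (excluded from PLMD by rule).
    """
    supine = PostureLabel("supine", "static")
    common = dict(duration_s=600.0, noise_sd_mm=noise_sd_mm, seed=seed)
    lib = {
        "exp1": SimConfig(
            posture_schedule=((0.0, supine),),
            episodes=(
                PLMEpisodeSpec("both", 60, 5, 2, 20, 150.0),
                PLMEpisodeSpec("left", 200, 5, 1, 15, 150.0),
                PLMEpisodeSpec("right", 320, 6, 2, 15, 150.0),
            ),
            **common,
        ),
        "exp2": SimConfig(
            posture_schedule=((0.0, supine),),
            episodes=(PLMEpisodeSpec("left", 100, 8, 1, 10, 150.0),),
            **common,
        ),
        "exp3": SimConfig(
            posture_schedule=((0.0, supine),),
            episodes=(
                PLMEpisodeSpec("right", 80, 6, 1, 12, 150.0),
                PLMEpisodeSpec("both", 300, 4, 2, 20, 150.0),
            ),
            **common,
        ),
        "exp4": SimConfig(
            posture_schedule=((0.0, supine),),
            episodes=(PLMEpisodeSpec("both", 100, 1, 120, 121, 150.0),),
            **common,
        ),
        "pose_change": SimConfig(
            posture_schedule=(
                (0.0, supine),
                (300.0, PostureLabel("prone", "static")),
            ),
            episodes=(),
            **common,
        ),
    }
    return lib


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
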