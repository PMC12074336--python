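"""Periodic limb movement detection over the lower-limb channels.

The detection chain, mirroring the streaming decision datapath:

1. **Posture matching** — each one-second window's six-bit occupancy pattern
   (augmented with a motion bit) is looked up in a balanced binary search
   tree of reference patterns; a miss falls back to the random forest.
2. **Fusion measurement** — per limb, the absolute difference between the
   mean distances of the previous and current one-second windows.
3. **Limb flags** — a limb is "in motion" in second ``t`` (logic 1) iff its
   fusion magnitude between seconds ``t-1`` and ``t`` exceeds the movement
   threshold.
4. **Event extraction** — maximal runs of equal flag state become movement
   events (left / right / both); TLM (time of limb movement) counts every
   flagged second once, whichever limbs moved.
5. **Decision fusion** — rule layer: a single one-second both-limb event at a
   posture transition is a pose change, not PLMD; an over-long unbroken run
   is constant movement, not PLMD; what remains is confirmed as a PLM series
   when enough events occur close enough together.  Confirmed durations feed
   a circular duration FIFO, and the events-per-hour rate sets the stage
   (early / middle / high).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .capture import Baseline, binarize, build_feature_vector, iter_windows
from .forest import Forest
from .simulate import CHANNELS, LLL, LLR, PostureLabel

LIMB_COLUMNS = {"left": 0, "right": 1}


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and rule parameters of the detection chain.

    Distances are tenths of a millimetre; durations are one-second movement
    units.  ``stage_bounds`` are events-per-hour cut points: below the first
    is early stage, below the second middle, at or above it high.
    """

    movement_threshold: float = 1000.0
    window_s: int = 1
    min_event_units: int = 1
    max_event_units: int = 40
    min_series: int = 4
    max_interval_s: int = 90
    stage_bounds: tuple[float, float] = (25.0, 50.0)
    duration_fifo_capacity: int = 8
    #: Window variance above this marks the window as time-variant when
    #: forming the BST lookup key.
    motion_var_threshold: float = 4000.0

    def __post_init__(self) -> None:
        if self.movement_threshold <= 0:
            raise ValueError("movement_threshold must be positive")
        if self.window_s != 1:
            raise ValueError("only 1 s analysis windows are supported")
        if not 1 <= self.min_event_units <= self.max_event_units:
            raise ValueError("need 1 <= min_event_units <= max_event_units")
        if self.min_series < 1 or self.max_interval_s < 1:
            raise ValueError("min_series and max_interval_s must be positive")
        if not 0 < self.stage_bounds[0] < self.stage_bounds[1]:
            raise ValueError("stage_bounds must be increasing and positive")
        if self.duration_fifo_capacity < 1:
            raise ValueError("duration_fifo_capacity must be positive")


@dataclass(frozen=True)
class MovementEvent:
    """A maximal run of seconds in which one limb set is in motion."""

    limb: str  # left | right | both
    start_s: int
    duration_units: int

    def __post_init__(self) -> None:
        if self.limb not in ("left", "right", "both"):
            raise ValueError("limb must be left, right or both")
        if self.duration_units < 1:
            raise ValueError("duration_units must be positive")

    @property
    def end_s(self) -> int:
        return self.start_s + self.duration_units


class DurationFIFO:
    """Circular buffer of the most recent confirmed movement durations."""

    def __init__(self, capacity: int = 8) -> None:
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._buf: list[int] = []

    def push(self, duration_units: int) -> None:
        if len(self._buf) == self.capacity:
            self._buf.pop(0)  # overwrite oldest-first
        self._buf.append(int(duration_units))

    def contents(self) -> list[int]:
        """Stored durations, oldest first."""
        return list(self._buf)

    def __len__(self) -> int:
        return len(self._buf)


class FeatureBST:
    """Balanced binary search tree mapping whole-number pattern keys to
    posture labels; the fast exact-match path of posture classification."""

    @dataclass
    class _Node:
        key: int
        label: str
        left: "FeatureBST._Node | None" = None
        right: "FeatureBST._Node | None" = None

    def __init__(self) -> None:
        self._root: FeatureBST._Node | None = None
        self.size = 0

    def lookup(self, key: int) -> str | None:
        node = self._root
        while node is not None:
            if key == node.key:
                return node.label
            node = node.left if key < node.key else node.right
        return None

    def in_order_keys(self) -> list[int]:
        out: list[int] = []

        def walk(node: "FeatureBST._Node | None") -> None:
            if node is None:
                return
            walk(node.left)
            out.append(node.key)
            walk(node.right)

        walk(self._root)
        return out


def bst_build(references: Mapping[int, str] | Iterable[tuple[int, str]]) -> FeatureBST:
    """Build a balanced BST from (key, label) reference patterns.

    A key appearing twice with conflicting labels is a configuration error.
    """
    pairs = list(references.items()) if isinstance(references, Mapping) \
        else list(references)
    seen: dict[int, str] = {}
    for key, label in pairs:
        if key in seen and seen[key] != label:
            raise ValueError(
                f"pattern key {key} maps to both {seen[key]!r} and {label!r}"
            )
        seen[key] = label
    items = sorted(seen.items())
    bst = FeatureBST()

    def build(lo: int, hi: int) -> "FeatureBST._Node | None":
        if lo >= hi:
            return None
        mid = (lo + hi) // 2
        key, label = items[mid]
        node = FeatureBST._Node(key=key, label=label)
        node.left = build(lo, mid)
        node.right = build(mid + 1, hi)
        return node

    bst._root = build(0, len(items))
    bst.size = len(items)
    return bst


def window_key(window: np.ndarray, baseline: Baseline,
               config: DetectorConfig) -> int:
    """BST lookup key of a window: occupancy-pattern value with a trailing
    motion bit (1 when any channel's window variance marks it time-variant)."""
    window = np.asarray(window, dtype=float)
    means = window.mean(axis=0)
    pattern = binarize(means, baseline)
    motion = int(window.var(axis=0).max() > config.motion_var_threshold)
    return (pattern.value << 1) | motion


def build_reference_bst(baseline: Baseline,
                        config: DetectorConfig | None = None) -> FeatureBST:
    """Reference BST from the encoded (per-posture) baselines.

    Each trained posture contributes the key its own windows produce: the
    occupancy pattern of its encoded profile plus the variant motion bit.
    """
    config = config or DetectorConfig()
    refs: list[tuple[int, str]] = []
    for key, profile in baseline.encoded.items():
        label = PostureLabel.from_key(key)
        pattern = binarize(profile, baseline)
        motion = int(label.variant == "time_variant")
        refs.append(((pattern.value << 1) | motion, key))
    return bst_build(refs)


def match_posture(bst: FeatureBST | None, key: int, forest: Forest,
                  x: np.ndarray) -> str:
    """Exact BST hit wins; otherwise the forest votes."""
    if bst is not None:
        hit = bst.lookup(key)
        if hit is not None:
            return hit
    label, _tally = forest.predict(x)
    return label


def fusion_measurement(prev_window: np.ndarray,
                       cur_window: np.ndarray) -> tuple[float, float]:
    """Per-limb motion magnitude between two consecutive 1 s windows:
    absolute difference of the window means of LLL and LLR (tenths of mm)."""
    prev_window = np.asarray(prev_window, dtype=float)
    cur_window = np.asarray(cur_window, dtype=float)
    for w in (prev_window, cur_window):
        if w.ndim != 2 or w.shape[1] != len(CHANNELS) or w.shape[0] < 1:
            raise ValueError("windows must be (frames, 6)")
    prev_means = prev_window.mean(axis=0)
    cur_means = cur_window.mean(axis=0)
    return (
        float(abs(cur_means[LLL] - prev_means[LLL])),
        float(abs(cur_means[LLR] - prev_means[LLR])),
    )


def limb_flags(frames: np.ndarray, config: DetectorConfig | None = None,
               sample_rate_hz: float = 4.0) -> np.ndarray:
    """Per-second motion flags for (LLL, LLR).

    Second ``t`` is flagged for a limb iff the fusion magnitude between the
    windows of seconds ``t-1`` and ``t`` exceeds the movement threshold;
    second 0 has no prior window and is never flagged.
    """
    config = config or DetectorConfig()
    frames = np.asarray(frames, dtype=float)
    fpw = int(round(sample_rate_hz))
    n_sec = len(frames) // fpw
    if n_sec < 2:
        raise ValueError("need at least 2 s of data for limb flags")
    windows = frames[: n_sec * fpw].reshape(n_sec, fpw, -1)
    means = windows.mean(axis=1)  # (n_sec, 6)
    flags = np.zeros((n_sec, 2), dtype=np.int8)
    diffs = np.abs(np.diff(means[:, [LLL, LLR]], axis=0))
    flags[1:] = (diffs > config.movement_threshold).astype(np.int8)
    return flags


def extract_events(flags: np.ndarray) -> tuple[list[MovementEvent], int]:
    """Partition the flag series into maximal constant-state runs.

    Per second the limb state is none / left / right / both; maximal runs of
    an identical non-none state become events (so a left run overlapping a
    right run splits into both + residual single-limb events).  TLM counts
    each second with any motion exactly once.
    """
    flags = np.asarray(flags)
    if flags.ndim != 2 or flags.shape[1] != 2:
        raise ValueError("flags must be (n_seconds, 2)")
    state = flags[:, 0] + 2 * flags[:, 1]  # 0 none, 1 left, 2 right, 3 both
    names = {1: "left", 2: "right", 3: "both"}
    events: list[MovementEvent] = []
    start = None
    cur = 0
    for s, st in enumerate(state.tolist() + [0]):
        if st != cur:
            if cur != 0:
                events.append(MovementEvent(names[cur], start, s - start))
            start = s
            cur = st
    tlm = int((state > 0).sum())
    return events, tlm


@dataclass
class PLMDResult:
    """Outcome of decision fusion for one session."""

    status: str  # none | left | right | both
    stage: str  # early | middle | high | not-applicable
    tlm_units: int
    events: list[MovementEvent] = field(default_factory=list)  # confirmed
    retained_events: list[MovementEvent] = field(default_factory=list)
    all_events: list[MovementEvent] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)
    events_per_hour: float = 0.0
    duration_fifo: list[int] = field(default_factory=list)
    report: dict[str, int] = field(default_factory=dict)
    posture_segments: list[tuple[str, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "stage": self.stage,
            "tlm_units": self.tlm_units,
            "events_per_hour": self.events_per_hour,
            "events": [
                {"limb": e.limb, "start_s": e.start_s,
                 "duration_units": e.duration_units}
                for e in self.events
            ],
            "all_events": [
                {"limb": e.limb, "start_s": e.start_s,
                 "duration_units": e.duration_units}
                for e in self.all_events
            ],
            "exclusions": self.exclusions,
            "duration_fifo": self.duration_fifo,
            "report": self.report,
            "posture_segments": [
                {"posture": p, "start_s": a, "end_s": b}
                for p, a, b in self.posture_segments
            ],
        }


def decision_fusion(events: Sequence[MovementEvent],
                    config: DetectorConfig | None = None,
                    posture_change_seconds: Iterable[int] = (),
                    session_duration_s: float | None = None,
                    fifo: DurationFIFO | None = None) -> PLMDResult:
    """Turn raw movement events into a PLMD status, stage and TLM.

    Exclusion rules first: a single one-unit both-limb event coinciding with
    a posture change is a pose change; any run longer than
    ``max_event_units`` is constant (non-periodic) movement.  The surviving
    events are confirmed as a PLM series when at least ``min_series`` of them
    occur with inter-event gaps of at most ``max_interval_s`` seconds.
    """
    config = config or DetectorConfig()
    changes = set(int(s) for s in posture_change_seconds)
    fifo = fifo or DurationFIFO(config.duration_fifo_capacity)

    exclusions: list[str] = []
    retained: list[MovementEvent] = []
    for ev in sorted(events, key=lambda e: e.start_s):
        if ev.limb == "both" and ev.duration_units == 1 and ev.start_s in changes:
            exclusions.append(
                f"pose change at {ev.start_s}s (single-instant both-limb shift)"
            )
            continue
        if ev.duration_units > config.max_event_units:
            exclusions.append(
                f"constant movement at {ev.start_s}s "
                f"({ev.duration_units} units exceeds {config.max_event_units})"
            )
            continue
        if ev.duration_units < config.min_event_units:
            exclusions.append(
                f"sub-minimal event at {ev.start_s}s ({ev.duration_units} units)"
            )
            continue
        retained.append(ev)

    # Group retained events into candidate series by inter-event gap.
    groups: list[list[MovementEvent]] = []
    for ev in retained:
        if groups and ev.start_s - groups[-1][-1].end_s <= config.max_interval_s:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    confirmed = [ev for g in groups if len(g) >= config.min_series for ev in g]

    limbs = {e.limb for e in confirmed}
    if not confirmed:
        status = "none"
    elif "both" in limbs or {"left", "right"} <= limbs:
        status = "both"
    else:
        status = limbs.pop()

    tlm = sum(e.duration_units for e in confirmed)
    for ev in confirmed:
        fifo.push(ev.duration_units)

    if confirmed and session_duration_s:
        rate = len(confirmed) / (session_duration_s / 3600.0)
        if rate < config.stage_bounds[0]:
            stage = "early"
        elif rate < config.stage_bounds[1]:
            stage = "middle"
        else:
            stage = "high"
    else:
        rate = 0.0
        stage = "not-applicable"

    return PLMDResult(
        status=status,
        stage=stage,
        tlm_units=tlm,
        events=confirmed,
        retained_events=retained,
        all_events=list(events),
        exclusions=exclusions,
        events_per_hour=rate,
        duration_fifo=fifo.contents(),
    )


def _unit_report(retained: Sequence[MovementEvent], n_seconds: int,
                 tlm_all: int, n_posture_changes: int) -> dict[str, int]:
    counts = {"static": n_seconds - tlm_all, "left": 0, "right": 0, "both": 0,
              "posture_changes": n_posture_changes}
    for ev in retained:
        counts[ev.limb] += ev.duration_units
    return counts


def analyze_stream(frames: np.ndarray, baseline: Baseline, forest: Forest,
                   config: DetectorConfig | None = None,
                   bst: FeatureBST | None = None,
                   sample_rate_hz: float = 4.0) -> PLMDResult:
    """Full per-session analysis: posture timeline, limb flags, events,
    decision fusion, and a unit-count report by event type.

    The stream is consumed in one-second windows.  Each window is classified
    (BST fast path, forest fallback); posture-label changes close out posture
    segments and mark pose-change seconds for the exclusion rule.
    """
    config = config or DetectorConfig()
    frames = np.asarray(frames, dtype=float)
    fpw = int(round(sample_rate_hz))
    if len(frames) < fpw:
        raise ValueError("stream shorter than one analysis window")

    postures: list[str] = []
    for i, window in enumerate(iter_windows(frames, fpw)):
        x = build_feature_vector(window, baseline, window_id=i).values
        key = window_key(window, baseline, config)
        postures.append(match_posture(bst, key, forest, x))

    change_seconds = [s for s in range(1, len(postures))
                     if postures[s] != postures[s - 1]]

    flags = limb_flags(frames, config, sample_rate_hz)
    events, tlm_all = extract_events(flags)
    result = decision_fusion(
        events, config,
        posture_change_seconds=change_seconds,
        session_duration_s=len(postures),
    )
    result.report = _unit_report(result.retained_events, len(postures),
                                 tlm_all, len(change_seconds))

    segments: list[tuple[str, int, int]] = []
    seg_start = 0
    for s in range(1, len(postures) + 1):
        if s == len(postures) or postures[s] != postures[seg_start]:
            segments.append((postures[seg_start], seg_start, s))
            seg_start = s
    result.posture_segments = segments
    return result
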