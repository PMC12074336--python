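"""Closed-form calculators for the monitoring rig: beam coverage on the bed,
pipeline latency of the streaming datapath, and prediction accuracy/error.

The sensor array hangs from the ceiling above the bed, one pair of ultrasonic
transducers per body row (upper trunk, mid trunk, lower limbs).  The footprint
each transducer illuminates on the mattress is a simple tangent projection of
its beam angle at the mounting height.  The latency model describes a
pipelined datapath with ``S`` stages clocked at ``t_clk`` processing ``N``
iterations back to back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BedGeometry:
    """Bed and sensor-rig geometry.

    Heights are metres.  ``sensor_to_target_m`` holds the mounting height of
    the (upper, middle, lower) sensor rows above the mattress surface.
    """

    ceiling_floor_height_m: float = 2.8
    sensor_to_target_m: tuple[float, float, float] = (2.2, 2.1, 1.9)
    bed_length_m: float = 2.0
    bed_width_m: float = 0.9
    beam_angle_deg: float = 22.0

    def __post_init__(self) -> None:
        if self.ceiling_floor_height_m <= 0:
            raise ValueError("ceiling_floor_height_m must be positive")
        if len(self.sensor_to_target_m) != 3:
            raise ValueError("sensor_to_target_m needs (upper, middle, lower)")
        for h in self.sensor_to_target_m:
            if h <= 0:
                raise ValueError("sensor mounting heights must be positive")
            if h > self.ceiling_floor_height_m:
                raise ValueError(
                    "sensor mounting height exceeds ceiling-floor height"
                )
        if self.bed_length_m <= 0 or self.bed_width_m <= 0:
            raise ValueError("bed dimensions must be positive")
        if not 0 < self.beam_angle_deg < 90:
            raise ValueError("beam_angle_deg must lie strictly in (0, 90)")


@dataclass(frozen=True)
class LatencyModel:
    """Pipelined-datapath timing: ``stages`` deep, ``iterations`` items,
    one clock of ``clk_ns`` nanoseconds per stage advance."""

    stages: int = 12
    clk_ns: float = 10.0
    iterations: int = 40

    def __post_init__(self) -> None:
        if self.stages < 1:
            raise ValueError("stages must be a positive count")
        if self.iterations < 1:
            raise ValueError("iterations must be a positive count")
        if self.clk_ns <= 0:
            raise ValueError("clk_ns must be positive")


@dataclass(frozen=True)
class AccuracyReport:
    correct: int
    total: int
    accuracy_pct: float = field(init=False)
    error_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total predictions must be positive")
        if not 0 <= self.correct <= self.total:
            raise ValueError("correct must lie in [0, total]")
        object.__setattr__(self, "accuracy_pct", 100.0 * self.correct / self.total)
        object.__setattr__(self, "error_pct", 100.0 - self.accuracy_pct)


def beam_coverage_cm(height_m: float, angle_deg: float) -> int:
    """Footprint length on the bed, in whole centimetres.

    ``tan(angle) * height`` truncated toward zero to an integer number of
    centimetres (the convention that reproduces the rig's printed coverages:
    88 / 84 / 76 cm for 2.2 / 2.1 / 1.9 m at 22 degrees).
    """
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    if not 0 <= angle_deg < 90:
        raise ValueError("angle_deg must lie in [0, 90)")
    return int(math.tan(math.radians(angle_deg)) * height_m * 100.0)


def per_iteration_latency_ns(model: LatencyModel) -> float:
    """Latency of one iteration through the pipeline: S * t_clk."""
    return model.stages * model.clk_ns


def pipeline_latency_ns(model: LatencyModel) -> float:
    """Total latency of N iterations through an S-stage pipeline:
    (N + S - 1) * t_clk.  Collapses to S * t_clk at N = 1."""
    return (model.iterations + model.stages - 1) * model.clk_ns


def accuracy_report(correct: int, total: int) -> AccuracyReport:
    """Prediction accuracy and complementary error rate, in percent."""
    return AccuracyReport(correct=correct, total=total)


def coverage_table(geometry: BedGeometry) -> list[tuple[str, float, int]]:
    """Per sensor row: (row name, mounting height m, coverage cm)."""
    rows = ("upper", "middle", "lower")
    return [
        (name, h, beam_coverage_cm(h, geometry.beam_angle_deg))
        for name, h in zip(rows, geometry.sensor_to_target_m)
    ]
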