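"""File formats: frame/truth/episode CSV, baseline CSV, result JSON, report
CSV, and the YAML run configuration.

All frame CSVs share the schema ``frame,t_s,UBL,UBR,MBL,MBR,LLL,LLR`` with
distances as integers in tenths of a millimetre; write/read round-trips are
byte-identical so that a (config, seed) pair fully determines every output
file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .capture import Baseline, N_FEATURES
from .detector import DetectorConfig, PLMDResult
from .forest import Forest, ForestConfig
from .geometry import BedGeometry
from .simulate import (
    CHANNELS, GroundTruth, PLMEpisodeSpec, PostureLabel, SENSOR_MAX,
    SENSOR_MIN, SimConfig, scenario_library,
)

FRAME_HEADER = ["frame", "t_s", *CHANNELS]


class FrameFormatError(ValueError):
    """Malformed frame CSV; message carries the offending location."""


def write_frames(frames: np.ndarray, path: str | Path,
                 sample_rate_hz: float = 4.0) -> None:
    frames = np.asarray(frames)
    df = pd.DataFrame(frames, columns=list(CHANNELS))
    df.insert(0, "t_s", [f"{i / sample_rate_hz:.2f}" for i in range(len(frames))])
    df.insert(0, "frame", np.arange(len(frames)))
    df.to_csv(path, index=False)


def read_frames(path: str | Path) -> np.ndarray:
    """Read and validate a frame CSV; returns (n, 6) int32 distances."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FrameFormatError(f"{path}: {exc}") from exc
    missing = [c for c in FRAME_HEADER if c not in df.columns]
    if missing:
        raise FrameFormatError(
            f"{path}: missing column(s) {', '.join(missing)}"
        )
    values = df[list(CHANNELS)]
    for ch in CHANNELS:
        col = pd.to_numeric(values[ch], errors="coerce")
        bad = col.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FrameFormatError(f"{path}:{line}: non-numeric {ch} value")
        out_of_range = (col < SENSOR_MIN) | (col > SENSOR_MAX)
        if out_of_range.any():
            line = int(out_of_range.idxmax()) + 2
            raise FrameFormatError(
                f"{path}:{line}: {ch} distance {col[out_of_range.idxmax()]:g} "
                f"outside sensor range [{SENSOR_MIN}, {SENSOR_MAX}]"
            )
    return values.to_numpy(dtype=np.int32)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    df = pd.DataFrame({
        "t_s": np.arange(len(truth.posture_per_second)),
        "posture": truth.posture_per_second,
        "flag_LLL": truth.flags[:, 0],
        "flag_LLR": truth.flags[:, 1],
    })
    df.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["t_s", "posture", "flag_LLL", "flag_LLR"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FrameFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def write_episodes(episodes: Sequence[PLMEpisodeSpec], path: str | Path) -> None:
    df = pd.DataFrame([
        {
            "limb": ep.limb, "onset_s": ep.onset_s, "count": ep.movement_count,
            "duration_s": ep.movement_duration_s,
            "interval_s": ep.inter_movement_interval_s,
            "magnitude_mm": ep.magnitude_mm,
        }
        for ep in episodes
    ], columns=["limb", "onset_s", "count", "duration_s", "interval_s",
                "magnitude_mm"])
    df.to_csv(path, index=False)


def write_baseline(baseline: Baseline, early_path: str | Path,
                   encoded_path: str | Path) -> None:
    pd.DataFrame({"channel": CHANNELS, "early": baseline.early}).to_csv(
        early_path, index=False)
    rows = [
        {"posture": key, **{ch: v for ch, v in zip(CHANNELS, profile)}}
        for key, profile in baseline.encoded.items()
    ]
    pd.DataFrame(rows, columns=["posture", *CHANNELS]).to_csv(
        encoded_path, index=False)


def read_baseline(early_path: str | Path, encoded_path: str | Path,
                  occupancy_margin: float = 1000.0) -> Baseline:
    early_df = pd.read_csv(early_path)
    early = np.empty(len(CHANNELS))
    by_channel = dict(zip(early_df["channel"], early_df["early"]))
    for i, ch in enumerate(CHANNELS):
        if ch not in by_channel:
            raise FrameFormatError(f"{early_path}: missing channel {ch}")
        early[i] = by_channel[ch]
    encoded_df = pd.read_csv(encoded_path)
    encoded = {
        row["posture"]: np.array([row[ch] for ch in CHANNELS], dtype=float)
        for _, row in encoded_df.iterrows()
    }
    return Baseline(early=early, encoded=encoded,
                    occupancy_margin=occupancy_margin)


def write_model(forest: Forest, path: str | Path) -> None:
    Path(path).write_text(forest.to_json() + "\n")


def read_model(path: str | Path) -> Forest:
    return Forest.from_json(Path(path).read_text())


def write_result(result: PLMDResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), sort_keys=True,
                                     indent=2) + "\n")


REPORT_ROWS = ("static", "left", "right", "both", "posture_changes")


def write_report(result: PLMDResult, path: str | Path) -> None:
    """Event-type vs unit-count table (the detector's summary axes)."""
    counts = result.report or {}
    df = pd.DataFrame({
        "event_type": REPORT_ROWS,
        "count_units": [int(counts.get(r, 0)) for r in REPORT_ROWS],
    })
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration

_GEOMETRY_KEYS = {"ceiling_floor_height_m", "sensor_to_target_m",
                  "bed_length_m", "bed_width_m", "beam_angle_deg"}
_SIMULATE_KEYS = {"scenario", "duration_s", "sample_rate_hz", "noise_sd_mm",
                  "baseline_drift_mm", "posture_schedule", "episodes",
                  "flag_threshold"}
_FOREST_KEYS = {"n_trees", "n_features"}
_DETECTOR_KEYS = {"movement_threshold", "window_s", "min_event_units",
                  "max_event_units", "min_series", "max_interval_s",
                  "stage_bounds", "duration_fifo_capacity",
                  "motion_var_threshold"}
_TOP_KEYS = {"geometry", "simulate", "forest", "detector", "seed",
             "occupancy_margin", "training_segment_s",
             "calibration_duration_s"}


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending section/key."""


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(unknown)}"
        )


@dataclass
class RunConfig:
    """Validated union of all module configurations for a pipeline run."""

    geometry: BedGeometry = field(default_factory=BedGeometry)
    sim: SimConfig | None = None
    scenario: str | None = "exp2"
    forest: ForestConfig = field(default_factory=ForestConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    seed: int = 0
    occupancy_margin: float = 1000.0
    training_segment_s: int = 20
    calibration_duration_s: int = 60

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigError("configuration must be a mapping")
        _check_keys("<top level>", doc, _TOP_KEYS)
        geo_doc = dict(doc.get("geometry") or {})
        _check_keys("geometry", geo_doc, _GEOMETRY_KEYS)
        if "sensor_to_target_m" in geo_doc:
            geo_doc["sensor_to_target_m"] = tuple(geo_doc["sensor_to_target_m"])
        try:
            geometry = BedGeometry(**geo_doc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"section 'geometry': {exc}") from exc

        sim_doc = dict(doc.get("simulate") or {})
        _check_keys("simulate", sim_doc, _SIMULATE_KEYS)
        scenario = sim_doc.pop("scenario", None)
        sim = None
        if sim_doc:
            if "posture_schedule" in sim_doc:
                sim_doc["posture_schedule"] = tuple(
                    (float(s), PostureLabel.from_key(k))
                    for s, k in sim_doc["posture_schedule"]
                )
            if "episodes" in sim_doc:
                sim_doc["episodes"] = tuple(
                    PLMEpisodeSpec(**e) for e in sim_doc["episodes"]
                )
            try:
                sim = SimConfig(geometry=geometry, **sim_doc)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"section 'simulate': {exc}") from exc
        elif scenario is None:
            scenario = "exp2"

        forest_doc = dict(doc.get("forest") or {})
        _check_keys("forest", forest_doc, _FOREST_KEYS)
        try:
            forest_cfg = ForestConfig(seed=int(doc.get("seed", 0)), **forest_doc)
            forest_cfg.resolve_m(N_FEATURES)  # pipeline features are M = 24
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"section 'forest': {exc}") from exc

        det_doc = dict(doc.get("detector") or {})
        _check_keys("detector", det_doc, _DETECTOR_KEYS)
        if "stage_bounds" in det_doc:
            det_doc["stage_bounds"] = tuple(det_doc["stage_bounds"])
        try:
            detector_cfg = DetectorConfig(**det_doc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"section 'detector': {exc}") from exc

        return cls(
            geometry=geometry,
            sim=sim,
            scenario=scenario,
            forest=forest_cfg,
            detector=detector_cfg,
            seed=int(doc.get("seed", 0)),
            occupancy_margin=float(doc.get("occupancy_margin", 1000.0)),
            training_segment_s=int(doc.get("training_segment_s", 20)),
            calibration_duration_s=int(doc.get("calibration_duration_s", 60)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc or {})

    def scenario_config(self) -> SimConfig:
        """The session to analyse: explicit simulate section or named preset."""
        if self.sim is not None:
            return self.sim
        lib = scenario_library()
        if self.scenario not in lib:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; "
                f"choose one of {', '.join(sorted(lib))}"
            )
        return lib[self.scenario]
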