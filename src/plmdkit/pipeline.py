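"""End-to-end pipeline: calibrate -> train -> simulate scenario -> detect ->
report, with every stage's artifact written to disk.

All randomness flows from one run seed; each stage derives its own seed from
it with a fixed offset, so a (config, seed) pair determines every output byte.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

from . import capture, detector, forest, io, simulate

log = logging.getLogger("plmdkit")

#: Fixed per-stage seed offsets (kept below 2**31 after derivation).
_STAGE_OFFSETS = {"calibration": 101, "training": 211, "scenario": 307}


def derive_seed(seed: int, stage: str) -> int:
    return (int(seed) + _STAGE_OFFSETS[stage]) % (2 ** 31)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def build_training_artifacts(config: io.RunConfig):
    """Calibrate the baselines and train the posture forest.

    Returns ``(baseline, trained_forest, bst)``.
    """
    try:
        empty_cfg = simulate.SimConfig(
            duration_s=float(config.calibration_duration_s),
            geometry=config.geometry,
            seed=derive_seed(config.seed, "calibration"),
        )
        empty_frames = simulate.empty_bed_session(empty_cfg)
    except Exception as exc:
        raise StageError("calibration", exc) from exc

    try:
        train_cfg = simulate.training_session_config(
            seed=derive_seed(config.seed, "training"),
            segment_s=config.training_segment_s,
            geometry=config.geometry,
        )
        train_frames, train_truth = simulate.simulate_session(train_cfg)
        baseline = capture.calibrate(
            empty_frames, train_frames, train_truth.posture_per_frame,
            occupancy_margin=config.occupancy_margin,
        )
        X, y = capture.build_dataset(train_frames,
                                     train_truth.posture_per_second, baseline)
        dataset = forest.Dataset.from_labelled(X, y,
                                               classes=simulate.LABEL_KEYS)
        trained = forest.train_forest(dataset, config.forest)
        bst = detector.build_reference_bst(baseline, config.detector)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("training", exc) from exc
    return empty_frames, baseline, trained, bst


def run_pipeline(config: io.RunConfig, out_dir: str | Path) -> detector.PLMDResult:
    """Execute the full monitoring pipeline and write all artifacts.

    Writes: empty-bed and scenario frame CSVs, ground-truth and episode CSVs,
    baseline CSVs, the forest model JSON, the PLMD result JSON and the
    event-type unit-count report CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=calibration+training seed=%d", config.seed)
    empty_frames, baseline, trained, bst = build_training_artifacts(config)
    io.write_frames(empty_frames, out / "empty_bed.csv")
    io.write_baseline(baseline, out / "baseline_early.csv",
                      out / "baseline_encoded.csv")
    io.write_model(trained, out / "model.json")

    try:
        scen = replace(config.scenario_config(),
                       geometry=config.geometry,
                       seed=derive_seed(config.seed, "scenario"))
        frames, truth = simulate.simulate_session(scen)
        io.write_frames(frames, out / "frames.csv")
        io.write_truth(truth, out / "truth.csv")
        io.write_episodes(truth.episodes, out / "episodes.csv")
        log.info("stage=scenario frames=%d episodes=%d",
                 len(frames), len(truth.episodes))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("scenario", exc) from exc

    try:
        result = detector.analyze_stream(frames, baseline, trained,
                                         config.detector, bst=bst)
        io.write_result(result, out / "result.json")
        io.write_report(result, out / "report.csv")
        log.info("stage=detect status=%s stage_label=%s tlm=%d",
                 result.status, result.stage, result.tlm_units)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("detect", exc) from exc
    return result
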