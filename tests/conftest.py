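import pytest

from plmdkit import capture, forest, simulate
from plmdkit.geometry import BedGeometry


@pytest.fixture(scope="session")
def geometry():
    return BedGeometry()


def make_zero_noise_config(duration_s=60.0, schedule=None, episodes=(),
                           seed=0):
    return simulate.SimConfig(
        duration_s=duration_s,
        noise_sd_mm=0.0,
        posture_schedule=schedule or ((0.0, simulate.PostureLabel("supine")),),
        episodes=tuple(episodes),
        seed=seed,
    )


@pytest.fixture(scope="session")
def zero_noise_training():
    """Noiseless labelled 12-posture session, baseline, and dataset."""
    cfg = simulate.training_session_config(seed=0, segment_s=20,
                                           noise_sd_mm=0.0)
    frames, truth = simulate.simulate_session(cfg)
    empty = simulate.empty_bed_session(
        simulate.SimConfig(duration_s=60.0, noise_sd_mm=0.0, seed=0))
    baseline = capture.calibrate(empty, frames, truth.posture_per_frame)
    X, y = capture.build_dataset(frames, truth.posture_per_second, baseline)
    dataset = forest.Dataset.from_labelled(X, y, classes=simulate.LABEL_KEYS)
    return cfg, frames, truth, baseline, dataset


@pytest.fixture(scope="session")
def trained_zero_noise_forest(zero_noise_training):
    _cfg, _frames, _truth, baseline, dataset = zero_noise_training
    return baseline, forest.train_forest(dataset, forest.ForestConfig(seed=7))
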