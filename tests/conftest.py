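import numpy as np
import pytest
from hypothesis import settings

from dragtraj.core import GeneratorConfig
from dragtraj import evaluate, preprocess, synthetic
from dragtraj.model import ModelConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """160 trajectories, 5 subjects per group, strong acceleration contrast."""
    cfg = GeneratorConfig(
        n_subjects_per_group=5, trajectories_per_subject=16, accel_effect=2.0, seed=7
    )
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def prepared_dataset(small_dataset):
    """The small dataset rotated to the canonical axis and length-filtered."""
    return preprocess.filter_by_length(preprocess.rotate_dataset(small_dataset))


@pytest.fixture(scope="session")
def trained_artifacts(prepared_dataset):
    """A briefly trained four-feature experiment with its fold models."""
    plan = evaluate.make_split(prepared_dataset, seed=11)
    cfg = ModelConfig(epochs=12, seed=11)
    report, artifacts = evaluate.run_experiment(
        prepared_dataset, cfg, "four_feature", plan, return_artifacts=True
    )
    return report, artifacts, plan


def make_trajectory(points, trajectory_id="t0", subject_id="s0", group="TD", dt=0.05):
    from dragtraj.core import Trajectory

    return Trajectory(
        trajectory_id=trajectory_id,
        subject_id=subject_id,
        group=group,
        points=np.asarray(points, dtype=float),
        dt=dt,
    )
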