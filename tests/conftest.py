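import numpy as np
import pandas as pd
import pytest

from oculomse import CohortConfig, CvConfig, PipelineConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but structured cohort: 5 TD + 4 ADHD-like, 20 s recordings."""
    config = CohortConfig(n_td=5, n_adhd=4, n_drug_naive=3, duration_s=20.0, seed=99)
    recordings, manifest = generate_cohort(config)
    return config, recordings, manifest


@pytest.fixture(scope="session")
def tiny_pipeline_config(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("pipe")
    return PipelineConfig(
        recordings_dir=str(tmp / "recordings"),
        manifest_path=str(tmp / "manifest.csv"),
        output_dir=str(tmp / "out"),
        seed=5,
        simulation=CohortConfig(
            n_td=5, n_adhd=4, n_drug_naive=3, duration_s=20.0, seed=5
        ),
        cv=CvConfig(
            lambda_grid=tuple(float(x) for x in np.logspace(-3, 1, 8)), seed=5
        ),
    )


def make_feature_table(
    n_td=10, n_adhd=8, seed=0, pupil_delta=0.0, entropy_delta=0.0, noise=0.3
):
    """Labelled feature table with controllable group effects."""
    rng = np.random.default_rng(seed)
    n = n_td + n_adhd
    group = np.array(["TD"] * n_td + ["ADHD"] * n_adhd)
    adhd = (group == "ADHD").astype(float)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "group": group,
            "drug_naive": np.r_[np.zeros(n_td), np.ones(n_adhd)].astype(int),
            "age_years": rng.uniform(20, 50, n).round(1),
            "sex": rng.choice(["M", "F"], n),
            "asrs_total": rng.integers(5, 60, n),
            "asrs_in": rng.integers(3, 30, n),
            "asrs_hypi": rng.integers(2, 30, n),
            "pupil_size": 4.0 + pupil_delta * adhd + rng.normal(0, noise, n),
            "hor_fuzzyen": -1.0 - entropy_delta * adhd + rng.normal(0, noise, n),
            "vert_fuzzyen": -1.0 - entropy_delta * adhd + rng.normal(0, noise, n),
        }
    )


@pytest.fixture
def feature_table():
    return make_feature_table(pupil_delta=0.4, entropy_delta=0.3, seed=7)
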