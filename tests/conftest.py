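import numpy as np
import pytest

from stsbalance.bos import default_template, extract_cop_profiles
from stsbalance.kinematics import preprocess
from stsbalance.pipeline import AnalysisConfig, analyze_trial
from stsbalance.synthetic import (
    SyntheticCohortSpec,
    generate_cop_excursion_trial,
    generate_quiet_standing,
    generate_sts_trial,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def cohort_spec():
    return SyntheticCohortSpec(seed=42)


@pytest.fixture(scope="session")
def noiseless_spec():
    return SyntheticCohortSpec(seed=42, noise_sd_marker=0.0, noise_sd_force=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_spec):
    return generate_sts_trial(noiseless_spec, 0, 0)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_trial, template):
    return analyze_trial(noiseless_trial, template=template,
                         config=AnalysisConfig(cutoff_hz=None))


@pytest.fixture(scope="session")
def noisy_trial(cohort_spec):
    return generate_sts_trial(cohort_spec, 1, 0)


@pytest.fixture(scope="session")
def noisy_result(noisy_trial, template):
    return analyze_trial(noisy_trial, template=template)


@pytest.fixture(scope="session")
def quiet_trials(cohort_spec):
    return [generate_quiet_standing(cohort_spec, s) for s in (0, 1)]


@pytest.fixture(scope="session")
def quiet_results(quiet_trials, template):
    return [analyze_trial(q, template=template) for q in quiet_trials]


@pytest.fixture(scope="session")
def excursion_profiles():
    trial = generate_cop_excursion_trial(seed=7)
    pre = preprocess(trial, cutoff_hz=10.0)
    return trial, extract_cop_profiles(pre)


def random_segments(rng, n):
    """Random physically-plausible segment states (single sample)."""
    from stsbalance.kinematics import SegmentState

    segs = []
    for _ in range(n):
        a = rng.normal(size=(3, 3))
        J = a @ a.T + 0.1 * np.eye(3)  # SPD
        segs.append(SegmentState(
            m=rng.uniform(1.0, 20.0),
            r=rng.normal(size=3),
            v=rng.normal(size=3),
            J=J,
            w=rng.normal(size=3),
        ))
    return segs
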