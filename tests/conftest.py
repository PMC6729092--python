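import pytest

from itug.pipeline import PipelineConfig, run_pipeline
from itug.synthetic import SyntheticCohortSpec, control_profile, pd_profile, simulate_trial


@pytest.fixture(scope="session")
def control_trial():
    """One control-like TUG trial with its ground-truth segmentation."""
    return simulate_trial(control_profile(subject_id="C0"), trial_index=2, seed=42)


@pytest.fixture(scope="session")
def pd_trial():
    """One PD/FOG-like TUG trial with its ground-truth segmentation."""
    return simulate_trial(pd_profile(0.7, subject_id="P0"), trial_index=2, seed=43)


@pytest.fixture(scope="session")
def cohort_report(tmp_path_factory):
    """Full pipeline run on the default synthetic cohort (31 PD, 6 controls).

    Session scoped: several statistical and direction checks share it.
    """
    out = tmp_path_factory.mktemp("cohort")
    cfg = PipelineConfig(
        synthetic=SyntheticCohortSpec(seed=1), seed=1, out_dir=out, log_level="WARNING"
    )
    return run_pipeline(cfg)
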