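import pytest

from prca_panel import PipelineConfig, Thresholds, load_paper_fixtures
from prca_panel.pipeline import run_on_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def pipeline_result(fixture_cohort):
    return run_on_cohort(fixture_cohort, PipelineConfig())


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()
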