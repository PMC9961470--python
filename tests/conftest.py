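import pytest

from ctga.pipeline import run_synthetic_pipeline
from ctga.synthetic_data import SyntheticParams, generate


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """One generated study under default conditions, shared by the suite."""
    outdir = tmp_path_factory.mktemp("study")
    return generate(SyntheticParams(seed=20230216), outdir)


@pytest.fixture(scope="session")
def pipeline_result(default_study):
    """Full pipeline run (place -> integrate -> compose) on the study."""
    return run_synthetic_pipeline(default_study)
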