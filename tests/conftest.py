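import pytest

from combopd.reference import interaction_params, pd_system
from combopd.synthesize import NoiseModel, default_design, generate_static, generate_timecourse

NOISE_FREE = NoiseModel(cv_proportional=0.0, sd_additive=0.0, seed=0)


@pytest.fixture(scope="session")
def noise_free_static():
    """cell_line -> noise-free static endpoint dataset from reference parameters."""
    def _make(cell_line: str):
        design = default_design(cell_line)
        return generate_static(design, interaction_params(cell_line), NOISE_FREE)

    return {cl: _make(cl) for cl in ("Huh7", "MDA-MB-468")}


@pytest.fixture(scope="session")
def noise_free_timecourse():
    """cell_line -> noise-free 0-96 h time-course dataset from reference parameters."""
    def _make(cell_line: str):
        design = default_design(cell_line)
        return generate_timecourse(design, pd_system(cell_line), NOISE_FREE)

    return {cl: _make(cl) for cl in ("Huh7", "MDA-MB-468")}
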