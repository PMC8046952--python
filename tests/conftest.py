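import pytest
from hypothesis import HealthCheck, settings

from wbconform.synthdata import CohortConfig, render_silhouette, sample_cohort

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def cohort():
    """Default-calibration synthetic cohort, fixed seed."""
    return sample_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def rendered():
    """A typical rendered silhouette (6-wk female proportions)."""
    return render_silhouette(20.3, 14.4, 9.2, bulge_frac=0.33, cm_per_px=0.05)
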