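import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sctbias import datasets  # noqa: E402


@pytest.fixture(scope="session")
def reference_trials():
    """The 16 bundled published studies, keyed by trial id."""
    return {t.trial_id: t for t in datasets.load_trials()}


@pytest.fixture(scope="session")
def reference_scts():
    """SCT arm-summary pairs for replay of the bundled studies."""
    return datasets.load_sct_summaries()


@pytest.fixture(scope="session")
def reference_table():
    return datasets.load_trials_table()
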