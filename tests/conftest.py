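import pytest

from oamlseq.filter_engine import FilterConfig, run_filter_cascade
from oamlseq.synthetic_cohort import toy_bundle


@pytest.fixture(scope="session")
def toy():
    """The 10-patient toy bundle: 4 designed survivors, 6 designed rejects."""
    return toy_bundle()


@pytest.fixture(scope="session")
def toy_decisions(toy):
    return run_filter_cascade(toy.variants, toy.panel, toy.snp_db, FilterConfig())
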