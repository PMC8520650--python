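import pytest
from hypothesis import HealthCheck, settings

import phosflow as pf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DEFAULT_SEED = 11
NULL_SEED = 12
FIXTURE_MIN_OCCURRENCES = 10  # desk-scale motif support floor


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions with planted fold changes, motifs and
    kinase activity shifts."""
    return pf.generate_dataset(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_results(default_dataset):
    ds = default_dataset
    return pf.analyze(
        ds.psms,
        ds.design,
        ds.proteome,
        annotations=ds.annotations,
        links=ds.links,
        family_patterns=ds.family_patterns,
        motif_min_occurrences=FIXTURE_MIN_OCCURRENCES,
    )


@pytest.fixture(scope="session")
def null_dataset():
    """No-effect fixture: 5,000 phospho-PSMs, one per site, one experiment."""
    return pf.generate_dataset(pf.null_config(), seed=NULL_SEED)


@pytest.fixture(scope="session")
def null_results(null_dataset):
    ds = null_dataset
    return pf.analyze(
        ds.psms,
        ds.design,
        ds.proteome,
        case_label="s1",
        motif_min_occurrences=FIXTURE_MIN_OCCURRENCES,
    )


@pytest.fixture()
def tiny_proteome():
    return {
        "KIN1": "MRASPEKKRRASLDEQSPRKTYAAAKSPLL",
        "SUB1": "AAAAAAASPAAAAAAKRRASAAAAAAAAAA",
    }
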