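import pytest

from nucleoclass.evaluation import loocv
from nucleoclass.io import load_cohort_dir
from nucleoclass.simulate import default_spec, generate_cohort


@pytest.fixture(scope="session")
def cohort_factory(tmp_path_factory):
    """Generate-and-load a synthetic cohort once per (preset, seed)."""
    cache = {}

    def make(preset: str = "high", seed: int = 42):
        key = (preset, seed)
        if key not in cache:
            out = tmp_path_factory.mktemp(f"cohort_{preset}_{seed}")
            generate_cohort(default_spec(preset, seed), out)
            cache[key] = load_cohort_dir(out)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def high_cohort(cohort_factory):
    return cohort_factory("high", 42)


@pytest.fixture(scope="session")
def medium_cohort(cohort_factory):
    return cohort_factory("medium", 42)


@pytest.fixture(scope="session")
def low_cohort(cohort_factory):
    return cohort_factory("low", 42)


@pytest.fixture(scope="session")
def loocv_cache(high_cohort, medium_cohort, low_cohort):
    """LOOCV predictions + report per preset, computed once per session."""
    cache = {}
    for name, (records, bundle, corpus) in (
        ("high", high_cohort),
        ("medium", medium_cohort),
        ("low", low_cohort),
    ):
        predictions, report = loocv(corpus, bundle)
        cache[name] = (predictions, report, corpus.labels)
    return cache
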