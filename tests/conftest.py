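import pytest

from faerspv import (DrugDictionary, SynthConfig, builtin_hierarchy,
                     deduplicate, extract_cases, generate, read_quarter)
from faerspv.synth_faers import TARGET, TARGET_SYNONYMS

SMALL_SEED = 7
SMALL_N = 3000


@pytest.fixture(scope="session")
def target_dictionary() -> DrugDictionary:
    return DrugDictionary(
        canonical_name="BENDAMUSTINE",
        synonyms=TARGET_SYNONYMS,
        match_mode="substring",
    )


@pytest.fixture(scope="session")
def hierarchy():
    return builtin_hierarchy()


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A 3,000-report, two-quarter corpus with one planted association and a
    high duplicate rate, used across the IO / cohort / mapping tests."""
    return SynthConfig(
        seed=SMALL_SEED,
        n_reports=SMALL_N,
        n_quarters=2,
        duplicate_fraction=0.2,
        target_share=0.10,  # enlarged cohort so per-SOC fits have data
        injected_pairs=((TARGET, "Pyrexia", 5.0),),
    )


@pytest.fixture(scope="session")
def small_corpus(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth_small")
    quarter_paths, manifest = generate(small_config, outdir)
    return dict(paths=quarter_paths, manifest=manifest, config=small_config,
                outdir=outdir)


@pytest.fixture(scope="session")
def small_quarters(small_corpus):
    return [read_quarter(p) for p in small_corpus["paths"]]


@pytest.fixture(scope="session")
def small_dedup(small_quarters):
    return deduplicate(small_quarters)


@pytest.fixture(scope="session")
def small_caseset(small_dedup, target_dictionary):
    return extract_cases(small_dedup.cases, target_dictionary, "PS")
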