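"""Shared fixtures: a scaled-down synthetic study with 3 clades x 4 families."""

import pytest

from phylochem import core_filter, ingest
from phylochem.synth import SynthConfig, generate_occurrences

#: Scaled study design used across the suite: same 3x4 clade/family layout,
#: smaller species pools so every stage runs in seconds.
SMALL_SPECIES = (30, 25, 12, 18, 20, 10, 22, 19, 60, 15, 40, 35)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        species_per_family=SMALL_SPECIES,
        n_background_compounds=40,
        core_compounds_per_family=30,
        singletons_per_family=15,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    occ, truth = generate_occurrences(small_config)
    return occ, truth


@pytest.fixture(scope="session")
def small_core(small_dataset):
    occ, truth = small_dataset
    core, report = core_filter.build_core(ingest.derive_elemental(occ))
    return core, report, truth
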