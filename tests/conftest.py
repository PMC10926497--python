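"""Shared fixtures: the simulated nine-population study set (noise 0) and
its derived alignment/consensus/diversity layers, computed once per session
because the progressive alignments dominate runtime."""

import pytest

import mitomarkers as mm


@pytest.fixture(scope="session")
def study0():
    """(PopulationSet, TruthRecord) for the default nine-population
    configuration at substitution-noise 0."""
    config = mm.study_config(1, noise_rate=0.0)
    pop_set, truth = mm.simulate_populations(config)
    return config, pop_set, truth


@pytest.fixture(scope="session")
def diversity0(study0):
    """Full diversity report (per-population MSAs, consensuses, pi values,
    similarity) for the noise-0 study set."""
    _, pop_set, _ = study0
    return mm.diversity_report(pop_set, mm.STUDY_REGIONS)


@pytest.fixture(scope="session")
def enzyme_library():
    return mm.default_enzyme_library()
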