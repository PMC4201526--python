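"""Shared fixtures: a small deterministic synthetic study reused across tests."""

from __future__ import annotations

import pytest

from evmir import simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=7,
        n_precursors=24,
        n_chromosomes=3,
        cluster_spec=[("chr1", 4, 800), ("chr2", 3, 2_000)],
        family_spec=[("fam-alpha", 3), ("fam-beta", 2)],
        n_reads_per_library=4_000,
        n_enriched_per_category=1,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.generate_reference(small_config)


@pytest.fixture(scope="session")
def small_truth(small_bundle, small_config):
    base = simulate.default_base_profile(small_bundle, small_config)
    assignment = simulate.default_venn_assignment(small_bundle, small_config)
    _, truth = simulate.make_enrichment_scenario(
        small_bundle, base, assignment, small_config.effect_log2,
        small_config.library_names,
    )
    return truth


@pytest.fixture(scope="session")
def small_study(small_config):
    """(bundle, truth, libraries) for the small configuration."""
    return simulate.simulate_study(small_config)
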