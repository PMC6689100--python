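"""Shared fixtures: small seeded synthetic bundles."""

from __future__ import annotations

import pytest

from riskloci.simulate import SimulationConfig, make_bundle


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A scaled-down cohort that keeps every planted structure present."""
    defaults = dict(
        seed=seed,
        n_samples=40,
        n_loci=8,
        n_background_blocks=4,
        n_background_snps=200,
        genome_length=2_000_000,
        haplotypes_per_block=200,
        n_strong_active_loci=5,
        n_weak_active_loci=2,
        planted_qtl_counts={
            "accessibility": 3,
            "h3k27ac": 2,
            "methylation": 4,
            "expression": 3,
        },
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return make_bundle(small_config())


@pytest.fixture(scope="session")
def study_bundle():
    """Full-size synthetic study (42 loci, 99 samples)."""
    return make_bundle(SimulationConfig(seed=11))
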