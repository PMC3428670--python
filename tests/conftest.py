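from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from wfinder.read_align import features_frame, map_reads_unique_detailed
from wfinder.reference_prep import prep_reference
from wfinder.synthetic_data import (
    GenomeSpec,
    simulate_genome,
    simulate_male_reads_detailed,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def run_experiment(spec: GenomeSpec) -> SimpleNamespace:
    """Simulate, prep, map and featurize one synthetic experiment."""
    genome, truth = simulate_genome(spec)
    prepped, funnel = prep_reference(genome)
    reads, provenance = simulate_male_reads_detailed(genome, truth, spec)
    placements, summary = map_reads_unique_detailed(reads, prepped)
    features = features_frame(prepped, placements, spec.read_len)
    return SimpleNamespace(
        spec=spec, genome=genome, truth=truth, prepped=prepped, funnel=funnel,
        reads=reads, provenance=provenance, placements=placements,
        mapping_summary=summary, features=features,
    )


@pytest.fixture(scope="session")
def small_sim() -> SimpleNamespace:
    """A clean, scaled-down ZW/ZZ experiment for module-level tests."""
    spec = GenomeSpec(
        n_w=12, n_z=12, n_autosome=56,
        w_len_range=(800, 2500), z_len_range=(800, 2500),
        autosome_len_range=(800, 2500), seed=11,
    )
    return run_experiment(spec)


@pytest.fixture(scope="session")
def anomaly_sim() -> SimpleNamespace:
    """An experiment with planted gametologs and male-specific deletions."""
    spec = GenomeSpec(
        n_w=15, n_z=15, n_autosome=60,
        w_len_range=(1000, 3000), z_len_range=(1000, 3000),
        autosome_len_range=(1000, 3000),
        n_gametolog_pairs=5, gametolog_len=400,
        n_male_deletions=3, seed=101,
    )
    return run_experiment(spec)
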