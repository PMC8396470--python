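import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bulkmap import CrossConfig, assign_bulks, build_variant_table, simulate_cross

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> CrossConfig:
    """A fast, miniature cross: one 600 kb chromosome, two genes."""
    base = dict(
        n_chromosomes=1, chrom_length_bp=600_000, genes_per_chromosome=2,
        n_marker_snps=40, n_induced_mutations=8, n_artifact_sites=4,
        causal_chrom_index=0, causal_gene_index=0,
        f2_size=120, bulk_size=12, seed=7,
    )
    base.update(overrides)
    return CrossConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    sim = simulate_cross(small_config())
    return sim


@pytest.fixture(scope="session")
def small_run():
    """Simulation + bulks + depth table for the miniature cross."""
    sim = simulate_cross(small_config(seed=11))
    bulks = assign_bulks(sim.f2, sim.config)
    table = build_variant_table(sim, bulks)
    return sim, bulks, table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
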