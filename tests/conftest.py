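import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from metabogwas.simulate import (  # noqa: E402
    SimulationConfig,
    simulate_population,
    simulate_metabolome,
    simulate_expression,
)


def small_config(seed: int = 1, **kw) -> SimulationConfig:
    """A desk-scale cohort: 100 accessions, 1200 SNPs on 8 x 3-Mb chromosomes."""
    base = dict(
        seed=seed,
        n_samples={"W": 25, "L": 30, "EI": 25, "WI": 20},
        n_chrom=8,
        chrom_length_bp=3_000_000,
        n_snps=1200,
        n_metabolites=40,
        n_mqtl=5,
        mqtl_pve=0.3,
        h2_target=0.5,
        n_genes=120,
        n_cis_genes=15,
        trans_hotspot_size=15,
        n_modules=2,
        module_size=35,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    g = simulate_population(cfg)
    met1, met2, truth_m = simulate_metabolome(g, cfg)
    expr, truth_e = simulate_expression(g, cfg)
    return dict(cfg=cfg, g=g, met1=met1, met2=met2, truth_m=truth_m,
                expr=expr, truth_e=truth_e)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
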