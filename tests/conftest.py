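import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nodulewaves import (
    build_ratio_matrix,
    normalize_arrays,
    select_invariant_genes,
    simulate_timecourse,
)
from nodulewaves.de import assign_stages, pairwise_stage_tests, select_de_genes
from nodulewaves.synthetic import GeneratorConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> GeneratorConfig:
    """Down-scaled study conditions for fast unit tests: 300 genes, 80
    differential (10 per profile), 150 invariant, 2 arrays per time point."""
    defaults = dict(n_genes=300, n_de=80, n_invariant=150, arrays_per_timepoint=2,
                    arrays_per_genotype=2, n_common=10, seed=0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_timecourse(small_cfg):
    tables, truth = simulate_timecourse(small_cfg, seed=11)
    return tables, truth


@pytest.fixture(scope="session")
def small_expr(small_cfg, small_timecourse):
    tables, truth = small_timecourse
    raw = build_ratio_matrix(tables.values())
    invariant = select_invariant_genes(raw, small_cfg.anchor_id, small_cfg.n_invariant)
    return normalize_arrays(raw, invariant)


@pytest.fixture(scope="session")
def small_de(small_expr):
    groups = assign_stages(small_expr.metadata)
    res = pairwise_stage_tests(small_expr, groups, alpha=0.01)
    return groups, res, select_de_genes(res)
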