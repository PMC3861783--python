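import numpy as np
import pytest

from seqdesign import disease_models as dm
from seqdesign import hapsim


@pytest.fixture(scope="session")
def small_pop():
    """A modest constant-size haplotype pool shared across tests."""
    return hapsim.simulate_population(
        "constant", n_hap=400, region_length_bp=50_000, seed=7,
        Ne=10_000, mutation_rate=5e-8,
    )


@pytest.fixture(scope="session")
def effect_model(small_pop):
    cfg = dm.EffectConfig(pi0=0.3, q0=0.01, rr_cap=8.0)
    return dm.assign_variant_effects(small_pop, cfg, seed=11)


@pytest.fixture(scope="session")
def null_model(small_pop):
    cfg = dm.EffectConfig(pi0=0.0)
    return dm.assign_variant_effects(small_pop, cfg, seed=12)


@pytest.fixture(scope="session")
def intercept(small_pop, effect_model):
    return dm.calibrate_intercept(small_pop, effect_model, 0.05, seed=13)


@pytest.fixture(scope="session")
def cohort(small_pop, effect_model, intercept):
    return dm.simulate_case_control_cohort(
        small_pop, effect_model, n_case=400, n_control=400, intercept=intercept,
        seed=17,
    )
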