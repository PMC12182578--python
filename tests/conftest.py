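"""Shared synthetic worlds for the test suite.

`small_world` is a 120x120, 24-township landscape for unit and oracle
tests; `study` is the full default-scale (400x400, 200-township) landscape
with models fitted under the production protocol, shared session-wide so
the expensive tuning runs once.
"""

import warnings

import numpy as np
import pytest

from dasypop import (
    LandscapeConfig,
    compute_mask,
    derive_a60_64,
    generate_landscape,
    generate_true_population,
    run_group_mappings,
    tabulate_census,
)
from dasypop.age_structure import age_proportion_grids, sum_age_groups
from dasypop.validation import fit_all_groups

SMALL_SEED = 11
STUDY_SEED = 42
SPLIT_SEED = 101
MODEL_SEED = 202


def _build_world(cfg):
    stack, zones = generate_landscape(cfg)
    truth = generate_true_population(stack, cfg)
    census = derive_a60_64(tabulate_census(truth, zones, "township"))
    mask = compute_mask(stack)
    return {"config": cfg, "stack": stack, "zones": zones, "truth": truth,
            "census": census, "mask": mask}


@pytest.fixture(scope="session")
def small_world():
    cfg = LandscapeConfig(n_rows=120, n_cols=120, n_cities=2,
                          counties_per_city=3, townships_per_county=4,
                          urban_core_count=2, seed=SMALL_SEED)
    return _build_world(cfg)


@pytest.fixture(scope="session")
def study():
    """Default-scale landscape, production-protocol fit, full mapping."""
    world = _build_world(LandscapeConfig(seed=STUDY_SEED))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models, table, train, test = fit_all_groups(
            world["census"], world["stack"], world["mask"], world["zones"],
            split_seed=SPLIT_SEED, model_seed=MODEL_SEED)
    pop = run_group_mappings(world["census"], models, world["stack"],
                             world["mask"], world["zones"])
    world.update(models=models, table=table, train=train, test=test,
                 pop=pop, total_sum=sum_age_groups(pop),
                 props=age_proportion_grids(pop))
    return world


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
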