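"""Shared fixtures: small synthetic landscapes and the multi-seed recovery
runs reused by several performance tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from snakerisk import (EnsembleSDM, define_virtual_species, generate_landscape,
                       sample_presences)

#: Study conditions for the recovery experiment: 200x200 grid, the
#: seven-layer stack, a species driven by two variables (one dominant) with
#: a sharp response and moderate prevalence (~0.28), 100 presence records,
#: 10,000 background points, 80/20 split.
RECOVERY_COEFFICIENTS = {"bio15": 4.0, "bio4": 2.0}
RECOVERY_INTERCEPT = -3.0
RECOVERY_STRONGEST = "bio15"
RECOVERY_N_PRESENCE = 100
RECOVERY_N_BACKGROUND = 10_000
RECOVERY_GRID = 200
RECOVERY_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def small_stack():
    return generate_landscape(60, 60, seed=11)


@pytest.fixture(scope="session")
def small_species(small_stack):
    return define_virtual_species(small_stack, RECOVERY_COEFFICIENTS,
                                  RECOVERY_INTERCEPT, "sp_small")


def _recovery_run(seed: int) -> dict:
    stack = generate_landscape(RECOVERY_GRID, RECOVERY_GRID, seed=seed)
    vs = define_virtual_species(stack, RECOVERY_COEFFICIENTS,
                                RECOVERY_INTERCEPT, "sp_rec")
    occ = sample_presences(vs, RECOVERY_N_PRESENCE, seed=seed + 1000,
                           transform=stack.transform)
    model = EnsembleSDM.from_points(stack, occ,
                                    n_background=RECOVERY_N_BACKGROUND,
                                    seed=seed + 2000)
    results = model.fit(seed=seed + 3000)
    ens = results.ensemble_surface(stack)
    m = ~stack.nodata_mask
    rho = float(spearmanr(ens.grid[m], vs.true_suitability[m]).statistic)
    return {
        "seed": seed,
        "rho": rho,
        "top_variable": results.importance.top_variable(),
        "auc": {meth: results.evaluations[meth].auc
                for meth in results.models},
        "evaluations": {meth: results.evaluations[meth]
                        for meth in results.evaluations},
    }


@pytest.fixture(scope="session")
def recovery_runs():
    """Ten independent recovery experiments under the default conditions.

    Expensive (fits all five learners per seed); shared across every test
    that judges ensemble recovery or per-method performance.
    """
    return [_recovery_run(seed) for seed in RECOVERY_SEEDS]
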