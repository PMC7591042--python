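import numpy as np
import pytest
from hypothesis import settings

import prlflex as pf

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return pf.build_schedule(seed=1)


@pytest.fixture(scope="session")
def cu_cohort(schedule):
    """15 counterfactual-update agents near the TD-children regime."""
    spec = pf.GroupSpec(
        "TD", "children", "CU",
        {"eta": 0.193, "beta": 1.202, "alpha": -0.042},
        {"eta": 0.087, "beta": 0.892, "alpha": 0.153},
        15,
    )
    return pf.generate_cohort([spec], schedule, seed=42)


@pytest.fixture(scope="session")
def quick_mcmc():
    return pf.MCMCConfig(chains=2, draws=250, warmup=300, thin=1, seed=7,
                         check_convergence=False)


@pytest.fixture(scope="session")
def cu_fit(cu_cohort, quick_mcmc):
    cohort, _ = cu_cohort
    return pf.fit_group(cohort, "CU", quick_mcmc)


@pytest.fixture()
def random_subjects(schedule):
    """Mixed-model random subjects for likelihood cross-checks."""
    def make(n_per_model=3, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for model in pf.MODEL_IDS:
            for i in range(n_per_model):
                params = _random_params(model, rng)
                out.append(
                    (
                        pf.simulate_agent(model, params, schedule, seed=int(rng.integers(2**31))),
                        model,
                        params,
                    )
                )
        return out

    return make


def _random_params(model_id, rng):
    params = {}
    for name in pf.MODEL_PARAMS[model_id]:
        lo, hi = pf.PARAM_BOUNDS[name]
        params[name] = float(rng.uniform(lo + 0.01, hi - 0.01))
    return params
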