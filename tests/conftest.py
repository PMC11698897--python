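import numpy as np
import pytest

import hetdyn as hd


@pytest.fixture
def two_type_matrix():
    """The 2-type chain with rates 2 (1->0) and 1 (0->1); pi = [2/3, 1/3]."""
    return np.array([[-1.0, 2.0], [1.0, -2.0]])


@pytest.fixture
def logistic_unit():
    return hd.make_growth_law("logistic", {"K": 1.0, "gamma": 1.0})


@pytest.fixture
def two_type_config(logistic_unit, two_type_matrix):
    return hd.ModelConfig(
        law=logistic_unit,
        schedule=hd.make_rate_schedule({"kind": "constant", "r": [1.0, 1.0]}),
        A=two_type_matrix,
        x0=np.array([0.2, 0.1]),
        t_span=(0.0, 30.0),
    )


def law_for(seed: int, family: str) -> hd.GrowthLaw:
    """Seeded random positive parameters for a registry family."""
    rng = np.random.default_rng(seed)
    gamma = 10.0 ** rng.uniform(np.log10(0.5), np.log10(2.0))
    if family in ("logistic", "gompertz"):
        return hd.make_growth_law(family, {"K": 10.0 ** rng.uniform(0, 2), "gamma": gamma})
    w = 10.0 ** rng.uniform(np.log10(0.5), np.log10(2.0))
    n_star = 10.0 ** rng.uniform(0, 2)
    return hd.make_growth_law(family, {"v": w * n_star**gamma, "w": w, "gamma": gamma})
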