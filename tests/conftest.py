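import numpy as np
import pytest

from wormsight.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """12 plain synthetic worms at working resolution."""
    return generate_dataset(12, GeneratorConfig(), master_seed=11)


@pytest.fixture(scope="session")
def planted_cohort():
    """Posterior-planted cohort (effect 0.3) used by the localization tests."""
    return generate_dataset(
        60, GeneratorConfig(planted_part="posterior", effect_size=0.3),
        master_seed=21)


def num_grad(f, x, eps=1e-5):
    """Central finite differences of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        lp = f()
        x[i] = old - eps
        lm = f()
        x[i] = old
        g[i] = (lp - lm) / (2 * eps)
    return g
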