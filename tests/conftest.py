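import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, loci):
    """Random GP map and strictly positive genotype frequencies."""
    n = 3**loci
    return rng.normal(size=n), rng.dirichlet(np.ones(n))


def le_tensor_oracle(G, pa, pb):
    """Classical two-locus orthogonal decomposition at LE/HWE frequencies.

    Built independently of the regression chain: per-locus orthogonal
    contrasts (constant, centred allele count, Gram-Schmidt dominance
    contrast) under the marginal Hardy-Weinberg weights, combined by
    products into the nine-function tensor basis; component values are the
    weighted Fourier coefficients times the basis functions.
    """
    G = np.asarray(G, dtype=float)
    wa = np.array([pa**2, 2 * pa * (1 - pa), (1 - pa) ** 2])
    wb = np.array([pb**2, 2 * pb * (1 - pb), (1 - pb) ** 2])

    def contrasts(w):
        x = np.array([0.0, 1.0, 2.0])
        h = np.array([0.0, 1.0, 0.0])
        ua = x - w @ x
        ud = h - w @ h - (w @ (h * ua)) / (w @ (ua * ua)) * ua
        return [np.ones(3), ua, ud]

    BA, BB = contrasts(wa), contrasts(wb)
    W = np.outer(wb, wa).ravel()  # canonical order: locus A fastest
    comp = {}
    for r in range(3):
        for s in range(3):
            psi = np.array([BA[r][a] * BB[s][b] for b in range(3) for a in range(3)])
            comp[(r, s)] = (W @ (G * psi)) / (W @ (psi * psi)) * psi
    return {
        "mu": comp[(0, 0)][0],
        "A": comp[(1, 0)] + comp[(0, 1)],
        "D": comp[(2, 0)] + comp[(0, 2)],
        "AA": comp[(1, 1)],
        "DA": comp[(2, 1)],  # dominance at locus A, additive at locus B
        "AD": comp[(1, 2)],
        "DD": comp[(2, 2)],
        "weights": W,
    }
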