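import numpy as np
import pytest

from prsmatch.panel import SnpDefinition, build_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """Two unambiguous SNPs with hand-checkable normalized triples."""
    return build_panel(
        [
            SnpDefinition("rs1", "A", "C", per_allele_or=1.2, raf=0.3),
            SnpDefinition("rs2", "G", "T", per_allele_or=1.1, raf=0.5),
        ]
    )


def simulate_conditional_sets(rng, n_sets, set_size, beta, n_cov=1):
    """Matched sets drawn exactly from the conditional-logit model.

    Covariates are standard normal; within each set the case slot is drawn
    with probability proportional to exp(x . beta) — the conditional
    likelihood itself, so fitted coefficients target ``beta`` exactly.
    Returns (X, is_case, set_id) with X of shape (n_sets*set_size, n_cov).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = rng.normal(size=(n_sets, set_size, n_cov))
    eta = X @ beta
    w = np.exp(eta - eta.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    u = rng.uniform(size=(n_sets, 1))
    case_slot = (u > cum).sum(axis=1)
    is_case = np.zeros((n_sets, set_size), dtype=bool)
    is_case[np.arange(n_sets), case_slot] = True
    set_id = np.repeat(np.arange(n_sets), set_size)
    return X.reshape(-1, beta.size), is_case.ravel(), set_id
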