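import numpy as np
import pytest

import factormet as fm
from factormet.ebmf import backfit, fit_greedy
from factormet.simulate import SimConfig


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: 335 lines, 2000 markers, 8 factors."""
    return fm.simulate_all(seed=3)


@pytest.fixture(scope="session")
def factor_model(bundle):
    """Greedy + backfit EBMF of the default bundle's metabolome."""
    Y = bundle.metabolome.values
    model = fit_greedy(Y, family="point-laplace", max_factors=12, tol=1e-5)
    return backfit(model, Y, max_sweeps=8, tol=1e-5)


@pytest.fixture(scope="session")
def small_geno():
    """Small unstructured panel for regression-model tests."""
    cfg = SimConfig(n_lines=300, n_markers=600, n_subpops=1,
                    fst_divergence=0.0, ld_block_size=3, seed=17)
    geno, labels, blocks = fm.simulate.simulate_genotypes(cfg)
    return geno, labels, blocks


def match_factors(truth_loadings, fitted_loadings):
    """Hungarian matching of fitted factors to truth by |correlation|."""
    from scipy.optimize import linear_sum_assignment
    K_t = truth_loadings.shape[0]
    K_f = fitted_loadings.shape[0]
    C = np.zeros((K_t, K_f))
    for i in range(K_t):
        for j in range(K_f):
            C[i, j] = abs(np.corrcoef(truth_loadings[i], fitted_loadings[j])[0, 1])
    rows, cols = linear_sum_assignment(-C)
    return rows, cols, C[rows, cols]
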