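"""Mixed-model scan, GRM construction, Meff/Sidak correction, R2 of hits."""

import numpy as np
import pytest
from scipy import stats

from factormet.gwas import (
    grm,
    grm_pcs,
    meff,
    r2_gwas,
    reml_null,
    scan,
    sidak_threshold,
)
from factormet.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(n_lines=335, n_markers=2000, n_subpops=6,
                    fst_divergence=0.05, ld_block_size=1, seed=13)
    geno, labels, _ = simulate_genotypes(cfg)
    G = grm(geno, "vanraden-2")
    return geno, G, grm_pcs(G, 2)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_two_line_hand_example():
    """Dosages (0, 2) at one marker: p=0.5, denominator 2p(1-p)=0.5."""
    G = grm(np.array([[0.0], [2.0]]), "vanraden-1")
    np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])


def test_grm_duplicated_line_gives_identical_rows():
    rng = np.random.default_rng(0)
    W = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
    W[3] = W[7]
    for method in ("vanraden-1", "vanraden-2"):
        G = grm(W, method)
        np.testing.assert_allclose(G[3], G[7])
        np.testing.assert_allclose(G, G.T)


def test_grm_methods_agree_for_equal_allele_frequencies():
    """When every marker has the same p, the per-marker scaling of method 2
    equals the pooled scaling of method 1."""
    rng = np.random.default_rng(1)
    base = rng.binomial(2, 0.5, size=20).astype(float)
    # permuted copies of one marker: identical frequencies
    W = np.column_stack([rng.permutation(base) for _ in range(30)])
    G1 = grm(W, "vanraden-1")
    G2 = grm(W, "vanraden-2")
    np.testing.assert_allclose(G1, G2, atol=1e-10)


def test_grm_is_psd_with_sane_diagonal(panel):
    _, G, _ = panel
    vals = np.linalg.eigvalsh(G)
    assert vals.min() > -1e-8
    assert 0.8 < np.diag(G).mean() < 1.5


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def test_reml_null_noise_trait_has_low_h2(panel):
    geno, G, pcs = panel
    rng = np.random.default_rng(2)
    fit = reml_null(rng.normal(size=335), pcs, G)
    assert fit.h2 < 0.15


def test_reml_recovers_planted_heritability(panel):
    geno, G, pcs = panel
    rng = np.random.default_rng(3)
    L = np.linalg.cholesky(G + 1e-8 * np.eye(335))
    g = L @ rng.normal(size=335)
    g /= g.std()
    y = np.sqrt(0.6) * g + np.sqrt(0.4) * rng.normal(size=335)
    fit = reml_null(y, pcs, G)
    assert 0.45 <= fit.h2 <= 0.75


def test_reml_identity_kinship_degenerates_with_warning():
    rng = np.random.default_rng(4)
    y = rng.normal(size=50)
    with pytest.warns(UserWarning, match="identity"):
        fit = reml_null(y, None, np.eye(50))
    assert fit.degenerate
    assert fit.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=0.05)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def test_scan_pvalues_match_explicit_gls_oracle():
    """Brute-force GLS with the explicit covariance inverse, 50 x 100."""
    rng = np.random.default_rng(3)
    W = rng.binomial(2, rng.uniform(0.2, 0.8, 100), size=(50, 100)).astype(float)
    G = grm(W, "vanraden-1") + 1e-3 * np.eye(50)
    y = rng.normal(size=50)
    pcs = grm_pcs(G, 2)
    null = reml_null(y, pcs, G)
    res = scan(y, W, pcs, G, null)
    V = null.sigma2_u * G + null.sigma2_e * np.eye(50)
    Vi = np.linalg.inv(V)
    X0 = np.column_stack([np.ones(50), pcs])
    for j in range(100):
        X = np.column_stack([X0, W[:, j]])
        XtVi = X.T @ Vi
        A = XtVi @ X
        beta = np.linalg.solve(A, XtVi @ y)
        r = y - X @ beta
        df = 50 - X0.shape[1] - 1
        s2 = (r @ Vi @ r) / df
        se = np.sqrt(s2 * np.linalg.inv(A)[-1, -1])
        p = 2 * stats.t.sf(abs(beta[-1] / se), df)
        assert abs(p - res.p[j]) < 1e-8


def test_scan_planted_qtl_is_top_association(panel):
    geno, G, pcs = panel
    rng = np.random.default_rng(13)
    W = geno.dosages
    Wc = W - W.mean(axis=0)
    q = 777
    gq = Wc[:, q] / Wc[:, q].std()
    bg = Wc @ rng.normal(size=2000)
    bg /= bg.std()
    y = (np.sqrt(0.10) * gq + np.sqrt(0.30) * bg
         + np.sqrt(0.60) * rng.normal(size=335))
    res = scan(y, geno, pcs, G)
    top = int(np.argmin(res.p))
    r2_proxy = np.corrcoef(W[:, top], W[:, q])[0, 1] ** 2
    assert top == q or r2_proxy > 0.8


def test_scan_null_type1_error_calibrated(panel):
    geno, G, pcs = panel
    rng = np.random.default_rng(14)
    y = rng.normal(size=335)
    res = scan(y, geno, pcs, G)
    frac = (res.p < 0.05).mean()
    ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
    assert abs(frac - 0.05) < ci + 0.005


def test_scan_duplicated_marker_gives_identical_pvalues(panel):
    geno, G, pcs = panel
    rng = np.random.default_rng(15)
    W = geno.dosages.copy()
    W[:, 1] = W[:, 0]
    y = rng.normal(size=335)
    res = scan(y, W, pcs, G)
    assert res.p[0] == pytest.approx(res.p[1])


def test_scan_marker_collinear_with_fixed_effects_flagged():
    rng = np.random.default_rng(16)
    W = rng.binomial(2, 0.5, size=(60, 5)).astype(float)
    W[:, 2] = 1.0  # constant marker = collinear with the intercept
    G = grm(W[:, [0, 1, 3, 4]], "vanraden-1") + 1e-3 * np.eye(60)
    res = scan(rng.normal(size=60), W, None, G)
    assert res.collinear[2]
    assert res.p[2] == 1.0


# ---------------------------------------------------------------------------
# Meff and Sidak
# ---------------------------------------------------------------------------

def test_meff_equals_m_for_exactly_orthogonal_markers():
    """Fourier columns are exactly orthogonal and zero-mean, so the
    correlation matrix is the identity and Meff = M."""
    n, M = 128, 20
    t = np.arange(n)
    W = np.column_stack([np.cos(2 * np.pi * (k + 1) * t / n)
                         for k in range(M)])
    assert meff(W) == pytest.approx(M, abs=1e-6)


def test_meff_identical_markers_collapse_to_one():
    base = np.random.default_rng(5).binomial(2, 0.5, size=100).astype(float)
    W = np.column_stack([base] * 10)
    assert meff(W) == pytest.approx(1.0, abs=1e-6)


def test_meff_block_ld_between_block_count_and_marker_count():
    cfg = SimConfig(n_lines=300, n_markers=500, n_subpops=1,
                    fst_divergence=0.0, ld_block_size=5, seed=6)
    geno, _, blocks = simulate_genotypes(cfg)
    m_eff = meff(geno)
    assert blocks.max() + 1 < m_eff < 500


def test_meff_invariant_to_marker_order():
    rng = np.random.default_rng(7)
    W = rng.binomial(2, 0.4, size=(80, 40)).astype(float)
    perm = rng.permutation(40)
    assert meff(W) == pytest.approx(meff(W[:, perm]), abs=1e-8)


def test_meff_windowed_variant_close_to_exact():
    rng = np.random.default_rng(8)
    W = rng.binomial(2, 0.4, size=(100, 60)).astype(float)
    exact = meff(W)
    windowed = meff(W, window=20)
    assert windowed >= exact - 1e-8  # windows ignore between-window correlation
    assert windowed <= 60


def test_sidak_threshold_reference_value():
    """alpha_e=0.1, Meff=4097, 100 factors -> 2.57e-7 to 3 significant digits."""
    val = sidak_threshold(0.1, 4097, 100)
    assert val == pytest.approx(2.57e-7, rel=5e-3)


def test_sidak_threshold_identity_and_closed_form():
    assert sidak_threshold(0.05, 1, 1) == pytest.approx(0.05)
    # high-precision evaluation: 1 - 0.95^(1/100)
    assert sidak_threshold(0.05, 100, 1) == pytest.approx(5.129e-4, rel=1e-3)


def test_sidak_threshold_input_validation():
    with pytest.raises(ValueError):
        sidak_threshold(0.0, 10, 1)
    with pytest.raises(ValueError):
        sidak_threshold(0.05, 0.5, 1)


# ---------------------------------------------------------------------------
# R2 of significant hits
# ---------------------------------------------------------------------------

def test_r2_gwas_empty_hit_set_is_zero(panel):
    geno, G, _ = panel
    rng = np.random.default_rng(9)
    r2, diff = r2_gwas(rng.normal(size=335), None, grm_pcs(G, 10))
    assert r2 == 0.0 and diff == 0.0


def test_r2_gwas_fully_determining_marker_near_one():
    rng = np.random.default_rng(10)
    w = rng.binomial(2, 0.5, size=200).astype(float)
    y = w * 2.0 + rng.normal(scale=1e-3, size=200)
    pcs10 = rng.normal(size=(200, 10))  # no PC signal
    r2, _ = r2_gwas(y, w, pcs10)
    assert r2 > 0.99


def test_r2_gwas_planted_ten_percent_qtl(panel):
    geno, G, pcs = panel
    rng = np.random.default_rng(11)
    Wc = geno.dosages - geno.dosages.mean(axis=0)
    q = 55
    gq = Wc[:, q] / Wc[:, q].std()
    y = np.sqrt(0.10) * gq + np.sqrt(0.90) * rng.normal(size=335)
    r2, _ = r2_gwas(y, geno.dosages[:, [q]], grm_pcs(G, 10))
    assert 0.03 <= r2 <= 0.2


def test_r2_gwas_too_many_predictors_rejected():
    rng = np.random.default_rng(12)
    with pytest.raises(ValueError):
        r2_gwas(rng.normal(size=20), rng.normal(size=(20, 15)),
                rng.normal(size=(20, 10)))
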