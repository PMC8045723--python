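"""Mixed-model GWAS on factor scores with Meff/Sidak multiple-testing control.

The association model per marker i is

    y = X b + w_i a_i + Z u + e ,    u ~ N(0, G sigma2_u),  e ~ N(0, I sigma2_e)

with y a factor score, X an intercept plus the first two principal
components of the genomic relationship matrix G, and u a polygenic effect.
Variance components are estimated once under the no-marker null (REML via
the spectral decomposition of G) and held fixed for every marker test —
the "population parameters previously determined" approximation — so each
marker reduces to generalized least squares on decorrelated data.

Multiple testing across markers and factors uses the Li–Ji effective
number of tests from the marker correlation eigenvalues and the Sidak
correction  alpha_p = 1 - (1 - alpha_e)^(1 / (Meff * n_factors)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from factormet.io import GenotypeMatrix

log = logging.getLogger("factormet")


# ---------------------------------------------------------------------------
# genomic relationship matrices
# ---------------------------------------------------------------------------

def grm(geno: GenotypeMatrix | np.ndarray, method: str = "vanraden-2") -> np.ndarray:
    """Genomic relationship matrix from allele dosages.

    ``vanraden-1``: ZZ' / (2 * sum p(1-p)) with Z the centered dosages.
    ``vanraden-2``: average over markers of z_i z_i' / (2 p_i (1 - p_i));
    monomorphic markers are excluded (their scaling is undefined).
    """
    W = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    p = W.mean(axis=0) / 2.0
    Z = W - 2.0 * p
    het = 2.0 * p * (1.0 - p)
    if method == "vanraden-1":
        denom = het.sum()
        if denom == 0:
            raise ValueError("all markers monomorphic")
        return Z @ Z.T / denom
    if method == "vanraden-2":
        keep = het > 0
        if not np.any(keep):
            raise ValueError("all markers monomorphic")
        Zk = Z[:, keep] / np.sqrt(het[keep])
        return Zk @ Zk.T / keep.sum()
    raise ValueError(f"unknown GRM method {method!r}")


def grm_pcs(G: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading eigenvectors of the GRM (principal components of relatedness)."""
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:n_pcs]]


# ---------------------------------------------------------------------------
# REML under the null
# ---------------------------------------------------------------------------

@dataclass
class NullFit:
    sigma2_u: float
    sigma2_e: float
    h2: float
    gamma: float               # sigma2_u / sigma2_e
    eigvals: np.ndarray        # of G
    eigvecs: np.ndarray
    X: np.ndarray              # fixed design (intercept + PCs)
    degenerate: bool = False


def reml_null(y: np.ndarray, pcs: np.ndarray | None, G: np.ndarray) -> NullFit:
    """REML variance components of ``y = Xb + u + e`` by spectral decomposition.

    One eigendecomposition of G and a one-dimensional optimization of the
    variance ratio gamma = sigma2_u / sigma2_e.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs])
    d, U = np.linalg.eigh(G)
    if d.min() < -1e-8:
        warnings.warn("G is not PSD; flooring negative eigenvalues at 0")
    d = np.maximum(d, 0.0)
    if np.allclose(d, d[0]):
        warnings.warn("G is (a multiple of) the identity: sigma2_u and "
                      "sigma2_e are not separately identifiable; returning "
                      "total variance")
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        tot = float(resid @ resid / max(n - X.shape[1], 1))
        return NullFit(sigma2_u=0.0, sigma2_e=tot, h2=0.0, gamma=0.0,
                       eigvals=d, eigvecs=U, X=X, degenerate=True)
    yt = U.T @ y
    Xt = U.T @ X
    c = X.shape[1]

    def neg_restricted_ll(log_gamma):
        g = np.exp(log_gamma)
        v = g * d + 1.0
        iv = 1.0 / v
        XtV = Xt * iv[:, None]
        XX = Xt.T @ XtV
        beta = np.linalg.solve(XX, XtV.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (iv * r))
        sigma2 = rss / (n - c)
        _, logdet_xx = np.linalg.slogdet(XX)
        return 0.5 * ((n - c) * np.log(sigma2) + np.log(v).sum() + logdet_xx
                      + (n - c))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    gamma = float(np.exp(res.x))
    v = gamma * d + 1.0
    iv = 1.0 / v
    XtV = Xt * iv[:, None]
    beta = np.linalg.solve(Xt.T @ XtV, XtV.T @ yt)
    r = yt - Xt @ beta
    sigma2_e = float(r @ (iv * r)) / (n - c)
    sigma2_u = gamma * sigma2_e
    return NullFit(sigma2_u=sigma2_u, sigma2_e=sigma2_e,
                   h2=sigma2_u / (sigma2_u + sigma2_e), gamma=gamma,
                   eigvals=d, eigvecs=U, X=X)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

@dataclass
class GwasResult:
    markers: list
    effect: np.ndarray
    se: np.ndarray
    p: np.ndarray
    collinear: np.ndarray
    null: NullFit
    meff: float | None = None
    alpha_p: float | None = None
    r2_gwas: float | None = None

    def significant(self, alpha_p: float) -> np.ndarray:
        return np.flatnonzero(self.p < alpha_p)


def scan(y: np.ndarray, geno: GenotypeMatrix | np.ndarray,
         pcs: np.ndarray | None, G: np.ndarray,
         null: NullFit | None = None) -> GwasResult:
    """Per-marker mixed-model association with variance components fixed
    at their null REML estimates.

    Each marker is tested by generalized least squares on data
    decorrelated through the spectral transform of V = gamma G + I;
    two-sided p-values come from the t distribution with
    n - rank(X) - 1 degrees of freedom.  Markers collinear with the fixed
    effects get p = 1 and a flag.
    """
    W = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    markers = list(geno.markers) if isinstance(geno, GenotypeMatrix) else \
        [f"m{j}" for j in range(W.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if null is None:
        null = reml_null(y, pcs, G)
    d, U, X = null.eigvals, null.eigvecs, null.X
    trans = (1.0 / np.sqrt(null.gamma * d + 1.0))[:, None] * U.T
    yt = trans @ y
    Xt = trans @ X
    Wt = trans @ W
    # project out the fixed effects
    Q, _ = np.linalg.qr(Xt)
    yp = yt - Q @ (Q.T @ yt)
    Wp = Wt - Q @ (Q.T @ Wt)
    ww = (Wp * Wp).sum(axis=0)
    n, c = y.size, X.shape[1]
    df = n - c - 1
    collinear = ww <= 1e-10 * (Wt * Wt).sum(axis=0).clip(min=1e-30)
    ww_safe = np.where(collinear, 1.0, ww)
    beta = (Wp.T @ yp) / ww_safe
    rss = (yp @ yp) - beta ** 2 * ww_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(np.maximum(sigma2 / ww_safe, 1e-300))
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(collinear, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    beta = np.where(collinear, 0.0, beta)
    return GwasResult(markers=markers, effect=beta, se=se, p=p,
                      collinear=collinear, null=null)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def _liji_meff(corr_eigvals: np.ndarray) -> float:
    lam = np.maximum(corr_eigvals, 0.0)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def meff(geno: GenotypeMatrix | np.ndarray, window: int = 5000) -> float:
    """Li–Ji effective number of independent tests.

    ``Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]``
    over the eigenvalues of the marker correlation matrix.  Constant
    markers are excluded.  For panels larger than ``window`` markers the
    eigendecomposition is done in non-overlapping windows and summed
    (the exact method is O(M^3)).
    """
    W = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    sd = W.std(axis=0)
    W = W[:, sd > 0]
    m = W.shape[1]
    if m < 2:
        raise ValueError("need at least 2 polymorphic markers")
    if m <= window:
        C = np.corrcoef(W, rowvar=False)
        return _liji_meff(np.linalg.eigvalsh(C))
    total = 0.0
    for start in range(0, m, window):
        block = W[:, start:start + window]
        if block.shape[1] == 1:
            total += 1.0
            continue
        C = np.corrcoef(block, rowvar=False)
        total += _liji_meff(np.linalg.eigvalsh(C))
    return total


def sidak_threshold(alpha_e: float, meff_value: float, n_factors: int) -> float:
    """Per-test threshold  alpha_p = 1 - (1 - alpha_e)^(1/(Meff * n_factors))."""
    if not (0.0 < alpha_e < 1.0):
        raise ValueError("alpha_e must lie in (0, 1)")
    if meff_value < 1 or n_factors < 1:
        raise ValueError("Meff and n_factors must be >= 1")
    return float(-np.expm1(np.log1p(-alpha_e) / (meff_value * n_factors)))


# ---------------------------------------------------------------------------
# variance explained by the hits
# ---------------------------------------------------------------------------

def r2_gwas(y: np.ndarray, W_significant: np.ndarray | None,
            pcs10: np.ndarray) -> tuple[float, float]:
    """Variance explained by significant markers beyond population structure.

    Full model: significant markers + first 10 GRM principal components;
    reduced model: the PCs only; both ordinary least squares with all
    terms fixed.  Returns ``(rss_reduced - rss_full) / rss_reduced`` (a
    proportion) and the unscaled RSS difference.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Xr = np.column_stack([np.ones(n), pcs10])
    if W_significant is None or W_significant.size == 0:
        return 0.0, 0.0
    W_significant = np.atleast_2d(np.asarray(W_significant, dtype=float))
    if W_significant.shape[0] != n:
        W_significant = W_significant.T
    Xf = np.column_stack([Xr, W_significant])
    if Xf.shape[1] >= n:
        raise ValueError("more predictors than observations in the full model")
    rss_r = float(np.sum((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2))
    rss_f = float(np.sum((y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]) ** 2))
    if rss_r == 0:
        return 0.0, 0.0
    return (rss_r - rss_f) / rss_r, rss_r - rss_f
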