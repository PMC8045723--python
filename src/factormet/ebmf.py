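"""Empirical Bayes matrix factorization (EBMF) of a standardized metabolome.

Model: ``Y = F Gamma + s`` for a centered and standardized n x p matrix Y,
with n x K factor scores F, K x p sparse loadings Gamma, and column-specific
Gaussian noise ``s_ij ~ N(0, psi_j)``.  The observed covariance decomposes
as ``V = Gamma' Gamma + Psi`` with diagonal Psi.  Both the scores and the
loadings of each factor receive a spike-and-slab prior whose point-mass
weight and slab scale are learned from the data by the EBNM solver
(:mod:`factormet.ebnm`); the fitted loading point-mass ``v`` gives the
factor "density" ``1 - v``.

Fitting combines a greedy search (add factors one at a time, each
initialized from the leading singular pair of the running residual) with
backfitting (cyclic refits of each factor against the residual of the
others).  Convergence is monitored through a variational lower bound on
the marginal likelihood; the bound is non-decreasing over backfit sweeps.

Missing cells are supported through an observation mask (zero weight in
every sum; Psi is updated from observed cells only), which is what the
threefold orthogonal cross-validation (:func:`orthogonal_cv`) uses for
model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from factormet.ebnm import EBNMFit, ebnm_solve, ebnm_expected_loglik

_LOG_2PI = np.log(2.0 * np.pi)
_PSI_FLOOR = 1e-8


class FactorDead(Exception):
    """Raised when a rank-1 factor collapses to zero on both sides."""


@dataclass
class FactorModel:
    """Fitted EBMF model.

    ``scores`` columns are scaled to unit sample variance with the scale
    absorbed into ``loadings``; the sign of each factor is chosen so its
    largest-|loading| entry is positive, and factors are ordered by PVE.
    """

    scores: np.ndarray          # n x K posterior-mean factor scores
    loadings: np.ndarray        # K x p posterior-mean loadings
    psi: np.ndarray             # p specific variances
    loading_pi0: np.ndarray     # K fitted point-mass weights v (loading side)
    score_pi0: np.ndarray       # K fitted point-mass weights (score side)
    family: str
    objective_trace: list = field(default_factory=list)
    # raw (unscaled) posterior moments, kept so backfitting can resume
    _ef: np.ndarray | None = None
    _ef2: np.ndarray | None = None
    _el: np.ndarray | None = None
    _el2: np.ndarray | None = None

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Posterior-mean fit ``F Gamma``."""
        return self.scores @ self.loadings


# ---------------------------------------------------------------------------
# rank-1 machinery
# ---------------------------------------------------------------------------

def _loading_update(RW, W, ef, ef2, psi, family, init=None):
    """EBNM collapse of the loading side: one observation per column."""
    denom = W.T @ ef2                      # sum_i w_ij E[f_i^2]
    ok = denom > 0
    x = np.zeros_like(denom)
    x[ok] = (RW.T @ ef)[ok] / denom[ok]
    se = np.full_like(denom, np.inf)
    se[ok] = np.sqrt(psi[ok] / denom[ok])
    if not np.any(ok):
        raise FactorDead("score side collapsed to zero")
    fit = ebnm_solve(x[ok], se[ok], family, init=init)
    el = np.zeros_like(x)
    el2 = np.zeros_like(x)
    el[ok] = fit.posterior_mean
    el2[ok] = fit.posterior_mean2
    return el, el2, fit, x[ok], se[ok]


def _score_update(RW, W, el, el2, psi, family, init=None):
    """EBNM collapse of the score side: one observation per row."""
    inv_psi = 1.0 / psi
    denom = W @ (el2 * inv_psi)            # sum_j w_ij E[l_j^2]/psi_j
    ok = denom > 0
    x = np.zeros_like(denom)
    x[ok] = (RW @ (el * inv_psi))[ok] / denom[ok]
    se = np.full_like(denom, np.inf)
    se[ok] = 1.0 / np.sqrt(denom[ok])
    if not np.any(ok):
        raise FactorDead("loading side collapsed to zero")
    fit = ebnm_solve(x[ok], se[ok], family, init=init)
    ef = np.zeros_like(x)
    ef2 = np.zeros_like(x)
    ef[ok] = fit.posterior_mean
    ef2[ok] = fit.posterior_mean2
    return ef, ef2, fit, x[ok], se[ok]


@dataclass
class Rank1Result:
    scores: np.ndarray
    scores2: np.ndarray
    loadings: np.ndarray
    loadings2: np.ndarray
    loading_fit: EBNMFit | None
    score_fit: EBNMFit | None
    dead: bool


def rank1_update(
    residual: np.ndarray,
    scores: np.ndarray,
    loadings: np.ndarray,
    psi: np.ndarray,
    family: str = "point-laplace",
    mask: np.ndarray | None = None,
    scores2: np.ndarray | None = None,
) -> Rank1Result:
    """One coordinate-ascent sweep of a single factor.

    ``residual`` is the data matrix with every *other* factor's fit
    removed.  The loading side is refit first (given the current score
    moments), then the score side.  A factor whose posterior means vanish
    on either side is flagged dead.
    """
    if np.any(psi <= 0):
        raise ValueError("psi must be strictly positive")
    W = np.ones_like(residual) if mask is None else mask.astype(float)
    RW = residual * W
    ef = np.asarray(scores, dtype=float)
    ef2 = ef * ef if scores2 is None else np.asarray(scores2, dtype=float)
    if not np.any(ef2 > 0):
        return Rank1Result(ef, ef2, np.zeros(residual.shape[1]),
                           np.zeros(residual.shape[1]), None, None, dead=True)
    el, el2, lfit, _, _ = _loading_update(RW, W, ef, ef2, psi, family)
    if not np.any(el2 > 0):
        return Rank1Result(ef, ef2, el, el2, lfit, None, dead=True)
    ef, ef2, sfit, _, _ = _score_update(RW, W, el, el2, psi, family)
    dead = not np.any(ef2 > 0)
    return Rank1Result(ef, ef2, el, el2, lfit, sfit, dead=dead)


# ---------------------------------------------------------------------------
# internal multi-factor state
# ---------------------------------------------------------------------------

class _State:
    def __init__(self, Y, mask, family):
        self.Y = np.asarray(Y, dtype=float)
        self.W = np.ones_like(self.Y) if mask is None else mask.astype(float)
        self.YW = self.Y * self.W
        self.n_obs_col = self.W.sum(axis=0)
        self.family = family
        self.ef, self.ef2, self.el, self.el2 = [], [], [], []
        self.lfits, self.sfits = [], []
        self.lx, self.lse, self.sx, self.sse = [], [], [], []
        self.psi = self._psi_from_resid()

    @property
    def K(self):
        return len(self.ef)

    def fitted(self):
        if self.K == 0:
            return np.zeros_like(self.Y)
        F = np.column_stack(self.ef)
        L = np.column_stack(self.el)
        return F @ L.T

    def residual(self, exclude=None):
        R = self.YW - self.fitted() * self.W
        if exclude is not None:
            R += np.outer(self.ef[exclude], self.el[exclude]) * self.W
        return R

    def _expected_sq_resid(self):
        R = self.YW - self.fitted() * self.W
        ER2 = R * R
        for k in range(self.K):
            var_term = (np.outer(self.ef2[k], self.el2[k])
                        - np.outer(self.ef[k] ** 2, self.el[k] ** 2))
            ER2 += var_term * self.W
        return ER2

    def _psi_from_resid(self):
        ER2 = self._expected_sq_resid() if hasattr(self, "ef") and self.K else (self.YW * self.YW)
        n = np.maximum(self.n_obs_col, 1.0)
        return np.maximum(ER2.sum(axis=0) / n, _PSI_FLOOR)

    def update_psi(self):
        ER2 = self._expected_sq_resid()
        n = np.maximum(self.n_obs_col, 1.0)
        self.psi = np.maximum(ER2.sum(axis=0) / n, _PSI_FLOOR)

    def elbo(self):
        """Variational lower bound on the marginal log-likelihood."""
        ER2 = self._expected_sq_resid()
        ll = float(np.sum(self.W * (-0.5 * (_LOG_2PI + np.log(self.psi))[None, :]))
                   - np.sum(ER2 / (2.0 * self.psi)[None, :]))
        for k in range(self.K):
            ll += self.lfits[k].loglik - ebnm_expected_loglik(
                self.lfits[k], self.lx[k], self.lse[k])
            ll += self.sfits[k].loglik - ebnm_expected_loglik(
                self.sfits[k], self.sx[k], self.sse[k])
        return ll

    def refit_factor(self, k):
        """One rank-1 sweep of factor k against the residual of the others."""
        RW = self.residual(exclude=k)
        linit = ((self.lfits[k].pi0, self.lfits[k].scale)
                 if self.lfits[k] is not None else None)
        sinit = ((self.sfits[k].pi0, self.sfits[k].scale)
                 if self.sfits[k] is not None else None)
        el, el2, lfit, lx, lse = _loading_update(
            RW, self.W, self.ef[k], self.ef2[k], self.psi, self.family, init=linit)
        if not np.any(el2 > 0):
            raise FactorDead(f"factor {k} loadings collapsed")
        ef, ef2, sfit, sx, sse = _score_update(
            RW, self.W, el, el2, self.psi, self.family, init=sinit)
        if not np.any(ef2 > 0):
            raise FactorDead(f"factor {k} scores collapsed")
        self.ef[k], self.ef2[k] = ef, ef2
        self.el[k], self.el2[k] = el, el2
        self.lfits[k], self.sfits[k] = lfit, sfit
        self.lx[k], self.lse[k] = lx, lse
        self.sx[k], self.sse[k] = sx, sse

    def drop_factor(self, k):
        for attr in ("ef", "ef2", "el", "el2", "lfits", "sfits",
                     "lx", "lse", "sx", "sse"):
            getattr(self, attr).pop(k)

    def add_factor_init(self, ef, el):
        self.ef.append(ef)
        self.ef2.append(ef * ef)
        self.el.append(el)
        self.el2.append(el * el)
        self.lfits.append(None)
        self.sfits.append(None)
        self.lx.append(None)
        self.lse.append(None)
        self.sx.append(None)
        self.sse.append(None)


def _leading_singular_pair(R):
    """Deterministic leading singular pair of the (zero-filled) residual."""
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    s = np.sqrt(S[0])
    return U[:, 0] * s, Vt[0] * s


def _finalize(state: _State, trace) -> FactorModel:
    n = state.Y.shape[0]
    K = state.K
    if K == 0:
        return FactorModel(
            scores=np.zeros((n, 0)), loadings=np.zeros((0, state.Y.shape[1])),
            psi=state.psi.copy(), loading_pi0=np.zeros(0), score_pi0=np.zeros(0),
            family=state.family, objective_trace=list(trace),
            _ef=np.zeros((n, 0)), _ef2=np.zeros((n, 0)),
            _el=np.zeros((0, state.Y.shape[1])), _el2=np.zeros((0, state.Y.shape[1])))
    F = np.column_stack(state.ef)
    L = np.column_stack(state.el).T        # K x p
    lpi0 = np.array([f.pi0 for f in state.lfits])
    spi0 = np.array([f.pi0 for f in state.sfits])
    # unit-variance scores, scale absorbed into loadings
    sd = F.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Fs = F / sd
    Ls = L * sd[:, None]
    # sign: largest-|loading| entry positive
    for k in range(K):
        j = np.argmax(np.abs(Ls[k]))
        if Ls[k, j] < 0:
            Ls[k] *= -1.0
            Fs[:, k] *= -1.0
    # order by PVE
    ss = (Ls * Ls).sum(axis=1)
    order = np.argsort(-ss)
    model = FactorModel(
        scores=Fs[:, order], loadings=Ls[order], psi=state.psi.copy(),
        loading_pi0=lpi0[order], score_pi0=spi0[order], family=state.family,
        objective_trace=list(trace),
        _ef=F[:, order], _ef2=np.column_stack(state.ef2)[:, order],
        _el=L[order], _el2=np.column_stack(state.el2).T[order])
    return model


def _state_from_model(model: FactorModel, Y, mask) -> _State:
    state = _State(Y, mask, model.family)
    for k in range(model.n_factors):
        state.add_factor_init(model._ef[:, k].copy(), model._el[k].copy())
        state.ef2[k] = model._ef2[:, k].copy()
        state.el2[k] = model._el2[k].copy()
    state.psi = model.psi.copy()
    # refresh EBNM fits so the objective is well defined; factors that die
    # during the refresh are dropped
    k = 0
    while k < state.K:
        try:
            state.refit_factor(k)
        except FactorDead:
            state.drop_factor(k)
            continue
        k += 1
    state.update_psi()
    return state


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_greedy(
    Y: np.ndarray,
    family: str = "point-laplace",
    max_factors: int = 20,
    tol: float = 1e-6,
    mask: np.ndarray | None = None,
    max_inner: int = 200,
) -> FactorModel:
    """Greedy EBMF: add factors one at a time until one dies.

    Each new factor is initialized from the leading singular pair of the
    running residual and iterated to convergence (relative objective
    change below ``tol``); the greedy search stops at the first factor
    whose loadings or scores collapse to zero, or at ``max_factors``.
    """
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    state = _State(Y, mask, family)
    trace = []
    for _ in range(max_factors):
        R = state.residual()
        ef, el = _leading_singular_pair(R)
        state.add_factor_init(ef, el)
        k = state.K - 1
        last = None
        died = False
        for _ in range(max_inner):
            try:
                state.refit_factor(k)
            except FactorDead:
                died = True
                break
            state.update_psi()
            obj = state.elbo()
            if last is not None and abs(obj - last) <= tol * (1.0 + abs(obj)):
                last = obj
                break
            last = obj
        if died:
            state.drop_factor(k)
            state.update_psi()
        if not died:
            # nullcheck: keep the factor only if the bound beats the model
            # with the factor removed (and Psi refit) — kills factors that
            # merely absorb sampling noise
            elbo_with = state.elbo()
            snapshot = (state.ef[k], state.ef2[k], state.el[k], state.el2[k],
                        state.lfits[k], state.sfits[k], state.lx[k],
                        state.lse[k], state.sx[k], state.sse[k],
                        state.psi.copy())
            state.drop_factor(k)
            state.update_psi()
            if state.elbo() >= elbo_with - 1e-9:
                died = True
            else:
                (ef_s, ef2_s, el_s, el2_s, lf, sf, lx, lse, sx, sse, psi_s) = snapshot
                state.add_factor_init(ef_s, el_s)
                state.ef2[k], state.el2[k] = ef2_s, el2_s
                state.lfits[k], state.sfits[k] = lf, sf
                state.lx[k], state.lse[k] = lx, lse
                state.sx[k], state.sse[k] = sx, sse
                state.psi = psi_s
        if died:
            break
        trace.append(last)
    return _finalize(state, trace)


def backfit(
    model: FactorModel,
    Y: np.ndarray,
    max_sweeps: int = 30,
    tol: float = 1e-6,
    mask: np.ndarray | None = None,
) -> FactorModel:
    """Cyclic refits of every factor against the residual of the others.

    The variational objective is non-decreasing over sweeps; factors that
    die during a sweep are removed.
    """
    if model.n_factors == 0:
        return model
    state = _state_from_model(model, Y, mask)
    trace = list(model.objective_trace)
    last = state.elbo()
    trace.append(last)
    for _ in range(max_sweeps):
        k = 0
        while k < state.K:
            try:
                state.refit_factor(k)
            except FactorDead:
                state.drop_factor(k)
                continue
            k += 1
        state.update_psi()
        if state.K == 0:
            break
        obj = state.elbo()
        trace.append(obj)
        if abs(obj - last) <= tol * (1.0 + abs(obj)):
            break
        last = obj
    return _finalize(state, trace)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def pve(model: FactorModel) -> tuple[float, np.ndarray]:
    """Percent variance explained, total and per factor.

    ``PVE = 100 * tr(Gamma' Gamma) / tr(Gamma' Gamma + Psi)``; each
    factor's share uses its own loading row in the numerator over the
    same denominator, so per-factor PVEs sum to the total.
    """
    if model.n_factors == 0:
        return 0.0, np.zeros(0)
    ss = (model.loadings * model.loadings).sum(axis=1)
    denom = ss.sum() + model.psi.sum()
    if denom == 0:
        return 0.0, np.zeros(model.n_factors)
    per = 100.0 * ss / denom
    return float(per.sum()), per


def factor_density(model: FactorModel) -> np.ndarray:
    """Per-factor loading density ``1 - v`` (v = fitted point-mass weight)."""
    return 1.0 - model.loading_pi0


# ---------------------------------------------------------------------------
# orthogonal (speckled) cross-validation
# ---------------------------------------------------------------------------

def ocv_masks(n: int, p: int, folds: int, rng: np.random.Generator):
    """Speckled fold masks: rows and columns are each partitioned into
    ``folds`` groups; fold t's test cells are the (row-group, col-group)
    blocks with ``(g_r + g_c) mod folds == t``.  Every row and column keeps
    exactly ``(folds-1)/folds`` of its cells in training, and the folds'
    test sets partition all cells.

    Returns a list of boolean test masks (True = held out).
    """
    row_groups = rng.permuted(np.arange(n) % folds)
    col_groups = rng.permuted(np.arange(p) % folds)
    total = (row_groups[:, None] + col_groups[None, :]) % folds
    return [total == t for t in range(folds)]


def orthogonal_cv(
    Y: np.ndarray,
    family: str = "point-laplace",
    folds: int = 3,
    repeats: int = 10,
    max_factors: int = 20,
    tol: float = 1e-5,
    backfit_sweeps: int = 10,
    seed: int = 0,
):
    """Orthogonal cross-validation of the EBMF model.

    For each fold the model is fit with the fold's test cells masked and
    the held-out cells are predicted by ``F Gamma``.  RMSE and Pearson r
    are averaged over folds; the distribution over ``repeats`` independent
    row/column partitions is returned.

    Returns a dict with per-repeat arrays ``rmse`` and ``cor`` plus their
    means.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds or p < folds:
        raise ValueError("Y must have at least `folds` rows and columns")
    rng = np.random.default_rng(seed)
    rmses, cors = [], []
    for _ in range(repeats):
        masks = ocv_masks(n, p, folds, rng)
        fold_rmse, fold_cor = [], []
        for test in masks:
            train_mask = ~test
            model = fit_greedy(Y, family=family, max_factors=max_factors,
                               tol=tol, mask=train_mask)
            if backfit_sweeps > 0:
                model = backfit(model, Y, max_sweeps=backfit_sweeps,
                                tol=tol, mask=train_mask)
            pred = model.reconstruct()[test]
            obs = Y[test]
            fold_rmse.append(float(np.sqrt(np.mean((pred - obs) ** 2))))
            if np.std(pred) > 0 and np.std(obs) > 0:
                fold_cor.append(float(stats.pearsonr(obs, pred)[0]))
            else:
                fold_cor.append(0.0)
        rmses.append(np.mean(fold_rmse))
        cors.append(np.mean(fold_cor))
    rmses = np.asarray(rmses)
    cors = np.asarray(cors)
    return {"rmse": rmses, "cor": cors,
            "rmse_mean": float(rmses.mean()), "cor_mean": float(cors.mean())}
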