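"""Empirical Bayes normal means (EBNM) with spike-and-slab priors.

The EBNM problem: given observations ``x_i = theta_i + N(0, s_i^2)`` with
known standard errors ``s_i``, estimate by maximum marginal likelihood a
shared prior

    theta ~ pi0 * delta_0 + (1 - pi0) * slab(scale)

where the slab is either a zero-mean normal ("point-normal") or a zero-mean
Laplace ("point-laplace"), then return the posterior mean and posterior
second moment of every ``theta_i``.  This solver is the inner engine of the
matrix factorization in :mod:`factormet.ebmf`: each rank-1 update collapses
the loading (or score) side of the model to exactly this problem.

All marginal densities are evaluated through exponentially scaled
complementary error functions so that extreme observations do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.special import log_ndtr

_SQRT_2 = np.sqrt(2.0)
_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)
_LOG_2PI = np.log(2.0 * np.pi)

FAMILIES = ("point-normal", "point-laplace")


@dataclass
class EBNMFit:
    """Result of an EBNM optimization.

    Attributes
    ----------
    family : str
        Prior family, ``"point-normal"`` or ``"point-laplace"``.
    pi0 : float
        Fitted point-mass weight at zero (the prior null probability ``v``;
        the factor "density" is ``1 - pi0``).
    scale : float
        Slab scale: variance ``tau^2`` for point-normal, rate ``b`` for
        point-laplace (density ``b/2 * exp(-b|theta|)``).
    posterior_mean : ndarray
        ``E[theta_i | x_i]`` per observation.
    posterior_mean2 : ndarray
        ``E[theta_i^2 | x_i]`` per observation.
    loglik : float
        Optimized marginal log-likelihood.
    """

    family: str
    pi0: float
    scale: float
    posterior_mean: np.ndarray
    posterior_mean2: np.ndarray
    loglik: float


# ---------------------------------------------------------------------------
# marginal log-densities of the slab convolved with Gaussian noise
# ---------------------------------------------------------------------------

def _log_norm_pdf(x, var):
    return -0.5 * (_LOG_2PI + np.log(var) + x * x / var)


def _log_erfcx(u):
    """log(erfcx(u)), valid for all real u.

    erfcx overflows for u below about -26; there ``erfcx(u) = 2 exp(u^2)
    - erfcx(-u)`` is dominated by the first term.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    lo = u < -20.0
    out[~lo] = np.log(special.erfcx(u[~lo]))
    out[lo] = u[lo] * u[lo] + np.log(2.0)
    return out


def _laplace_conv_logpdf(x, s, b):
    """log density of Laplace(b) + N(0, s^2) at x, overflow-safe.

    f(x) = (b/4) exp(-x^2 / 2s^2) [erfcx((bs + x/s)/sqrt2)
                                   + erfcx((bs - x/s)/sqrt2)]
    """
    z = x / s
    u1 = (b * s + z) / _SQRT_2
    u2 = (b * s - z) / _SQRT_2
    return (np.log(b / 4.0) - 0.5 * z * z
            + np.logaddexp(_log_erfcx(u1), _log_erfcx(u2)))


def _marginal_loglik(x, s, family, pi0, scale):
    """Sum of log[pi0 N(x;0,s^2) + (1-pi0) slab*N(x)] over observations."""
    log_null = _log_norm_pdf(x, s * s)
    if family == "point-normal":
        log_slab = _log_norm_pdf(x, s * s + scale)
    else:
        log_slab = _laplace_conv_logpdf(x, s, scale)
    # log-sum-exp of the two mixture components
    if pi0 <= 0.0:
        return float(np.sum(log_slab))
    if pi0 >= 1.0:
        return float(np.sum(log_null))
    a = np.log(pi0) + log_null
    c = np.log1p(-pi0) + log_slab
    return float(np.sum(np.logaddexp(a, c)))


# ---------------------------------------------------------------------------
# posterior moments
# ---------------------------------------------------------------------------

def _slab_weight(x, s, family, pi0, scale):
    """Posterior probability that theta_i came from the slab."""
    if pi0 <= 0.0:
        return np.ones_like(x)
    if pi0 >= 1.0:
        return np.zeros_like(x)
    log_null = _log_norm_pdf(x, s * s)
    if family == "point-normal":
        log_slab = _log_norm_pdf(x, s * s + scale)
    else:
        log_slab = _laplace_conv_logpdf(x, s, scale)
    logit = np.log1p(-pi0) - np.log(pi0) + log_slab - log_null
    return special.expit(logit)


def _normal_slab_moments(x, s, tau2):
    """Posterior mean / second moment of theta | slab for a normal slab."""
    shrink = tau2 / (tau2 + s * s)
    m = shrink * x
    v = shrink * s * s
    return m, m * m + v


def _hazard(z):
    """phi(z) / Phi(z), computed stably for very negative z."""
    return _SQRT_2_OVER_PI / special.erfcx(-z / _SQRT_2)


def _laplace_slab_moments(x, s, b):
    """Posterior mean / second moment of theta | slab for a Laplace slab.

    The posterior given the slab is a two-component mixture of normals
    N(x -+ b s^2, s^2) truncated to the positive / negative half-line.
    """
    mp = x - b * s * s  # mean of the positive-side component
    mm = x + b * s * s  # mean of the negative-side component
    zp = mp / s
    zm = mm / s
    # log relative weight of the positive component
    delta = -2.0 * b * x + log_ndtr(zp) - log_ndtr(-zm)
    wpos = special.expit(delta)
    lam_p = _hazard(zp)          # phi(zp)/Phi(zp)
    lam_m = _hazard(-zm)         # phi(zm)/Phi(-zm)
    mean_p = mp + s * lam_p
    mean_m = mm - s * lam_m
    m2_p = mp * mp + s * s + mp * s * lam_p
    m2_m = mm * mm + s * s - mm * s * lam_m
    mean = wpos * mean_p + (1.0 - wpos) * mean_m
    m2 = wpos * m2_p + (1.0 - wpos) * m2_m
    return mean, m2


def _posterior_moments(x, s, family, pi0, scale):
    w = _slab_weight(x, s, family, pi0, scale)
    if family == "point-normal":
        m, m2 = _normal_slab_moments(x, s, scale)
    else:
        m, m2 = _laplace_slab_moments(x, s, scale)
    return w * m, w * m2


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

_LOGIT_CAP = 18.0  # pi0 within [expit(-18), expit(18)] ~ [1.5e-8, 1 - 1.5e-8]


def ebnm_solve(
    observations: np.ndarray,
    standard_errors: np.ndarray | float,
    family: str = "point-laplace",
    fix_pi0: float | None = None,
    init: tuple[float, float] | None = None,
) -> EBNMFit:
    """Fit the spike-and-slab EBNM model by maximum marginal likelihood.

    Parameters
    ----------
    observations : array
        Noisy observations ``x_i``.
    standard_errors : array or float
        Known standard errors ``s_i > 0`` (broadcast if scalar).
    family : str
        ``"point-normal"`` or ``"point-laplace"``.
    fix_pi0 : float, optional
        Hold the point-mass weight fixed (e.g. 0 for a pure slab) and
        optimize only the slab scale.
    init : (pi0, scale), optional
        Warm start (e.g. the previous fit inside an iterative refit);
        added to the start set, not replacing it.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown prior family {family!r}; expected one of {FAMILIES}")
    x = np.asarray(observations, dtype=float).ravel()
    s = np.broadcast_to(np.asarray(standard_errors, dtype=float), x.shape).ravel().copy()
    if x.size == 0:
        raise ValueError("no observations")
    if np.any(s <= 0):
        if np.all(x == 0):
            raise ValueError("all-zero observations with zero standard errors")
        raise ValueError("standard errors must be strictly positive")

    # slab-scale search grid anchored on the moment of the de-noised signal
    excess = max(np.mean(x * x - s * s), 1e-8 * float(np.mean(s * s)))
    if family == "point-normal":
        scale_grid = excess * np.array([0.25, 1.0, 4.0, 16.0])
        log_scale_bounds = (np.log(excess) - 15.0, np.log(excess) + 15.0)
    else:
        # Laplace(b) has variance 2/b^2 -> moment-matched rate
        b0 = np.sqrt(2.0 / excess)
        scale_grid = b0 * np.array([0.25, 1.0, 4.0])
        log_scale_bounds = (np.log(b0) - 15.0, np.log(b0) + 15.0)

    def neg_loglik(params):
        if fix_pi0 is None:
            pi0 = special.expit(params[0])
            scale = np.exp(params[1])
        else:
            pi0 = fix_pi0
            scale = np.exp(params[0])
        return -_marginal_loglik(x, s, family, pi0, scale)

    best = None
    if fix_pi0 is None:
        if init is not None:
            # warm start from a previous fit plus one moment-matched start
            p_init = float(np.clip(init[0], 1e-6, 1.0 - 1e-6))
            starts = [np.array([special.logit(p_init), np.log(init[1])]),
                      np.array([0.0, np.log(scale_grid[1])])]
        else:
            starts = [np.array([logit_p, np.log(scale_grid[1])])
                      for logit_p in (-2.0, 2.0)]
            starts.append(np.array([0.0, np.log(scale_grid[-1])]))
        bounds = [(-_LOGIT_CAP, _LOGIT_CAP), log_scale_bounds]
    else:
        starts = [np.array([np.log(sc)]) for sc in scale_grid]
        bounds = [log_scale_bounds]

    for x0 in starts:
        res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 80})
        if best is None or res.fun < best.fun:
            best = res

    if fix_pi0 is None:
        pi0 = float(special.expit(best.x[0]))
        scale = float(np.exp(best.x[1]))
        # snap near-boundary pi0 to the boundary when it does not hurt the fit
        for cand in (0.0, 1.0):
            ll_cand = _marginal_loglik(x, s, family, cand, scale)
            if ll_cand >= -best.fun - 1e-9:
                pi0 = cand
    else:
        pi0 = float(fix_pi0)
        scale = float(np.exp(best.x[0]))

    pm, pm2 = _posterior_moments(x, s, family, pi0, scale)
    return EBNMFit(
        family=family,
        pi0=pi0,
        scale=scale,
        posterior_mean=pm,
        posterior_mean2=pm2,
        loglik=_marginal_loglik(x, s, family, pi0, scale),
    )


def ebnm_expected_loglik(fit: EBNMFit, x: np.ndarray, s: np.ndarray) -> float:
    """E_q[log N(x_i; theta_i, s_i^2)] summed over observations.

    Together with the marginal log-likelihood this gives the negative KL
    term of the variational objective: ``-KL(q || prior) + E_q log p(x|theta)
    = loglik``, so ``-KL = loglik - E_q log p(x|theta)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    s = np.broadcast_to(np.asarray(s, dtype=float), x.shape).ravel()
    quad = x * x - 2.0 * x * fit.posterior_mean + fit.posterior_mean2
    return float(np.sum(-0.5 * (_LOG_2PI + 2.0 * np.log(s)) - quad / (2.0 * s * s)))
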