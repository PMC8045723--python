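"""Bayesian whole-genome regression: Bayes C-pi, BayesB, and the
density–polygenicity analysis.

Bayes C-pi models marker effects as a mixture of a point mass at zero
(probability pi) and a Gaussian with a common variance (probability
1 - pi); pi itself gets a uniform prior and is sampled, so the posterior
mean of 1 - pi estimates the trait's polygenicity.  BayesB replaces the
common slab variance with per-marker variances drawn from a scaled
inverse-chi-square (marginally, scaled-t effects) and puts a beta prior
on pi.

Priors: the residual and effect variances get weakly informative scaled
inverse-chi-square priors (5 df) with scales matched to an even split of
the phenotypic variance between genetics and noise; these hyperparameters
are exposed.  Chains default to a desk-scale 20,000 iterations with half
discarded; longer chains are a flag away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from factormet._gibbs import spike_slab_gibbs
from factormet.io import GenotypeMatrix


@dataclass
class WgrFit:
    """Posterior summaries of a spike-and-slab whole-genome regression."""

    model: str                      # "bayes-cpi" | "bayes-b"
    effect: np.ndarray              # posterior-mean marker effects
    include_prob: np.ndarray        # posterior inclusion probability per marker
    pi: float                       # posterior mean P(zero effect)
    polygenicity: float             # posterior mean 1 - pi
    h2: float                       # posterior mean genomic heritability
    sigma2_e: float
    sigma2_a: float
    mu: float
    genomic_value: np.ndarray       # posterior-mean W a per line
    iterations: int
    burn_in: int
    thin: int
    seed: int


def _prepare(y, geno, prior_genetic_share=0.5, nu=5.0):
    W = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    W = W - W.mean(axis=0)
    y = np.asarray(y, dtype=float).ravel()
    vy = float(np.var(y))
    vy = vy if vy > 0 else 1.0
    msx = float((W * W).mean(axis=0).sum())  # sum of marker variances
    # match the effect-variance prior scale so that, at the initial pi=0.5,
    # the expected genetic variance is prior_genetic_share * var(y)
    Sa = prior_genetic_share * vy / max(0.5 * msx, 1e-12)
    Se = (1.0 - prior_genetic_share) * vy
    return W, y, Sa, Se, nu


def bayes_cpi(
    y: np.ndarray,
    geno: GenotypeMatrix | np.ndarray,
    iterations: int = 20000,
    burn_in: int = 10000,
    thin: int = 10,
    seed: int = 0,
) -> WgrFit:
    """Bayes C-pi on line-level phenotypes (e.g. factor scores).

    Gibbs sweep: intercept; per marker, inclusion from its conditional
    odds then the effect from its Gaussian conditional; the common effect
    variance (scaled inverse-chi-square conjugate); pi from
    Beta(#excluded + 1, #included + 1); the residual variance.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    W, y, Sa, Se, nu = _prepare(y, geno)
    n = W.shape[0]
    if y.size != n:
        raise ValueError("y length does not match the number of lines")
    out = spike_slab_gibbs(
        W, y, np.arange(n, dtype=np.int64), np.zeros(n, dtype=np.int64), 0,
        iterations, burn_in, thin, 0,
        nu, Sa, nu, Se, nu, 0.25 * max(np.var(y), 1e-12),
        1.0, 1.0, seed)
    (eff, inc, pi, poly, h2, se2, sa2, mu, g) = out
    return WgrFit("bayes-cpi", eff, inc, float(pi), float(poly), float(h2),
                  float(se2), float(sa2), float(mu), g,
                  iterations, burn_in, thin, seed)


def bayes_b(
    y: np.ndarray,
    geno: GenotypeMatrix | np.ndarray,
    line_of: np.ndarray | None = None,
    trial_of: np.ndarray | None = None,
    iterations: int = 20000,
    burn_in: int = 5000,
    thin: int = 10,
    seed: int = 0,
    pi0: float = 0.5,
    pi_concentration: float = 2.0,
) -> WgrFit:
    """BayesB with optional random trial effects.

    ``y`` may hold multi-trial records; ``line_of`` maps records to rows
    of the marker matrix and ``trial_of`` to trial indices (both default
    to one record per line, no trials).  Marker effects are marginally
    scaled-t; pi has a Beta(pi0*c, (1-pi0)*c) prior.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    W, y, Sa, Se, nu = _prepare(y, geno)
    n = W.shape[0]
    if line_of is None:
        if y.size != n:
            raise ValueError("y length does not match the number of lines "
                             "(pass line_of for record-level data)")
        line_of = np.arange(n, dtype=np.int64)
    else:
        line_of = np.asarray(line_of, dtype=np.int64)
    if trial_of is None:
        trial_of = np.zeros(y.size, dtype=np.int64)
        n_trials = 0
    else:
        trial_of = np.asarray(trial_of, dtype=np.int64)
        n_trials = int(trial_of.max()) + 1
    out = spike_slab_gibbs(
        W, y, line_of, trial_of, n_trials,
        iterations, burn_in, thin, 1,
        nu, Sa, nu, Se, nu, 0.25 * max(np.var(y), 1e-12),
        pi0 * pi_concentration, (1.0 - pi0) * pi_concentration, seed)
    (eff, inc, pi, poly, h2, se2, sa2, mu, g) = out
    return WgrFit("bayes-b", eff, inc, float(pi), float(poly), float(h2),
                  float(se2), float(sa2), float(mu), g,
                  iterations, burn_in, thin, seed)


def polygenicity_summary(
    fits: dict[int, WgrFit] | list[WgrFit],
    densities: np.ndarray,
    h2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-factor architecture table: polygenicity (1 - pi), loading
    density (1 - v), and genomic heritability, with the partial Spearman
    correlation of polygenicity vs density controlling for h2 attached as
    ``DataFrame.attrs['partial_spearman']`` when there are enough factors.
    """
    if isinstance(fits, dict):
        keys = sorted(fits)
        fit_list = [fits[k] for k in keys]
    else:
        keys = list(range(len(fits)))
        fit_list = list(fits)
    densities = np.asarray(densities, dtype=float)
    if len(fit_list) != densities.size:
        raise ValueError("one fit per factor is required")
    h2_vals = (np.array([f.h2 for f in fit_list], dtype=float)
               if h2 is None else np.asarray(h2, dtype=float))
    table = pd.DataFrame({
        "factor": keys,
        "polygenicity": [f.polygenicity for f in fit_list],
        "density": densities,
        "h2": h2_vals,
    })
    if len(fit_list) >= 5:
        rho, p = partial_spearman(table["polygenicity"].to_numpy(),
                                  table["density"].to_numpy(),
                                  table["h2"].to_numpy())
        table.attrs["partial_spearman"] = {"rho": rho, "p": p}
    return table


def partial_spearman(x: np.ndarray, y: np.ndarray, control: np.ndarray):
    """Partial Spearman correlation of x and y given a control variable.

    All three are ranked; the x- and y-ranks are each regressed on the
    control ranks by ordinary least squares, and the Pearson correlation
    of the two residual vectors is returned with a p-value from the t
    transform on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    control = np.asarray(control, dtype=float)
    n = x.size
    if not (y.size == n and control.size == n):
        raise ValueError("inputs must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    for name, v in (("x", x), ("y", y), ("control", control)):
        if np.all(v == v[0]):
            raise ValueError(f"constant input {name}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = stats.rankdata(control)
    Z = np.column_stack([np.ones(n), rc])
    res_x = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(res_x ** 2) * np.sum(res_y ** 2))
    if denom == 0:
        raise ValueError("degenerate residuals (constant after ranking)")
    rho = float(np.sum(res_x * res_y) / denom)
    df = n - 3
    rho_c = min(max(rho, -0.9999999), 0.9999999)
    t = rho_c * np.sqrt(df / (1.0 - rho_c ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p
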