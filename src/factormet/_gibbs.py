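"""Numba-compiled Gibbs samplers.

Two cores:

* :func:`spike_slab_gibbs` — whole-genome regression with spike-and-slab
  marker effects.  With a common slab variance and a uniform prior on the
  exclusion probability pi this is Bayes C-pi; with per-marker slab
  variances (marginally scaled-t effects) and a beta prior on pi it is
  BayesB.  Phenotype records may repeat lines (multi-trial designs) and
  optionally include random trial effects.

* :func:`ridge_block_gibbs` — Bayesian ridge regression with independent
  variance components per column block.  With blocks built from scaled
  kernel eigenvectors this is (multi-kernel) GBLUP; a 0/1 trial-incidence
  block gives random trial effects.

Scaled inverse-chi-square draws are composed from chi-square variates;
all randomness flows through numpy's legacy global RNG seeded inside the
jitted function, so chains reproduce exactly for a fixed seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def spike_slab_gibbs(W, y, line_of, trial_of, n_trials,
                     niter, burn, thin, bayesb,
                     nu_a, Sa, nu_e, Se, nu_s, Ss,
                     pi_a0, pi_b0, seed):
    """Spike-and-slab whole-genome regression sampler.

    Parameters
    ----------
    W : n_lines x m marker matrix (centered columns recommended)
    y : r phenotype records
    line_of, trial_of : record -> line / trial index (trials ignored when
        n_trials == 0)
    bayesb : 0 = common slab variance (Bayes C-pi for pi_a0=pi_b0=1);
             1 = per-marker variances (scaled-t slab) with a beta prior on pi

    Returns posterior means:
      (effect, include_prob, pi, one_minus_pi, h2, sigma2_e,
       sigma2_a, mu, g_line)
    """
    np.random.seed(seed)
    n, m = W.shape
    r = y.size

    cnt_line = np.zeros(n)
    ysum_line = np.zeros(n)
    for rec in range(r):
        cnt_line[line_of[rec]] += 1.0
        ysum_line[line_of[rec]] += y[rec]

    # record-level squared norm of each marker column
    wtw = np.zeros(m)
    for j in range(m):
        acc = 0.0
        for l in range(n):
            acc += W[l, j] * W[l, j] * cnt_line[l]
        wtw[j] = acc

    a = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    sig2j = np.full(m, Sa)
    sigma2_a = Sa
    vy = np.var(y)
    sigma2_e = 0.5 * vy if vy > 0 else 1.0
    pi = 0.5
    mu = 0.0
    s = np.zeros(max(n_trials, 1))
    sigma2_s = Ss

    g_line = np.zeros(n)             # genomic value per line (W a)
    st_line = np.zeros(n)            # sum of current trial effects per line

    n_keep = 0
    sum_a = np.zeros(m)
    sum_delta = np.zeros(m)
    sum_pi = 0.0
    sum_h2 = 0.0
    sum_se = 0.0
    sum_sa = 0.0
    sum_mu = 0.0
    sum_g = np.zeros(n)

    for it in range(niter):
        # ----- global residual pass: intercept, trials, sigma2_e -----
        # intercept
        tot = 0.0
        for rec in range(r):
            tot += y[rec] - g_line[line_of[rec]]
            if n_trials > 0:
                tot -= s[trial_of[rec]]
        mu = tot / r + np.random.normal() * np.sqrt(sigma2_e / r)

        # trial effects
        if n_trials > 0:
            for t in range(n_trials):
                ssum = 0.0
                cnt = 0.0
                for rec in range(r):
                    if trial_of[rec] == t:
                        ssum += y[rec] - mu - g_line[line_of[rec]]
                        cnt += 1.0
                prec = cnt / sigma2_e + 1.0 / sigma2_s
                mean = (ssum / sigma2_e) / prec
                s[t] = mean + np.random.normal() / np.sqrt(prec)
            ss2 = 0.0
            for t in range(n_trials):
                ss2 += s[t] * s[t]
            sigma2_s = (nu_s * Ss + ss2) / np.random.chisquare(nu_s + n_trials)
            for l in range(n):
                st_line[l] = 0.0
            for rec in range(r):
                st_line[line_of[rec]] += s[trial_of[rec]]

        # ----- marker loop on line-level aggregates -----
        n_in = 0
        ssq_in = 0.0
        for j in range(m):
            a_old = a[j]
            # rhs = w_j . residual  with marker j's own contribution removed
            rhs = a_old * wtw[j]
            for l in range(n):
                e_l = ysum_line[l] - cnt_line[l] * (mu + g_line[l]) - st_line[l]
                rhs += W[l, j] * e_l
            s2 = sig2j[j] if bayesb == 1 else sigma2_a
            C = wtw[j] / sigma2_e + 1.0 / s2
            rhs_e = rhs / sigma2_e
            log_odds = (np.log(1.0 - pi) - np.log(pi)
                        + 0.5 * rhs_e * rhs_e / C
                        - 0.5 * np.log(s2 * C))
            if log_odds > 35.0:
                p_in = 1.0
            elif log_odds < -35.0:
                p_in = 0.0
            else:
                p_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_in:
                a_new = rhs_e / C + np.random.normal() / np.sqrt(C)
                delta[j] = 1
                n_in += 1
                ssq_in += a_new * a_new
                if bayesb == 1:
                    sig2j[j] = (nu_a * Sa + a_new * a_new) / \
                        np.random.chisquare(nu_a + 1.0)
            else:
                a_new = 0.0
                delta[j] = 0
                if bayesb == 1:
                    sig2j[j] = nu_a * Sa / np.random.chisquare(nu_a)
            d = a_new - a_old
            if d != 0.0:
                for l in range(n):
                    g_line[l] += W[l, j] * d
            a[j] = a_new

        if bayesb == 0:
            sigma2_a = (nu_a * Sa + ssq_in) / np.random.chisquare(nu_a + n_in)

        # pi is the probability of a zero effect
        pi = np.random.beta(pi_a0 + (m - n_in), pi_b0 + n_in)
        if pi < 1e-12:
            pi = 1e-12
        if pi > 1.0 - 1e-12:
            pi = 1.0 - 1e-12

        # residual variance
        sse = 0.0
        for rec in range(r):
            e_rec = y[rec] - mu - g_line[line_of[rec]]
            if n_trials > 0:
                e_rec -= s[trial_of[rec]]
            sse += e_rec * e_rec
        sigma2_e = (nu_e * Se + sse) / np.random.chisquare(nu_e + r)

        if it >= burn and (it - burn) % thin == 0:
            n_keep += 1
            gbar = 0.0
            for l in range(n):
                gbar += g_line[l]
            gbar /= n
            gvar = 0.0
            for l in range(n):
                gvar += (g_line[l] - gbar) ** 2
            gvar /= n
            sum_h2 += gvar / (gvar + sigma2_e)
            sum_pi += pi
            sum_se += sigma2_e
            sum_sa += sigma2_a
            sum_mu += mu
            for j in range(m):
                sum_a[j] += a[j]
                sum_delta[j] += delta[j]
            for l in range(n):
                sum_g[l] += g_line[l]

    inv = 1.0 / max(n_keep, 1)
    return (sum_a * inv, sum_delta * inv, sum_pi * inv,
            1.0 - sum_pi * inv, sum_h2 * inv, sum_se * inv, sum_sa * inv,
            sum_mu * inv, sum_g * inv)


@njit(cache=True)
def ridge_block_gibbs(B, y, block_start, block_end,
                      niter, burn, thin, nu, S0, nu_e, Se, seed):
    """Bayesian ridge with one variance component per column block.

    B : r x q design (e.g. scaled kernel eigenvectors stacked with a
        trial incidence block); block b owns columns
        [block_start[b], block_end[b]).
    S0 : per-block prior scale for the block variance.

    Returns (coef_mean, sigma2_block_mean, sigma2_e_mean, mu_mean).
    """
    np.random.seed(seed)
    r, q = B.shape
    nb = block_start.size
    colsq = np.zeros(q)
    for c in range(q):
        acc = 0.0
        for i in range(r):
            acc += B[i, c] * B[i, c]
        colsq[c] = acc

    coef = np.zeros(q)
    sigma2_b = S0.copy()
    vy = np.var(y)
    sigma2_e = 0.5 * vy if vy > 0 else 1.0
    mu = 0.0
    e = y.copy()

    n_keep = 0
    sum_coef = np.zeros(q)
    sum_sb = np.zeros(nb)
    sum_se = 0.0
    sum_mu = 0.0

    for it in range(niter):
        tot = 0.0
        for i in range(r):
            tot += e[i]
        mu_new = tot / r + mu + np.random.normal() * np.sqrt(sigma2_e / r)
        shift = mu_new - mu
        for i in range(r):
            e[i] -= shift
        mu = mu_new

        for b in range(nb):
            ssq = 0.0
            for c in range(block_start[b], block_end[b]):
                old = coef[c]
                rhs = colsq[c] * old
                for i in range(r):
                    rhs += B[i, c] * e[i]
                prec = colsq[c] / sigma2_e + 1.0 / sigma2_b[b]
                mean = (rhs / sigma2_e) / prec
                new = mean + np.random.normal() / np.sqrt(prec)
                d = new - old
                if d != 0.0:
                    for i in range(r):
                        e[i] -= B[i, c] * d
                coef[c] = new
                ssq += new * new
            qb = block_end[b] - block_start[b]
            sigma2_b[b] = (nu * S0[b] + ssq) / np.random.chisquare(nu + qb)

        sse = 0.0
        for i in range(r):
            sse += e[i] * e[i]
        sigma2_e = (nu_e * Se + sse) / np.random.chisquare(nu_e + r)

        if it >= burn and (it - burn) % thin == 0:
            n_keep += 1
            for c in range(q):
                sum_coef[c] += coef[c]
            for b in range(nb):
                sum_sb[b] += sigma2_b[b]
            sum_se += sigma2_e
            sum_mu += mu

    inv = 1.0 / max(n_keep, 1)
    return sum_coef * inv, sum_sb * inv, sum_se * inv, sum_mu * inv
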