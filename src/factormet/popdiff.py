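"""Subpopulation screening: per-metabolite ANOVA, Pst vs Fst, factor PVE.

Divergence of a quantitative phenotype among subpopulations is measured by

    Pst = (c/h2 * sigma2_B) / (c/h2 * sigma2_B + 2 * sigma2_W)

with between/within variance components from a one-way ANOVA (negative
between-group estimates clipped at zero; ``c/h2 = 1`` by default).  The
genetic baseline is the per-locus multi-population Weir–Cockerham theta;
metabolites whose Pst exceeds the 80th percentile of the locus-wise Fst
distribution are candidates for divergence by selection rather than drift.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from factormet.io import GenotypeMatrix

log = logging.getLogger("factormet")


def _group_stats(values: np.ndarray, labels: np.ndarray):
    """Per-group sample sizes, means, and within-group SS (columnwise)."""
    groups = np.unique(labels)
    ns = np.array([(labels == g).sum() for g in groups])
    return groups, ns


def anova_screen(values: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.01) -> pd.DataFrame:
    """One-way ANOVA per metabolite with Benjamini–Hochberg adjustment.

    ``values`` is lines x metabolites.  Groups with a single member are
    dropped with a warning.  Returns a table with p, p_BH, and the
    significance flag at ``p_BH < alpha``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == len(np.asarray(labels)):
        pass
    labels = np.asarray(labels)
    groups, ns = _group_stats(values, labels)
    singletons = groups[ns < 2]
    if singletons.size:
        warnings.warn(f"dropping {singletons.size} single-member group(s)")
        keep = ~np.isin(labels, singletons)
        values, labels = values[keep], labels[keep]
        groups, ns = _group_stats(values, labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups with at least 2 members")
    samples = [values[labels == g] for g in groups]
    F, p = stats.f_oneway(*samples, axis=0)
    p = np.atleast_1d(p)
    rej, p_bh, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"F": np.atleast_1d(F), "p": p, "p_bh": p_bh,
                         "significant": p_bh < alpha})


def _anova_components(y: np.ndarray, labels: np.ndarray):
    """MSB, MSW and the unequal-group-size coefficient n0."""
    groups = np.unique(labels)
    k = groups.size
    N = y.size
    means = np.array([y[labels == g].mean() for g in groups])
    ns = np.array([(labels == g).sum() for g in groups])
    grand = y.mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((y[labels == g] - means[i]) ** 2)
                    for i, g in enumerate(groups)))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - np.sum(ns ** 2) / N) / (k - 1)
    return msb, msw, n0


def pst(values: np.ndarray, labels: np.ndarray, c_over_h2: float = 1.0) -> float:
    """Phenotypic divergence among subpopulations.

    ``Pst = (c/h2 * s2_B) / (c/h2 * s2_B + 2 * s2_W)`` with
    ``s2_B = max(0, (MSB - MSW)/n0)`` and ``s2_W = MSW``.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 groups")
    msb, msw, n0 = _anova_components(y, labels)
    s2b = max(0.0, (msb - msw) / n0)
    denom = c_over_h2 * s2b + 2.0 * msw
    if denom == 0:
        warnings.warn("zero within- and between-group variance; Pst undefined, "
                      "returning 0")
        return 0.0
    return float(c_over_h2 * s2b / denom)


def fst_loci(geno: GenotypeMatrix | np.ndarray, labels: np.ndarray):
    """Per-locus multi-population Weir–Cockerham theta and its quantiles.

    Treats each line as a diploid individual (dosage 1 = heterozygote).
    Monomorphic loci have an undefined estimate and are excluded (NaN).
    Returns (fst_per_locus, q80).
    """
    W = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    r = groups.size
    if r < 2:
        raise ValueError("need at least 2 subpopulations")
    # per-subpop sample sizes, allele freqs, observed het per locus
    n_i = np.array([(labels == g).sum() for g in groups], dtype=float)
    p_i = np.stack([W[labels == g].mean(axis=0) / 2.0 for g in groups])   # r x m
    h_i = np.stack([(W[labels == g] == 1).mean(axis=0) for g in groups])  # r x m

    nbar = n_i.mean()
    nc = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / n_i.sum()
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / n_i.sum()

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, a / denom, np.nan)
    theta = np.where(pbar * (1 - pbar) > 0, theta, np.nan)
    valid = theta[~np.isnan(theta)]
    if valid.size == 0:
        raise ValueError("no polymorphic loci; Fst undefined")
    q80 = float(np.percentile(valid, 80))
    return theta, q80


def pst_fst_flags(pst_values: np.ndarray, fst_values: np.ndarray) -> pd.DataFrame:
    """Flag metabolites whose Pst exceeds the 80th percentile of Fst."""
    fst = np.asarray(fst_values, dtype=float)
    fst = fst[~np.isnan(fst)]
    if fst.size == 0:
        raise ValueError("empty Fst vector")
    q80 = float(np.percentile(fst, 80))
    ps = np.asarray(pst_values, dtype=float)
    flags = ps > q80
    log.info("%d/%d metabolites exceed the Fst 80th percentile (%.3f)",
             int(flags.sum()), ps.size, q80)
    return pd.DataFrame({"pst": ps, "flag": flags, "fst_q80": q80})


def kmeans_subpops(geno: GenotypeMatrix | np.ndarray, n_groups: int,
                   n_pcs: int = 10, seed: int = 0) -> np.ndarray:
    """Convenience clustering of lines into subpopulations.

    k-means on the leading principal components of the genomic
    relationship matrix; purely plumbing for when labels are not given.
    """
    from sklearn.cluster import KMeans
    from factormet.gwas import grm, grm_pcs
    G = grm(geno, "vanraden-1")
    pcs = grm_pcs(G, n_pcs)
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    return km.fit_predict(pcs)


def subpop_pve_factors(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Percent variance of each factor score explained by subpopulation.

    The fixed-effect group-means model's R^2, as a percentage, per factor.
    """
    F = np.atleast_2d(np.asarray(scores, dtype=float))
    if F.shape[0] != len(np.asarray(labels)):
        F = F.T
    labels = np.asarray(labels)
    groups = np.unique(labels)
    out = np.empty(F.shape[1])
    grand = F.mean(axis=0)
    sst = ((F - grand) ** 2).sum(axis=0)
    ssb = np.zeros(F.shape[1])
    for g in groups:
        sel = labels == g
        ssb += sel.sum() * (F[sel].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sst > 0, 100.0 * ssb / sst, 0.0)
    return out
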