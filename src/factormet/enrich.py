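"""Chemical-class enrichment of factor loadings with a permutation null.

For factor k and class c the statistic is the share of the factor's
loading sum-of-squares carried by the class's compounds,

    PVE_kc = sum_{j in c} lambda_kj^2 / sum_j lambda_kj^2 ,

compared against an empirical null obtained by drawing random compound
sets of the same size (sampling all loadings — annotated or not — without
replacement).  q-values are computed jointly across every (factor, level,
class) test.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from factormet.ebmf import FactorModel
from factormet.io import AnnotationHierarchy

log = logging.getLogger("factormet")


def pve_class(loadings: np.ndarray, class_members: np.ndarray) -> float:
    """Share of a factor's loading sum-of-squares within a compound set.

    ``class_members`` indexes (or boolean-masks) the compounds in the class.
    """
    lam = np.asarray(loadings, dtype=float)
    total = float(np.sum(lam * lam))
    if total == 0:
        raise ValueError("dead factor: all loadings are zero")
    return float(np.sum(lam[class_members] ** 2)) / total


def permutation_null(loadings: np.ndarray, class_size: int, observed: float,
                     n_perm: int = 1000, seed: int = 0,
                     rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for an observed PVE_kc.

    Null sets of ``class_size`` compounds are drawn without replacement
    from all compounds; ``p = (1 + #{null >= observed}) / (1 + n_perm)``
    (the +1 pseudocount avoids zero Monte-Carlo p-values).
    """
    lam = np.asarray(loadings, dtype=float)
    p = lam.size
    if not (0 < class_size <= p):
        raise ValueError("class_size must lie in (0, n_compounds]")
    if class_size == p:
        return 1.0
    if rng is None:
        rng = np.random.default_rng(seed)
    lam2 = lam * lam
    total = lam2.sum()
    if total == 0:
        raise ValueError("dead factor: all loadings are zero")
    # vectorized sampling without replacement: random keys, take the
    # class_size smallest per draw
    keys = rng.random((n_perm, p))
    idx = np.argpartition(keys, class_size - 1, axis=1)[:, :class_size]
    null = lam2[idx].sum(axis=1) / total
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_perm))


def storey_qvalues(pvals: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda plug-in pi0 estimate.

    Falls back to Benjamini–Hochberg (pi0 = 1) when there are too few
    tests for the plug-in to be stable.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if m < 50:
        pi0 = 1.0
    else:
        pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
        if pi0 <= 0:
            pi0 = 1.0 / m
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def enrich_all(
    model: FactorModel,
    hierarchy: AnnotationHierarchy,
    min_class_size: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every (factor, level, class) with at least ``min_class_size``
    compounds; q-values are computed jointly across all tests.

    Returns a table with columns factor, level, class, size, pve, p, q,
    sorted by q.
    """
    compounds = hierarchy.compounds
    comp_index = {c: j for j, c in enumerate(compounds)}
    rng = np.random.default_rng(seed)
    rows = []
    for level in range(1, 6):
        classes = hierarchy.classes_at(level)
        for cls, members in sorted(classes.items()):
            if len(members) < min_class_size:
                continue
            idx = np.fromiter((comp_index[c] for c in members), dtype=int)
            for k in range(model.n_factors):
                lam = model.loadings[k]
                obs = pve_class(lam, idx)
                pval = permutation_null(lam, idx.size, obs,
                                        n_perm=n_perm, rng=rng)
                rows.append((k, level, cls, idx.size, obs, pval))
    if not rows:
        warnings.warn("no classes with enough annotated compounds; "
                      "nothing testable")
        return pd.DataFrame(columns=["factor", "level", "class", "size",
                                     "pve", "p", "q"])
    out = pd.DataFrame(rows, columns=["factor", "level", "class", "size",
                                      "pve", "p"])
    out["q"] = storey_qvalues(out["p"].to_numpy())
    return out.sort_values("q", kind="stable").reset_index(drop=True)
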