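"""Informed-kernel construction, multi-kernel fits, and line-level CV."""

import numpy as np
import pytest

from factormet.gwas import grm
from factormet.mkpred import (
    build_kernels,
    cross_validate,
    fit_multikernel,
    gblup,
    hits_for_enriched_factors,
    make_gblup_model,
    make_mk_model,
    select_informed_markers,
)
from factormet.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(n_lines=250, n_markers=800, n_subpops=1,
                    fst_divergence=0.0, ld_block_size=4, seed=23)
    geno, _, blocks = simulate_genotypes(cfg)
    return geno, blocks


@pytest.fixture(scope="module")
def planted_trait(panel):
    """Two-trial trait driven by 3 large QTL, h2 = 0.5."""
    geno, _ = panel
    W = geno.dosages
    Wc = W - W.mean(axis=0)
    rng = np.random.default_rng(23)
    qtl = rng.choice(800, 3, replace=False)
    g = Wc[:, qtl] @ np.array([1.0, 0.8, 0.9])
    g /= g.std()
    n = 250
    gv = np.sqrt(0.5) * g
    y = np.concatenate([gv + 0.3 + np.sqrt(0.5) * rng.normal(size=n),
                        gv - 0.3 + np.sqrt(0.5) * rng.normal(size=n)])
    line_of = np.concatenate([np.arange(n), np.arange(n)])
    trial_of = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    return qtl, gv, y, line_of, trial_of


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def test_duplicate_of_hit_included_independent_excluded(panel):
    geno, _ = panel
    W = geno.dosages.copy()
    W[:, 10] = W[:, 0]   # perfect proxy of the hit
    import dataclasses
    from factormet.io import GenotypeMatrix
    g2 = GenotypeMatrix(lines=geno.lines, markers=geno.markers, dosages=W)
    pair = select_informed_markers([geno.markers[0]], g2, 0.25)
    assert 10 in pair.informed
    # a marker from a far block with negligible correlation is excluded
    far = 400
    r2 = np.corrcoef(W[:, far], W[:, 0])[0, 1] ** 2
    assert r2 < 0.25 and far in pair.complement


def test_hit_pulls_in_its_whole_ld_block(panel):
    geno, blocks = panel
    hit = 40
    pair = select_informed_markers([hit], geno, 0.25)
    same_block = np.flatnonzero(blocks == blocks[hit])
    assert set(same_block) <= set(pair.informed)
    other_blocks = np.unique(blocks[pair.informed])
    assert other_blocks.size <= 3  # essentially only the hit's block


def test_sets_are_disjoint_and_cover_all_markers(panel):
    geno, _ = panel
    pair = select_informed_markers([1, 2, 3], geno, 0.25)
    assert np.intersect1d(pair.informed, pair.complement).size == 0
    assert pair.informed.size + pair.complement.size == 800


def test_empty_hit_list_falls_back_to_single_kernel(panel):
    geno, _ = panel
    pair = select_informed_markers([], geno, 0.25)
    assert pair.informed.size == 0
    pair = build_kernels(geno, pair)
    assert pair.K_in is None and pair.K_out is not None


def test_unmatched_hits_dropped(panel):
    geno, _ = panel
    pair = select_informed_markers(["not_a_marker", geno.markers[5]], geno)
    assert 5 in pair.informed


def test_hits_for_enriched_factors_filters_by_class():
    import pandas as pd
    enr = pd.DataFrame({"factor": [0, 1, 2], "level": [2, 2, 2],
                        "class": ["lipids", "lipids", "sugars"],
                        "size": [10, 10, 10], "pve": [0.5, 0.2, 0.4],
                        "p": [0.001, 0.2, 0.001], "q": [0.01, 0.5, 0.01]})
    hits = {0: ["a", "b"], 1: ["c"], 2: ["d"]}
    assert sorted(hits_for_enriched_factors(hits, enr, "lipids")) == ["a", "b"]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def test_kernel_split_reconstructs_whole_genome_grm(panel):
    geno, _ = panel
    rng = np.random.default_rng(1)
    informed = np.sort(rng.choice(800, 300, replace=False))
    pair = build_kernels(geno, select_informed_markers(
        [], geno, 0.25).__class__(informed=informed,
                                  complement=np.setdiff1d(np.arange(800),
                                                          informed),
                                  r2_threshold=0.25))
    G = grm(geno, "vanraden-1")
    p = geno.dosages.mean(0) / 2
    het = 2 * p * (1 - p)
    w_in = het[pair.informed].sum() / het.sum()
    w_out = het[pair.complement].sum() / het.sum()
    recon = pair.K_in * w_in + pair.K_out * w_out
    assert np.abs(recon - G).max() < 0.05


def test_kernels_are_psd_and_respect_duplicate_lines(panel):
    geno, _ = panel
    from factormet.io import GenotypeMatrix
    W = geno.dosages.copy()
    W[1] = W[0]
    g2 = GenotypeMatrix(lines=geno.lines, markers=geno.markers, dosages=W)
    pair = build_kernels(g2, select_informed_markers([3], g2, 0.25))
    for K in (pair.K_in, pair.K_out):
        assert np.linalg.eigvalsh(K).min() > -1e-8
        np.testing.assert_allclose(K[0], K[1])


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def test_signal_free_informed_kernel_gets_little_variance(panel, planted_trait):
    """When the informed set carries no causal markers, its variance
    component stays small relative to the complement's."""
    geno, blocks = panel
    qtl, gv, y, line_of, trial_of = planted_trait
    non_causal = np.setdiff1d(np.arange(800), qtl)
    rng = np.random.default_rng(2)
    decoy = np.sort(rng.choice(non_causal, 12, replace=False))
    from factormet.mkpred import KernelPair
    pair = build_kernels(geno, KernelPair(
        informed=decoy, complement=np.setdiff1d(np.arange(800), decoy),
        r2_threshold=0.25))
    fit = fit_multikernel(y, line_of, pair.K_in, pair.K_out, trial_of,
                          iterations=3000, burn_in=1000, thin=4, seed=3)
    vc = fit.variance_components
    assert vc["sigma2_u0"] / vc["sigma2_u1"] < 0.3


def test_multikernel_predicts_planted_genetics(panel, planted_trait):
    geno, _ = panel
    qtl, gv, y, line_of, trial_of = planted_trait
    pair = build_kernels(geno, select_informed_markers(
        [geno.markers[j] for j in qtl], geno, 0.25))
    fit = fit_multikernel(y, line_of, pair.K_in, pair.K_out, trial_of,
                          iterations=3000, burn_in=1000, thin=4, seed=3)
    assert np.corrcoef(fit.genomic_value, gv)[0, 1] > 0.9
    assert fit.genomic_value.size == 250


def test_gblup_equals_multikernel_with_split_grm(panel, planted_trait):
    """MK with K_in = K_out = G/2 is the same model as gBLUP."""
    geno, _ = panel
    _, gv, y, line_of, trial_of = planted_trait
    G = grm(geno, "vanraden-1")
    f1 = gblup(y, line_of, G, trial_of, iterations=4000, burn_in=1500,
               thin=4, seed=7)
    f2 = fit_multikernel(y, line_of, G / 2, G / 2, trial_of,
                         iterations=4000, burn_in=1500, thin=4, seed=7)
    r = np.corrcoef(f1.genomic_value, f2.genomic_value)[0, 1]
    assert r > 0.98


def test_single_trial_warns(panel, planted_trait):
    geno, _ = panel
    _, _, y, line_of, _ = planted_trait
    G = grm(geno, "vanraden-1")
    with pytest.warns(UserWarning, match="single trial"):
        gblup(y[:250], line_of[:250], G, np.zeros(250, int),
              iterations=400, burn_in=200)


def test_kernel_line_mismatch_rejected(planted_trait):
    _, _, y, line_of, trial_of = planted_trait
    with pytest.raises(ValueError, match="kernel"):
        fit_multikernel(y, line_of, None, np.eye(10), trial_of,
                        iterations=400, burn_in=200)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_cv_perfect_predictor_scores_one(planted_trait):
    _, gv, y, line_of, trial_of = planted_trait
    line_values = np.zeros(250)
    for l in range(250):
        line_values[l] = y[line_of == l].mean()

    def perfect(y_train, lo, to, seed):
        return line_values

    rep = cross_validate({"perfect": perfect}, line_values[np.arange(250)],
                         np.arange(250), None, 250, folds=5, repeats=2,
                         seed=0, baselines=())
    assert np.all(rep.accuracy["perfect"] > 0.999)


def test_cv_random_predictor_scores_zero(planted_trait):
    _, _, y, line_of, trial_of = planted_trait
    rng = np.random.default_rng(5)

    def random_model(y_train, lo, to, seed):
        return rng.normal(size=250)

    rep = cross_validate({"rand": random_model}, y, line_of, trial_of, 250,
                         folds=5, repeats=10, seed=1, baselines=())
    assert abs(rep.accuracy["rand"].mean()) < 0.1


def test_cv_fold_assignment_reproducible(planted_trait):
    _, _, y, line_of, trial_of = planted_trait
    calls = []

    def spy(y_train, lo, to, seed):
        calls.append(len(y_train))
        return np.zeros(250)

    cross_validate({"spy": spy}, y, line_of, trial_of, 250, folds=5,
                   repeats=1, seed=3, baselines=())
    first = list(calls)
    calls.clear()
    cross_validate({"spy": spy}, y, line_of, trial_of, 250, folds=5,
                   repeats=1, seed=3, baselines=())
    assert calls == first


def test_cv_rejects_more_folds_than_lines():
    with pytest.raises(ValueError):
        cross_validate({}, np.zeros(3), np.arange(3), None, 3, folds=5)
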