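"""The synthetic generator must realize the conditions it is asked for:
divergence, LD, heritability, loading density, annotation coverage."""

import numpy as np
import pytest

import factormet as fm
from factormet.gwas import grm, reml_null
from factormet.popdiff import fst_loci
from factormet.simulate import (
    POLYGENIC,
    SimConfig,
    simulate_all,
    simulate_annotations,
    simulate_genotypes,
    simulate_traits,
    write_fixture_set,
)


def test_config_validation_names_the_offending_field():
    with pytest.raises(ValueError, match="fst_divergence"):
        SimConfig(fst_divergence=1.5).validate()
    with pytest.raises(ValueError, match="ld_block_size"):
        SimConfig(ld_block_size=0).validate()
    with pytest.raises(ValueError, match="factor_h2"):
        SimConfig(n_factors=2, factor_h2=(0.5,), factor_density=(0.5, 0.5),
                  factor_n_qtl=(3, 3)).validate()
    with pytest.raises(ValueError, match="n_qtl"):
        SimConfig(n_factors=1, n_markers=10, factor_h2=(0.5,),
                  factor_density=(0.5,), factor_n_qtl=(50,)).validate()


def test_no_divergence_gives_near_zero_fst():
    cfg = SimConfig(n_lines=300, n_markers=2000, n_subpops=2,
                    fst_divergence=0.0, ld_block_size=1, seed=1)
    geno, labels, _ = simulate_genotypes(cfg)
    fst, _ = fst_loci(geno, labels)
    assert abs(np.nanmean(fst)) < 0.02


def test_balding_nichols_fst_matches_requested_divergence():
    """Independent Weir-Cockerham estimate lands near the BN parameter."""
    cfg = SimConfig(n_lines=300, n_markers=2000, n_subpops=2,
                    fst_divergence=0.1, ld_block_size=1, seed=1)
    geno, labels, _ = simulate_genotypes(cfg)
    fst, _ = fst_loci(geno, labels)
    assert 0.05 <= np.nanmean(fst) <= 0.15


def test_block_size_one_gives_independent_markers():
    cfg = SimConfig(n_lines=300, n_markers=200, n_subpops=1,
                    fst_divergence=0.0, ld_block_size=1, seed=2)
    geno, _, _ = simulate_genotypes(cfg)
    C = np.corrcoef(geno.dosages, rowvar=False)
    off = C[np.triu_indices(200, 1)] ** 2
    assert off.mean() < 0.05


def test_ld_blocks_have_high_internal_r2():
    cfg = SimConfig(n_lines=300, n_markers=100, n_subpops=1,
                    fst_divergence=0.0, ld_block_size=5, seed=2)
    geno, _, blocks = simulate_genotypes(cfg)
    r2 = []
    for blk in np.unique(blocks):
        cols = np.flatnonzero(blocks == blk)
        C = np.corrcoef(geno.dosages[:, cols], rowvar=False)
        r2.append((C[np.triu_indices(cols.size, 1)] ** 2).mean())
    assert np.mean(r2) > 0.25


def test_dosages_are_integers_in_range(bundle):
    d = bundle.genotypes.dosages
    assert set(np.unique(d)) <= {0.0, 1.0, 2.0}


def test_null_heritability_scores_show_no_marker_association():
    cfg = SimConfig(n_lines=300, n_markers=400, n_subpops=1, ld_block_size=1,
                    n_factors=1, factor_h2=(0.0,), factor_density=(0.5,),
                    factor_n_qtl=(POLYGENIC,), n_traits=1, trait_h2=(0.5,),
                    trait_factor_weights=((1.0,),),
                    enriched_factor_class_pairs=((0, "lipids"),), seed=5)
    bundle = simulate_all(cfg)
    y = bundle.truth.true_scores[:, 0]
    W = bundle.genotypes.dosages
    from scipy import stats
    ps = np.array([stats.pearsonr(W[:, j], y)[1] for j in range(400)])
    assert abs((ps < 0.05).mean() - 0.05) < 0.04


def test_full_density_loadings_all_nonzero():
    cfg = SimConfig(n_factors=1, factor_h2=(0.5,), factor_density=(1.0,),
                    factor_n_qtl=(5,), n_metabolites=100, n_traits=1,
                    trait_h2=(0.5,), trait_factor_weights=((1.0,),),
                    enriched_factor_class_pairs=((0, "lipids"),), seed=6)
    bundle = simulate_all(cfg)
    assert np.all(bundle.truth.true_loadings != 0)


def test_realized_loading_density_matches_request(bundle):
    cfg = bundle.config
    realized = (bundle.truth.true_loadings != 0).mean(axis=1)
    np.testing.assert_allclose(realized, cfg.factor_density, atol=0.1)


def test_realized_heritability_recovered_by_reml(bundle):
    """REML with the true kinship recovers the planted h2 of a factor."""
    geno = bundle.genotypes
    G = grm(geno, "vanraden-1")
    k = 2  # planted h2 = 0.7
    fit = reml_null(bundle.truth.true_scores[:, k], None, G)
    assert abs(fit.h2 - bundle.config.factor_h2[k]) < 0.15


def test_metabolome_is_standardized(bundle):
    v = bundle.metabolome.values
    np.testing.assert_allclose(v.mean(axis=0), 0, atol=1e-8)
    np.testing.assert_allclose(v.var(axis=0), 1, atol=1e-8)


def test_y_equals_factor_product_plus_noise_before_standardization(bundle):
    t = bundle.truth
    resid = t.y_raw - t.true_scores @ t.true_loadings
    # the residual is the column-specific Gaussian noise; its scale matches
    sd = bundle.config.metabolite_noise_sd
    assert abs(resid.std() - sd) < 0.05 * sd


def test_requesting_heritability_without_genetic_variance_errors():
    from factormet.io import GenotypeMatrix
    from factormet.simulate import simulate_factor_metabolome
    cfg = SimConfig(n_factors=1, factor_h2=(1.0,), factor_density=(0.5,),
                    factor_n_qtl=(1,), n_lines=2, n_markers=1,
                    n_metabolites=10, n_traits=1, trait_h2=(0.5,),
                    trait_factor_weights=((1.0,),),
                    enriched_factor_class_pairs=((0, "lipids"),), seed=0)
    mono = GenotypeMatrix(lines=["a", "b"], markers=["m1"],
                          dosages=np.array([[1.0], [1.0]]))
    with pytest.raises(ValueError, match="zero"):
        simulate_factor_metabolome(cfg, mono)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def test_annotated_fraction_matches_request(bundle):
    ann = bundle.annotations.is_annotated()
    expected = round(bundle.config.annotated_fraction
                     * bundle.config.n_metabolites)
    assert abs(int(ann.sum()) - expected) <= 1


def test_annotation_hierarchy_is_nested(bundle):
    """Each class at level l+1 maps into exactly one parent class."""
    tab = bundle.annotations.table
    annotated = tab[(tab != "").any(axis=1)]
    for child, parent in (("level_2", "level_1"), ("level_3", "level_2")):
        parents = annotated.groupby(child)[parent].nunique()
        assert (parents <= 1).all()


def test_planted_class_captures_top_loading_compounds(bundle):
    cfg = bundle.config
    factor, cls = cfg.enriched_factor_class_pairs[0]
    lam = bundle.truth.true_loadings[factor]
    top = set(int(j) for j in
              np.argsort(-np.abs(lam))[:cfg.enrichment_top_n])
    members = bundle.annotations.classes_at(2).get(cls, set())
    member_idx = {int(c[1:]) for c in members}
    # a compound topping several planted factors keeps the last assignment,
    # so only compounds not claimed by a later pair must be in the class
    claimed_later = set()
    for f_later, _ in cfg.enriched_factor_class_pairs[1:]:
        lam_l = bundle.truth.true_loadings[f_later]
        claimed_later |= set(
            int(j) for j in np.argsort(-np.abs(lam_l))[:cfg.enrichment_top_n])
    assert (top - claimed_later) <= member_idx
    assert len(top & member_idx) >= 0.8 * len(top)


def test_enriched_pair_with_unknown_factor_rejected():
    with pytest.raises(ValueError, match="factor 11"):
        SimConfig(enriched_factor_class_pairs=((11, "lipids"),)).validate()


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def test_trait_tracks_designated_factor(bundle):
    """Trait 0's genetic value is factor 0's genetic value up to scale."""
    t = bundle.truth
    g_factor = t.true_genetic_scores[:, 0]
    g_trait = t.true_trait_genetic_values[:, 0]
    r = np.corrcoef(g_factor, g_trait)[0, 1]
    assert abs(r) > 0.9999


def test_trait_records_per_line_and_trial(bundle):
    tab = bundle.phenotypes.table
    cfg = bundle.config
    assert len(tab) == cfg.n_lines * cfg.n_traits * cfg.n_trials


def test_weights_referencing_missing_factor_rejected(bundle):
    import dataclasses
    bad = dataclasses.replace(bundle.config,
                              trait_factor_weights=((1.0,) * 9,) * 2)
    with pytest.raises(ValueError):
        simulate_traits(bad, bundle.truth)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def test_fixture_roundtrip_and_determinism(tmp_path):
    cfg = SimConfig(n_lines=40, n_markers=60, n_metabolites=50, n_factors=2,
                    factor_h2=(0.5, 0.3), factor_density=(0.5, 0.8),
                    factor_n_qtl=(3, POLYGENIC), n_traits=1, trait_h2=(0.5,),
                    trait_factor_weights=((1.0, 0.0),),
                    enriched_factor_class_pairs=((0, "lipids"),),
                    enrichment_top_n=10, seed=9)
    b1 = write_fixture_set(tmp_path / "a", cfg)
    b2 = write_fixture_set(tmp_path / "b", cfg)
    for f in ("genotypes.tsv", "metabolites.tsv", "annotations.tsv",
              "phenotypes.tsv", "subpops.tsv"):
        assert (tmp_path / "a" / f).read_text() == (tmp_path / "b" / f).read_text()
    # different seed -> different genotypes
    b3 = write_fixture_set(tmp_path / "c", cfg, seed=10)
    assert not np.array_equal(b1.genotypes.dosages, b3.genotypes.dosages)
    # lossless round-trip through the readers
    geno = fm.read_genotypes(tmp_path / "a" / "genotypes.tsv", maf_threshold=0.0)
    kept = [b1.genotypes.markers.index(m) for m in geno.markers]
    np.testing.assert_array_equal(geno.dosages, b1.genotypes.dosages[:, kept])
    metab = fm.read_metabolites(tmp_path / "a" / "metabolites.tsv",
                                standardize=False)
    np.testing.assert_allclose(metab.values, b1.metabolome.values, atol=1e-12)
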