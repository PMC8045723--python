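# factormet

From an untargeted seed metabolome to biologically informed genomic
prediction.

Plant breeders who assay hundreds to thousands of metabolites on a
genotyped diversity panel face two linked problems: the metabolome is far
too high-dimensional for marker association study (one GWAS per compound
multiplies the testing burden), and most compounds are unannotated, so the
biology behind any association is opaque. `factormet` implements a pipeline
that addresses both: it compresses the metabolite matrix into a small set
of sparse latent factors, attaches chemistry to the factors by class
enrichment, maps the factors' genetic basis, and routes the associated
markers into a dedicated kernel of a multi-kernel genomic prediction model
for seed quality traits.

## The model

The centered, standardized line × metabolite matrix **Y** (n × p) is
decomposed as

```
Y = F Γ + s,        V = Γ'Γ + Ψ
```

with factor scores **F** (n × K), sparse loadings **Γ** (K × p), and
diagonal specific variances **Ψ**. Both the loadings and the scores of each
factor carry a spike-and-slab prior — a point mass at zero with weight *v*
(loadings) and a Laplace or normal slab — whose parameters are learned
from the data by empirical Bayes (the inner normal-means problem is solved
by maximum marginal likelihood). Fitting is greedy (factors added one at a
time from the leading singular pair of the residual) followed by
backfitting, with a variational bound for convergence; model quality is
judged by PVE = 100·tr(Γ'Γ)/tr(Γ'Γ+Ψ) and by threefold *orthogonal*
(speckled) cross-validation, which masks cell blocks so that no row or
column is ever fully hidden.

Downstream, per factor *k* and chemical class *c*:

* enrichment: PVE_kc = Σ_{j∈c} λ_kj² / Σ_j λ_kj², tested against a
  permutation null (random compound sets of equal size) with Storey
  q-values across all factor × class tests;
* association: the mixed model y = Xb + w_i a_i + Zu + e per marker, with
  variance components fixed at their null REML estimates, and the
  experiment-wise threshold α_p = 1 − (1 − α_e)^{1/(Meff·K)} from the
  Li–Ji effective number of tests;
* architecture: Bayes Cπ (spike-and-slab with common slab variance and a
  sampled π) gives the polygenicity 1 − π of each factor, which is
  compared to the loading density 1 − v by partial Spearman correlation
  controlling for h²;
* prediction: MK-BLUP, y = μ + Z_u u_in + Z_u u_out + Z_e s + e, where the
  informed kernel K_in is built from factor-GWAS hits plus markers in LD
  (r² > 0.25) with them, against gBLUP and BayesB baselines under
  fivefold line-level cross-validation; a gain is called significant when
  the informed model wins in ≥ 90% of resampling runs.

A synthetic-data module generates all five inputs (genotypes with block LD
and Balding–Nichols subpopulation divergence, a factor-structured
metabolome, a partially annotated five-level class hierarchy, multi-trial
traits) with known ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
import factormet as fm
from factormet.ebmf import fit_greedy, backfit, pve
from factormet.gwas import grm, grm_pcs, meff, scan, sidak_threshold, r2_gwas

bundle = fm.simulate_all(seed=3)          # 335 lines, 2000 markers, 8 factors
Y = bundle.metabolome.values
model = backfit(fit_greedy(Y, max_factors=12), Y, max_sweeps=8)
total, per = pve(model)
print(f"retained K={model.n_factors} factors, total PVE={total:.1f}%")

G = grm(bundle.genotypes, "vanraden-2")
alpha_p = sidak_threshold(0.1, meff(bundle.genotypes), model.n_factors)
res = scan(model.scores[:, 2], bundle.genotypes, grm_pcs(G, 2), G)
hits = res.significant(alpha_p)
r2, _ = r2_gwas(model.scores[:, 2], bundle.genotypes.dosages[:, hits],
                grm_pcs(G, 10))
fit = fm.bayes_cpi(model.scores[:, 2], bundle.genotypes,
                   iterations=8000, burn_in=4000, seed=3)
print(f"{hits.size} hits at alpha_p={alpha_p:.2e}, R2_GWAS={r2:.2f}, "
      f"polygenicity={fit.polygenicity:.3f}")
```

prints

```
retained K=8 factors, total PVE=92.2%
6 hits at alpha_p=2.83e-05, R2_GWAS=0.41, polygenicity=0.004
```

The generator planted 8 factors; fitted factor 2 tracks a planted
oligogenic factor (5 QTL, h² = 0.6) at r = 0.99. All 6 significant markers
fall in true QTL LD blocks, the hits explain 41% of the score variance
beyond population structure, and the posterior polygenicity 0.004 correctly
calls the architecture oligogenic. The same objects feed
`factormet.enrich.enrich_all` (class enrichment of the loadings) and
`factormet.mkpred` (informed-kernel prediction); see `docs/methods.md`.

A command-line interface chains the stages:

```
factormet run-all --config config.yaml --seed 1 --out results/
```

with subcommands `simulate`, `factorize`, `enrich`, `popdiff`, `gwas`,
`wgr`, `predict`.

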