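"""Stage orchestration: chain simulate -> factorize -> enrich -> popdiff ->
gwas -> wgr -> predict, with per-stage tables written to a report directory.

The configuration is one mapping (usually loaded from YAML) with one key
per stage; every stochastic stage takes an explicit seed.  Stages consume
the upstream artifacts they need and fail with a clear message when a
requested stage is missing its dependency.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from factormet import __version__
from factormet import ebmf, enrich, gwas, popdiff, wgr
from factormet import mkpred
from factormet.io import (
    align_lines,
    read_annotations,
    read_genotypes,
    read_metabolites,
    read_phenotypes,
    read_subpops,
)
from factormet.simulate import SimConfig, write_fixture_set

log = logging.getLogger("factormet")

ALL_STAGES = ["simulate", "factorize", "enrich", "popdiff", "gwas", "wgr", "predict"]


class PipelineError(RuntimeError):
    pass


def _require(ctx, key, stage, hint):
    if key not in ctx:
        raise PipelineError(
            f"stage {stage!r} requires {key!r}; run {hint!r} first or point "
            "the config at existing inputs")
    return ctx[key]


def run_pipeline(config: dict, out_dir, stages=None) -> Path:
    """Execute the selected stages and write their outputs under ``out_dir``.

    ``config`` keys (all optional, with defaults):
      seed, inputs {genotypes, metabolites, annotations, phenotypes, subpops},
      simulate {...SimConfig overrides}, factorize {family, max_factors,
      backfit_sweeps}, enrich {min_class_size, n_perm}, gwas {alpha_e,
      maf_threshold}, wgr {iterations, burn_in}, predict {r2_threshold,
      folds, repeats, iterations, burn_in}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or ALL_STAGES)
    seed = int(config.get("seed", 0))
    ctx: dict = {}

    if "simulate" in stages:
        sim_cfg = SimConfig(**config.get("simulate", {}), seed=seed)
        bundle = write_fixture_set(out / "inputs", sim_cfg)
        ctx["genotypes"] = bundle.genotypes
        ctx["metabolome"] = bundle.metabolome
        ctx["annotations"] = bundle.annotations
        ctx["phenotypes"] = bundle.phenotypes
        ctx["subpops"] = bundle.subpop_labels
        ctx["truth"] = bundle.truth
    elif "inputs" in config:
        paths = config["inputs"]
        if "genotypes" in paths:
            ctx["genotypes"] = read_genotypes(
                paths["genotypes"],
                config.get("gwas", {}).get("maf_threshold", 0.05))
        if "metabolites" in paths:
            ctx["metabolome"] = read_metabolites(paths["metabolites"])
        if "genotypes" in ctx and "metabolome" in ctx:
            ctx["genotypes"], ctx["metabolome"] = align_lines(
                ctx["genotypes"], ctx["metabolome"])
        if "annotations" in paths:
            compounds = (ctx["metabolome"].metabolites
                         if "metabolome" in ctx else None)
            ctx["annotations"] = read_annotations(paths["annotations"], compounds)
        if "phenotypes" in paths:
            ctx["phenotypes"] = read_phenotypes(paths["phenotypes"])
        if "subpops" in paths:
            labels = read_subpops(paths["subpops"])
            if "genotypes" in ctx:
                labels = labels.loc[ctx["genotypes"].lines]
            ctx["subpops"] = labels.to_numpy()

    if "factorize" in stages:
        metab = _require(ctx, "metabolome", "factorize", "simulate")
        fcfg = config.get("factorize", {})
        model = ebmf.fit_greedy(metab.values,
                                family=fcfg.get("family", "point-laplace"),
                                max_factors=fcfg.get("max_factors", 20),
                                tol=fcfg.get("tol", 1e-5))
        model = ebmf.backfit(model, metab.values,
                             max_sweeps=fcfg.get("backfit_sweeps", 10),
                             tol=fcfg.get("tol", 1e-5))
        ctx["model"] = model
        total, per = ebmf.pve(model)
        dens = ebmf.factor_density(model)
        pd.DataFrame(model.scores, index=metab.lines,
                     columns=[f"factor{k}" for k in range(model.n_factors)]) \
            .rename_axis("line").to_csv(out / "factor_scores.tsv", sep="\t")
        pd.DataFrame(model.loadings,
                     index=[f"factor{k}" for k in range(model.n_factors)],
                     columns=metab.metabolites) \
            .rename_axis("factor").to_csv(out / "factor_loadings.tsv", sep="\t")
        pd.DataFrame({"pve": per, "density": dens,
                      "score_pi0": model.score_pi0}) \
            .rename_axis("factor").to_csv(out / "factor_summary.tsv", sep="\t")
        log.info("factorize: K=%d, total PVE=%.1f%%", model.n_factors, total)

    if "enrich" in stages:
        model = _require(ctx, "model", "enrich", "factorize")
        hierarchy = _require(ctx, "annotations", "enrich", "simulate")
        ecfg = config.get("enrich", {})
        table = enrich.enrich_all(model, hierarchy,
                                  min_class_size=ecfg.get("min_class_size", 5),
                                  n_perm=ecfg.get("n_perm", 1000),
                                  seed=seed)
        ctx["enrichment"] = table
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    if "popdiff" in stages:
        metab = _require(ctx, "metabolome", "popdiff", "simulate")
        labels = _require(ctx, "subpops", "popdiff", "simulate")
        geno = _require(ctx, "genotypes", "popdiff", "simulate")
        screen = popdiff.anova_screen(metab.values, labels)
        screen.index = metab.metabolites
        psts = np.array([popdiff.pst(metab.values[:, j], labels)
                         for j in range(len(metab.metabolites))])
        fst, q80 = popdiff.fst_loci(geno, labels)
        flags = popdiff.pst_fst_flags(psts, fst)
        div = screen.copy()
        div["pst"] = psts
        div["pst_gt_fst_q80"] = flags["flag"].to_numpy()
        div.rename_axis("metabolite").to_csv(out / "divergence.tsv", sep="\t")
        if "model" in ctx:
            pve_sub = popdiff.subpop_pve_factors(ctx["model"].scores, labels)
            pd.DataFrame({"subpop_pve": pve_sub}).rename_axis("factor") \
                .to_csv(out / "factor_subpop_pve.tsv", sep="\t")
        ctx["fst_q80"] = q80

    if "gwas" in stages:
        model = _require(ctx, "model", "gwas", "factorize")
        geno = _require(ctx, "genotypes", "gwas", "simulate")
        gcfg = config.get("gwas", {})
        G = gwas.grm(geno, gcfg.get("grm_method", "vanraden-2"))
        pcs = gwas.grm_pcs(G, 2)
        pcs10 = gwas.grm_pcs(G, 10)
        m_eff = gwas.meff(geno)
        alpha_p = gwas.sidak_threshold(gcfg.get("alpha_e", 0.1), m_eff,
                                       max(model.n_factors, 1))
        hits_per_factor = {}
        rows = []
        for k in range(model.n_factors):
            res = gwas.scan(model.scores[:, k], geno, pcs, G)
            sig = res.significant(alpha_p)
            r2, _ = gwas.r2_gwas(model.scores[:, k],
                                 geno.dosages[:, sig] if sig.size else None,
                                 pcs10)
            hits_per_factor[k] = [geno.markers[j] for j in sig]
            rows.append((k, m_eff, alpha_p, sig.size, r2))
            pd.DataFrame({"marker": res.markers, "effect": res.effect,
                          "se": res.se, "p": res.p}) \
                .to_csv(out / f"gwas_factor{k}.tsv", sep="\t", index=False)
        pd.DataFrame(rows, columns=["factor", "meff", "alpha_p",
                                    "n_hits", "r2_gwas"]) \
            .to_csv(out / "gwas_summary.tsv", sep="\t", index=False)
        ctx["hits_per_factor"] = hits_per_factor
        ctx["grm"] = G

    if "wgr" in stages:
        model = _require(ctx, "model", "wgr", "factorize")
        geno = _require(ctx, "genotypes", "wgr", "simulate")
        wcfg = config.get("wgr", {})
        fits = {}
        for k in range(model.n_factors):
            fits[k] = wgr.bayes_cpi(model.scores[:, k], geno,
                                    iterations=wcfg.get("iterations", 20000),
                                    burn_in=wcfg.get("burn_in", 10000),
                                    seed=seed + k)
        table = wgr.polygenicity_summary(fits, ebmf.factor_density(model))
        table.to_csv(out / "architecture.tsv", sep="\t", index=False)
        if "partial_spearman" in table.attrs:
            (out / "architecture_partial_spearman.json").write_text(
                json.dumps(table.attrs["partial_spearman"]))
        ctx["wgr_fits"] = fits

    if "predict" in stages:
        geno = _require(ctx, "genotypes", "predict", "simulate")
        pheno = _require(ctx, "phenotypes", "predict", "simulate")
        hits_per_factor = _require(ctx, "hits_per_factor", "predict", "gwas")
        pcfg = config.get("predict", {})
        hits = [h for hs in hits_per_factor.values() for h in hs]
        pair = mkpred.select_informed_markers(
            hits, geno, pcfg.get("r2_threshold", 0.25))
        pair = mkpred.build_kernels(geno, pair)
        G = ctx.get("grm")
        if G is None:
            G = gwas.grm(geno, "vanraden-1")
        line_index = {l: i for i, l in enumerate(geno.lines)}
        reports = {}
        for trait in pheno.traits:
            sub = pheno.trait(trait)
            sub = sub[sub["line"].isin(line_index)]
            y = sub["value"].to_numpy()
            line_of = sub["line"].map(line_index).to_numpy()
            trials = {t: i for i, t in enumerate(sorted(sub["trial"].unique()))}
            trial_of = sub["trial"].map(trials).to_numpy()
            iters = pcfg.get("iterations", 4000)
            burn = pcfg.get("burn_in", 1000)
            models = {"gblup": mkpred.make_gblup_model(G, iters, burn)}
            if pair.K_in is not None:
                models["mk"] = mkpred.make_mk_model(
                    pair.K_in, pair.K_out, iters, burn,
                    kernel_shares=(pair.informed.size, pair.complement.size))
            report = mkpred.cross_validate(
                models, y, line_of, trial_of, len(geno.lines),
                folds=pcfg.get("folds", 5),
                repeats=pcfg.get("repeats", 10), seed=seed)
            report.accuracy.to_csv(out / f"cv_accuracy_{trait}.tsv",
                                   sep="\t", index=False)
            reports[trait] = report
        summary = {t: {"win_fraction": r.win_fraction,
                       "significant": r.significant,
                       "mean_accuracy": r.accuracy.mean().to_dict()}
                   for t, r in reports.items()}
        (out / "prediction_summary.json").write_text(
            json.dumps(summary, indent=2, default=str))
        ctx["cv_reports"] = reports

    (out / "run_log.json").write_text(json.dumps(
        {"version": __version__, "seed": seed, "stages": stages}, indent=2))
    return out
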