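"""Synthetic genotypes, factor-structured metabolomes, annotations, and traits.

The generator emulates a diversity panel of inbred-ish lines assayed for an
untargeted seed metabolome:

* genotypes — allele dosages in {0,1,2} over LD blocks.  Each block shares
  one subpopulation-specific allele frequency drawn from a
  Balding–Nichols model (Beta with divergence parameter ``fst_divergence``
  around an ancestral frequency); markers within a block are copies of a
  seed marker with a small per-line re-draw probability, which yields
  controllably high intra-block r².
* metabolome — the latent-factor model ``Y = F Gamma + s``.  Each factor's
  score is a genetic value (a handful of QTL for oligogenic factors, or
  small effects at every marker for polygenic ones) plus environmental
  noise, scaled to a target narrow-sense heritability; loadings are sparse
  with an exact per-factor density and Laplace-distributed nonzero values.
  Columns are centered and standardized after noise, as the factorization
  expects.
* annotations — a nested five-level class hierarchy covering a configurable
  fraction of compounds (a third by default), with optional planted
  (factor, class) enrichment: the top-loading compounds of a factor are
  preferentially assigned to a designated class.
* traits — multi-trial quantitative traits whose genetic values are linear
  combinations of the factors' genetic values, observed with trial effects
  and residual noise.

All randomness flows from one seeded generator; per-stage sub-seeds are
derived deterministically, so identical configurations give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from factormet.io import (
    ANNOTATION_LEVELS,
    AnnotationHierarchy,
    GenotypeMatrix,
    MetabolomeMatrix,
    PhenotypeTable,
    write_annotations,
    write_genotypes,
    write_metabolites,
    write_phenotypes,
    write_subpops,
)

POLYGENIC = None  # sentinel for "every marker is causal"


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror a diversity panel of 335 lines in six weakly diverged
    subpopulations, eight latent factors spanning oligogenic to polygenic
    architectures with heritabilities in the 0.1–0.8 range and loading
    densities from sparse to dense, a metabolome with a third of compounds
    annotated, and two multi-trial seed traits driven by designated
    factors.
    """

    n_lines: int = 335
    n_markers: int = 2000
    n_subpops: int = 6
    fst_divergence: float = 0.1
    ld_block_size: int = 5
    block_flip_prob: float = 0.1

    n_factors: int = 8
    factor_h2: tuple = (0.6, 0.5, 0.7, 0.4, 0.3, 0.5, 0.2, 0.1)
    factor_density: tuple = (0.6, 0.2, 0.8, 0.3, 0.5, 0.15, 0.7, 0.4)
    # n_qtl <= 10 is "oligogenic"; POLYGENIC (None) means every marker causal
    factor_n_qtl: tuple = (5, 3, POLYGENIC, 8, POLYGENIC, 4, POLYGENIC, 10)
    qtl_variance_fraction: float = 0.9   # share of genetic variance from the QTL
    n_metabolites: int = 600
    metabolite_noise_sd: float = 0.4

    annotated_fraction: float = 1.0 / 3.0
    n_classes_per_level: tuple = (2, 4, 8, 16, 32)
    # planted enrichment: the top-loading compounds of each factor are routed
    # to the named level-2 ("superclass") class; lipid classes dominate, as
    # they do in real seed metabolomes
    enriched_factor_class_pairs: tuple = ((0, "lipids"), (1, "lipids"),
                                          (3, "amino_acids"))
    enrichment_top_n: int = 30

    n_traits: int = 2
    n_trials: int = 2
    trait_factor_weights: tuple | None = None   # (n_traits, n_factors); default built
    trait_h2: tuple = (0.5, 0.5)
    trial_effect_sd: float = 0.5

    seed: int = 0

    def validate(self):
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.fst_divergence < 1.0):
            raise ValueError("fst_divergence must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.block_flip_prob <= 1.0):
            raise ValueError("block_flip_prob must lie in [0, 1]")
        for name in ("factor_h2", "factor_density", "factor_n_qtl"):
            if len(getattr(self, name)) != self.n_factors:
                raise ValueError(f"{name} must have length n_factors={self.n_factors}")
        for h2 in self.factor_h2:
            if not (0.0 <= h2 <= 1.0):
                raise ValueError("factor_h2 entries must lie in [0, 1]")
        for d in self.factor_density:
            if not (0.0 < d <= 1.0):
                raise ValueError("factor_density entries must lie in (0, 1]")
        for q in self.factor_n_qtl:
            if q is not POLYGENIC and not (1 <= q <= self.n_markers):
                raise ValueError("factor_n_qtl entries must satisfy 1 <= n_qtl <= n_markers")
        if not (0.0 <= self.qtl_variance_fraction <= 1.0):
            raise ValueError("qtl_variance_fraction must lie in [0, 1]")
        if not (0.0 < self.annotated_fraction <= 1.0):
            raise ValueError("annotated_fraction must lie in (0, 1]")
        if len(self.n_classes_per_level) != 5:
            raise ValueError("n_classes_per_level must list 5 levels")
        if any(b < a for a, b in zip(self.n_classes_per_level,
                                     self.n_classes_per_level[1:])):
            raise ValueError("n_classes_per_level must be non-decreasing "
                             "(finer levels cannot have fewer classes)")
        for factor, _cls in self.enriched_factor_class_pairs:
            if not (0 <= factor < self.n_factors):
                raise ValueError(
                    f"enriched_factor_class_pairs references factor {factor} "
                    f"but n_factors={self.n_factors}")
        if self.trait_factor_weights is not None:
            W = np.asarray(self.trait_factor_weights)
            if W.shape != (self.n_traits, self.n_factors):
                raise ValueError("trait_factor_weights must be n_traits x n_factors")
        if len(self.trait_h2) != self.n_traits:
            raise ValueError("trait_h2 must have length n_traits")
        return self

    def weights(self) -> np.ndarray:
        if self.trait_factor_weights is not None:
            return np.asarray(self.trait_factor_weights, dtype=float)
        # default: trait 0 tracks the first (enriched, oligogenic) factor;
        # remaining traits mix all factors with decaying weights
        W = np.zeros((self.n_traits, self.n_factors))
        if self.n_traits >= 1:
            W[0, 0] = 1.0
        for t in range(1, self.n_traits):
            W[t] = 1.0 / (1.0 + np.arange(self.n_factors))
        return W


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    true_scores: np.ndarray            # n_lines x n_factors (genetic + noise)
    true_genetic_scores: np.ndarray    # n_lines x n_factors (genetic part only)
    true_loadings: np.ndarray          # n_factors x n_metabolites
    true_qtl: list                     # per factor: (marker indices, effects)
    subpop_labels: np.ndarray          # per line
    marker_block: np.ndarray           # block index per marker
    true_trait_genetic_values: np.ndarray | None = None  # n_lines x n_traits
    trial_effects: np.ndarray | None = None              # n_traits x n_trials
    y_raw: np.ndarray | None = None    # metabolome before standardization


def _stage_rng(config: SimConfig, stage: str) -> np.random.Generator:
    # crc32 gives a stable per-stage sub-seed (builtin hash() is salted)
    import zlib
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(zlib.crc32(stage.encode()),)))


def _standardize_vec(x, rng=None):
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig):
    """Generate the marker panel; returns (GenotypeMatrix, labels, block index).

    Subpopulation allele frequencies follow a Balding–Nichols divergence
    with parameter ``fst_divergence``; markers within an LD block copy a
    seed marker with per-line flip probability ``block_flip_prob``.
    """
    config.validate()
    rng = _stage_rng(config, "genotypes")
    n, m = config.n_lines, config.n_markers
    labels = np.sort(np.arange(n) % config.n_subpops)
    n_blocks = int(np.ceil(m / config.ld_block_size))
    block_of = np.repeat(np.arange(n_blocks), config.ld_block_size)[:m]

    F = config.fst_divergence
    anc = rng.uniform(0.1, 0.9, size=n_blocks)
    if F > 0:
        a = anc * (1.0 - F) / F
        b = (1.0 - anc) * (1.0 - F) / F
        subpop_freq = rng.beta(a[:, None], b[:, None],
                               size=(n_blocks, config.n_subpops))
    else:
        subpop_freq = np.repeat(anc[:, None], config.n_subpops, axis=1)
    subpop_freq = np.clip(subpop_freq, 0.01, 0.99)

    dosages = np.empty((n, m), dtype=float)
    p_line = subpop_freq[:, labels]                 # n_blocks x n
    for blk in range(n_blocks):
        cols = np.flatnonzero(block_of == blk)
        seed_dose = rng.binomial(2, p_line[blk])
        dosages[:, cols[0]] = seed_dose
        for c in cols[1:]:
            flip = rng.random(n) < config.block_flip_prob
            redraw = rng.binomial(2, p_line[blk])
            dosages[:, c] = np.where(flip, redraw, seed_dose)

    geno = GenotypeMatrix(
        lines=[f"line{i:04d}" for i in range(n)],
        markers=[f"m{j:05d}" for j in range(m)],
        dosages=dosages)
    return geno, labels, block_of


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

def simulate_factor_metabolome(config: SimConfig, geno: GenotypeMatrix,
                               labels=None, block_of=None):
    """Generate Y = F Gamma + s plus the ground truth.

    Per factor, the score is a standardized genetic value (QTL sum or
    genome-wide small effects) mixed with standardized environmental noise
    so the realized heritability matches the target; loadings have an
    exact nonzero count per the requested density.
    """
    config.validate()
    rng = _stage_rng(config, "metabolome")
    n, p, K = config.n_lines, config.n_metabolites, config.n_factors
    W = geno.dosages
    Wc = W - W.mean(axis=0)

    F_scores = np.empty((n, K))
    G_scores = np.empty((n, K))
    qtl_truth = []
    for k in range(K):
        h2 = config.factor_h2[k]
        n_qtl = config.factor_n_qtl[k]
        if h2 > 0:
            if n_qtl is POLYGENIC:
                beta = rng.normal(size=W.shape[1])
                g = Wc @ beta
                qtl_truth.append((np.arange(W.shape[1]), beta))
            else:
                idx = rng.choice(W.shape[1], size=n_qtl, replace=False)
                beta = rng.normal(size=n_qtl)
                g_qtl = Wc[:, idx] @ beta
                if config.qtl_variance_fraction < 1.0:
                    bg = Wc @ rng.normal(size=W.shape[1])
                    g = (np.sqrt(config.qtl_variance_fraction) * _standardize_vec(g_qtl)
                         + np.sqrt(1 - config.qtl_variance_fraction) * _standardize_vec(bg))
                else:
                    g = g_qtl
                qtl_truth.append((idx, beta))
            g = _standardize_vec(g)
            if g.std() == 0:
                raise ValueError(
                    f"factor {k}: requested h2={h2} but genetic value has zero variance")
        else:
            g = np.zeros(n)
            qtl_truth.append((np.array([], dtype=int), np.array([])))
        if h2 == 1.0 and g.std() == 0:
            raise ValueError(f"factor {k}: h2=1 with zero genetic variance")
        eps = _standardize_vec(rng.normal(size=n))
        F_scores[:, k] = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * eps
        G_scores[:, k] = np.sqrt(h2) * g

    # sparse Laplace loadings with exact per-factor density
    Gamma = np.zeros((K, p))
    for k in range(K):
        n_nz = max(1, round(config.factor_density[k] * p))
        nz = rng.choice(p, size=n_nz, replace=False)
        Gamma[k, nz] = rng.laplace(scale=1.0, size=n_nz)

    noise = rng.normal(scale=config.metabolite_noise_sd, size=(n, p))
    y_raw = F_scores @ Gamma + noise

    metab = MetabolomeMatrix(
        lines=list(geno.lines),
        metabolites=[f"c{j:04d}" for j in range(p)],
        values=y_raw).standardize()

    truth = SimTruth(
        true_scores=F_scores, true_genetic_scores=G_scores,
        true_loadings=Gamma, true_qtl=qtl_truth,
        subpop_labels=np.asarray(labels) if labels is not None else np.zeros(n, dtype=int),
        marker_block=(np.asarray(block_of) if block_of is not None
                      else np.zeros(W.shape[1], dtype=int)),
        y_raw=y_raw)
    return metab, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _class_tree(config: SimConfig, rng):
    """Random nested hierarchy: each class at level l+1 has one parent at l.

    Returns per-level class name lists and a leaf -> full path map.
    """
    sizes = config.n_classes_per_level
    names = [[f"L{l + 1}_C{c}" for c in range(sizes[l])] for l in range(5)]
    # reserve readable names for planted level-2 classes
    planted = [cls for _, cls in config.enriched_factor_class_pairs]
    for i, cls in enumerate(dict.fromkeys(planted)):
        if i < len(names[1]):
            names[1][i] = cls
    # permuted round-robin parents: random nesting, but every class at a
    # coarser level is guaranteed at least one descendant leaf
    parents = [None]
    for l in range(1, 5):
        perm = rng.permutation(sizes[l])
        parents.append(perm % sizes[l - 1])
    paths = {}
    for leaf in range(sizes[4]):
        path = [0] * 5
        path[4] = leaf
        for l in range(4, 0, -1):
            path[l - 1] = int(parents[l][path[l]])
        paths[leaf] = tuple(names[l][path[l]] for l in range(5))
    return names, paths


def simulate_annotations(config: SimConfig, true_loadings: np.ndarray,
                         compounds=None) -> AnnotationHierarchy:
    """Annotate a fraction of compounds with nested class paths.

    For each planted (factor, class) pair, the ``enrichment_top_n``
    compounds with the largest |loading| on that factor are routed to
    leaves descending from that class; other annotated compounds get
    random leaves.
    """
    import warnings

    config.validate()
    rng = _stage_rng(config, "annotations")
    p = true_loadings.shape[1]
    if compounds is None:
        compounds = [f"c{j:04d}" for j in range(p)]
    names, paths = _class_tree(config, rng)
    n_annot = round(config.annotated_fraction * p)

    forced: dict[int, tuple] = {}
    for factor, cls in config.enriched_factor_class_pairs:
        leaves = [leaf for leaf, path in paths.items() if path[1] == cls]
        if not leaves:  # cannot happen with non-decreasing level sizes
            raise RuntimeError(f"class {cls!r} has no descendant leaves")
        top = np.argsort(-np.abs(true_loadings[factor]))[:config.enrichment_top_n]
        if len(top) < 5:
            warnings.warn(f"planted class {cls!r} smaller than 5 compounds; "
                          "it will be filtered downstream")
        for j in top:
            forced[int(j)] = paths[int(rng.choice(leaves))]

    pool = [j for j in range(p) if j not in forced]
    n_random = max(0, n_annot - len(forced))
    random_annot = rng.choice(pool, size=min(n_random, len(pool)), replace=False)

    rows = {}
    all_leaves = list(paths)
    for j in range(p):
        if j in forced:
            rows[compounds[j]] = forced[j]
        elif j in set(random_annot.tolist()):
            rows[compounds[j]] = paths[int(rng.choice(all_leaves))]
        else:
            rows[compounds[j]] = ("",) * 5
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=ANNOTATION_LEVELS).loc[compounds]
    return AnnotationHierarchy(table=table)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(config: SimConfig, truth: SimTruth) -> PhenotypeTable:
    """Multi-trial traits genetically coupled to the latent factors.

    Trait genetic value = trait_factor_weights x true factor genetic
    values, standardized; observed value = sqrt(h2) * genetic +
    trial effect + sqrt(1 - h2) * residual, one record per line x trial.
    """
    config.validate()
    rng = _stage_rng(config, "traits")
    Wt = config.weights()
    if Wt.shape[1] != truth.true_genetic_scores.shape[1]:
        raise ValueError("trait_factor_weights reference nonexistent factors")
    n = truth.true_genetic_scores.shape[0]
    gvals = np.empty((n, config.n_traits))
    records = []
    trial_effects = rng.normal(scale=config.trial_effect_sd,
                               size=(config.n_traits, config.n_trials))
    lines = [f"line{i:04d}" for i in range(n)]
    for t in range(config.n_traits):
        g = truth.true_genetic_scores @ Wt[t]
        g = _standardize_vec(g)
        h2 = config.trait_h2[t]
        gvals[:, t] = np.sqrt(h2) * g
        for e in range(config.n_trials):
            resid = rng.normal(size=n) * np.sqrt(1.0 - h2)
            obs = np.sqrt(h2) * g + trial_effects[t, e] + resid
            for i in range(n):
                records.append((lines[i], f"trait{t}", f"trial{e}", obs[i]))
    truth.true_trait_genetic_values = gvals
    truth.trial_effects = trial_effects
    return PhenotypeTable(table=pd.DataFrame(
        records, columns=["line", "trait", "trial", "value"]))


# ---------------------------------------------------------------------------
# bundle + fixtures on disk
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    genotypes: GenotypeMatrix
    subpop_labels: np.ndarray
    metabolome: MetabolomeMatrix
    annotations: AnnotationHierarchy
    phenotypes: PhenotypeTable
    truth: SimTruth


def simulate_all(config: SimConfig | None = None, **overrides) -> SimBundle:
    """Run every generator stage; returns the full bundle with truth."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    config.validate()
    geno, labels, block_of = simulate_genotypes(config)
    metab, truth = simulate_factor_metabolome(config, geno, labels, block_of)
    annot = simulate_annotations(config, truth.true_loadings, metab.metabolites)
    pheno = simulate_traits(config, truth)
    return SimBundle(config=config, genotypes=geno, subpop_labels=labels,
                     metabolome=metab, annotations=annot, phenotypes=pheno,
                     truth=truth)


def write_fixture_set(path, config: SimConfig | None = None, **overrides) -> SimBundle:
    """Write all five inputs plus truth tables under ``path``.

    Files: genotypes.tsv, metabolites.tsv, annotations.tsv, phenotypes.tsv,
    subpops.tsv, truth_scores.tsv, truth_loadings.tsv, truth_qtl.tsv.
    Round-trips losslessly through the readers in :mod:`factormet.io`.
    """
    bundle = simulate_all(config, **overrides)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_genotypes(path / "genotypes.tsv", bundle.genotypes)
    write_metabolites(path / "metabolites.tsv", bundle.metabolome)
    write_annotations(path / "annotations.tsv", bundle.annotations)
    write_phenotypes(path / "phenotypes.tsv", bundle.phenotypes)
    labels = pd.Series(bundle.subpop_labels, index=bundle.genotypes.lines)
    write_subpops(path / "subpops.tsv", labels)
    t = bundle.truth
    pd.DataFrame(t.true_scores, index=bundle.genotypes.lines,
                 columns=[f"factor{k}" for k in range(t.true_scores.shape[1])]) \
        .rename_axis("line").to_csv(path / "truth_scores.tsv", sep="\t")
    pd.DataFrame(t.true_loadings,
                 index=[f"factor{k}" for k in range(t.true_loadings.shape[0])],
                 columns=bundle.metabolome.metabolites) \
        .rename_axis("factor").to_csv(path / "truth_loadings.tsv", sep="\t")
    qtl_rows = [(f"factor{k}", int(j), float(b))
                for k, (idx, beta) in enumerate(t.true_qtl)
                for j, b in zip(idx, beta)]
    pd.DataFrame(qtl_rows, columns=["factor", "marker_index", "effect"]) \
        .to_csv(path / "truth_qtl.tsv", sep="\t", index=False)
    return bundle
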