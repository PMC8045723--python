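"""Readers, writers, and the in-memory containers shared across stages.

On-disk format is tab-delimited text with a header row and a first
identifier column; genotypes may alternatively come from a VCF (dosage =
alternate-allele count).  Line alignment across inputs is always by
identifier, never by row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("factormet")

ANNOTATION_LEVELS = ["level_1", "level_2", "level_3", "level_4", "level_5"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Line x marker allele dosages (0/1/2) with allele frequencies.

    Missing dosages are imputed to the marker mean on read; frequencies
    are recomputed after any subsetting.
    """

    lines: list
    markers: list
    dosages: np.ndarray            # n x m float (imputed values may be fractional)
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.lines), len(self.markers)):
            raise ValueError("dosage matrix shape does not match identifiers")
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency p of the counted allele."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def maf_mask(self, threshold: float) -> np.ndarray:
        return self.maf() > threshold

    def filter_maf(self, threshold: float) -> "GenotypeMatrix":
        keep = self.maf_mask(threshold)
        if not np.any(keep):
            raise ValueError(f"no markers pass MAF threshold {threshold}")
        return self.subset_markers(np.flatnonzero(keep))

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            lines=list(self.lines),
            markers=[self.markers[i] for i in idx],
            dosages=self.dosages[:, idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx])

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        index = {l: i for i, l in enumerate(self.lines)}
        idx = [index[l] for l in line_ids]
        return GenotypeMatrix(
            lines=list(line_ids), markers=list(self.markers),
            dosages=self.dosages[idx], chrom=self.chrom, pos=self.pos)


@dataclass
class MetabolomeMatrix:
    """Line x metabolite matrix of deregressed line values."""

    lines: list
    metabolites: list
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lines), len(self.metabolites)):
            raise ValueError("value matrix shape does not match identifiers")

    def standardize(self) -> "MetabolomeMatrix":
        """Center and scale each metabolite to mean 0, variance 1."""
        sd = self.values.std(axis=0, ddof=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"cannot standardize constant metabolite column "
                f"{self.metabolites[bad[0]]!r}")
        vals = (self.values - self.values.mean(axis=0)) / sd
        return MetabolomeMatrix(list(self.lines), list(self.metabolites),
                                vals, standardized=True)

    def subset_lines(self, line_ids) -> "MetabolomeMatrix":
        index = {l: i for i, l in enumerate(self.lines)}
        idx = [index[l] for l in line_ids]
        return MetabolomeMatrix(list(line_ids), list(self.metabolites),
                                self.values[idx], self.standardized)


@dataclass
class AnnotationHierarchy:
    """Compound -> nested chemical-class labels at five ontology levels.

    ``table`` has one row per compound and columns ``level_1``..``level_5``;
    empty strings mark missing (shallower or absent) annotations.
    Unannotated compounds are present with all-empty paths.
    """

    table: pd.DataFrame

    def __post_init__(self):
        for col in ANNOTATION_LEVELS:
            if col not in self.table.columns:
                self.table[col] = ""
        self.table = self.table[ANNOTATION_LEVELS].fillna("")

    @property
    def compounds(self) -> list:
        return list(self.table.index)

    def is_annotated(self) -> pd.Series:
        return (self.table != "").any(axis=1)

    def classes_at(self, level: int) -> dict[str, set]:
        """Reverse index {class label -> compound set} at a 1-based level."""
        col = ANNOTATION_LEVELS[level - 1]
        out: dict[str, set] = {}
        for compound, label in self.table[col].items():
            if label:
                out.setdefault(label, set()).add(compound)
        return out


@dataclass
class PhenotypeTable:
    """Long-format phenotypes: one record per (line, trait, trial)."""

    table: pd.DataFrame  # columns: line, trait, trial, value

    def __post_init__(self):
        required = ["line", "trait", "trial", "value"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        dup = self.table.duplicated(subset=["line", "trait", "trial"])
        if dup.any():
            bad = self.table[dup].iloc[0]
            raise ValueError(
                f"duplicated phenotype record for line={bad['line']!r} "
                f"trait={bad['trait']!r} trial={bad['trial']!r}")

    def trait(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == name]
        if sub.empty:
            raise KeyError(f"unknown trait {name!r}")
        return sub.reset_index(drop=True)

    @property
    def traits(self) -> list:
        return sorted(self.table["trait"].unique())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})


def read_genotypes(path, maf_threshold: float = 0.05) -> GenotypeMatrix:
    """Read a line x marker dosage table (TSV) or a VCF.

    Missing dosages are imputed to the marker mean; markers failing the
    MAF threshold are dropped.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        geno = _read_vcf(path)
    else:
        df = _read_table(path)
        vals = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            try:
                vals[:, j] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                              & df[col].notna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(
                    f"non-numeric dosage at line {row!r}, marker {col!r}")
        # impute missing to marker mean
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            col_means = np.nanmean(vals, axis=0)
            idx = np.where(np.isnan(vals))
            vals[idx] = col_means[idx[1]]
            log.info("imputed %d missing dosages to marker means", n_missing)
        geno = GenotypeMatrix(lines=list(df.index.astype(str)),
                              markers=list(df.columns), dosages=vals)
    before = len(geno.markers)
    geno = geno.filter_maf(maf_threshold)
    log.info("genotypes: %d lines, %d/%d markers pass MAF > %g",
             len(geno.lines), len(geno.markers), before, maf_threshold)
    return geno


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF genotypes requires cyvcf2") from exc
    vcf = VCF(str(path))
    lines = list(vcf.samples)
    markers, chroms, poss, rows = [], [], [], []
    for var in vcf:
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dose = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append(dose)
    vals = np.asarray(rows).T
    if np.isnan(vals).any():
        col_means = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = col_means[idx[1]]
    return GenotypeMatrix(lines=lines, markers=markers, dosages=vals,
                          chrom=np.asarray(chroms), pos=np.asarray(poss))


def read_metabolites(path, standardize: bool = True) -> MetabolomeMatrix:
    """Read a line x metabolite table of deregressed line values."""
    df = _read_table(path)
    mat = MetabolomeMatrix(lines=list(df.index.astype(str)),
                           metabolites=list(df.columns),
                           values=df.to_numpy(dtype=float))
    if standardize:
        mat = mat.standardize()
    return mat


def read_annotations(path, compounds=None) -> AnnotationHierarchy:
    """Read a compound annotation table (columns level_1..level_5).

    ``compounds``, if given, is the full compound list; entries absent
    from the file are added with empty paths, and file entries not in the
    list trigger a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.astype(str)
    if compounds is not None:
        unknown = set(df.index) - set(compounds)
        if unknown:
            log.warning("annotations for %d unknown compounds ignored", len(unknown))
            df = df.loc[[c for c in df.index if c in set(compounds)]]
        df = df.reindex(compounds, fill_value="")
    return AnnotationHierarchy(table=df)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "trait": str, "trial": str})
    return PhenotypeTable(table=df)


def read_subpops(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return df.iloc[:, 0]


# ---------------------------------------------------------------------------
# writers (used by the fixture generator and the pipeline)
# ---------------------------------------------------------------------------

def write_genotypes(path, geno: GenotypeMatrix):
    df = pd.DataFrame(geno.dosages, index=geno.lines, columns=geno.markers)
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def write_metabolites(path, metab: MetabolomeMatrix):
    df = pd.DataFrame(metab.values, index=metab.lines, columns=metab.metabolites)
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def write_annotations(path, hierarchy: AnnotationHierarchy):
    df = hierarchy.table.copy()
    df.index.name = "compound"
    df.to_csv(path, sep="\t")


def write_phenotypes(path, pheno: PhenotypeTable):
    pheno.table.to_csv(path, sep="\t", index=False)


def write_subpops(path, labels: pd.Series):
    df = labels.rename("subpop").to_frame()
    df.index.name = "line"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_lines(geno: GenotypeMatrix, metab: MetabolomeMatrix):
    """Intersect and order lines by identifier across genotypes and
    metabolome; returns the two subset objects."""
    common = [l for l in geno.lines if l in set(metab.lines)]
    if len(common) < 2:
        raise ValueError(f"only {len(common)} overlapping lines between "
                         "genotypes and metabolome")
    if len(common) < len(geno.lines) or len(common) < len(metab.lines):
        log.info("aligned %d common lines (genotypes %d, metabolome %d)",
                 len(common), len(geno.lines), len(metab.lines))
    return geno.subset_lines(common), metab.subset_lines(common)
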