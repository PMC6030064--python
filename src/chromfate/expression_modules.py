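"""Transcriptional-module identification from time-course RPKM matrices.

Genes with more than a 1.5-fold change relative to a reference sample are
clustered by Ward.D2 agglomerative linkage on Euclidean distances between
log2-transformed RPKM profiles, and flat modules are cut at a dendrogram
height (default 20).  Module-level WT-vs-KO differences are flagged when
the mean member expression changes by more than 1.25-fold and a paired
two-sided t-test across member genes gives p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionMatrix",
    "ModuleAssignment",
    "filter_dynamic_genes",
    "cluster_modules",
    "module_profiles",
    "module_significance",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM matrix with per-sample metadata.

    ``values``: DataFrame indexed by gene id, one column per sample (>= 0).
    ``samples``: DataFrame with columns ``sample``, ``condition`` (WT/KO)
    and ``timepoint``, one row per column of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be >= 0")
        if self.samples["sample"].duplicated().any():
            raise ValueError("sample labels must be unique")
        missing = set(self.values.columns) - set(self.samples["sample"])
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples)

    def columns_for(self, condition: str, timepoint: str) -> List[str]:
        sel = self.samples[
            (self.samples["condition"] == condition)
            & (self.samples["timepoint"] == timepoint)
        ]
        return sel["sample"].tolist()

    @classmethod
    def read_tables(cls, matrix_path, sheet_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        samples = pd.read_csv(sheet_path, sep="\t", dtype=str)
        return cls(values, samples)

    def write_tables(self, matrix_path, sheet_path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.samples.to_csv(sheet_path, sep="\t", index=False)


@dataclass
class ModuleAssignment:
    """Gene -> module id (positive integers) from one dendrogram cut."""

    labels: pd.Series
    height: float

    def members(self, module: int) -> List[str]:
        return self.labels[self.labels == module].index.tolist()

    @property
    def module_ids(self) -> List[int]:
        return sorted(self.labels.unique())


def filter_dynamic_genes(
    m: ExpressionMatrix,
    reference_sample: str,
    fold: float = 1.5,
    pseudocount: float = 1.0,
) -> List[str]:
    """Genes changing more than ``fold`` relative to the reference sample.

    A gene is kept when for some sample ``(rpkm_s + pc) / (rpkm_ref + pc)``
    exceeds ``fold`` or falls below ``1/fold``.  Constant genes are dropped.
    """
    if reference_sample not in m.values.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    ref = m.values[reference_sample] + pseudocount
    ratios = m.values.add(pseudocount).div(ref, axis=0)
    dynamic = ((ratios > fold) | (ratios < 1.0 / fold)).any(axis=1)
    return m.values.index[dynamic].tolist()


def cluster_modules(
    m: ExpressionMatrix,
    height: float = 20.0,
    pseudocount: float = 1.0,
) -> ModuleAssignment:
    """Ward.D2 hierarchical clustering of log2 expression profiles.

    Euclidean distances on ``log2(rpkm + pc)``, agglomerated with the
    Ward criterion on squared distances (scipy's ``ward`` on Euclidean
    input, the Ward.D2 variant), cut at ``height``.  Deterministic given
    the input; equal-linkage ties merge the lowest-index pair (scipy's
    tie-break).  Module ids are renumbered 1..k in order of first gene
    appearance so labels do not depend on dendrogram internals.
    """
    if len(m.values) < 2:
        raise ValueError("need >= 2 genes to cluster")
    log2 = np.log2(m.values.to_numpy(dtype=float) + pseudocount)
    z = linkage(pdist(log2, metric="euclidean"), method="ward")
    flat = fcluster(z, t=height, criterion="distance")
    # stable relabeling: module 1 = module of the first gene, etc.
    remap: Dict[int, int] = {}
    labels = np.empty(len(flat), dtype=int)
    for i, raw in enumerate(flat):
        if raw not in remap:
            remap[raw] = len(remap) + 1
        labels[i] = remap[raw]
    return ModuleAssignment(
        labels=pd.Series(labels, index=m.values.index, name="module"),
        height=height,
    )


def module_profiles(
    assign: ModuleAssignment,
    m: ExpressionMatrix,
    reference_sample: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-module mean relative expression (to the reference sample) +/- SEM.

    Per gene, relative expression is ``(rpkm + pc) / (rpkm_ref + pc)``; the
    module profile is the mean and standard error across member genes at
    each sample.  SEM of a single-gene module is reported missing.
    """
    if not set(m.values.index).issubset(set(assign.labels.index)):
        raise ValueError("assignment does not cover all matrix genes")
    ref = m.values[reference_sample] + pseudocount
    rel = m.values.add(pseudocount).div(ref, axis=0)
    rows = []
    for module in assign.module_ids:
        genes = [g for g in assign.members(module) if g in rel.index]
        sub = rel.loc[genes]
        mean = sub.mean(axis=0)
        sem = (
            sub.std(axis=0, ddof=1) / np.sqrt(len(sub))
            if len(sub) > 1
            else pd.Series(np.nan, index=rel.columns)
        )
        for sample in rel.columns:
            rows.append((module, len(genes), sample, mean[sample], sem[sample]))
    return pd.DataFrame(
        rows, columns=["module", "n_genes", "sample", "mean_relative", "sem"]
    )


def module_significance(
    assign: ModuleAssignment,
    m: ExpressionMatrix,
    fold: float = 1.25,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Flag module/timepoint pairs with a WT-vs-KO expression difference.

    At each timepoint present in both conditions, a module is flagged when
    the ratio of mean member expression (KO over WT, pseudocount applied)
    exceeds ``fold`` or falls below ``1/fold`` AND a two-sided t-test across
    member genes, paired by gene, gives p < ``alpha``.  Modules with < 2
    genes get a missing flag.  Replicate samples within a condition and
    timepoint are averaged per gene first.
    """
    timepoints = [
        t
        for t in pd.unique(m.samples["timepoint"])
        if m.columns_for("WT", t) and m.columns_for("KO", t)
    ]
    rows = []
    for module in assign.module_ids:
        genes = [g for g in assign.members(module) if g in m.values.index]
        for t in timepoints:
            wt = m.values.loc[genes, m.columns_for("WT", t)].mean(axis=1)
            ko = m.values.loc[genes, m.columns_for("KO", t)].mean(axis=1)
            if len(genes) < 2:
                rows.append((module, t, len(genes), np.nan, np.nan, None))
                continue
            ratio = (ko.mean() + pseudocount) / (wt.mean() + pseudocount)
            diff = ko - wt
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.ttest_rel(ko, wt).pvalue)
            flagged = bool((ratio > fold or ratio < 1.0 / fold) and p < alpha)
            rows.append((module, t, len(genes), float(ratio), p, flagged))
    return pd.DataFrame(
        rows,
        columns=["module", "timepoint", "n_genes", "ko_wt_ratio", "p_value", "flagged"],
    )
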