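"""Four-state promoter classification and WT->KO transition analysis.

A promoter carries a mark when log2(mark/input) > 1 and the BH-adjusted
Poisson p-value is < 0.05, with H3K4me3 counted in TSS +/- 2 kb and
H3K27me3 in TSS +/- 5 kb.  The two presence flags define four states:
active (K4 only), bivalent (both), repressive (K27 only), no_mark
(neither).  Transition tables count genes by (WT state, KO state); the
retention rate of a state is its diagonal fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BinnedTrack, FragmentSet, TssAnnotation
from .enrichment import DEFAULT_PSEUDOCOUNT_CPM, bh_adjust

__all__ = [
    "MARK_HALFWIDTH",
    "STATES",
    "quantify_promoters",
    "classify_promoter",
    "classify_states",
    "transition_table",
    "TransitionTable",
    "signal_by_class",
]

#: Mark-specific promoter window halfwidths (bp around the TSS).
MARK_HALFWIDTH: Dict[str, int] = {"H3K4me3": 2_000, "H3K27me3": 5_000}

#: Canonical state order used by every table.
STATES = ["active", "bivalent", "repressive", "no_mark"]


def quantify_promoters(
    chip: FragmentSet,
    input_: FragmentSet,
    tss: TssAnnotation,
    mark: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
    alpha: float = 0.05,
    log2_threshold: float = 1.0,
    halfwidth: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene mark quantification and presence call.

    Counts ChIP and input fragments (midpoint rule) in the mark-specific
    symmetric TSS window, tests the ChIP count against the input-implied
    Poisson rate, BH-adjusts across all promoters of the mark, and flags
    ``present`` when both the fold and FDR gates pass.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS annotation")
    if halfwidth is None:
        try:
            halfwidth = MARK_HALFWIDTH[mark]
        except KeyError:
            raise ValueError(
                f"unknown mark {mark!r}; pass halfwidth= explicitly"
            ) from None
    win = tss.windows(halfwidth)
    chip_counts = chip.count_windows(win)
    input_counts = input_.count_windows(win)
    chip_cpm = chip_counts / chip.library_size * 1e6
    input_cpm = input_counts / input_.library_size * 1e6
    lam = (input_cpm + pseudocount) * chip.library_size / 1e6
    p = stats.poisson.sf(chip_counts - 1, lam)
    q = bh_adjust(p)
    log2_ratio = np.log2((chip_cpm + pseudocount) / (input_cpm + pseudocount))
    out = win[["gene_id", "chrom", "start", "end"]].copy()
    out["mark"] = mark
    out["chip_count"] = chip_counts
    out["input_count"] = input_counts
    out["chip_cpm"] = chip_cpm
    out["input_cpm"] = input_cpm
    out["log2_ratio"] = log2_ratio
    out["p_value"] = p
    out["q_value"] = q
    out["present"] = (log2_ratio > log2_threshold) & (q < alpha)
    return out


def classify_promoter(k4_present: bool, k27_present: bool) -> str:
    """Map the two presence flags to the four-state vocabulary."""
    if k4_present:
        return "bivalent" if k27_present else "active"
    return "repressive" if k27_present else "no_mark"


def classify_states(k4: pd.DataFrame, k27: pd.DataFrame) -> pd.Series:
    """Combine per-mark quantification tables into a per-gene state series.

    Both tables must cover the same gene universe (the TSS annotation).
    """
    k4_flags = k4.set_index("gene_id")["present"]
    k27_flags = k27.set_index("gene_id")["present"]
    if set(k4_flags.index) != set(k27_flags.index):
        raise ValueError("K4 and K27 tables cover different gene universes")
    k27_flags = k27_flags.reindex(k4_flags.index)
    states = np.where(
        k4_flags.to_numpy(),
        np.where(k27_flags.to_numpy(), "bivalent", "active"),
        np.where(k27_flags.to_numpy(), "repressive", "no_mark"),
    )
    return pd.Series(states, index=k4_flags.index, name="state")


@dataclass
class TransitionTable:
    """4x4 WT->KO state-transition counts with derived summaries.

    ``row_percent`` gives each WT row as percentages summing to 100;
    ``retention`` is the diagonal fraction per WT state, NaN for an empty
    WT class (0/0 is reported as missing, never 0).
    """

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    retention: pd.Series

    @property
    def n_genes(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_table(states_wt: pd.Series, states_ko: pd.Series) -> TransitionTable:
    """Cross-tabulate per-gene promoter states between two conditions."""
    only_wt = set(states_wt.index) - set(states_ko.index)
    only_ko = set(states_ko.index) - set(states_wt.index)
    if only_wt or only_ko:
        offenders = sorted(only_wt | only_ko)
        raise ValueError(
            f"gene universes differ between conditions: {offenders[:10]}"
        )
    states_ko = states_ko.reindex(states_wt.index)
    counts = (
        pd.crosstab(states_wt, states_ko)
        .reindex(index=STATES, columns=STATES, fill_value=0)
        .astype(int)
    )
    counts.index.name = "wt_state"
    counts.columns.name = "ko_state"
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_percent = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
        retention = pd.Series(
            np.diag(counts) / row_sums.replace(0, np.nan).to_numpy(),
            index=counts.index,
            name="retention",
        )
    return TransitionTable(counts=counts, row_percent=row_percent, retention=retention)


def signal_by_class(
    track: BinnedTrack,
    states: pd.Series,
    tss: TssAnnotation,
    halfwidth: int = 2_000,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Mean track signal around the TSS per promoter state, with Welch tests.

    For each gene, the signal is the mean normalized bin value over
    TSS +/- ``halfwidth``; per-class means are compared pairwise with a
    two-sided Welch t-test.  Pairs with a class of < 2 members or zero
    variance are skipped with a warning (p reported NaN).
    """
    tss_df = tss.df.set_index("gene_id")
    per_gene = {}
    for gene_id, state in states.items():
        row = tss_df.loc[gene_id]
        start = max(int(row["tss"]) - halfwidth, 0)
        end = int(row["tss"]) + halfwidth
        per_gene[gene_id] = track.mean_in(str(row["chrom"]), start, end)
    sig = pd.Series(per_gene, name="signal")
    by_class = {s: sig[states[states == s].index].dropna() for s in STATES}
    means = pd.Series(
        {s: (v.mean() if len(v) else np.nan) for s, v in by_class.items()},
        name="mean_signal",
    )
    rows = []
    for a, b in combinations(STATES, 2):
        va, vb = by_class[a], by_class[b]
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"class pair ({a}, {b}) skipped: <2 members")
            rows.append((a, b, len(va), len(vb), np.nan, np.nan))
            continue
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            warnings.warn(f"class pair ({a}, {b}) skipped: zero variance")
            rows.append((a, b, len(va), len(vb), np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append((a, b, len(va), len(vb), float(t), float(p)))
    tests = pd.DataFrame(
        rows, columns=["class_a", "class_b", "n_a", "n_b", "t_stat", "p_value"]
    )
    return means, tests
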