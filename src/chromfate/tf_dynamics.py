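"""Condition-specific peak comparison, Oct4 binding-fate calls, and ATAC tests.

Two peaks are "overlapping" when at most 100 bases separate them edge to
edge (gap <= 100, with gap 0 for genuinely intersecting intervals).  A
WT-specific Oct4 peak that gains a KO-specific Sox2 and/or Nanog peak
within that distance is a replacement event; one that gains nothing is a
loss.  ATAC accessibility uses only sub-nucleosomal fragments (< 150 bp)
and compares per-million-normalized in-peak counts between conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FragmentSet, GenomicInterval, TssAnnotation

__all__ = [
    "PeakSet",
    "FateCall",
    "PeakSetComparison",
    "FATES",
    "interval_gap",
    "compare_peak_sets",
    "classify_oct4_fate",
    "nearest_tss",
    "filter_fragments_by_size",
    "signal_in_peaks_test",
]

FATES = ["loss", "Sox2_replacement", "Nanog_replacement", "Sox2_Nanog_replacement"]


@dataclass
class PeakSet:
    """Peaks of one factor in one condition (called upstream, e.g. by MACS)."""

    factor: str
    condition: str
    peaks: List[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class FateCall:
    peak: GenomicInterval
    fate: str
    target_gene: str = "NA"


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge distance in bp: 0 when overlapping, +inf across chromosomes.

    For disjoint same-chromosome intervals this is the number of bases
    strictly between them (``later.start - earlier.end``).
    """
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def _sorted_arrays(peaks: Sequence[GenomicInterval]) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for chrom, rows in by_chrom.items():
        arr = np.array(sorted(rows), dtype=np.int64)
        out[chrom] = np.column_stack([arr[:, 0], np.maximum.accumulate(arr[:, 1])])
    return out


def _has_neighbor(
    idx: Dict[str, np.ndarray], peak: GenomicInterval, tol: int
) -> bool:
    """True when some indexed interval is within ``tol`` bp of ``peak``."""
    arr = idx.get(peak.chrom)
    if arr is None:
        return False
    # candidates: start <= peak.end + tol and (running max) end >= peak.start - tol
    j = np.searchsorted(arr[:, 0], peak.end + tol, side="right")
    return j > 0 and bool(arr[j - 1, 1] >= peak.start - tol)


@dataclass
class PeakSetComparison:
    a_specific: PeakSet
    b_specific: PeakSet
    a_shared: PeakSet
    b_shared: PeakSet

    @property
    def shared_pairs(self) -> Tuple[int, int]:
        """(shared-in-a, shared-in-b) counts; a Venn overlap has two sides."""
        return len(self.a_shared), len(self.b_shared)


def compare_peak_sets(a: PeakSet, b: PeakSet, tol: int = 100) -> PeakSetComparison:
    """Split two peak sets into shared and condition-specific peaks.

    A peak of ``a`` is shared iff some peak of ``b`` lies within ``tol`` bp
    (edge gap), and symmetrically for ``b``; each peak is classified exactly
    once, against the full other set (no one-to-one matching is forced).
    """
    idx_a, idx_b = _sorted_arrays(a.peaks), _sorted_arrays(b.peaks)
    a_spec, a_sh = [], []
    for p in a.peaks:
        (a_sh if _has_neighbor(idx_b, p, tol) else a_spec).append(p)
    b_spec, b_sh = [], []
    for p in b.peaks:
        (b_sh if _has_neighbor(idx_a, p, tol) else b_spec).append(p)
    mk = lambda peaks, which: PeakSet(a.factor if which == "a" else b.factor,
                                      a.condition if which == "a" else b.condition,
                                      peaks)
    return PeakSetComparison(
        a_specific=mk(a_spec, "a"),
        b_specific=mk(b_spec, "b"),
        a_shared=mk(a_sh, "a"),
        b_shared=mk(b_sh, "b"),
    )


def classify_oct4_fate(
    oct4_wt_specific: PeakSet,
    sox2_ko_specific: PeakSet,
    nanog_ko_specific: PeakSet,
    tol: int = 100,
    tss: Optional[TssAnnotation] = None,
) -> Tuple[List[FateCall], pd.Series]:
    """Assign each WT-specific Oct4 peak a loss/replacement fate.

    Overlap (gap <= ``tol``) with a KO-specific Sox2 peak only gives
    Sox2_replacement; Nanog only, Nanog_replacement; both,
    Sox2_Nanog_replacement; neither, loss.  Fate fractions sum to 1 over
    all input peaks.  When a TSS annotation is given, each peak is also
    assigned its nearest gene.
    """
    if len(oct4_wt_specific) == 0:
        warnings.warn("empty WT-specific Oct4 peak set: no fates to call")
        return [], pd.Series(0.0, index=FATES, name="fraction")
    idx_sox2 = _sorted_arrays(sox2_ko_specific.peaks)
    idx_nanog = _sorted_arrays(nanog_ko_specific.peaks)
    calls: List[FateCall] = []
    for peak in oct4_wt_specific.peaks:
        s = _has_neighbor(idx_sox2, peak, tol)
        n = _has_neighbor(idx_nanog, peak, tol)
        if s and n:
            fate = "Sox2_Nanog_replacement"
        elif s:
            fate = "Sox2_replacement"
        elif n:
            fate = "Nanog_replacement"
        else:
            fate = "loss"
        target = nearest_tss(peak, tss) if tss is not None else "NA"
        calls.append(FateCall(peak=peak, fate=fate, target_gene=target))
    counts = pd.Series([c.fate for c in calls]).value_counts()
    fractions = counts.reindex(FATES, fill_value=0) / len(calls)
    fractions.name = "fraction"
    return calls, fractions


def nearest_tss(peak: GenomicInterval, tss: TssAnnotation) -> str:
    """Gene whose TSS is closest to the peak midpoint; ties break to the
    lexicographically smallest gene id; "NA" when the chromosome has none."""
    sub = tss.df[tss.df["chrom"] == peak.chrom]
    if not len(sub):
        return "NA"
    dist = (sub["tss"] - peak.midpoint).abs()
    best = dist.min()
    return str(sub.loc[dist == best, "gene_id"].min())


def filter_fragments_by_size(fragments: FragmentSet, max_bp: int = 150) -> FragmentSet:
    """Keep fragments strictly shorter than ``max_bp`` (sub-nucleosomal).

    A fragment of exactly ``max_bp`` is removed; the library size of the
    result is the retained count.
    """
    sizes = fragments.df["end"] - fragments.df["start"]
    kept = fragments.df.loc[sizes < max_bp]
    return FragmentSet(fragments.library_id, kept)


def signal_in_peaks_test(
    wt: FragmentSet,
    ko: FragmentSet,
    peaks: PeakSet,
    pseudocount: float = 0.5,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Compare normalized in-peak signal between conditions.

    Per peak: CPM-normalized WT and KO midpoint counts and
    ``log2((ko_cpm + pc) / (wt_cpm + pc))``.  The summary is a two-sided
    paired t-test of the per-peak log2 ratios against 0 (the quantities are
    measured on the same regions), plus the mean log2 ratio.  Identical
    inputs yield zero ratios everywhere; the degenerate test is reported as
    p = 1 with a zero-variance flag.
    """
    if len(peaks) < 2:
        raise ValueError("need >= 2 peaks for the in-peak comparison")
    if len(peaks) == 2:
        warnings.warn("only 2 peaks: the paired t-test will have minimal power")
    win = pd.DataFrame(
        [(p.chrom, p.start, p.end) for p in peaks.peaks],
        columns=["chrom", "start", "end"],
    )
    wt_counts = wt.count_windows(win)
    ko_counts = ko.count_windows(win)
    wt_cpm = wt_counts / wt.library_size * 1e6
    ko_cpm = ko_counts / ko.library_size * 1e6
    log2_ratio = np.log2((ko_cpm + pseudocount) / (wt_cpm + pseudocount))
    table = win.copy()
    table["wt_count"] = wt_counts
    table["ko_count"] = ko_counts
    table["wt_cpm"] = wt_cpm
    table["ko_cpm"] = ko_cpm
    table["log2_ratio"] = log2_ratio
    zero_variance = bool(np.allclose(log2_ratio, log2_ratio[0]))
    if zero_variance:
        t_stat, p_value = float("nan"), 1.0
    else:
        t_stat, p_value = stats.ttest_1samp(log2_ratio, popmean=0.0)
        t_stat, p_value = float(t_stat), float(p_value)
    summary = {
        "n_peaks": float(len(peaks)),
        "mean_log2_ratio": float(log2_ratio.mean()),
        "t_stat": t_stat,
        "p_value": p_value,
        "zero_variance": float(zero_variance),
    }
    return table, summary
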