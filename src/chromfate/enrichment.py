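"""Poisson ChIP-vs-input enrichment testing and sliding-window region calling.

The statistical core: a window is enriched when the ChIP library shows more
than a ``fold`` (default 2) difference over the depth-normalized input and
the Benjamini-Hochberg adjusted Poisson p-value is below ``alpha`` (default
0.05), evaluated in 10-kb sliding windows.  The expected ChIP count under
the null is the input CPM (plus a pseudocount) rescaled to the ChIP library
depth; depletion is the mirror-image test of input against the ChIP-implied
rate, so swapping the two libraries exactly exchanges the two output sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountPair, FragmentSet, GenomicInterval, TssAnnotation, cpm_normalize

__all__ = [
    "WindowTest",
    "RegionCallSet",
    "poisson_upper_pvalue",
    "bh_adjust",
    "test_window",
    "call_differential_windows",
    "annotate_regions",
    "DEFAULT_PSEUDOCOUNT_CPM",
]

#: CPM pseudocount added to both libraries before ratios and null rates.
DEFAULT_PSEUDOCOUNT_CPM = 0.5


def poisson_upper_pvalue(k, lam) -> float:
    """Upper-tail Poisson probability ``P(X >= k)`` for ``X ~ Poisson(lam)``.

    Equals ``1 - CDF(k - 1; lam)`` and is 1.0 at ``k = 0`` (the whole
    support).  ``lam`` must be positive — apply a pseudocount upstream.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be > 0 (apply a pseudocount first)")
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer):
        if np.any(k_arr < 0) or np.any(k_arr != np.floor(k_arr)):
            raise ValueError("k must be a non-negative integer")
        k_arr = k_arr.astype(np.int64)
    p = stats.poisson.sf(k_arr - 1, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(p)
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, ``q_(i) = min_{j >= i} p_(j) * n / j`` clipped at 1,
    returned in the input order.  Output is monotone non-decreasing along
    the sorted-p order and ``q >= p`` elementwise.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = q_sorted
    return out


@dataclass
class WindowTest:
    """Two-directional Poisson test result for one window.

    ``p_enrich``/``q_enrich`` test ChIP against the input-implied rate;
    ``p_deplete``/``q_deplete`` the mirror image.  ``call`` is one of
    ``enriched``/``depleted``/``none`` after the fold gate and FDR gate.
    """

    region: GenomicInterval
    chip_cpm: float
    input_cpm: float
    log2_ratio: float
    p_enrich: float
    p_deplete: float
    q_enrich: float = math.nan
    q_deplete: float = math.nan
    call: str = "none"

    @property
    def p_value(self) -> float:
        return min(self.p_enrich, self.p_deplete)

    @property
    def q_value(self) -> float:
        qs = [q for q in (self.q_enrich, self.q_deplete) if not math.isnan(q)]
        return min(qs) if qs else math.nan


def test_window(pair: CountPair, pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM) -> WindowTest:
    """Poisson enrichment/depletion test for a single window.

    The null ChIP rate is ``(input_cpm + pseudocount)`` rescaled to the ChIP
    depth; the depletion direction rescales the ChIP CPM to input depth.
    q-values are left NaN — fill them with :func:`bh_adjust` across all
    windows of a run.
    """
    chip_cpm = float(cpm_normalize(pair.chip_count, pair.chip_libsize))
    input_cpm = float(cpm_normalize(pair.input_count, pair.input_libsize))
    lam_chip = (input_cpm + pseudocount) * pair.chip_libsize / 1e6
    lam_input = (chip_cpm + pseudocount) * pair.input_libsize / 1e6
    return WindowTest(
        region=pair.region,
        chip_cpm=chip_cpm,
        input_cpm=input_cpm,
        log2_ratio=float(
            np.log2((chip_cpm + pseudocount) / (input_cpm + pseudocount))
        ),
        p_enrich=poisson_upper_pvalue(pair.chip_count, lam_chip),
        p_deplete=poisson_upper_pvalue(pair.input_count, lam_input),
    )


@dataclass
class RegionCallSet:
    """Merged enriched/depleted regions plus the per-window test table."""

    enriched: List[GenomicInterval]
    depleted: List[GenomicInterval]
    window_bp: int = 10_000
    step_bp: int = 2_000
    alpha: float = 0.05
    fold: float = 2.0
    windows: Optional[pd.DataFrame] = field(default=None, repr=False)


def _tile_windows(chrom_sizes: Mapping[str, int], window_bp: int, step_bp: int) -> pd.DataFrame:
    rows = []
    for chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        starts = np.arange(0, size, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, size)
        keep = ends > starts
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep]})
        )
    return pd.concat(rows, ignore_index=True)


def _direction_scores(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: int,
    lib_b: int,
    pseudocount: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log2 ratio (a over b), raw p and BH q for 'a enriched over b'."""
    cpm_a = counts_a / lib_a * 1e6 + pseudocount
    cpm_b = counts_b / lib_b * 1e6 + pseudocount
    log2_ratio = np.log2(cpm_a / cpm_b)
    lam = cpm_b * lib_a / 1e6
    p = stats.poisson.sf(counts_a - 1, lam)
    return log2_ratio, p, bh_adjust(p)


def _merge_sig_windows(win: pd.DataFrame, sig: np.ndarray) -> List[Tuple[str, int, int]]:
    """Union of significant windows, merged when overlapping or adjacent."""
    merged: List[Tuple[str, int, int]] = []
    sub = win.loc[sig].sort_values(["chrom", "start"])
    for chrom, grp in sub.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, int(cur_s), int(cur_e)))
    return merged


def _refine_region(
    chrom: str,
    start: int,
    end: int,
    frag_a: FragmentSet,
    frag_b: FragmentSet,
    lib_a: int,
    lib_b: int,
    step_bp: int,
    window_bp: int,
    fold: float,
    alpha: float,
    pseudocount: float,
) -> Optional[GenomicInterval]:
    """Trim a merged candidate to the fine bins that carry the signal.

    A window-level test localizes a region only to within the window width;
    inside each candidate the per-bin rates are far apart (8x vs 1x in the
    planted regime), so the boundary is recovered at quarter-step bins.
    Per bin, the null rate comes from the comparison library smoothed over
    a full window centered on the bin (a bin-sized input count is too noisy
    a denominator), with a half-fragment pseudocount; the bin passes on the
    fold gate plus a Poisson test at a Bonferroni-corrected level (``alpha``
    over the candidate's bin count, controlling spurious boundary
    extension).  The refined region is the longest consecutive run of
    passing bins, so an isolated noise bin cannot stretch the span.
    """
    refine_bp = max(step_bp // 4, 1)
    starts = np.arange(start, end, refine_bp, dtype=np.int64)
    ends = np.minimum(starts + refine_bp, end)
    mids = (starts + ends) // 2
    half = window_bp // 2
    smooth_lo = np.maximum(mids - half, 0)
    smooth_hi = mids + half
    ca = frag_a.count_in(chrom, starts, ends)
    cb_win = frag_b.count_in(chrom, smooth_lo, smooth_hi)
    widths = (smooth_hi - smooth_lo).astype(float)
    rate_a = (ca + 0.5) / lib_a
    rate_b = (cb_win * (ends - starts) / widths + 0.5) / lib_b
    lam = rate_b * lib_a
    p = stats.poisson.sf(ca - 1, lam)
    keep = (rate_a > fold * rate_b) & (p < alpha / max(len(starts), 1))
    if not keep.any():
        return None
    # longest consecutive run of passing bins (first on ties)
    best_len = best_start = cur_len = 0
    cur_start = -1
    for i, k in enumerate(keep):
        if k:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    i0, i1 = best_start, best_start + best_len - 1
    return GenomicInterval(chrom, int(starts[i0]), int(ends[i1]))


def _call_one_direction(
    frag_a: FragmentSet,
    frag_b: FragmentSet,
    win: pd.DataFrame,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    step_bp: int,
    window_bp: int,
    fold: float,
    alpha: float,
    pseudocount: float,
) -> Tuple[List[GenomicInterval], np.ndarray, np.ndarray, np.ndarray]:
    lib_a, lib_b = frag_a.library_size, frag_b.library_size
    log2_ratio, p, q = _direction_scores(counts_a, counts_b, lib_a, lib_b, pseudocount)
    sig = (log2_ratio > np.log2(fold)) & (q < alpha)
    regions: List[GenomicInterval] = []
    for chrom, s, e in _merge_sig_windows(win, sig):
        refined = _refine_region(
            chrom, s, e, frag_a, frag_b, lib_a, lib_b, step_bp, window_bp,
            fold, alpha, pseudocount,
        )
        if refined is not None:
            regions.append(refined)
    return regions, log2_ratio, p, q


def call_differential_windows(
    chip: FragmentSet,
    input_: FragmentSet,
    chrom_sizes: Mapping[str, int],
    window_bp: int = 10_000,
    step_bp: Optional[int] = None,
    fold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> RegionCallSet:
    """Call ChIP-enriched and ChIP-depleted regions by sliding window.

    Windows of ``window_bp`` tile each chromosome at ``step_bp`` (default
    ``window_bp // 5``); each is Poisson-tested in both directions with BH
    correction applied per direction across all windows; significant windows
    passing the fold gate are merged and their boundaries refined at step
    resolution.  Depletion is literally the enrichment call with the two
    libraries swapped, so ``call_differential_windows(b, a)`` exactly
    exchanges the two output sets.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step_bp = step_bp if step_bp is not None else max(window_bp // 5, 1)
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    if chip.library_size == 0 or input_.library_size == 0:
        raise ValueError("both libraries must be non-empty")

    win = _tile_windows(chrom_sizes, window_bp, step_bp)
    counts_chip = chip.count_windows(win)
    counts_input = input_.count_windows(win)

    enriched, l2r, p_enr, q_enr = _call_one_direction(
        chip, input_, win, counts_chip, counts_input, step_bp, window_bp, fold,
        alpha, pseudocount,
    )
    depleted, _, p_dep, q_dep = _call_one_direction(
        input_, chip, win, counts_input, counts_chip, step_bp, window_bp, fold,
        alpha, pseudocount,
    )

    table = win.copy()
    table["chip_count"] = counts_chip
    table["input_count"] = counts_input
    table["log2_ratio"] = l2r
    table["p_enrich"] = p_enr
    table["q_enrich"] = q_enr
    table["p_deplete"] = p_dep
    table["q_deplete"] = q_dep
    call = np.where(
        (l2r > np.log2(fold)) & (q_enr < alpha),
        "enriched",
        np.where((-l2r > np.log2(fold)) & (q_dep < alpha), "depleted", "none"),
    )
    table["call"] = call
    return RegionCallSet(
        enriched=enriched,
        depleted=depleted,
        window_bp=window_bp,
        step_bp=step_bp,
        alpha=alpha,
        fold=fold,
        windows=table,
    )


def annotate_regions(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    tss: TssAnnotation,
    promoter_halfwidth: int = 2_000,
) -> Tuple[List[str], pd.DataFrame]:
    """Label each region promoter / gene_body / intergenic.

    Precedence: a region overlapping any TSS +/- ``promoter_halfwidth``
    window is a promoter region; otherwise overlapping a gene body makes it
    genic; otherwise intergenic.  Returns the per-region labels and a
    summary with counts and fractions (fractions sum to 1).
    """
    prom_windows = tss.windows(promoter_halfwidth)
    prom_by_chrom: Dict[str, np.ndarray] = {}
    for chrom, sub in prom_windows.groupby("chrom", sort=False):
        arr = np.stack(
            [sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)], axis=1
        )
        prom_by_chrom[str(chrom)] = arr[np.argsort(arr[:, 0])]
    gene_by_chrom: Dict[str, np.ndarray] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))  # type: ignore[arg-type]
    gene_by_chrom = {
        c: np.array(sorted(v), dtype=np.int64) for c, v in gene_by_chrom.items()
    }

    def _hits(arr: Optional[np.ndarray], start: int, end: int) -> bool:
        if arr is None or not len(arr):
            return False
        # sorted by start with running max of end handles nesting
        run_max = np.maximum.accumulate(arr[:, 1])
        idx = np.searchsorted(arr[:, 0], end, side="left")
        return idx > 0 and bool(run_max[idx - 1] > start)

    labels: List[str] = []
    for r in regions:
        if _hits(prom_by_chrom.get(r.chrom), r.start, r.end):
            labels.append("promoter")
        elif _hits(gene_by_chrom.get(r.chrom), r.start, r.end):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    counts = pd.Series(labels).value_counts()
    summary = pd.DataFrame(
        {
            "category": ["promoter", "gene_body", "intergenic"],
        }
    )
    summary["count"] = summary["category"].map(counts).fillna(0).astype(int)
    total = max(summary["count"].sum(), 1)
    summary["fraction"] = summary["count"] / total
    return labels, summary
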