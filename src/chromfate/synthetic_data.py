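"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis stages consume can be generated here: Poisson
window counts with state-dependent ChIP enrichment over input, planted
differentially-enriched regions, condition-specific TF peak sets with
planted replacement/loss structure (including exact 100/101-bp boundary
cases), ATAC fragment-length mixtures with planted in-peak depletion,
time-course expression with planted co-expression modules and KO shifts,
and bait/control peptide tables with planted interactors.

All generators are pure functions of the configuration: one global seed is
expanded into fixed, named substreams so changing one component's
parameters never perturbs another component's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import FragmentSet, GenomicInterval, TssAnnotation
from .expression_modules import ExpressionMatrix
from .interactome import PeptideTable
from .promoter_states import MARK_HALFWIDTH, STATES
from .tf_dynamics import PeakSet

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_states",
    "simulate_chip",
    "simulate_differential_regions",
    "simulate_tf_peaks",
    "simulate_atac",
    "simulate_expression",
    "simulate_peptides",
]

# fixed substream ids: generator outputs must not depend on call order
_STREAMS = {
    "annotation": 1,
    "states": 2,
    "chip": 3,
    "regions": 4,
    "tf_peaks": 5,
    "atac": 6,
    "expression": 7,
    "peptides": 8,
}

#: default per-gene WT state frequencies (ESC-like promoter landscape)
DEFAULT_WT_STATE_PROBS = {
    "active": 0.45,
    "bivalent": 0.25,
    "repressive": 0.15,
    "no_mark": 0.15,
}

#: default WT -> KO transition matrix: bivalent promoters largely resolve
#: to active/repressive, repressive promoters frequently lose their mark,
#: active and unmarked promoters are mostly stable.
DEFAULT_TRANSITION = {
    "active": {"active": 0.90, "bivalent": 0.04, "repressive": 0.02, "no_mark": 0.04},
    "bivalent": {"active": 0.30, "bivalent": 0.45, "repressive": 0.15, "no_mark": 0.10},
    "repressive": {"active": 0.04, "bivalent": 0.06, "repressive": 0.40, "no_mark": 0.50},
    "no_mark": {"active": 0.05, "bivalent": 0.02, "repressive": 0.05, "no_mark": 0.88},
}

_K4_PRESENT = {"active", "bivalent"}
_K27_PRESENT = {"bivalent", "repressive"}

# four non-constant binary time profiles with pairwise Hamming distance >= 2
_MODULE_PATTERNS = [
    (0, 1, 1, 0),
    (1, 0, 0, 1),
    (0, 0, 1, 1),
    (1, 1, 0, 0),
    (0, 1, 0, 1),
    (1, 0, 1, 0),
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    The defaults are the conditions the analyses are validated under:
    2,000 genes, 4x ChIP enrichment over a mean of 50 input fragments per
    promoter window, 8x 10-kb planted differential regions, a 60/40
    sub-/supra-150-bp ATAC size mixture with a 0.5x in-peak KO effect,
    4 expression modules of 100 genes separated by 2 log2 units with noise
    SD 0.3 and a 1.5x KO shift on half of them, and AP-MS tables whose
    planted interactors clear the two-fold normalized-excess gate.
    """

    seed: int = 0
    # genome & annotation
    chromosomes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    n_genes: int = 2_000
    gene_length_range: Tuple[int, int] = (1_000, 5_000)
    min_tss_spacing: int = 10_500  # keeps +/-5 kb mark windows disjoint
    # promoter states & ChIP
    wt_state_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WT_STATE_PROBS)
    )
    transition_matrix: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITION.items()}
    )
    chip_fold: float = 4.0
    mean_input_fragments: float = 50.0
    background_fragments: int = 600_000
    fragment_length: int = 200
    # differential (enriched/depleted) regions
    region_chromosomes: Dict[str, int] = field(
        default_factory=lambda: {"chrU": 20_000_000}
    )
    n_enriched_regions: int = 6
    region_length: int = 10_000
    region_fold: float = 8.0
    region_background_density: float = 0.01  # fragments per bp (100 / 10 kb)
    # TF peak fates
    n_shared_peaks: int = 60
    fate_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "loss": 40,
            "Sox2_replacement": 30,
            "Nanog_replacement": 20,
            "Sox2_Nanog_replacement": 10,
        }
    )
    peak_length: int = 400
    # ATAC
    n_atac_peaks: int = 300
    atac_depth_per_peak: float = 30.0  # expected sub-150 WT fragments per peak
    atac_ko_effect: float = 0.5  # KO in-peak rate multiplier
    sub150_fraction: float = 0.6
    atac_background_fragments: int = 500_000
    # expression modules
    n_modules: int = 4
    genes_per_module: int = 100
    n_constant_genes: int = 50
    profile_separation: float = 2.0  # log2 units
    expression_noise_sd: float = 0.3  # log2 units
    expression_base_log2: float = 4.0
    ko_shift_fold: float = 1.5
    ko_shift_modules: Tuple[int, ...] = (2, 4)
    ko_shift_from_timepoint: int = 2  # 0-based index into timepoints
    timepoints: Tuple[str, ...] = ("wk0", "wk1", "wk2", "wk4")
    # interactome
    n_decoy_proteins: int = 45
    n_planted_interactors: int = 8
    n_background_proteins: int = 5
    peptide_replicates: int = 2

    def __post_init__(self) -> None:
        if abs(sum(self.wt_state_probs.values()) - 1.0) > 1e-9:
            raise ValueError("wt_state_probs must sum to 1")
        for state, row in self.transition_matrix.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row {state!r} must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=[int(self.seed), _STREAMS[stream]])
        )


# ---------------------------------------------------------------------------
# annotation & promoter states
# ---------------------------------------------------------------------------


def simulate_annotation(
    cfg: SimulationConfig,
) -> Tuple[Dict[str, int], TssAnnotation, List[GenomicInterval]]:
    """Non-overlapping gene bodies with TSSs at the strand-appropriate end.

    TSSs keep a minimum spacing so that symmetric mark windows of
    neighbouring promoters do not overlap; gene bodies are shorter than
    half the spacing, so bodies never overlap either.
    """
    rng = cfg.rng("annotation")
    sizes = dict(cfg.chromosomes)
    total_len = sum(sizes.values())
    genes_per_chrom = {
        c: int(round(cfg.n_genes * sizes[c] / total_len)) for c in sizes
    }
    # fix rounding drift on the last chromosome
    drift = cfg.n_genes - sum(genes_per_chrom.values())
    if genes_per_chrom:
        genes_per_chrom[list(sizes)[-1]] += drift

    margin = 20_000
    rows = []
    bodies: List[GenomicInterval] = []
    idx = 0
    for chrom, n_c in genes_per_chrom.items():
        if n_c <= 0:
            continue
        usable = sizes[chrom] - 2 * margin
        if n_c * cfg.min_tss_spacing > usable:
            raise ValueError(
                f"{n_c} genes with {cfg.min_tss_spacing} bp TSS spacing do not "
                f"fit on {chrom} ({sizes[chrom]} bp)"
            )
        jitter = (usable - n_c * cfg.min_tss_spacing) // max(n_c, 1)
        gaps = cfg.min_tss_spacing + rng.integers(0, jitter + 1, size=n_c)
        tss_pos = margin + np.cumsum(gaps)
        strands = rng.choice(["+", "-"], size=n_c)
        lengths = rng.integers(*cfg.gene_length_range, size=n_c, endpoint=True)
        for tss, strand, length in zip(tss_pos, strands, lengths):
            idx += 1
            gene_id = f"gene{idx:05d}"
            tss = int(tss)
            if strand == "+":
                body = GenomicInterval(chrom, tss, tss + int(length), "+", gene_id)
            else:
                body = GenomicInterval(
                    chrom, tss - int(length) + 1, tss + 1, "-", gene_id
                )
            bodies.append(body)
            rows.append((gene_id, chrom, strand, tss))
    tss_table = TssAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])
        if rows
        else pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss"]).astype(
            {"tss": np.int64}
        )
    )
    return sizes, tss_table, bodies


def simulate_states(cfg: SimulationConfig, tss: TssAnnotation) -> pd.DataFrame:
    """Planted WT states and KO states drawn from the transition matrix."""
    rng = cfg.rng("states")
    n = len(tss)
    wt_probs = [cfg.wt_state_probs[s] for s in STATES]
    wt = rng.choice(STATES, size=n, p=wt_probs)
    ko = np.empty(n, dtype=object)
    for state in STATES:
        mask = wt == state
        row = [cfg.transition_matrix[state][s] for s in STATES]
        ko[mask] = rng.choice(STATES, size=int(mask.sum()), p=row)
    return pd.DataFrame(
        {"gene_id": tss.df["gene_id"], "wt_state": wt, "ko_state": ko}
    ).set_index("gene_id")


def _place_fragments(
    rng: np.random.Generator,
    chrom_arr: List[str],
    start_arr: List[np.ndarray],
    end_arr: List[np.ndarray],
    chrom: str,
    n: int,
    lo: int,
    hi: int,
    frag_len: int,
) -> None:
    """Append n fragments with midpoints uniform on [lo, hi)."""
    if n <= 0:
        return
    mids = rng.integers(lo, hi, size=n)
    half = frag_len // 2
    starts = np.maximum(mids - half, 0)
    chrom_arr.extend([chrom] * n)
    start_arr.append(starts)
    end_arr.append(starts + frag_len)


def _build_fragset(
    library_id: str,
    chrom_arr: List[str],
    start_arr: List[np.ndarray],
    end_arr: List[np.ndarray],
) -> FragmentSet:
    if not chrom_arr:
        return FragmentSet(
            library_id,
            pd.DataFrame({"chrom": [], "start": [], "end": []}).astype(
                {"chrom": str, "start": np.int64, "end": np.int64}
            ),
        )
    return FragmentSet.from_arrays(
        library_id,
        np.array(chrom_arr),
        np.concatenate(start_arr),
        np.concatenate(end_arr),
    )


def _background(
    rng: np.random.Generator,
    chrom_arr: List[str],
    start_arr: List[np.ndarray],
    end_arr: List[np.ndarray],
    chrom_sizes: Dict[str, int],
    n_total: int,
    frag_len: int,
    exclude: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Uniform background, optionally rejecting midpoints inside ``exclude``.

    ``exclude`` maps chrom -> (n, 2) sorted disjoint interval array.  The
    promoter-window exclusion keeps the planted per-window Poisson rates
    exact (the window count IS the planted count, as in the generative
    model); rejected draws are dropped, not resampled, so the realized
    background rate outside windows stays uniform.
    """
    total = sum(chrom_sizes.values())
    for chrom, size in chrom_sizes.items():
        n_c = int(round(n_total * size / total))
        mids = rng.integers(frag_len // 2, size - frag_len, size=n_c)
        if exclude is not None and chrom in exclude:
            win = exclude[chrom]
            idx = np.searchsorted(win[:, 0], mids, side="right")
            inside = (idx > 0) & (mids < win[np.maximum(idx - 1, 0), 1])
            mids = mids[~inside]
        half = frag_len // 2
        starts = np.maximum(mids - half, 0)
        chrom_arr.extend([chrom] * len(mids))
        start_arr.append(starts)
        end_arr.append(starts + frag_len)


def simulate_chip(
    cfg: SimulationConfig,
    chrom_sizes: Dict[str, int],
    tss: TssAnnotation,
    states: pd.DataFrame,
) -> Dict[Tuple[str, str], Tuple[FragmentSet, FragmentSet]]:
    """ChIP + matched input libraries for each (mark, condition).

    Per promoter window the input count is Poisson(mean) and the ChIP count
    Poisson(mean * fold) when the planted state carries the mark, else
    Poisson(mean); fragments are placed uniformly within the window.  A
    uniform background is added to both libraries outside the mark's
    promoter windows, so window counts equal the planted Poisson draws.
    """
    rng = cfg.rng("chip")
    out: Dict[Tuple[str, str], Tuple[FragmentSet, FragmentSet]] = {}
    for mark in ("H3K4me3", "H3K27me3"):
        present_states = _K4_PRESENT if mark == "H3K4me3" else _K27_PRESENT
        win = tss.windows(MARK_HALFWIDTH[mark])
        win = win.merge(states.reset_index(), on="gene_id")
        exclude: Dict[str, np.ndarray] = {}
        for chrom, sub in win.groupby("chrom", sort=False):
            arr = np.stack(
                [sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)],
                axis=1,
            )
            exclude[str(chrom)] = arr[np.argsort(arr[:, 0])]
        for cond, col in (("WT", "wt_state"), ("KO", "ko_state")):
            present = win[col].isin(present_states).to_numpy()
            chip_mean = np.where(
                present,
                cfg.mean_input_fragments * cfg.chip_fold,
                cfg.mean_input_fragments,
            )
            chip_counts = rng.poisson(chip_mean)
            input_counts = rng.poisson(cfg.mean_input_fragments, size=len(win))
            libs = {}
            for label, counts in (("chip", chip_counts), ("input", input_counts)):
                c_arr: List[str] = []
                s_arr: List[np.ndarray] = []
                e_arr: List[np.ndarray] = []
                for (chrom, lo, hi), n in zip(
                    win[["chrom", "start", "end"]].itertuples(index=False),
                    counts,
                ):
                    _place_fragments(
                        rng, c_arr, s_arr, e_arr, chrom, int(n), lo, hi,
                        cfg.fragment_length,
                    )
                _background(
                    rng, c_arr, s_arr, e_arr, chrom_sizes,
                    cfg.background_fragments, cfg.fragment_length,
                    exclude=exclude,
                )
                libs[label] = _build_fragset(
                    f"{mark}_{cond}_{label}", c_arr, s_arr, e_arr
                )
            out[(mark, cond)] = (libs["chip"], libs["input"])
    return out


# ---------------------------------------------------------------------------
# differential regions
# ---------------------------------------------------------------------------


def simulate_differential_regions(
    cfg: SimulationConfig,
    chrom_sizes: Dict[str, int],
    with_comark: bool = False,
):
    """Planted enriched regions: uniform background + extra ChIP rate inside.

    Both libraries share the background density; inside each planted region
    the ChIP rate is ``region_fold`` times the background.  With
    ``with_comark`` a second, independent ChIP-like library sharing the
    same planted regions is emitted (for track-correlation checks).
    Returns ``(chip, input, regions[, comark])``.
    """
    rng = cfg.rng("regions")
    chroms = list(chrom_sizes)
    regions: List[GenomicInterval] = []
    for i in range(cfg.n_enriched_regions):
        chrom = chroms[i % len(chroms)]
        size = chrom_sizes[chrom]
        lo = 100_000 + (i // len(chroms)) * ((size - 200_000) // max(
            1, -(-cfg.n_enriched_regions // len(chroms))
        ))
        start = (lo + int(rng.integers(0, 50)) * 1_000)
        regions.append(
            GenomicInterval(chrom, start, start + cfg.region_length, name=f"region{i+1}")
        )

    def _library(label: str, enriched: bool) -> FragmentSet:
        c_arr: List[str] = []
        s_arr: List[np.ndarray] = []
        e_arr: List[np.ndarray] = []
        for chrom, size in chrom_sizes.items():
            n_bg = rng.poisson(cfg.region_background_density * size)
            _place_fragments(
                rng, c_arr, s_arr, e_arr, chrom, int(n_bg), 0,
                size - cfg.fragment_length, cfg.fragment_length,
            )
        if enriched:
            for reg in regions:
                extra = rng.poisson(
                    cfg.region_background_density
                    * reg.length
                    * (cfg.region_fold - 1.0)
                )
                _place_fragments(
                    rng, c_arr, s_arr, e_arr, reg.chrom, int(extra),
                    reg.start, reg.end, cfg.fragment_length,
                )
        return _build_fragset(label, c_arr, s_arr, e_arr)

    chip = _library("uhrf1_chip", enriched=True)
    input_ = _library("uhrf1_input", enriched=False)
    if with_comark:
        comark = _library("comark_chip", enriched=True)
        return chip, input_, regions, comark
    return chip, input_, regions


# ---------------------------------------------------------------------------
# TF peaks with planted fates
# ---------------------------------------------------------------------------


def simulate_tf_peaks(
    cfg: SimulationConfig, chrom_sizes: Dict[str, int]
) -> Tuple[Dict[Tuple[str, str], PeakSet], pd.DataFrame]:
    """Oct4/Sox2/Nanog peak sets per condition with planted Oct4 fates.

    WT-specific Oct4 peaks get, per planted fate, a KO-specific Sox2 and/or
    Nanog peak at an edge gap cycling through {0, 50, 100} bp (all within
    the 100-bp overlap rule); every fourth loss peak gets a decoy Sox2
    KO-specific peak at a gap of exactly 101 bp, just outside the rule.
    Shared peaks (present in both conditions) are added to every factor.
    """
    chrom = list(chrom_sizes)[0]
    L = cfg.peak_length
    slot_pitch = 3_000
    pos = 50_000
    peaks: Dict[Tuple[str, str], List[GenomicInterval]] = {
        (f, c): [] for f in ("Oct4", "Sox2", "Nanog") for c in ("WT", "KO")
    }
    truth_rows = []

    def _next_slot() -> int:
        nonlocal pos
        slot = pos
        pos += slot_pitch
        if pos > chrom_sizes[chrom] - 10_000:
            raise ValueError("genome too small for requested peak count")
        return slot

    # shared peaks: same coordinates in WT and KO for every factor
    for i in range(cfg.n_shared_peaks):
        for factor in ("Oct4", "Sox2", "Nanog"):
            s = _next_slot()
            iv = GenomicInterval(chrom, s, s + L, name=f"{factor}_shared{i+1}")
            peaks[(factor, "WT")].append(iv)
            peaks[(factor, "KO")].append(iv)

    gap_cycle = [0, 50, 100]
    loss_i = 0
    k = 0
    for fate, count in cfg.fate_counts.items():
        for j in range(count):
            k += 1
            s = _next_slot()
            oct4 = GenomicInterval(chrom, s, s + L, name=f"Oct4_wtspec{k}")
            peaks[("Oct4", "WT")].append(oct4)
            gap = gap_cycle[j % len(gap_cycle)]
            # neighbour start for an edge gap of exactly `gap` bp
            nb_start = oct4.end + gap if gap > 0 else oct4.start + L // 2
            if fate in ("Sox2_replacement", "Sox2_Nanog_replacement"):
                peaks[("Sox2", "KO")].append(
                    GenomicInterval(chrom, nb_start, nb_start + L, name=f"Sox2_rep{k}")
                )
            if fate in ("Nanog_replacement", "Sox2_Nanog_replacement"):
                nb2 = oct4.start - gap - L if gap > 0 else nb_start
                peaks[("Nanog", "KO")].append(
                    GenomicInterval(chrom, nb2, nb2 + L, name=f"Nanog_rep{k}")
                )
            if fate == "loss":
                loss_i += 1
                if loss_i % 4 == 0:
                    decoy_start = oct4.end + 101  # just outside the overlap rule
                    peaks[("Sox2", "KO")].append(
                        GenomicInterval(
                            chrom, decoy_start, decoy_start + L, name=f"Sox2_decoy{k}"
                        )
                    )
            truth_rows.append((oct4.name, oct4.chrom, oct4.start, oct4.end, fate))

    peaksets = {
        (f, c): PeakSet(factor=f, condition=c, peaks=v)
        for (f, c), v in peaks.items()
    }
    truth = pd.DataFrame(
        truth_rows, columns=["peak_name", "chrom", "start", "end", "fate"]
    )
    return peaksets, truth


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------


def _atac_sizes(rng: np.random.Generator, n_sub: int, n_supra: int) -> np.ndarray:
    sub = np.clip(np.round(rng.normal(80, 20, size=n_sub)), 30, 149)
    supra = np.clip(np.round(rng.normal(220, 40, size=n_supra)), 150, 400)
    return np.concatenate([sub, supra]).astype(np.int64)


def simulate_atac(
    cfg: SimulationConfig, chrom_sizes: Dict[str, int]
) -> Tuple[FragmentSet, FragmentSet, PeakSet, Dict[str, float]]:
    """WT/KO ATAC libraries with a size mixture and planted in-peak depletion.

    Fragment lengths come from a two-component mixture (sub-150 fraction
    ``sub150_fraction``); the KO in-peak rate is scaled by
    ``atac_ko_effect`` for both size classes, on top of an identical
    genome-wide background.
    """
    rng = cfg.rng("atac")
    chrom = list(chrom_sizes)[-1]
    pitch = 5_000
    start0 = 60_000
    peaks = [
        GenomicInterval(
            chrom, start0 + i * pitch, start0 + i * pitch + cfg.peak_length,
            name=f"atac_peak{i+1}",
        )
        for i in range(cfg.n_atac_peaks)
    ]
    if peaks and peaks[-1].end > chrom_sizes[chrom] - 10_000:
        raise ValueError("genome too small for requested ATAC peak count")

    f = cfg.sub150_fraction
    supra_per_sub = (1.0 - f) / f

    def _library(label: str, effect: float) -> FragmentSet:
        c_arr: List[str] = []
        starts: List[np.ndarray] = []
        sizes_all: List[np.ndarray] = []
        # in-peak fragments
        for peak in peaks:
            n_sub = rng.poisson(cfg.atac_depth_per_peak * effect)
            n_supra = rng.poisson(cfg.atac_depth_per_peak * supra_per_sub * effect)
            n = n_sub + n_supra
            if n == 0:
                continue
            mids = rng.integers(peak.start, peak.end, size=n)
            sizes = _atac_sizes(rng, n_sub, n_supra)
            c_arr.extend([peak.chrom] * n)
            starts.append(np.maximum(mids - sizes // 2, 0))
            sizes_all.append(sizes)
        # genome-wide background outside the peaks (in-peak rates stay the
        # planted Poisson draws), same mixture in both conditions
        peak_arr = np.array([(p.start, p.end) for p in peaks], dtype=np.int64)
        total = sum(chrom_sizes.values())
        for c, size in chrom_sizes.items():
            n_c = int(round(cfg.atac_background_fragments * size / total))
            mids = rng.integers(500, size - 500, size=n_c)
            if c == chrom and len(peak_arr):
                idx = np.searchsorted(peak_arr[:, 0], mids, side="right")
                inside = (idx > 0) & (mids < peak_arr[np.maximum(idx - 1, 0), 1])
                mids = mids[~inside]
            n_c = len(mids)
            n_sub = rng.binomial(n_c, f)
            sizes = _atac_sizes(rng, n_sub, n_c - n_sub)
            c_arr.extend([c] * n_c)
            starts.append(np.maximum(mids - sizes // 2, 0))
            sizes_all.append(sizes)
        s = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        z = np.concatenate(sizes_all) if sizes_all else np.empty(0, dtype=np.int64)
        return FragmentSet.from_arrays(label, np.array(c_arr), s, s + z)

    wt = _library("atac_WT", 1.0)
    ko = _library("atac_KO", cfg.atac_ko_effect)
    truth = {
        "ko_effect": cfg.atac_ko_effect,
        "expected_log2_ratio": float(np.log2(cfg.atac_ko_effect)),
        "sub150_fraction": cfg.sub150_fraction,
    }
    return wt, ko, PeakSet("Oct4", "WT", peaks), truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimulationConfig,
) -> Tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Time-course RPKM matrix with planted modules and KO shifts.

    Module mean profiles are binary on/off patterns over the timepoints,
    scaled by ``profile_separation`` log2 units; per-gene log-normal noise
    has SD ``expression_noise_sd`` (log2).  Modules in
    ``ko_shift_modules`` get a ``ko_shift_fold`` KO/WT shift from timepoint
    index ``ko_shift_from_timepoint`` on.  Constant (non-dynamic) filler
    genes exercise the dynamic-gene filter.
    Returns (matrix, planted labels, planted per-module/timepoint shifts).
    """
    if cfg.n_modules > len(_MODULE_PATTERNS):
        raise ValueError(f"at most {len(_MODULE_PATTERNS)} modules supported")
    if len(cfg.timepoints) != 4:
        raise ValueError("module patterns are defined over exactly 4 timepoints")
    rng = cfg.rng("expression")
    samples = []
    for cond in ("WT", "KO"):
        for t in cfg.timepoints:
            samples.append((f"{cond}_{t}", cond, t))
    sheet = pd.DataFrame(samples, columns=["sample", "condition", "timepoint"])

    gene_ids, labels, rows = [], [], []
    shift_log2 = np.log2(cfg.ko_shift_fold)
    for m in range(1, cfg.n_modules + 1):
        pattern = _MODULE_PATTERNS[m - 1]
        for g in range(cfg.genes_per_module):
            gene_ids.append(f"mod{m}_gene{g+1:03d}")
            labels.append(m)
            vals = []
            for _, cond, t in samples:
                ti = cfg.timepoints.index(t)
                x = cfg.expression_base_log2 + cfg.profile_separation * pattern[ti]
                if (
                    cond == "KO"
                    and m in cfg.ko_shift_modules
                    and ti >= cfg.ko_shift_from_timepoint
                ):
                    x += shift_log2
                vals.append(x + rng.normal(0, cfg.expression_noise_sd))
            rows.append(vals)
    for g in range(cfg.n_constant_genes):
        gene_ids.append(f"flat_gene{g+1:03d}")
        labels.append(0)  # 0 = not in any planted module
        base = cfg.expression_base_log2 + cfg.profile_separation / 2
        rows.append(
            [base + rng.normal(0, cfg.expression_noise_sd / 3) for _ in samples]
        )
    values = pd.DataFrame(
        np.power(2.0, np.array(rows)), index=gene_ids, columns=sheet["sample"]
    )
    values.index.name = "gene_id"
    matrix = ExpressionMatrix(values=values, samples=sheet)
    planted = pd.Series(labels, index=gene_ids, name="module")
    shift_rows = []
    for m in range(1, cfg.n_modules + 1):
        for ti, t in enumerate(cfg.timepoints):
            shift_rows.append(
                (
                    m,
                    t,
                    bool(
                        m in cfg.ko_shift_modules
                        and ti >= cfg.ko_shift_from_timepoint
                    ),
                )
            )
    shifts = pd.DataFrame(shift_rows, columns=["module", "timepoint", "shifted"])
    return matrix, planted, shifts


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------


def simulate_peptides(
    cfg: SimulationConfig,
) -> Tuple[List[PeptideTable], List[PeptideTable], List[str], List[str]]:
    """Bait/control peptide tables with recoverable planted interactors.

    Decoys draw comparable counts in bait and control (ratio bounded below
    2); planted interactors get a four-fold raw excess in every replicate
    (one planted protein is absent from the controls, exercising the
    zero-control pseudo-fraction path); background proteins get large
    counts in both channels.
    Returns (bait tables, control tables, planted ids, background ids).
    """
    rng = cfg.rng("peptides")
    planted = [f"INT{i+1:02d}" for i in range(cfg.n_planted_interactors)]
    decoys = [f"DEC{i+1:02d}" for i in range(cfg.n_decoy_proteins)]
    background = [f"BGP{i+1:02d}" for i in range(cfg.n_background_proteins)]
    baits, controls = [], []
    for r in range(cfg.peptide_replicates):
        bait_counts, control_counts = {}, {}
        for i, p in enumerate(planted):
            if i == 0:
                control_counts[p] = 0  # zero-control interactor
                bait_counts[p] = int(rng.integers(4, 9))
            else:
                c = int(rng.integers(2, 6))
                control_counts[p] = c
                bait_counts[p] = 4 * c
        for p in decoys:
            n = int(rng.integers(15, 26))
            bait_counts[p] = n
            control_counts[p] = int(rng.integers(15, 26))
        for p in background:
            bait_counts[p] = int(rng.integers(30, 60))
            control_counts[p] = int(rng.integers(30, 60))
        rep = f"rep{r+1}"
        baits.append(
            PeptideTable(rep, "bait", pd.Series(bait_counts, name="unique_peptides"))
        )
        controls.append(
            PeptideTable(
                rep, "control", pd.Series(control_counts, name="unique_peptides")
            )
        )
    return baits, controls, planted, background
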