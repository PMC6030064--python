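"""End-to-end synthetic-study pipeline: simulate, analyze, score vs truth.

Each ``run_*_stage`` function generates the inputs for one analysis from a
:class:`~chromfate.synthetic_data.SimulationConfig`, runs the corresponding
analysis module, and scores the result against the planted truth.
:func:`run_full` chains all stages and optionally writes every summary
table as deterministic TSV/BED text, so two runs from one seed produce
byte-identical output trees.
"""

from __future__ import annotations

import os
from dataclasses import replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .core_io import FragmentSet, GenomicInterval, make_binned_track, track_pearson, write_bed, write_chrom_sizes
from .enrichment import annotate_regions, call_differential_windows
from .expression_modules import (
    ExpressionMatrix,
    cluster_modules,
    filter_dynamic_genes,
    module_profiles,
    module_significance,
)
from .interactome import PeptideTable, call_interactors
from .promoter_states import classify_states, quantify_promoters, transition_table
from .tf_dynamics import (
    classify_oct4_fate,
    compare_peak_sets,
    filter_fragments_by_size,
    signal_in_peaks_test,
)

__all__ = [
    "run_promoter_stage",
    "run_region_stage",
    "run_tf_stage",
    "run_atac_stage",
    "run_module_stage",
    "run_interactome_stage",
    "load_toy_interactome",
    "run_full",
]


def _write(df: pd.DataFrame, outdir: Optional[str], name: str, **kwargs) -> None:
    if outdir is not None:
        df.to_csv(os.path.join(outdir, name), sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# promoter states
# ---------------------------------------------------------------------------


def run_promoter_stage(cfg: sd.SimulationConfig, outdir: Optional[str] = None) -> Dict:
    """Simulate ChIP/input per mark and condition, classify, score vs truth."""
    chrom_sizes, tss, genes = sd.simulate_annotation(cfg)
    truth = sd.simulate_states(cfg, tss)
    libraries = sd.simulate_chip(cfg, chrom_sizes, tss, truth)

    states: Dict[str, pd.Series] = {}
    quants: Dict[Tuple[str, str], pd.DataFrame] = {}
    for cond in ("WT", "KO"):
        per_mark = {}
        for mark in ("H3K4me3", "H3K27me3"):
            chip, input_ = libraries[(mark, cond)]
            per_mark[mark] = quantify_promoters(chip, input_, tss, mark)
            quants[(mark, cond)] = per_mark[mark]
        states[cond] = classify_states(per_mark["H3K4me3"], per_mark["H3K27me3"])

    table = transition_table(states["WT"], states["KO"])
    truth_table = transition_table(
        truth["wt_state"].rename("state"), truth["ko_state"].rename("state")
    )
    accuracy = {
        cond: float(
            (states[cond].reindex(truth.index) == truth[f"{cond.lower()}_state"]).mean()
        )
        for cond in ("WT", "KO")
    }
    row_dev = (table.row_percent - truth_table.row_percent).abs().to_numpy()
    retention_dev = (table.retention - truth_table.retention).abs()

    if outdir is not None:
        for cond in ("WT", "KO"):
            merged = (
                quants[("H3K4me3", cond)][["gene_id", "log2_ratio", "q_value"]]
                .rename(columns={"log2_ratio": "k4_log2", "q_value": "k4_q"})
                .merge(
                    quants[("H3K27me3", cond)][["gene_id", "log2_ratio", "q_value"]]
                    .rename(columns={"log2_ratio": "k27_log2", "q_value": "k27_q"}),
                    on="gene_id",
                )
            )
            merged["state"] = states[cond].reindex(merged["gene_id"]).to_numpy()
            _write(merged, outdir, f"promoter_states_{cond}.tsv", index=False,
                   float_format="%.6g")
        _write(table.counts, outdir, "transition_counts.tsv")
        _write(table.row_percent, outdir, "transition_row_percent.tsv",
               float_format="%.4f")
        _write(table.retention.to_frame(), outdir, "retention.tsv",
               float_format="%.6f")
        _write(truth.reset_index(), outdir, "truth_states.tsv", index=False)

    return {
        "chrom_sizes": chrom_sizes,
        "tss": tss,
        "genes": genes,
        "truth": truth,
        "states": states,
        "transition": table,
        "truth_transition": truth_table,
        "state_accuracy": accuracy,
        "max_row_percent_dev": float(np.nanmax(row_dev)),
        "max_retention_dev": float(retention_dev.max()),
    }


# ---------------------------------------------------------------------------
# differential regions
# ---------------------------------------------------------------------------


def _interval_union_length(regions: Sequence[GenomicInterval]) -> int:
    total = 0
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for rows in by_chrom.values():
        rows.sort()
        cur_s, cur_e = rows[0]
        for s, e in rows[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def _overlap_length(
    called: Sequence[GenomicInterval], truth: Sequence[GenomicInterval]
) -> int:
    total = 0
    for c in called:
        for t in truth:
            if c.chrom == t.chrom:
                total += max(0, min(c.end, t.end) - max(c.start, t.start))
    return total


def base_recall_precision(
    called: Sequence[GenomicInterval], truth: Sequence[GenomicInterval]
) -> Tuple[float, float]:
    """Base-level recall and precision of called vs planted regions."""
    ov = _overlap_length(called, truth)
    truth_len = _interval_union_length(truth) if truth else 0
    called_len = _interval_union_length(called) if called else 0
    recall = ov / truth_len if truth_len else float("nan")
    precision = ov / called_len if called_len else float("nan")
    return recall, precision


def run_region_stage(cfg: sd.SimulationConfig, outdir: Optional[str] = None) -> Dict:
    """Planted-region recovery, swap symmetry, annotation, track correlation."""
    chrom_sizes = dict(cfg.region_chromosomes)
    chip, input_, regions, comark = sd.simulate_differential_regions(
        cfg, chrom_sizes, with_comark=True
    )
    # a small gene annotation on the region genome, for the genic/intergenic tally
    ann_cfg = replace(
        cfg,
        chromosomes=dict(cfg.region_chromosomes),
        n_genes=max(
            10,
            int(
                cfg.n_genes
                * sum(chrom_sizes.values())
                // max(sum(cfg.chromosomes.values()), 1)
            ),
        ),
    )
    _, tss, genes = sd.simulate_annotation(ann_cfg)
    calls = call_differential_windows(chip, input_, chrom_sizes)
    recall, precision = base_recall_precision(calls.enriched, regions)
    swapped = call_differential_windows(input_, chip, chrom_sizes)
    swap_exact = [
        (i.chrom, i.start, i.end) for i in calls.enriched
    ] == [(i.chrom, i.start, i.end) for i in swapped.depleted] and [
        (i.chrom, i.start, i.end) for i in calls.depleted
    ] == [(i.chrom, i.start, i.end) for i in swapped.enriched]

    chip_track = make_binned_track(chip, chrom_sizes, 10_000)
    comark_track = make_binned_track(comark, chrom_sizes, 10_000)
    pearson = track_pearson(chip_track, comark_track)

    _, annotation = annotate_regions(calls.enriched, genes, tss)

    if outdir is not None:
        write_bed(calls.enriched, os.path.join(outdir, "enriched_regions.bed"))
        write_bed(calls.depleted, os.path.join(outdir, "depleted_regions.bed"))
        write_bed(regions, os.path.join(outdir, "planted_regions.bed"))
        _write(annotation, outdir, "enriched_region_annotation.tsv",
               index=False, float_format="%.6f")

    return {
        "calls": calls,
        "planted": regions,
        "recall": recall,
        "precision": precision,
        "n_enriched": len(calls.enriched),
        "n_depleted": len(calls.depleted),
        "swap_exact": bool(swap_exact),
        "comark_pearson": float(pearson),
        "annotation": annotation,
    }


# ---------------------------------------------------------------------------
# TF fates
# ---------------------------------------------------------------------------


def run_tf_stage(
    cfg: sd.SimulationConfig, outdir: Optional[str] = None, tss=None
) -> Dict:
    """Peak-set comparison and Oct4 fate calls scored against planted fates."""
    chrom_sizes = dict(cfg.chromosomes)
    peaksets, truth = sd.simulate_tf_peaks(cfg, chrom_sizes)
    oct4 = compare_peak_sets(peaksets[("Oct4", "WT")], peaksets[("Oct4", "KO")])
    sox2 = compare_peak_sets(peaksets[("Sox2", "WT")], peaksets[("Sox2", "KO")])
    nanog = compare_peak_sets(peaksets[("Nanog", "WT")], peaksets[("Nanog", "KO")])
    calls, fractions = classify_oct4_fate(
        oct4.a_specific, sox2.b_specific, nanog.b_specific, tss=tss
    )
    called = pd.DataFrame(
        [
            (c.peak.name, c.peak.chrom, c.peak.start, c.peak.end, c.fate, c.target_gene)
            for c in calls
        ],
        columns=["peak_name", "chrom", "start", "end", "fate", "target_gene"],
    )
    merged = truth.merge(
        called[["peak_name", "fate", "target_gene"]],
        on="peak_name",
        suffixes=("_planted", "_called"),
        how="left",
    )
    n_errors = int((merged["fate_planted"] != merged["fate_called"]).sum())
    total = truth["fate"].value_counts()
    planted_fractions = (total / total.sum()).reindex(fractions.index, fill_value=0.0)

    if outdir is not None:
        _write(called, outdir, "oct4_fates.tsv", index=False)
        _write(
            pd.DataFrame(
                {"fraction_called": fractions, "fraction_planted": planted_fractions}
            ),
            outdir,
            "oct4_fate_fractions.tsv",
            float_format="%.6f",
        )

    return {
        "calls": called,
        "fractions": fractions,
        "planted_fractions": planted_fractions,
        "n_fate_errors": n_errors,
        "n_wt_specific": len(calls),
    }


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------


def run_atac_stage(cfg: sd.SimulationConfig, outdir: Optional[str] = None) -> Dict:
    """Sub-nucleosomal filter + in-peak WT/KO comparison vs planted effect."""
    chrom_sizes = dict(cfg.chromosomes)
    wt, ko, peaks, truth = sd.simulate_atac(cfg, chrom_sizes)
    wt_sizes = (wt.df["end"] - wt.df["start"]).to_numpy()
    sub_frac_wt = float((wt_sizes < 150).mean())
    wt_f = filter_fragments_by_size(wt, 150)
    ko_f = filter_fragments_by_size(ko, 150)
    table, summary = signal_in_peaks_test(wt_f, ko_f, peaks)
    if outdir is not None:
        _write(table, outdir, "atac_in_peak.tsv", index=False, float_format="%.6g")
        _write(
            pd.DataFrame([summary]), outdir, "atac_summary.tsv", index=False,
            float_format="%.6g",
        )
    return {
        "table": table,
        "summary": summary,
        "sub150_fraction_observed": sub_frac_wt,
        "sub150_fraction_planted": truth["sub150_fraction"],
        "expected_log2_ratio": truth["expected_log2_ratio"],
        "n_kept_wt": wt_f.library_size,
        "n_total_wt": wt.library_size,
    }


# ---------------------------------------------------------------------------
# expression modules
# ---------------------------------------------------------------------------


def _adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two flat labelings (contingency form)."""
    a_ids, a_inv = np.unique(a, return_inverse=True)
    b_ids, b_inv = np.unique(b, return_inverse=True)
    n = len(a)
    cont = np.zeros((len(a_ids), len(b_ids)), dtype=np.int64)
    np.add.at(cont, (a_inv, b_inv), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_cells = comb(cont).sum()
    sum_rows = comb(cont.sum(axis=1)).sum()
    sum_cols = comb(cont.sum(axis=0)).sum()
    expected = sum_rows * sum_cols / comb(n)
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def run_module_stage(cfg: sd.SimulationConfig, outdir: Optional[str] = None) -> Dict:
    """Dynamic-gene filter, Ward.D2 clustering and module significance flags."""
    matrix, planted, shifts = sd.simulate_expression(cfg)
    ref = f"WT_{cfg.timepoints[0]}"
    dynamic = filter_dynamic_genes(matrix, reference_sample=ref)
    sub = matrix.subset_genes(dynamic)
    assign = cluster_modules(sub)
    planted_genes = planted[planted > 0].index
    eval_genes = [g for g in planted_genes if g in assign.labels.index]
    ari = _adjusted_rand_index(
        planted.loc[eval_genes].to_numpy(), assign.labels.loc[eval_genes].to_numpy()
    )
    profiles = module_profiles(assign, sub, reference_sample=ref)
    flags = module_significance(assign, sub)

    # map recovered module ids to planted ids by majority membership
    mapping: Dict[int, int] = {}
    for m in assign.module_ids:
        members = assign.labels[assign.labels == m].index
        p = planted.reindex(members).dropna()
        mapping[m] = int(p.mode().iloc[0]) if len(p) else 0
    flags = flags.assign(planted_module=flags["module"].map(mapping))
    merged = flags.merge(shifts, left_on=["planted_module", "timepoint"],
                         right_on=["module", "timepoint"], how="left",
                         suffixes=("", "_truth"))
    valid = merged["shifted"].notna() & merged["flagged"].notna()
    flag_errors = int(
        (merged.loc[valid, "flagged"].astype(bool)
         != merged.loc[valid, "shifted"].astype(bool)).sum()
    )

    if outdir is not None:
        _write(assign.labels.to_frame(), outdir, "module_assignment.tsv")
        _write(profiles, outdir, "module_profiles.tsv", index=False,
               float_format="%.6g")
        _write(flags, outdir, "module_significance.tsv", index=False,
               float_format="%.6g")
    return {
        "assignment": assign,
        "planted": planted,
        "ari": float(ari),
        "n_dynamic": len(dynamic),
        "n_modules": len(assign.module_ids),
        "flags": flags,
        "flag_errors": flag_errors,
    }


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------


def load_toy_interactome() -> Tuple[List[PeptideTable], List[PeptideTable], List[str], pd.Series]:
    """Packaged 12-protein x 2-replicate toy dataset with hand-computed truth."""
    root = resources.files("chromfate").joinpath("data/interactome_toy")
    baits, controls = [], []
    for r in ("rep1", "rep2"):
        with resources.as_file(root.joinpath(f"bait_{r}.tsv")) as p:
            baits.append(PeptideTable.read_table(p, r, "bait"))
        with resources.as_file(root.joinpath(f"control_{r}.tsv")) as p:
            controls.append(PeptideTable.read_table(p, r, "control"))
    with resources.as_file(root.joinpath("background.txt")) as p:
        background = [l.strip() for l in open(p) if l.strip()]
    with resources.as_file(root.joinpath("truth.tsv")) as p:
        truth = pd.read_csv(p, sep="\t").set_index("protein_id")["candidate"]
    return baits, controls, background, truth


def run_interactome_stage(
    cfg: sd.SimulationConfig, outdir: Optional[str] = None
) -> Dict:
    """Simulated AP-MS filtering scored against planted interactors."""
    baits, controls, planted, background = sd.simulate_peptides(cfg)
    calls = call_interactors(baits, controls, background=background)
    called = set(calls.index[calls["candidate"]])
    missed = sorted(set(planted) - called)
    false = sorted(called - set(planted))
    if outdir is not None:
        _write(calls, outdir, "interactome_calls.tsv", float_format="%.6g")
    return {
        "calls": calls,
        "planted": planted,
        "n_candidates": int(calls["candidate"].sum()),
        "missed": missed,
        "false_positives": false,
    }


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def run_full(
    cfg: Optional[sd.SimulationConfig] = None,
    outdir: Optional[str] = None,
    seed: int = 0,
) -> Dict:
    """Run every stage from one seed; optionally write all summary tables."""
    if cfg is None:
        cfg = sd.SimulationConfig(seed=seed)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    promoter = run_promoter_stage(cfg, outdir)
    if outdir is not None:
        write_chrom_sizes(promoter["chrom_sizes"], os.path.join(outdir, "chrom.sizes"))
        promoter["tss"].write_table(os.path.join(outdir, "tss.tsv"))
    regions = run_region_stage(cfg, outdir)
    tf = run_tf_stage(cfg, outdir, tss=promoter["tss"])
    atac = run_atac_stage(cfg, outdir)
    modules = run_module_stage(cfg, outdir)
    inter = run_interactome_stage(cfg, outdir)
    return {
        "config": cfg,
        "promoter": promoter,
        "regions": regions,
        "tf": tf,
        "atac": atac,
        "modules": modules,
        "interactome": inter,
    }
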