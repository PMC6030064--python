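"""AP-MS candidate-interactor filtering from replicate unique-peptide counts.

Proteins with fewer than two unique peptides, and common background
proteins, are removed; each protein's unique-peptide count is normalized to
the total unique peptides of all sequenced proteins in that pull-down
(totals are computed before any removal); a protein is a candidate
interactor when its normalized bait count is at least two-fold the matched
control in at least one replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

__all__ = [
    "PeptideTable",
    "InteractorCall",
    "prefilter_proteins",
    "call_interactors",
]


@dataclass
class PeptideTable:
    """Unique-peptide counts of one pull-down replicate.

    ``total_unique_peptides`` defaults to the column sum and is preserved
    through prefiltering, since normalization uses the total over all
    sequenced proteins, not the post-filter survivors.
    """

    replicate: str
    channel: str  # "bait" or "control"
    counts: pd.Series  # protein_id -> unique peptide count
    total_unique_peptides: Optional[int] = None

    def __post_init__(self) -> None:
        if self.channel not in ("bait", "control"):
            raise ValueError("channel must be 'bait' or 'control'")
        self.counts = self.counts.astype(int)
        if (self.counts < 0).any():
            raise ValueError("peptide counts must be >= 0")
        if self.counts.index.duplicated().any():
            raise ValueError("protein ids must be unique per table")
        if self.total_unique_peptides is None:
            self.total_unique_peptides = int(self.counts.sum())
        if self.total_unique_peptides <= 0:
            raise ValueError("total unique peptides must be > 0")

    def fractions(self) -> pd.Series:
        return self.counts / self.total_unique_peptides

    @classmethod
    def read_table(cls, path, replicate: str, channel: str) -> "PeptideTable":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        counts = df.set_index("protein_id")["unique_peptides"]
        return cls(replicate=replicate, channel=channel, counts=counts)


@dataclass
class InteractorCall:
    protein_id: str
    bait_fractions: List[float]
    control_fractions: List[float]
    ratios: List[float]
    max_ratio: float
    candidate: bool


def prefilter_proteins(
    t: PeptideTable,
    background: Iterable[str] = (),
    min_peptides: int = 2,
) -> PeptideTable:
    """Drop low-evidence and background proteins, keeping the original total.

    Removes proteins with fewer than ``min_peptides`` unique peptides in
    this table and any protein on the background list; the normalization
    total is *not* recomputed (it covers all sequenced proteins).
    """
    background = set(background)
    keep = (t.counts >= min_peptides) & ~t.counts.index.isin(background)
    return PeptideTable(
        replicate=t.replicate,
        channel=t.channel,
        counts=t.counts[keep],
        total_unique_peptides=t.total_unique_peptides,
    )


def call_interactors(
    bait_reps: Sequence[PeptideTable],
    control_reps: Sequence[PeptideTable],
    fold: float = 2.0,
    pseudo_fraction: Optional[float] = None,
    background: Iterable[str] = (),
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Candidate-interactor calls across replicate bait/control pairs.

    Replicates are paired positionally (bait r vs control r); with unequal
    replicate counts each extra bait replicate is compared against the
    pooled control fractions.  Per pair, ``ratio = bait_fraction /
    control_fraction`` using the raw control fraction when the control saw
    the protein, else ``pseudo_fraction`` (default: half a peptide over the
    control total) as the denominator.  A protein is a candidate when it
    survives prefiltering in some bait replicate whose ratio reaches
    ``fold``.

    Returns a table with per-replicate fractions, per-replicate ratios, the
    max ratio and the candidate flag, sorted by protein id.
    """
    if not bait_reps:
        raise ValueError("need at least one bait replicate")
    background = set(background)
    pooled_control_frac: Optional[pd.Series] = None
    pooled_total = sum(c.total_unique_peptides for c in control_reps)
    if control_reps and len(control_reps) != len(bait_reps):
        pooled_counts = (
            pd.concat([c.counts for c in control_reps], axis=1).fillna(0).sum(axis=1)
        )
        pooled_control_frac = pooled_counts / pooled_total

    proteins = sorted(
        set().union(*[set(b.counts.index) for b in bait_reps]) - background
    )
    rows: Dict[str, Dict[str, float]] = {p: {} for p in proteins}
    candidate = {p: False for p in proteins}

    for r, bait in enumerate(bait_reps):
        filtered = prefilter_proteins(bait, background, min_peptides)
        bait_frac = bait.fractions()
        if r < len(control_reps):
            control = control_reps[r]
            control_frac = control.fractions()
            control_total = control.total_unique_peptides
        else:
            if pooled_control_frac is None:
                raise ValueError("no control replicate available for pairing")
            control_frac = pooled_control_frac
            control_total = pooled_total
        pseudo = (
            pseudo_fraction if pseudo_fraction is not None else 0.5 / control_total
        )
        for p in proteins:
            bf = float(bait_frac.get(p, 0.0))
            cf = float(control_frac.get(p, 0.0))
            denom = cf if cf > 0 else pseudo
            ratio = bf / denom
            rows[p][f"bait_frac_{bait.replicate}"] = bf
            rows[p][f"control_frac_{bait.replicate}"] = cf
            rows[p][f"ratio_{bait.replicate}"] = ratio
            if p in filtered.counts.index and ratio >= fold:
                candidate[p] = True

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "protein_id"
    ratio_cols = [c for c in out.columns if c.startswith("ratio_")]
    out["max_ratio"] = out[ratio_cols].max(axis=1)
    out["candidate"] = pd.Series(candidate)
    return out.sort_index()
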