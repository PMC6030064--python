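"""Domain types and I/O shared by every analysis stage.

Coordinates are 0-based half-open (BED convention) throughout: an interval
``[start, end)`` covers ``end - start`` bases.  Fragments are assigned to
windows and bins by their midpoint ``floor((start + end) / 2)``, so every
fragment is counted exactly once and window counts are sum-conserving.
Strand is carried on intervals but ignored by all counting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TssAnnotation",
    "FragmentSet",
    "BinnedTrack",
    "CountPair",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "count_fragments_in",
    "cpm_normalize",
    "make_binned_track",
    "track_pearson",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unspecified); ``name``
    is an optional label (peak id, region id ...).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class TssAnnotation:
    """Table of transcription start sites: one row per gene.

    Columns: ``gene_id`` (unique), ``chrom``, ``strand``, ``tss`` (0-based
    position).  Promoter windows are symmetric around the TSS, so strand only
    matters for bookkeeping.
    """

    COLUMNS = ["gene_id", "chrom", "strand", "tss"]

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, self.COLUMNS].copy()
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (df["tss"] < 0).any():
            raise ValueError("tss positions must be >= 0")
        df["tss"] = df["tss"].astype(np.int64)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def windows(self, halfwidth: int) -> pd.DataFrame:
        """Symmetric promoter windows ``[tss - halfwidth, tss + halfwidth)``.

        Window starts are clipped at 0 so intervals stay valid near the
        chromosome origin.
        """
        out = self.df[["gene_id", "chrom", "tss"]].copy()
        out["start"] = np.maximum(out["tss"] - halfwidth, 0)
        out["end"] = out["tss"] + halfwidth
        return out

    @classmethod
    def read_table(cls, path) -> "TssAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return cls(df)

    def write_table(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


class FragmentSet:
    """A sequencing library as a collection of genomic fragments.

    Backed by a DataFrame with columns ``chrom``, ``start``, ``end``;
    midpoints are pre-sorted per chromosome so that counting fragments in a
    window is a pair of binary searches.
    """

    def __init__(self, library_id: str, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")
        if len(df) and ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError("fragments must satisfy 0 <= start < end")
        self.library_id = library_id
        self.df = df.reset_index(drop=True)
        mids = (
            self.df["start"].to_numpy(np.int64) + self.df["end"].to_numpy(np.int64)
        ) // 2
        self._mid_by_chrom: Dict[str, np.ndarray] = {}
        if len(df):
            chroms = self.df["chrom"].to_numpy()
            order = np.lexsort((mids, chroms))
            s_chrom, s_mid = chroms[order], mids[order]
            bounds = np.flatnonzero(np.r_[True, s_chrom[1:] != s_chrom[:-1], True])
            for i, j in zip(bounds[:-1], bounds[1:]):
                self._mid_by_chrom[s_chrom[i]] = s_mid[i:j]

    @property
    def library_size(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def chroms(self) -> List[str]:
        return sorted(self._mid_by_chrom)

    def count_in(self, chrom: str, start, end) -> np.ndarray:
        """Vectorized midpoint counts for windows ``[start, end)`` on one chromosome."""
        mids = self._mid_by_chrom.get(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if mids is None:
            return np.zeros(start.shape, dtype=np.int64)
        return np.searchsorted(mids, end, side="left") - np.searchsorted(
            mids, start, side="left"
        )

    def count_windows(self, windows: pd.DataFrame) -> np.ndarray:
        """Midpoint counts for a window table with ``chrom``/``start``/``end``."""
        windows = windows.reset_index(drop=True)
        out = np.zeros(len(windows), dtype=np.int64)
        for chrom, sub in windows.groupby("chrom", sort=False):
            out[sub.index.to_numpy()] = self.count_in(
                str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy()
            )
        return out

    @classmethod
    def from_intervals(
        cls, library_id: str, intervals: Iterable[GenomicInterval]
    ) -> "FragmentSet":
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        if not len(rows):
            df = df.astype({"chrom": str, "start": np.int64, "end": np.int64})
        return cls(library_id, df)

    @classmethod
    def from_arrays(cls, library_id, chrom, start, end) -> "FragmentSet":
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom),
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
            }
        )
        return cls(library_id, df)

    @classmethod
    def from_bed(cls, path, library_id: Optional[str] = None) -> "FragmentSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        return cls(library_id or str(path), df)

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class BinnedTrack:
    """Per-chromosome binned coverage of a library.

    ``raw`` holds integer fragment counts per bin (midpoint assignment);
    ``values`` holds the same counts normalized to fragments per million.
    Bins tile each chromosome from 0 without gaps; the last bin may be short.
    """

    bin_width: int
    chrom_sizes: Dict[str, int]
    raw: Dict[str, np.ndarray]
    values: Dict[str, np.ndarray]

    def concat(self) -> np.ndarray:
        """Genome-wide normalized bin vector, chromosomes in sorted order."""
        return np.concatenate([self.values[c] for c in sorted(self.values)])

    def concat_raw(self) -> np.ndarray:
        return np.concatenate([self.raw[c] for c in sorted(self.raw)])

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        """Mean normalized value of the bins overlapping ``[start, end)``."""
        v = self.values[chrom]
        lo = start // self.bin_width
        hi = min(-(-end // self.bin_width), len(v))
        if hi <= lo:
            return float("nan")
        return float(v[lo:hi].mean())


@dataclass(frozen=True)
class CountPair:
    """Raw ChIP and input counts for one region, with library depths."""

    region: GenomicInterval
    chip_count: int
    input_count: int
    chip_libsize: int
    input_libsize: int

    def __post_init__(self) -> None:
        if self.chip_count < 0 or self.input_count < 0:
            raise ValueError("counts must be >= 0")
        if self.chip_libsize <= 0 or self.input_libsize <= 0:
            raise ValueError("library sizes must be > 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_bed(path) -> List[GenomicInterval]:
    """Read a BED3/BED6 file into a list of intervals, in file order.

    Columns beyond 6 are ignored; the score column (5) is not retained.
    Malformed lines raise ``ValueError`` naming the offending line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"start >= end at line {lineno}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED3, or BED6 (score 0) if any carries a name/strand."""
    six = any(iv.name is not None or iv.strand != "." for iv in intervals)
    buf = io.StringIO()
    for iv in intervals:
        if six:
            buf.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )
        else:
            buf.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column ``chrom<TAB>length`` file -> ordered mapping."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'chrom length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------


def count_fragments_in(fragments: FragmentSet, region: GenomicInterval) -> int:
    """Number of fragments whose midpoint lies in ``[region.start, region.end)``."""
    return int(fragments.count_in(region.chrom, region.start, region.end))


def cpm_normalize(count, library_size: int):
    """Counts per million mapped fragments: ``count / library_size * 1e6``."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(count, dtype=float) / library_size * 1e6


def make_binned_track(
    fragments: FragmentSet, chrom_sizes: Mapping[str, int], bin_width: int
) -> BinnedTrack:
    """Bin a library genome-wide by fragment midpoint and CPM-normalize.

    Every chromosome in ``chrom_sizes`` gets a (possibly all-zero) vector;
    a fragment on a chromosome absent from ``chrom_sizes`` is an error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    unknown = set(fragments._mid_by_chrom) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on chromosomes absent from sizes: {sorted(unknown)}")
    raw: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    libsize = max(fragments.library_size, 1)
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_width)
        mids = fragments._mid_by_chrom.get(chrom)
        if mids is None:
            counts = np.zeros(n_bins, dtype=np.int64)
        else:
            counts = np.bincount(mids // bin_width, minlength=n_bins).astype(np.int64)
        raw[chrom] = counts
        values[chrom] = counts / libsize * 1e6
    return BinnedTrack(bin_width=bin_width, chrom_sizes=dict(chrom_sizes), raw=raw, values=values)


def track_pearson(a: BinnedTrack, b: BinnedTrack) -> float:
    """Pearson correlation of two tracks over the concatenated genome-wide bins.

    Requires identical bin width and chromosome partition; a zero-variance
    vector is an error, never silently 0.
    """
    if a.bin_width != b.bin_width or a.chrom_sizes != b.chrom_sizes:
        raise ValueError("tracks have mismatched binning")
    x, y = a.concat(), b.concat()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance track: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
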