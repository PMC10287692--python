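"""Tabular formats, coordinate conventions and validation.

In-memory containers
--------------------
SV calls, copy-number segments and sample metadata travel through the pipeline
as pandas DataFrames with fixed, validated column schemas:

``SV_COLUMNS``
    One row per somatic SV (one record per SV, not per breakend; a
    translocation carries both chromosomes in one row). Breakpoint positions
    are 1-based. ``rsv`` is the SV-supporting read count; ``rref1``/``rref2``
    are reference-supporting counts at each breakpoint.
``SEG_COLUMNS``
    Per-sample segmented copy-number ratio on a linear scale (1.0 = normal
    diploid). Intervals are 1-based inclusive and non-overlapping per sample
    and chromosome.
``META_COLUMNS``
    Per-sample tumor purity in (0, 1] plus arbitrary clinical/molecular
    feature columns.

Annotation tracks (chromatin state, LINE-1 elements, common fragile sites)
are read from BED and kept in their native 0-based half-open convention
inside :class:`AnnotationTrack`; all queries accept 1-based positions so the
conversion happens in exactly one place.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

SV_COLUMNS = [
    "sample_id", "chrom1", "pos1", "chrom2", "pos2",
    "sv_type", "orientation1", "orientation2", "rsv", "rref1", "rref2",
]

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "cnr"]

META_COLUMNS = ["sample_id", "purity"]


class FormatError(ValueError):
    """A table violated the schema or an invariant; message names the row."""


# ---------------------------------------------------------------------------
# SV tables
# ---------------------------------------------------------------------------

def validate_sv_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate SV-record invariants, returning the frame unchanged.

    Checks: required columns, known SV types, pos1 <= pos2 on the same
    chromosome, TRA if and only if the chromosomes differ, and non-negative
    read counts.
    """
    missing = [c for c in SV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SV table missing columns: {missing}")
    if len(df) == 0:
        return df
    bad_type = ~df["sv_type"].isin(SV_TYPES)
    if bad_type.any():
        row = df.index[bad_type][0]
        raise FormatError(f"row {row}: unknown sv_type {df.loc[row, 'sv_type']!r}")
    intra = df["chrom1"] == df["chrom2"]
    is_tra = df["sv_type"] == "TRA"
    if (is_tra & intra).any():
        row = df.index[is_tra & intra][0]
        raise FormatError(f"row {row}: sv_type TRA requires chrom1 != chrom2")
    if (~is_tra & ~intra).any():
        row = df.index[~is_tra & ~intra][0]
        raise FormatError(f"row {row}: chrom1 != chrom2 requires sv_type TRA")
    disordered = intra & (df["pos1"] > df["pos2"])
    if disordered.any():
        row = df.index[disordered][0]
        raise FormatError(f"row {row}: pos1 > pos2 on the same chromosome")
    for col in ("rsv", "rref1", "rref2"):
        if (df[col] < 0).any():
            row = df.index[df[col] < 0][0]
            raise FormatError(f"row {row}: negative {col}")
    return df


def read_sv_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a somatic SV table.

    Parameters
    ----------
    path
        TSV file. ``dialect="tsv"`` expects the native 1-based ``SV_COLUMNS``
        schema; ``dialect="bedpe"`` expects 10 standard BEDPE columns
        (0-based half-open starts) followed by ``sample_id sv_type rsv rref1
        rref2``, with breakpoints taken as ``start + 1``.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "bedpe":
        bedpe = pd.read_csv(path, sep="\t")
        required = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                    "name", "score", "strand1", "strand2",
                    "sample_id", "sv_type", "rsv", "rref1", "rref2"]
        missing = [c for c in required if c not in bedpe.columns]
        if missing:
            raise FormatError(f"BEDPE missing columns: {missing}")
        df = pd.DataFrame({
            "sample_id": bedpe["sample_id"],
            "chrom1": bedpe["chrom1"],
            "pos1": bedpe["start1"].astype(int) + 1,
            "chrom2": bedpe["chrom2"],
            "pos2": bedpe["start2"].astype(int) + 1,
            "sv_type": bedpe["sv_type"],
            "orientation1": bedpe["strand1"],
            "orientation2": bedpe["strand2"],
            "rsv": bedpe["rsv"].astype(int),
            "rref1": bedpe["rref1"].astype(int),
            "rref2": bedpe["rref2"].astype(int),
        })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return validate_sv_table(df.reset_index(drop=True))


def write_sv_table(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write an SV table in the given dialect (inverse of :func:`read_sv_table`)."""
    path = Path(path)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "bedpe":
        out = pd.DataFrame({
            "chrom1": df["chrom1"],
            "start1": df["pos1"].astype(int) - 1,
            "end1": df["pos1"].astype(int),
            "chrom2": df["chrom2"],
            "start2": df["pos2"].astype(int) - 1,
            "end2": df["pos2"].astype(int),
            "name": [f"sv{i}" for i in range(len(df))],
            "score": 0,
            "strand1": df["orientation1"],
            "strand2": df["orientation2"],
            "sample_id": df["sample_id"],
            "sv_type": df["sv_type"],
            "rsv": df["rsv"],
            "rref1": df["rref1"],
            "rref2": df["rref2"],
        })
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------

def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Check segment invariants: start <= end, cnr > 0, no overlap per sample."""
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment table missing columns: {missing}")
    if len(df) == 0:
        return df
    if (df["start"] > df["end"]).any():
        row = df.index[df["start"] > df["end"]][0]
        raise FormatError(f"row {row}: segment start > end")
    if (df["cnr"] <= 0).any():
        row = df.index[df["cnr"] <= 0][0]
        raise FormatError(f"row {row}: non-positive copy-number ratio")
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise FormatError(
                f"overlapping segments for sample {sample} on {chrom}")
    return df


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like TSV of copy-number segments.

    Accepts either a ``cnr`` column (linear ratio) or a ``log2ratio`` column,
    which is exponentiated to linear scale. Coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t")
    if "cnr" not in df.columns:
        if "log2ratio" not in df.columns:
            raise FormatError("segment table needs a 'cnr' or 'log2ratio' column")
        df = df.copy()
        df["cnr"] = np.exp2(df["log2ratio"].astype(float))
        df = df.drop(columns=["log2ratio"])
    df = df[[c for c in df.columns if c in SEG_COLUMNS + ["acn"]]]
    return validate_segments(df.reset_index(drop=True))


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata; requires sample_id and purity in (0, 1]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")
    bad = (df["purity"] <= 0) | (df["purity"] > 1)
    if bad.any():
        row = df.index[bad][0]
        raise FormatError(f"row {row}: purity outside (0, 1]")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnnotationTrack:
    """A named set of genomic intervals in 0-based half-open convention.

    Intervals are stored merged and sorted per chromosome as parallel numpy
    arrays, which makes point-overlap and nearest-distance queries a pair of
    ``searchsorted`` calls.
    """

    name: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (starts, ends)

    @classmethod
    def from_intervals(cls, name: str,
                       rows: Iterable[tuple[str, int, int]]) -> "AnnotationTrack":
        """Build a track from (chrom, start, end) 0-based half-open rows.

        Zero-length or inverted intervals raise; overlapping and adjacent
        intervals are merged (interval union).
        """
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in rows:
            if start < 0 or end <= start:
                raise FormatError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            starts = np.array([s for s, _ in out], dtype=np.int64)
            ends = np.array([e for _, e in out], dtype=np.int64)
            merged[chrom] = (starts, ends)
        return cls(name=name, intervals=merged)

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def contains(self, chrom: str, pos: int | np.ndarray) -> np.ndarray | bool:
        """Whether 1-based position(s) fall inside the track."""
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        if chrom not in self.intervals:
            result = np.zeros(pos0.shape, dtype=bool)
            return bool(result) if result.ndim == 0 else result
        starts, ends = self.intervals[chrom]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        return bool(inside) if inside.ndim == 0 else inside

    def distance(self, chrom: str, pos: int) -> float:
        """Distance in bp from a 1-based position to the nearest interval.

        0 if inside; ``inf`` if the chromosome carries no intervals.
        """
        if chrom not in self.intervals:
            return float("inf")
        starts, ends = self.intervals[chrom]
        pos0 = int(pos) - 1
        idx = int(np.searchsorted(starts, pos0, side="right")) - 1
        best = float("inf")
        if idx >= 0:
            if pos0 < ends[idx]:
                return 0.0
            best = min(best, pos0 - ends[idx] + 1)
        if idx + 1 < len(starts):
            best = min(best, starts[idx + 1] - pos0)
        return float(best)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, int(s), int(e))
                for c in sorted(self.intervals)
                for s, e in zip(*self.intervals[c])]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_track(path: str | Path, name: str) -> AnnotationTrack:
    """Read a BED3(+) file into an :class:`AnnotationTrack` (union of intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    rows = zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int),
               df.iloc[:, 2].astype(int))
    return AnnotationTrack.from_intervals(name, rows)


def write_track(track: AnnotationTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)
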