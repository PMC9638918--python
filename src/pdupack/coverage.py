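"""Per-base read coverage and median-chromosome normalization.

Coverage of a replicon is the number of primary alignments overlapping each
base.  Tracks are normalized against the median per-base coverage of the
chromosome of the same sample:

    normalized[b] = (depth[b] - median_chrom) / median_chrom

so a value of 0 means chromosome-median coverage, -1 means no coverage, and
+2 means threefold the chromosome median.  The median is taken over all
chromosome positions including zeros (excluding zeros would inflate the
baseline; switchable via ``include_zeros``).  Coordinates are 0-based,
half-open; strand is ignored (the analysis is strand-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import Replicon, SampleModel

ALIGNMENT_COLUMNS = ["replicon", "start", "end", "strand", "is_primary"]

_NON_PRIMARY_TAGS = (":secondary", ":supplementary")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary-alignment interval (0-based, half-open)."""

    replicon: str
    start: int
    end: int
    strand: str = "+"
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"alignment interval invalid: [{self.start}, {self.end})")


@dataclass
class DepthTrack:
    """Integer per-base coverage of one replicon."""

    replicon: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")


@dataclass
class NormalizedTrack:
    """Median-chromosome-normalized coverage of one replicon.

    For replicate averages ``medians_used`` records each input's median.
    """

    replicon: str
    values: np.ndarray
    median_used: float
    medians_used: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def as_frame(alignments) -> pd.DataFrame:
    """Coerce a list of AlignmentRecord, or a compatible DataFrame, to a table."""
    if isinstance(alignments, pd.DataFrame):
        frame = alignments
        if "strand" not in frame.columns:
            frame = frame.assign(strand="+")
        if "is_primary" not in frame.columns:
            frame = frame.assign(is_primary=True)
        return frame[ALIGNMENT_COLUMNS]
    return pd.DataFrame(
        [(a.replicon, a.start, a.end, a.strand, a.is_primary) for a in alignments],
        columns=ALIGNMENT_COLUMNS,
    )


def _load_bed(path: Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AlignmentError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AlignmentError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise AlignmentError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else ""
            if any(name.endswith(tag) for tag in _NON_PRIMARY_TAGS):
                continue
            strand = fields[5] if len(fields) > 5 else "+"
            records.append(AlignmentRecord(fields[0], start, end, strand, True))
    return records


def _load_bam(path: Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path)) as bam:  # format auto-detected (BAM or SAM)
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            records.append(
                AlignmentRecord(
                    read.reference_name,
                    read.reference_start,
                    read.reference_end,
                    "-" if read.is_reverse else "+",
                    True,
                )
            )
    return records


def load_alignments(
    path: str | Path,
    dialect: str = "bed",
    model: SampleModel | None = None,
) -> list[AlignmentRecord]:
    """Load primary alignments from BED6 or coordinate-sorted BAM.

    Secondary/supplementary records (BAM flags, or BED name suffixes
    ``:secondary`` / ``:supplementary``) and unmapped records are excluded.
    Records are returned sorted by (replicon, start), stable for ties.
    When a model is given, unknown replicon names raise an error listing
    the offending names.
    """
    path = Path(path)
    if dialect == "bed":
        records = _load_bed(path)
    elif dialect == "bam":
        records = _load_bam(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'bed' or 'bam'")
    records.sort(key=lambda a: (a.replicon, a.start))
    if model is not None:
        known = {r.name for r in model.replicons}
        unknown = sorted({a.replicon for a in records} - known)
        if unknown:
            raise AlignmentError(f"alignments reference unknown replicons: {unknown}")
    return records


def compute_depth(alignments, replicon: Replicon) -> DepthTrack:
    """Per-base count of primary alignments overlapping each base.

    Uses a difference-array (event) accumulation; intervals are clipped to
    the replicon bounds.  Result is invariant to the order of alignments.
    """
    frame = as_frame(alignments)
    sub = frame[(frame["replicon"] == replicon.name) & frame["is_primary"]]
    L = replicon.length
    diff = np.zeros(L + 1, dtype=np.int64)
    if len(sub):
        starts = np.clip(sub["start"].to_numpy(np.int64), 0, L)
        ends = np.clip(sub["end"].to_numpy(np.int64), 0, L)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
    return DepthTrack(replicon.name, np.cumsum(diff[:-1]))


def median_chromosome_depth(track: DepthTrack, include_zeros: bool = True) -> float:
    """Median per-base coverage of the chromosome (zeros included by default)."""
    if track.depth.size == 0:
        raise ValueError("cannot take the median of a zero-length track")
    depth = track.depth if include_zeros else track.depth[track.depth > 0]
    if depth.size == 0:
        return 0.0
    return float(np.median(depth))


def normalize_depth(track: DepthTrack, median: float) -> NormalizedTrack:
    """Median-chromosome normalization: (depth - median) / median."""
    if median <= 0:
        raise ValueError("chromosome coverage too sparse to normalize (median <= 0)")
    values = (track.depth.astype(float) - median) / median
    return NormalizedTrack(track.replicon, values, float(median), (float(median),))


def average_replicates(tracks: Sequence[NormalizedTrack]) -> NormalizedTrack:
    """Elementwise mean of replicate normalized tracks (same replicon/length)."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.replicon != first.replicon:
            raise ValueError("cannot average tracks of different replicons")
        if t.values.shape != first.values.shape:
            raise ValueError("cannot average tracks of different lengths")
    values = np.mean([t.values for t in tracks], axis=0)
    medians = tuple(m for t in tracks for m in (t.medians_used or (t.median_used,)))
    return NormalizedTrack(first.replicon, values, float(np.mean(medians)), medians)


def write_bedgraph(
    replicon_name: str,
    values: np.ndarray,
    path: str | Path,
    fmt: str = "%.6g",
) -> Path:
    """Write a 4-column bedGraph (0-based, half-open), run-length compressed."""
    values = np.asarray(values)
    path = Path(path)
    with path.open("w") as fh:
        if values.size:
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{replicon_name}\t{s}\t{e}\t{fmt % values[s]}\n")
    return path
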