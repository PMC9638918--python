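"""Read-enrichment statistics for the 600-bp operator segment.

For each replicon the *expected* percentage of reads per 600 bp is the
share a random 600-bp window of that replicon would capture if the reads
mapped to the replicon were spread homogeneously along it:

    expected_pct(rep) = 100 * (N_rep / L_rep * 600) / N_total

The *observed* percentage is the share of all reads assigned to the fixed
operator-carrying segment, and the plasmid-relative percentage is the share
of the target plasmid's own reads that fall in the segment:

    observed_pct        = 100 * N_seg / N_total
    plasmid_relative    = 100 * N_seg / N_rep(target)

Fold enrichment compares the observed segment share with the share a random
600-bp window on the target plasmid would capture under a homogeneous,
copy-number-weighted read distribution across the whole sample (the
sampling null of the background model):

    uniform_null_pct(rep) = 100 * 600 * copy_number(rep) / sum_i L_i * cn_i
    fold                  = observed_pct / uniform_null_pct(target)

``fold_vs_replicon`` (observed over the realized per-replicon expectation)
is also reported; note it is bounded above by L_target / 600 because the
realized N_rep already reflects the packaging enrichment of the plasmid.

Two counting policies are provided: ``overlap_any`` (default; >= 1 bp of
overlap, matching region extraction on indexed alignments) and ``start_in``
(alignment start inside the window).  ``start_in`` partitions reads across
a tiling of windows and is unbiased for null comparisons; ``overlap_any``
overstates a window's share by roughly the mean read length / 600.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import as_frame
from .genome import Replicon, SampleModel, Segment, SEGMENT_LEN

POLICIES = ("overlap_any", "start_in")


@dataclass(frozen=True)
class ReadCounts:
    """Primary-alignment counts of one sample."""

    per_replicon: dict[str, int]
    segment_count: int
    segment_replicon: str

    @property
    def total(self) -> int:
        return sum(self.per_replicon.values())

    def __post_init__(self) -> None:
        n_rep = self.per_replicon.get(self.segment_replicon, 0)
        if not (0 <= self.segment_count <= n_rep):
            raise ValueError(
                f"segment count {self.segment_count} outside [0, {n_rep}] "
                f"for replicon {self.segment_replicon!r}"
            )


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-replicon expected shares and the segment's observed enrichment."""

    expected_pct: dict[str, float]
    observed_pct: float
    plasmid_relative_pct: float  # NaN when the target plasmid has no reads
    fold: float
    fold_vs_replicon: float


def count_segment_reads(alignments, segment: Segment, policy: str = "overlap_any") -> int:
    """Count primary alignments assigned to the segment under a policy."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    frame = as_frame(alignments)
    frame = frame[frame["is_primary"]]
    if len(frame) == 0:
        return 0
    if segment.replicon not in set(frame["replicon"]):
        raise ValueError(
            f"segment replicon {segment.replicon!r} absent from alignments"
        )
    sub = frame[frame["replicon"] == segment.replicon]
    start = sub["start"].to_numpy(np.int64)
    end = sub["end"].to_numpy(np.int64)
    if policy == "overlap_any":
        hit = (start < segment.end) & (end > segment.start)
    else:
        hit = (start >= segment.start) & (start < segment.end)
    return int(hit.sum())


def counts_from_alignments(
    alignments, model: SampleModel, policy: str = "overlap_any"
) -> ReadCounts:
    """Tally per-replicon and segment counts for one sample."""
    frame = as_frame(alignments)
    frame = frame[frame["is_primary"]]
    per = {r.name: 0 for r in model.replicons}
    vc = frame["replicon"].value_counts()
    for name, n in vc.items():
        if name not in per:
            raise ValueError(f"alignments reference unknown replicon {name!r}")
        per[name] = int(n)
    seg_count = (
        count_segment_reads(frame, model.segment, policy)
        if per.get(model.segment.replicon, 0)
        else 0
    )
    return ReadCounts(per, seg_count, model.segment.replicon)


def expected_pct_per_600(
    counts: ReadCounts, replicon: Replicon, window: int = SEGMENT_LEN
) -> float:
    """Share of all reads a random `window`-bp stretch of `replicon` captures."""
    if replicon.length <= 0:
        raise ValueError("replicon length must be > 0")
    total = counts.total
    if total == 0:
        raise ValueError("no mapped reads: expected percentage undefined")
    n_rep = counts.per_replicon.get(replicon.name, 0)
    return 100.0 * (n_rep / replicon.length * window) / total


def observed_pct(counts: ReadCounts) -> float:
    """Segment reads as a percentage of all mapped reads."""
    total = counts.total
    if total == 0:
        raise ValueError("no mapped reads: observed percentage undefined")
    return 100.0 * counts.segment_count / total


def plasmid_relative_pct(counts: ReadCounts) -> float:
    """Segment reads as a percentage of the target plasmid's reads.

    Undefined (NaN, rendered "NA" in reports) when the plasmid has no reads;
    never silently 0.
    """
    n_rep = counts.per_replicon.get(counts.segment_replicon, 0)
    if n_rep == 0:
        return math.nan
    return 100.0 * counts.segment_count / n_rep


def uniform_null_pct(
    model: SampleModel, replicon: Replicon | None = None, window: int = SEGMENT_LEN
) -> float:
    """Share a random `window` of `replicon` captures under the homogeneous,
    copy-number-weighted null (reads spread over all replicons by cn x length)."""
    if replicon is None:
        replicon = model.segment_replicon
    mass = sum(r.copy_number * r.length for r in model.replicons)
    return 100.0 * window * replicon.copy_number / mass


def build_report(counts: ReadCounts, model: SampleModel) -> EnrichmentReport:
    """Assemble the enrichment quantities of one replicate."""
    expected = {
        r.name: expected_pct_per_600(counts, r) for r in model.replicons
    }
    obs = observed_pct(counts)
    null = uniform_null_pct(model)
    exp_target = expected[model.segment.replicon]
    return EnrichmentReport(
        expected_pct=expected,
        observed_pct=obs,
        plasmid_relative_pct=plasmid_relative_pct(counts),
        fold=obs / null,
        fold_vs_replicon=(obs / exp_target) if exp_target > 0 else math.nan,
    )


def average_reports(reports: Sequence[EnrichmentReport]) -> EnrichmentReport:
    """Arithmetic mean of each percentage across replicates (NaN-propagating
    only when all replicates are undefined)."""
    if not reports:
        raise ValueError("no reports to average")
    keys = set(reports[0].expected_pct)
    for r in reports[1:]:
        if set(r.expected_pct) != keys:
            raise ValueError("inconsistent replicon sets across replicates")

    def nmean(vals: list[float]) -> float:
        finite = [v for v in vals if not math.isnan(v)]
        return sum(finite) / len(finite) if finite else math.nan

    return EnrichmentReport(
        expected_pct={k: nmean([r.expected_pct[k] for r in reports]) for k in keys},
        observed_pct=nmean([r.observed_pct for r in reports]),
        plasmid_relative_pct=nmean([r.plasmid_relative_pct for r in reports]),
        fold=nmean([r.fold for r in reports]),
        fold_vs_replicon=nmean([r.fold_vs_replicon for r in reports]),
    )


def _fmt(v: float) -> str:
    return "NA" if (isinstance(v, float) and math.isnan(v)) else f"{v:.3f}"


def write_report_tsv(
    reports: Sequence[EnrichmentReport],
    model: SampleModel,
    path: str | Path,
    averaged: EnrichmentReport | None = None,
) -> Path:
    """Write per-replicate and averaged enrichment percentages as TSV.

    Rows follow the replicon order of the model (expected % per 600 bp),
    then the observed segment share, the plasmid-relative share, and the
    fold enrichments.  Percentages are printed to 3 decimals.
    """
    path = Path(path)
    cols = [f"replicate_{i + 1}" for i in range(len(reports))]
    if averaged is not None:
        cols.append("average")
    rows: list[tuple[str, list[float]]] = []
    for r in model.replicons:
        rows.append(
            (f"expected_pct_per_600bp[{r.name}]", [rep.expected_pct[r.name] for rep in reports])
        )
    rows.append(("segment_observed_pct", [rep.observed_pct for rep in reports]))
    rows.append(("segment_plasmid_relative_pct", [rep.plasmid_relative_pct for rep in reports]))
    rows.append(("fold_enrichment", [rep.fold for rep in reports]))
    rows.append(("fold_vs_replicon_expectation", [rep.fold_vs_replicon for rep in reports]))
    if averaged is not None:
        avg_vals = (
            [averaged.expected_pct[r.name] for r in model.replicons]
            + [
                averaged.observed_pct,
                averaged.plasmid_relative_pct,
                averaged.fold,
                averaged.fold_vs_replicon,
            ]
        )
    with path.open("w") as fh:
        fh.write("quantity\t" + "\t".join(cols) + "\n")
        for i, (name, vals) in enumerate(rows):
            line = [name] + [_fmt(v) for v in vals]
            if averaged is not None:
                line.append(_fmt(avg_vals[i]))
            fh.write("\t".join(line) + "\n")
    return path
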