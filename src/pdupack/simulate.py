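"""Synthetic-data generator: footprint protection, degradation, and reads.

The model follows the proposed packaging mechanism: repressor molecules
occupy their operator sites on plasmid molecules; protein-bound DNA is
shielded from host nucleases while unprotected extrachromosomal DNA is
degraded during shell assembly.  The DNA recovered from purified
compartments therefore consists of

* protected operator-cluster fragments (150-300 bp after shearing),
* a small number of unprotected plasmid fragments that escaped degradation
  (Bernoulli survival, one parameter), and
* a sequence-nonspecific background drawn copy-number-weighted from all
  replicons, reproducing the residual chromosomal/helper-plasmid reads seen
  in real samples.

Reads are single-end and cover whole fragments (Ion-Torrent-like, variable
length); there is no paired-end mode.  All randomness flows through named
child streams ("occupancy", "degradation", "reads") of one root seed, so a
fixed seed yields byte-identical FASTQ/BED output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import SampleModel, Replicon

ORIGIN_PROTECTED = "protected"
ORIGIN_BACKGROUND = "background"

_QUAL_CHAR = "?"  # constant Phred+33 Q30

TRUTH_COLUMNS = ["replicon", "start", "end", "origin"]


class NothingToSampleError(RuntimeError):
    """No fragments survived and background sampling is disabled."""


@dataclass(frozen=True)
class ProtectionParams:
    """Parameters of the protection/degradation/read model.

    p_occ
        Per-site, per-molecule occupancy probability of LacI/LexA sites.
    footprint
        Protected bp added on each side of a bound site (nucleosome-style
        footprint extension; bound repressors plus steric shielding).
    merge_gap
        Protected intervals separated by fewer than this many bp merge.
    survival_unprotected
        Probability that an unprotected plasmid fragment escapes degradation.
    background_rate
        Expected fraction of reads drawn uniformly (copy-number-weighted)
        from all replicons, modelling sequence-nonspecific co-packaging.
    frag_len_min, frag_len_max
        Packaged fragment length bounds (bp); defaults 150-300.
    molecule_count
        Plasmid molecules simulated per run, allocated across plasmids in
        proportion to copy number.
    """

    p_occ: float = 0.9
    footprint: int = 25
    merge_gap: int = 10
    survival_unprotected: float = 0.002
    background_rate: float = 0.05
    frag_len_min: int = 150
    frag_len_max: int = 300
    n_reads: int = 100_000
    error_rate: float = 0.005
    seed: int = 0
    molecule_count: int = 1000

    def __post_init__(self) -> None:
        for name in ("p_occ", "survival_unprotected", "background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.frag_len_min <= self.frag_len_max):
            raise ValueError("need 0 < frag_len_min <= frag_len_max")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        if self.molecule_count < 1:
            raise ValueError("molecule_count must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.footprint < 0 or self.merge_gap < 0:
            raise ValueError("footprint and merge_gap must be >= 0")


@dataclass(frozen=True)
class Fragment:
    """A surviving DNA fragment with its provenance.

    ``origin`` is "protected" for pieces of repressor-protected intervals and
    "background" for unprotected plasmid pieces that escaped degradation.
    ``short`` flags protected remainders below frag_len_min that were emitted
    as-is rather than discarded (protein-bound DNA is never lost).
    """

    replicon: str
    start: int
    end: int
    origin: str
    short: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedReads:
    """Paths and in-memory truth of one read simulation."""

    fastq_path: Path | None
    bed_path: Path | None
    truth: pd.DataFrame  # columns: replicon, start, end, origin


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG stream of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def allocate_molecules(model: SampleModel, molecule_count: int) -> dict[str, int]:
    """Distribute plasmid molecules across plasmids in proportion to copy number.

    Uses largest-remainder rounding; every plasmid gets at least one molecule
    when molecule_count allows.  The chromosome gets none: it contributes
    reads only through the background channel.
    """
    plasmids = model.plasmids
    if not plasmids:
        return {}
    weights = np.array([p.copy_number for p in plasmids], dtype=float)
    exact = molecule_count * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    remainder = molecule_count - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    if molecule_count >= len(plasmids):
        while (counts == 0).any():
            counts[np.argmax(counts)] -= 1
            counts[np.argmin(counts)] += 1
    return {p.name: int(c) for p, c in zip(plasmids, counts)}


def _merge_intervals(intervals: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe < merge_gap or s <= pe:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def simulate_occupancy(
    model: SampleModel,
    params: ProtectionParams,
    molecule_count: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[list[tuple[int, int]]]]:
    """Simulate per-molecule repressor occupancy and protected intervals.

    For every plasmid molecule each LacI/LexA site is bound independently
    with probability ``p_occ``; each bound site protects
    [start - footprint, end + footprint) clipped to the replicon, and
    intervals closer than ``merge_gap`` merge.  I-SceI sites never protect.
    Returns {plasmid name: [per-molecule list of merged (start, end)]}.
    """
    if molecule_count is None:
        molecule_count = params.molecule_count
    if molecule_count < 1:
        raise ValueError("molecule_count must be >= 1")
    if rng is None:
        rng = stream(params.seed, "occupancy")
    allocation = allocate_molecules(model, molecule_count)
    out: dict[str, list[list[tuple[int, int]]]] = {}
    for plasmid in model.plasmids:
        n_mol = allocation.get(plasmid.name, 0)
        sites = model.factor_sites(plasmid.name)
        raw = [
            (max(0, s.start - params.footprint), min(plasmid.length, s.end + params.footprint))
            for s in sites
        ]
        molecules: list[list[tuple[int, int]]] = []
        if sites:
            u = rng.random((n_mol, len(sites)))
            for row in u:
                bound = [iv for iv, ui in zip(raw, row) if ui < params.p_occ]
                molecules.append(_merge_intervals(bound, params.merge_gap))
        else:
            molecules = [[] for _ in range(n_mol)]
        out[plasmid.name] = molecules
    return out


def _chop(
    start: int,
    end: int,
    rng: np.random.Generator,
    lmin: int,
    lmax: int,
    keep_short: bool,
) -> list[tuple[int, int, bool]]:
    """Cut [start, end) into pieces within [lmin, lmax] at random breakpoints.

    A final remainder shorter than lmin is kept (flagged) when keep_short,
    otherwise discarded.  Intervals already within bounds pass through whole.
    """
    out: list[tuple[int, int, bool]] = []
    pos = start
    while end - pos > lmax:
        cut = int(rng.integers(lmin, lmax + 1))
        out.append((pos, pos + cut, False))
        pos += cut
    rem = end - pos
    if rem >= lmin:
        out.append((pos, end, False))
    elif rem > 0 and keep_short:
        out.append((pos, end, True))
    return out


def degrade_and_fragment(
    model: SampleModel,
    occupancy: dict[str, list[list[tuple[int, int]]]],
    params: ProtectionParams,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Apply nuclease degradation and shearing to every simulated molecule.

    Protected intervals always survive; they are sheared into pieces within
    [frag_len_min, frag_len_max] (protected remainders below the minimum are
    emitted flagged).  Unprotected stretches are sheared the same way but
    each piece survives only with probability ``survival_unprotected``.
    """
    if rng is None:
        rng = stream(params.seed, "degradation")
    lmin, lmax = params.frag_len_min, params.frag_len_max
    fragments: list[Fragment] = []
    for plasmid in model.plasmids:
        L = plasmid.length
        for protected in occupancy.get(plasmid.name, []):
            for s, e in protected:
                for ps, pe, short in _chop(s, e, rng, lmin, lmax, keep_short=True):
                    fragments.append(Fragment(plasmid.name, ps, pe, ORIGIN_PROTECTED, short))
            # complement of the protected intervals within [0, L)
            pos = 0
            gaps: list[tuple[int, int]] = []
            for s, e in protected:
                if s > pos:
                    gaps.append((pos, s))
                pos = max(pos, e)
            if pos < L:
                gaps.append((pos, L))
            if params.survival_unprotected > 0.0:
                for gs, ge in gaps:
                    for ps, pe, _ in _chop(gs, ge, rng, lmin, lmax, keep_short=False):
                        if rng.random() < params.survival_unprotected:
                            fragments.append(Fragment(plasmid.name, ps, pe, ORIGIN_BACKGROUND))
    return fragments


def sample_read_intervals(
    model: SampleModel,
    params: ProtectionParams,
    fragments: Sequence[Fragment] | None = None,
) -> pd.DataFrame:
    """Draw the truth placements of ``n_reads`` reads (no sequences).

    Per read, a Bernoulli(background_rate) coin selects the background
    channel (replicon chosen with probability proportional to
    copy_number x length, start uniform on the replicon, length uniform in
    [frag_len_min, frag_len_max], truncated at the replicon end) versus the
    packaging channel (one fragment chosen uniformly; the read covers the
    whole fragment).  Returns a DataFrame with columns replicon, start, end,
    origin, in read order.
    """
    if fragments is None:
        if params.background_rate >= 1.0:
            fragments = []
        else:
            occ = simulate_occupancy(model, params)
            fragments = degrade_and_fragment(model, occ, params)
    rng = stream(params.seed, "reads")
    n = params.n_reads
    is_bg = rng.random(n) < params.background_rate
    if not fragments:
        if params.background_rate == 0.0:
            raise NothingToSampleError(
                "nothing to sample: no fragments survived and background_rate is 0"
            )
        is_bg[:] = True

    repl_names = np.array([r.name for r in model.replicons])
    lengths = np.array([r.length for r in model.replicons], dtype=np.int64)
    weights = np.array([r.copy_number * r.length for r in model.replicons], dtype=float)
    weights /= weights.sum()

    start = np.zeros(n, dtype=np.int64)
    end = np.zeros(n, dtype=np.int64)
    repl_idx = np.zeros(n, dtype=np.int64)
    origin = np.empty(n, dtype=object)

    bg_pos = np.flatnonzero(is_bg)
    if bg_pos.size:
        ridx = rng.choice(len(repl_names), size=bg_pos.size, p=weights)
        L = lengths[ridx]
        s = np.floor(rng.random(bg_pos.size) * L).astype(np.int64)
        ln = rng.integers(params.frag_len_min, params.frag_len_max + 1, size=bg_pos.size)
        e = np.minimum(s + ln, L)
        repl_idx[bg_pos] = ridx
        start[bg_pos] = s
        end[bg_pos] = e
        origin[bg_pos] = ORIGIN_BACKGROUND

    pk_pos = np.flatnonzero(~is_bg)
    if pk_pos.size:
        name_to_idx = {name: i for i, name in enumerate(repl_names)}
        frag_repl = np.array([name_to_idx[f.replicon] for f in fragments], dtype=np.int64)
        frag_start = np.array([f.start for f in fragments], dtype=np.int64)
        frag_end = np.array([f.end for f in fragments], dtype=np.int64)
        frag_origin = np.array([f.origin for f in fragments], dtype=object)
        fidx = rng.integers(0, len(fragments), size=pk_pos.size)
        repl_idx[pk_pos] = frag_repl[fidx]
        start[pk_pos] = frag_start[fidx]
        end[pk_pos] = frag_end[fidx]
        origin[pk_pos] = frag_origin[fidx]

    return pd.DataFrame(
        {
            "replicon": repl_names[repl_idx],
            "start": start,
            "end": end,
            "origin": origin,
        }
    )


_COMPLEMENT_CHOICES = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    picks = rng.integers(0, 3, size=hits.size)
    for i, p in zip(hits, picks):
        chars[i] = _COMPLEMENT_CHOICES.get(chars[i], "ACG")[p]
    return "".join(chars)


def simulate_reads(
    model: SampleModel,
    params: ProtectionParams,
    fastq_path: str | Path | None = None,
    bed_path: str | Path | None = None,
) -> SimulatedReads:
    """Full read simulation: truth placements, sequences, FASTQ and truth BED.

    Sequences are reference substrings at the truth interval with uniform
    substitution errors at ``error_rate``; qualities are constant Q30.  The
    truth BED is BED6 with name = origin, and line i corresponds to FASTQ
    record i.  Requires replicon sequences.
    """
    for r in model.replicons:
        if r.sequence is None:
            raise ValueError(f"replicon {r.name!r} has no sequence; cannot emit reads")
    truth = sample_read_intervals(model, params)
    err_rng = stream(params.seed, "errors")
    seqs_by_name = {r.name: r.sequence for r in model.replicons}

    fastq_path = Path(fastq_path) if fastq_path is not None else None
    bed_path = Path(bed_path) if bed_path is not None else None
    fq_lines: list[str] = []
    bed_lines: list[str] = []
    repl = truth["replicon"].to_numpy()
    start = truth["start"].to_numpy()
    end = truth["end"].to_numpy()
    origin = truth["origin"].to_numpy()
    for i in range(len(truth)):
        seq = seqs_by_name[repl[i]][start[i]:end[i]]
        seq = _mutate(seq, err_rng, params.error_rate)
        if fastq_path is not None:
            fq_lines.append(f"@r{i:07d}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
        if bed_path is not None:
            bed_lines.append(f"{repl[i]}\t{start[i]}\t{end[i]}\t{origin[i]}\t0\t+\n")
    if fastq_path is not None:
        fastq_path.write_text("".join(fq_lines))
    if bed_path is not None:
        bed_path.write_text("".join(bed_lines))
    return SimulatedReads(fastq_path=fastq_path, bed_path=bed_path, truth=truth)


def truth_to_alignments(truth: pd.DataFrame) -> pd.DataFrame:
    """Convert truth placements to an alignment table usable by `coverage`.

    Synthetic reads carry their ground-truth placement, so mapping is
    bypassed: every record is a primary, plus-strand alignment.
    """
    out = truth[["replicon", "start", "end"]].copy()
    out["strand"] = "+"
    out["is_primary"] = True
    return out
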