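"""Replicon and operator-site models for Pdu-microcompartment DNA packaging studies.

A packaging experiment involves a host chromosome plus two plasmids: a
helper plasmid (pOH analogue, p15A-like, ~9 copies/cell) expressing the
shell proteins and the PduD(1-18)-LacI cargo adaptor, and a target plasmid
(pRW analogue, RK2-like, ~2 copies/cell) carrying a cluster of repressor
operators flanked (or preceded) by 18-bp I-SceI meganuclease sites.  Three
target architectures are modelled:

``lacO5``
    Five LacI operators plus a promoter spacer inside a 594-bp region
    bracketed by two I-SceI sites, so that in-vivo restriction releases a
    594-bp operator fragment.
``lacO8``
    Eight LacI operators downstream of a single I-SceI site (no fragment
    release possible).
``lexA``
    The mixed layout (lacO)2-(lexA_BT)2-(lacO)2 between two I-SceI sites,
    recruiting both LacI and a non-cleavable B. thuringiensis LexA.

The 600-bp analysis window (``segment``) covers the operator cluster of the
target plasmid; it is the interval over which read enrichment is scored.

Coordinates are 0-based, half-open throughout.  Replicons are treated as
linear for coverage purposes: the analysed segments are interior, so no
origin-spanning reads are generated and circular-coordinate ambiguity is
avoided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FACTOR_LACI = "LacI"
FACTOR_LEXA = "LexA_BT"
FACTOR_ISCEI = "I-SceI"
FACTORS = frozenset({FACTOR_LACI, FACTOR_LEXA, FACTOR_ISCEI})

ISCEI_SITE_LEN = 18

# The I-SceI recognition sequence is the canonical 18-mer.  The LacI motif is
# the symmetrised lac operator.  The LexA_BT motif is a synthetic 14-bp
# palindromic placeholder, not the authentic B. thuringiensis operator (which
# is not reproduced here); all motifs are configurable via `build_design`.
DEFAULT_MOTIFS = {
    FACTOR_LACI: "AATTGTGAGCGGATAACAATT",  # 21 bp
    FACTOR_LEXA: "TACTGTATGAGCAT",  # 14 bp synthetic placeholder
    FACTOR_ISCEI: "TAGGGATAACAGGGTAAT",  # 18 bp
}

DESIGNS = ("lacO5", "lacO8", "lexA")

_BASES = np.array(list("ACGT"))


class DesignError(ValueError):
    """Raised for unknown designs or backbones too short to host the segment."""


@dataclass(frozen=True)
class Replicon:
    """A named DNA molecule (chromosome or plasmid) present in the cell.

    copy_number is the mean number of copies per cell and weights
    background read sampling; it need not be an integer.
    """

    name: str
    length: int
    copy_number: float = 1.0
    sequence: str | None = None
    is_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"replicon {self.name!r}: length must be > 0")
        if self.copy_number <= 0:
            raise ValueError(f"replicon {self.name!r}: copy_number must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"replicon {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class OperatorSite:
    """A factor-binding or nuclease interval on a replicon (0-based, half-open)."""

    replicon: str
    start: int
    end: int
    factor: str
    site_id: str

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"site {self.site_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.factor == FACTOR_ISCEI and self.end - self.start != ISCEI_SITE_LEN:
            raise ValueError(
                f"site {self.site_id!r}: I-SceI sites are {ISCEI_SITE_LEN} bp"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segment:
    """The operator-carrying analysis window (default 600 bp)."""

    replicon: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


SEGMENT_LEN = 600


@dataclass
class SampleModel:
    """Replicons, operator sites, and the analysis segment of one sample."""

    replicons: list[Replicon]
    sites: list[OperatorSite]
    segment: Segment

    def __post_init__(self) -> None:
        n_chrom = sum(r.is_chromosome for r in self.replicons)
        if n_chrom != 1:
            raise ValueError(f"exactly one chromosome expected, found {n_chrom}")
        names = {r.name for r in self.replicons}
        if len(names) != len(self.replicons):
            raise ValueError("replicon names must be unique")
        by_name = {r.name: r for r in self.replicons}
        for s in self.sites:
            if s.replicon not in by_name:
                raise ValueError(f"site {s.site_id!r} references unknown replicon {s.replicon!r}")
            if s.end > by_name[s.replicon].length:
                raise ValueError(f"site {s.site_id!r} extends past replicon end")
        if self.segment.replicon not in by_name:
            raise ValueError(f"segment references unknown replicon {self.segment.replicon!r}")
        seg_rep = by_name[self.segment.replicon]
        if not (0 <= self.segment.start < self.segment.end <= seg_rep.length):
            raise ValueError("segment does not lie within its replicon")

    def replicon_by_name(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def chromosome(self) -> Replicon:
        return next(r for r in self.replicons if r.is_chromosome)

    @property
    def plasmids(self) -> list[Replicon]:
        return [r for r in self.replicons if not r.is_chromosome]

    @property
    def segment_replicon(self) -> Replicon:
        return self.replicon_by_name(self.segment.replicon)

    def factor_sites(self, replicon: str | None = None) -> list[OperatorSite]:
        """Repressor-binding sites (LacI/LexA); I-SceI sites never protect."""
        out = [s for s in self.sites if s.factor != FACTOR_ISCEI]
        if replicon is not None:
            out = [s for s in out if s.replicon == replicon]
        return sorted(out, key=lambda s: (s.replicon, s.start))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _splice(sequence: str, start: int, motif: str) -> str:
    return sequence[:start] + motif + sequence[start + len(motif):]


def build_design(
    design_name: str,
    backbone_length: int = 5000,
    seed: int = 0,
    *,
    chromosome_length: int = 100_000,
    helper_plasmid_length: int = 8_000,
    motifs: dict[str, str] | None = None,
) -> SampleModel:
    """Build a synthetic three-replicon sample for one target-plasmid design.

    Returns a chromosome (copy number 1), a helper-plasmid analogue
    (copy number 9), and the designed target plasmid (copy number 2) with
    operator motifs spliced into an otherwise random, seed-deterministic
    backbone.  The chromosome here is a 100-kb synthetic stand-in for the
    4.6-Mb E. coli chromosome; copy-number weighting, not absolute length,
    drives the background read model.
    """
    if design_name not in DESIGNS:
        raise DesignError(f"unknown design {design_name!r}; expected one of {DESIGNS}")
    motifs = {**DEFAULT_MOTIFS, **(motifs or {})}
    if len(motifs[FACTOR_ISCEI]) != ISCEI_SITE_LEN:
        raise DesignError("I-SceI motif must be 18 bp")

    laci = motifs[FACTOR_LACI]
    lexa = motifs[FACTOR_LEXA]
    iscei = motifs[FACTOR_ISCEI]
    plasmid_name = f"pRW-{design_name}"

    # Relative layouts: (factor, offset from cluster anchor).  For the two
    # excisable designs the inner edges of the I-SceI pair sit 594 bp apart.
    sites_rel: list[tuple[str, int]] = []
    if design_name == "lacO5":
        sites_rel.append((FACTOR_ISCEI, 0))
        for i in range(5):
            sites_rel.append((FACTOR_LACI, 18 + 60 + i * (len(laci) + 40)))
        sites_rel.append((FACTOR_ISCEI, 18 + 594))
        span = 18 + 594 + 18
        seg_rel = (15, 615)
    elif design_name == "lacO8":
        sites_rel.append((FACTOR_ISCEI, 0))
        for i in range(8):
            sites_rel.append((FACTOR_LACI, 18 + 50 + i * (len(laci) + 40)))
        span = sites_rel[-1][1] + len(laci)
        seg_rel = (18, 618)
    else:  # lexA: (lacO)2-(lexA_BT)2-(lacO)2 between two I-SceI sites
        sites_rel.append((FACTOR_ISCEI, 0))
        order = [FACTOR_LACI, FACTOR_LACI, FACTOR_LEXA, FACTOR_LEXA, FACTOR_LACI, FACTOR_LACI]
        off = 18 + 60
        for factor in order:
            motif_len = len(laci) if factor == FACTOR_LACI else len(lexa)
            sites_rel.append((factor, off))
            off += motif_len + 40
        sites_rel.append((FACTOR_ISCEI, 18 + 594))
        span = 18 + 594 + 18
        seg_rel = (15, 615)

    needed = max(span, seg_rel[1]) + 400
    if backbone_length < max(2000, needed):
        raise DesignError(
            f"backbone_length {backbone_length} too short to host the "
            f"{design_name} segment (need >= {max(2000, needed)})"
        )

    rng = np.random.default_rng(seed)
    chrom_seq = _random_sequence(rng, chromosome_length)
    helper_seq = _random_sequence(rng, helper_plasmid_length)
    target_seq = _random_sequence(rng, backbone_length)

    anchor = (backbone_length - span) // 2
    sites: list[OperatorSite] = []
    counters: dict[str, int] = {}
    for factor, rel in sites_rel:
        motif = motifs[factor]
        start = anchor + rel
        target_seq = _splice(target_seq, start, motif)
        counters[factor] = counters.get(factor, 0) + 1
        prefix = {FACTOR_LACI: "lacO", FACTOR_LEXA: "lexA", FACTOR_ISCEI: "IsceI"}[factor]
        sites.append(
            OperatorSite(
                replicon=plasmid_name,
                start=start,
                end=start + len(motif),
                factor=factor,
                site_id=f"{prefix}_{counters[factor]}",
            )
        )

    segment = Segment(plasmid_name, anchor + seg_rel[0], anchor + seg_rel[1])
    replicons = [
        Replicon("chromosome", chromosome_length, 1.0, chrom_seq, is_chromosome=True),
        Replicon("pOH", helper_plasmid_length, 9.0, helper_seq),
        Replicon(plasmid_name, backbone_length, 2.0, target_seq),
    ]
    return SampleModel(replicons=replicons, sites=sites, segment=segment)


# ---------------------------------------------------------------------------
# FASTA / BED / YAML plumbing


def write_fasta(model: SampleModel, path: str | Path) -> Path:
    """Write one FASTA record per replicon (sequences must be present)."""
    records = []
    for r in model.replicons:
        if r.sequence is None:
            raise ValueError(f"replicon {r.name!r} has no sequence")
        records.append(SeqRecord(Seq(r.sequence), id=r.name, description=""))
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA into {name: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sites_bed(model: SampleModel, path: str | Path) -> Path:
    """Write operator sites as BED6: name column is ``factor:site_id``."""
    path = Path(path)
    with path.open("w") as fh:
        for s in sorted(model.sites, key=lambda s: (s.replicon, s.start)):
            fh.write(f"{s.replicon}\t{s.start}\t{s.end}\t{s.factor}:{s.site_id}\t0\t+\n")
    return path


class BedParseError(ValueError):
    pass


def read_sites_bed(path: str | Path, model: SampleModel) -> list[OperatorSite]:
    """Parse a BED6 site file back into OperatorSites, validated against model."""
    sites: list[OperatorSite] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if ":" not in fields[3]:
                raise BedParseError(f"{path}:{lineno}: name must be 'factor:site_id'")
            factor, site_id = fields[3].split(":", 1)
            try:
                site = OperatorSite(fields[0], start, end, factor, site_id)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            sites.append(site)
    by_name = {r.name: r for r in model.replicons}
    for s in sites:
        if s.replicon not in by_name:
            raise BedParseError(f"site {s.site_id!r} references unknown replicon {s.replicon!r}")
        if s.end > by_name[s.replicon].length:
            raise BedParseError(f"site {s.site_id!r} extends past replicon end")
    return sites


def write_model_yaml(model: SampleModel, path: str | Path) -> Path:
    """Write a sequence-free sample descriptor (replicons + segment)."""
    doc = {
        "replicons": [
            {
                "name": r.name,
                "length": int(r.length),
                "copy_number": float(r.copy_number),
                "is_chromosome": bool(r.is_chromosome),
            }
            for r in model.replicons
        ],
        "segment": {
            "replicon": model.segment.replicon,
            "start": int(model.segment.start),
            "end": int(model.segment.end),
        },
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_model_yaml(path: str | Path, sequences: dict[str, str] | None = None) -> SampleModel:
    """Read a sample descriptor; optionally attach sequences by replicon name."""
    doc = yaml.safe_load(Path(path).read_text())
    replicons = [
        Replicon(
            name=d["name"],
            length=int(d["length"]),
            copy_number=float(d["copy_number"]),
            sequence=(sequences or {}).get(d["name"]),
            is_chromosome=bool(d.get("is_chromosome", False)),
        )
        for d in doc["replicons"]
    ]
    seg = doc["segment"]
    return SampleModel(
        replicons=replicons,
        sites=[],
        segment=Segment(seg["replicon"], int(seg["start"]), int(seg["end"])),
    )
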