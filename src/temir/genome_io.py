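"""I/O layer: FASTA, interval tables, Newick trees and wig-like score tracks.

Coordinate convention
---------------------
All external coordinates are 1-based inclusive, in the UCSC browser text style
``chrN:start-end(strand)`` used throughout repeat and duplication tables.
Internally, sequence slicing converts to 0-based half-open exactly once, in
:meth:`GenomicInterval.slice_of`.  A 1-based inclusive span has length
``end - start + 1``; this is the convention under which the packaged coverage
percentages come out right (e.g. a 150-bp precursor at chr20:48664580-48664729).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO


log = logging.getLogger("temir")

__all__ = [
    "ParseError",
    "GenomicInterval",
    "SequenceRecord",
    "ScoreTrack",
    "RepeatAnnotation",
    "SegDupPair",
    "read_fasta",
    "write_fasta",
    "read_interval_table",
    "write_interval_table",
    "read_score_track",
    "write_score_track",
    "read_newick",
    "write_newick",
    "load_packaged_table",
    "revcomp",
    "normalize_nt",
]

_COORD_RE = re.compile(
    r"^(?P<chrom>[A-Za-z0-9_.]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>.)\)$"
)
_NT = set("ACGTUN")
_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def normalize_nt(seq: str) -> str:
    """Uppercase and collapse U onto T so DNA/RNA spellings compare equal."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement (U complements to A, like T)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic span with strand and an optional label."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    @classmethod
    def from_string(cls, text: str, name: str = "") -> "GenomicInterval":
        m = _COORD_RE.match(text.strip())
        if m is None:
            raise ParseError(f"cannot parse coordinate {text!r}")
        return cls(
            chrom=m.group("chrom"),
            start=int(m.group("start")),
            end=int(m.group("end")),
            strand=m.group("strand"),
            name=name,
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment of *other*; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def slice_of(self, seq: str) -> str:
        """Extract this span from a plus-strand chromosome sequence.

        The result is reverse-complemented for minus-strand intervals, so it
        always reads 5'→3' on the annotated strand.
        """
        if self.end > len(seq):
            raise ValueError(
                f"interval {self.to_string()} extends past sequence of "
                f"length {len(seq)}"
            )
        sub = seq[self.start - 1 : self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,U,N} (case preserved)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq.upper()) - _NT
        if bad:
            raise ParseError(
                f"record {self.id!r} contains illegal characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat-element instance: where it is and which family it belongs to."""

    interval: GenomicInterval
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")


@dataclass(frozen=True)
class SegDupPair:
    """Two duplicated genomic regions; orientation follows the two strands."""

    sd1: GenomicInterval
    sd2: GenomicInterval
    pair_id: str = ""

    def __post_init__(self) -> None:
        for side in (self.sd1, self.sd2):
            if side.length < 1000:
                log.warning(
                    "segmental duplication side %s is shorter than 1 kb",
                    side.to_string(),
                )

    @property
    def orientation(self) -> str:
        return "same" if self.sd1.strand == self.sd2.strand else "inverted"


@dataclass
class ScoreTrack:
    """Contiguous per-base conservation scores in [0,1], 1-based origin."""

    chrom: str
    origin: int
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.scores:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0,1]")

    @property
    def end(self) -> int:
        return self.origin + len(self.scores) - 1

    def value_at(self, pos: int) -> float:
        """Score at a 1-based genomic position."""
        if not self.origin <= pos <= self.end:
            raise ValueError(f"position {pos} outside track span")
        return self.scores[pos - self.origin]

    def values_over(self, iv: GenomicInterval) -> list[float]:
        if iv.chrom != self.chrom or iv.start < self.origin or iv.end > self.end:
            raise ValueError(
                f"interval {iv.to_string()} not covered by track "
                f"{self.chrom}:{self.origin}-{self.end}"
            )
        lo = iv.start - self.origin
        return self.scores[lo : lo + iv.length]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord`s (U and T preserved as given)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            log.warning("FASTA file %s is empty", path)
            return []
        if first != ">":
            raise ParseError(f"{path}:1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def genome_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    return {r.id: r.seq for r in records}


# ---------------------------------------------------------------------------
# Interval tables
# ---------------------------------------------------------------------------

_KINDS = ("mirna", "repeat", "segdup", "est", "exon")


def _table_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split()


def read_interval_table(path: str | Path, kind: str):
    """Parse a whitespace/tab-separated interval table.

    Column order by *kind*:

    * ``mirna`` / ``est`` / ``exon``: ``coordinate  [name  extra...]`` →
      list of :class:`GenomicInterval`
    * ``repeat``: ``coordinate  family  [extra...]`` →
      list of :class:`RepeatAnnotation`
    * ``segdup``: ``pair_id  sd1_coordinate  sd2_coordinate  [extra...]`` →
      list of :class:`SegDupPair`

    Extra columns are ignored with a logged warning so that lightly reshaped
    RepeatMasker-style files can be ingested.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    out = []
    warned_extra = False
    for lineno, cols in _table_rows(path):
        try:
            if kind == "segdup":
                if len(cols) < 3:
                    raise ParseError("need pair_id, sd1 and sd2 columns")
                pair_id, sd1, sd2 = cols[0], cols[1], cols[2]
                extra = cols[3:]
                out.append(
                    SegDupPair(
                        sd1=GenomicInterval.from_string(sd1),
                        sd2=GenomicInterval.from_string(sd2),
                        pair_id=pair_id,
                    )
                )
            elif kind == "repeat":
                if len(cols) < 2:
                    raise ParseError("need coordinate and family columns")
                extra = cols[2:]
                out.append(
                    RepeatAnnotation(
                        interval=GenomicInterval.from_string(cols[0]),
                        family=cols[1],
                    )
                )
            else:
                name = cols[1] if len(cols) > 1 else ""
                extra = cols[2:]
                out.append(GenomicInterval.from_string(cols[0], name=name))
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if extra and not warned_extra:
            log.warning("%s: ignoring %d extra column(s)", path, len(extra))
            warned_extra = True
    return out


def write_interval_table(items: Sequence, path: str | Path) -> None:
    """Serialize intervals / repeats / segdup pairs back to TSV.

    Round-trips with :func:`read_interval_table` for the matching kind.
    """
    with open(path, "w") as fh:
        for item in items:
            if isinstance(item, SegDupPair):
                fh.write(
                    f"{item.pair_id}\t{item.sd1.to_string()}\t"
                    f"{item.sd2.to_string()}\n"
                )
            elif isinstance(item, RepeatAnnotation):
                fh.write(f"{item.interval.to_string()}\t{item.family}\n")
            else:
                name = item.name or "."
                fh.write(f"{item.to_string()}\t{name}\n")


def load_packaged_table(name: str, kind: str):
    """Load one of the fixture tables shipped under ``temir/data``."""
    ref = resources.files("temir.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_interval_table(path, kind=kind)


# ---------------------------------------------------------------------------
# Score tracks (fixedStep wiggle)
# ---------------------------------------------------------------------------

def read_score_track(path: str | Path) -> ScoreTrack:
    """Read a fixedStep (step=1) wiggle track of per-base scores in [0,1]."""
    path = Path(path)
    chrom: str | None = None
    origin = 1
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                chrom = fields.get("chrom")
                origin = int(fields.get("start", 1))
                step = int(fields.get("step", 1))
                if step != 1:
                    raise ParseError(f"{path}:{lineno}: only step=1 supported")
                continue
            try:
                value = float(line)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {line!r}") from exc
            if not 0.0 <= value <= 1.0:
                raise ParseError(
                    f"{path}:{lineno}: score {value} outside [0,1]"
                )
            scores.append(value)
    if chrom is None:
        raise ParseError(f"{path}: missing fixedStep declaration line")
    return ScoreTrack(chrom=chrom, origin=origin, scores=scores)


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={track.chrom} start={track.origin} step=1\n")
        for s in track.scores:
            fh.write(f"{s:g}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path, rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
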