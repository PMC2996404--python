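"""Repeat-overlap classification of miRNA loci.

A miRNA gene is called repeat-derived when the annotated repeats cover at
least 50% of its precursor span, or 100% of its mature span.  Coverage is the
union of per-repeat overlaps (so two abutting repeats covering different parts
of the precursor are summed, never double-counted) expressed as a percentage
of the 1-based inclusive precursor length and rounded half-up to 2 decimals.
Strand is ignored everywhere: repeat annotations routinely sit on the opposite
strand of the miRNA they gave rise to.

Also provided: intersection of miRNA loci with segmental-duplication pairs
(full containment in either side) and per-interval averaging of a
conservation score track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .genome_io import (
    GenomicInterval,
    RepeatAnnotation,
    ScoreTrack,
    SegDupPair,
)

__all__ = [
    "MirnaLocus",
    "CoverageRecord",
    "overlap_length",
    "coverage_percent",
    "classify_repeat_derived",
    "intersect_with_segdups",
    "distinct_loci",
    "mean_conservation",
]

PRECURSOR_THRESHOLD = Decimal("50")
MATURE_THRESHOLD = Decimal("100")


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA gene: precursor span, optional mature span and sequences."""

    precursor: GenomicInterval
    mature: GenomicInterval | None = None
    pre_seq: str = ""
    mature_seq: str = ""

    @property
    def name(self) -> str:
        return self.precursor.name

    def __post_init__(self) -> None:
        if self.mature is not None and not self.precursor.contains(self.mature):
            raise ValueError(
                f"mature {self.mature.to_string()} not contained in "
                f"precursor {self.precursor.to_string()}"
            )


@dataclass
class CoverageRecord:
    """Repeat coverage of one miRNA interval and the resulting call."""

    mirna: GenomicInterval
    percent: Decimal
    contributors: list[tuple[RepeatAnnotation, int]] = field(default_factory=list)
    derived_call: bool = False
    mature_percent: Decimal | None = None


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two 1-based inclusive spans; strand ignored."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _round2(value: Decimal) -> Decimal:
    return value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def _union_coverage(mirna: GenomicInterval, repeats: list[RepeatAnnotation]) -> int:
    """Total bp of *mirna* covered by the union of the repeat spans."""
    clipped = []
    for rep in repeats:
        if overlap_length(mirna, rep.interval) > 0:
            clipped.append(
                (max(mirna.start, rep.interval.start), min(mirna.end, rep.interval.end))
            )
    covered = 0
    last_end = None
    for start, end in sorted(clipped):
        if last_end is None or start > last_end:
            covered += end - start + 1
            last_end = end
        elif end > last_end:
            covered += end - last_end
            last_end = end
    return covered


def coverage_percent(
    mirna: GenomicInterval, repeats: list[RepeatAnnotation]
) -> CoverageRecord:
    """Percent of *mirna* covered by the union of repeat overlaps."""
    contributors = [
        (rep, ov)
        for rep in repeats
        if (ov := overlap_length(mirna, rep.interval)) > 0
    ]
    covered = _union_coverage(mirna, repeats)
    percent = _round2(Decimal(100 * covered) / Decimal(mirna.length))
    return CoverageRecord(mirna=mirna, percent=percent, contributors=contributors)


def classify_repeat_derived(
    pre: GenomicInterval,
    mature: GenomicInterval | None,
    repeats: list[RepeatAnnotation],
) -> CoverageRecord:
    """Apply the 50%-precursor / 100%-mature repeat-derived rule.

    ``mature`` may be None when only precursor coordinates are known (as in
    coordinate-only tables); the mature rule is then simply unavailable.
    """
    rec = coverage_percent(pre, repeats)
    fires = rec.percent >= PRECURSOR_THRESHOLD
    if mature is not None:
        if not pre.contains(mature):
            raise ValueError(
                f"mature {mature.to_string()} not within precursor "
                f"{pre.to_string()}"
            )
        mrec = coverage_percent(mature, repeats)
        rec.mature_percent = mrec.percent
        fires = fires or mrec.percent == MATURE_THRESHOLD
    rec.derived_call = fires
    return rec


def _precursor_of(locus) -> GenomicInterval:
    return locus.precursor if isinstance(locus, MirnaLocus) else locus


def intersect_with_segdups(
    mirnas: list, segdups: list[SegDupPair], containment: bool = True
) -> list[tuple[GenomicInterval, SegDupPair]]:
    """miRNA loci lying within segmental duplications.

    A locus is reported for a pair when its precursor is fully contained in
    either side (``containment=False`` relaxes to >=1 bp overlap).  A locus
    may appear with several pairs; use :func:`distinct_loci` to count loci.
    """
    hits: list[tuple[GenomicInterval, SegDupPair]] = []
    for locus in mirnas:
        pre = _precursor_of(locus)
        for sd in segdups:
            for side in (sd.sd1, sd.sd2):
                inside = side.contains(pre) if containment else side.overlaps(pre)
                if inside:
                    hits.append((pre, sd))
                    break
    return hits


def distinct_loci(
    hits: list[tuple[GenomicInterval, SegDupPair]]
) -> list[GenomicInterval]:
    """Deduplicated miRNA loci from segdup intersection hits (stable order)."""
    seen: dict[tuple, GenomicInterval] = {}
    for pre, _ in hits:
        key = (pre.chrom, pre.start, pre.end, pre.strand, pre.name)
        seen.setdefault(key, pre)
    return list(seen.values())


def mean_conservation(interval: GenomicInterval, track: ScoreTrack) -> float:
    """Arithmetic mean of per-base conservation scores over *interval*."""
    values = track.values_over(interval)
    return sum(values) / len(values)
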