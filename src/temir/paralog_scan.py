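"""Genome-wide scan of repeat-element instances for paralogous miRNA genes.

Three-step scheme over annotated element instances:

1. exact seed match — the 7-mer at mature positions 2–8 is searched on both
   strands of every element instance;
2. precursor excision — for every seed hit, two 110-nt windows are excised so
   that the seed-carrying 21-mer sits on the 5' arm (``left``) or the 3' arm
   (``right``) of the putative hairpin, 10 nt in from the corresponding
   window end;
3. filtering — each window must fold to an acceptable single-stem hairpin,
   overlap transcription evidence (ESTs) and avoid annotated exons.

All coordinates are 1-based inclusive genome coordinates; windows that would
run off a chromosome end are dropped with a logged warning.  The scan is
fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_io import (
    GenomicInterval,
    RepeatAnnotation,
    SequenceRecord,
    genome_dict,
    normalize_nt,
    revcomp,
)
from .hairpin import HairpinThresholds, HairpinVerdict, is_premirna_like

log = logging.getLogger("temir")

__all__ = [
    "ScanConfig",
    "SeedMatch",
    "ParalogCandidate",
    "seed_of",
    "find_seed_matches",
    "excise_precursors",
    "transcribed_not_exonic",
    "scan_paralogs",
]

SEED_START = 2  # 1-based position within the mature sequence, inclusive
SEED_END = 8


@dataclass
class ScanConfig:
    """Tunable parameters of the paralog scan."""

    window: int = 110          # excised precursor length, nt
    flank: int = 10            # distance of mature from the window end, nt
    mature_len: int = 21
    both_strands: bool = True  # search elements on both strands
    est_policy: str = "strict"  # "strict": no EST evidence => not transcribed
    hairpin: HairpinThresholds = field(default_factory=HairpinThresholds)


@dataclass(frozen=True)
class SeedMatch:
    """An exact seed occurrence inside one element instance.

    ``offset`` is 0-based within the element sequence read 5'→3' on the
    reported strand (i.e. within the reverse complement for '-' matches).
    """

    element: RepeatAnnotation
    offset: int
    strand: str


@dataclass
class ParalogCandidate:
    """A 110-nt excised precursor candidate with its filter flags."""

    interval: GenomicInterval
    seq: str
    arm: str                        # "left" or "right"
    hairpin: HairpinVerdict | None = None
    transcribed: bool = False
    exonic: bool = False
    source: SeedMatch | None = None

    @property
    def final_call(self) -> bool:
        return (
            self.hairpin is not None
            and self.hairpin.accepted
            and self.transcribed
            and not self.exonic
        )


def seed_of(mature: str) -> str:
    """The seed 7-mer: mature positions 2–8 (1-based, inclusive)."""
    if len(mature) < SEED_END:
        raise ValueError(
            f"mature sequence of length {len(mature)} has no positions "
            f"{SEED_START}-{SEED_END}"
        )
    return mature[SEED_START - 1 : SEED_END].upper()


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits = []
    pos = haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)  # overlapping hits included
    return hits


def find_seed_matches(
    genome: list[SequenceRecord] | dict[str, str],
    elements: list[RepeatAnnotation],
    seed: str,
    both_strands: bool = True,
) -> list[SeedMatch]:
    """Every exact seed occurrence within each element, on both strands."""
    chroms = genome if isinstance(genome, dict) else genome_dict(genome)
    seed_t = normalize_nt(seed)
    matches: list[SeedMatch] = []
    for el in elements:
        iv = el.interval
        if iv.chrom not in chroms or iv.end > len(chroms[iv.chrom]):
            raise ValueError(
                f"element {iv.to_string()} lies outside the genome"
            )
        plus = normalize_nt(chroms[iv.chrom][iv.start - 1 : iv.end])
        for off in _occurrences(plus, seed_t):
            matches.append(SeedMatch(element=el, offset=off, strand="+"))
        if both_strands:
            for off in _occurrences(revcomp(plus), seed_t):
                matches.append(SeedMatch(element=el, offset=off, strand="-"))
    return matches


def _seed_genome_span(match: SeedMatch) -> tuple[int, int]:
    """Plus-strand genome (start, end) of the matched seed 7-mer."""
    iv = match.element.interval
    seed_len = SEED_END - SEED_START + 1
    if match.strand == "+":
        start = iv.start + match.offset
    else:
        start = iv.end - match.offset - (seed_len - 1)
    return start, start + seed_len - 1


def excise_precursors(
    genome: list[SequenceRecord] | dict[str, str],
    match: SeedMatch,
    cfg: ScanConfig | None = None,
) -> list[ParalogCandidate]:
    """Excise the left-arm and right-arm precursor windows for one seed hit.

    The mature 21-mer is placed around the seed (seed at mature positions
    2–8).  The left-arm window puts the mature on the 5' arm, starting
    ``flank`` nt from the window's 5' end; the right-arm window mirrors this
    at the 3' end.  Windows truncated by a chromosome end are dropped.
    """
    cfg = cfg or ScanConfig()
    chroms = genome if isinstance(genome, dict) else genome_dict(genome)
    chrom = match.element.interval.chrom
    chrom_len = len(chroms[chrom])
    sg_start, sg_end = _seed_genome_span(match)
    # mature span in plus-strand genome coordinates
    lead = SEED_START - 1          # nt of mature 5' of the seed (= 1)
    tail = cfg.mature_len - SEED_END  # nt of mature 3' of the seed (= 13)
    if match.strand == "+":
        m_start, m_end = sg_start - lead, sg_end + tail
    else:
        m_start, m_end = sg_start - tail, sg_end + lead

    out: list[ParalogCandidate] = []
    for arm in ("left", "right"):
        w_start, w_end = _window_span(
            m_start, m_end, arm, match.strand, cfg.window, cfg.flank
        )
        if w_start < 1 or w_end > chrom_len:
            log.warning(
                "dropping truncated %s-arm window %s:%d-%d", arm, chrom,
                w_start, w_end,
            )
            continue
        iv = GenomicInterval(chrom=chrom, start=w_start, end=w_end,
                             strand=match.strand)
        out.append(
            ParalogCandidate(
                interval=iv,
                seq=iv.slice_of(chroms[chrom]),
                arm=arm,
                source=match,
            )
        )
    return out


def _window_span(
    m_start: int, m_end: int, arm: str, strand: str, window: int, flank: int
) -> tuple[int, int]:
    """Plus-strand (start, end) of the excision window, strand-aware."""
    if strand == "+":
        if arm == "left":
            start = m_start - flank
            return start, start + window - 1
        end = m_end + flank
        return end - window + 1, end
    # minus strand: 5' end of the window is the highest genome coordinate
    if arm == "left":
        end = m_end + flank
        return end - window + 1, end
    start = m_start - flank
    return start, start + window - 1


def transcribed_not_exonic(
    cand: ParalogCandidate,
    ests: list[GenomicInterval] | None,
    exons: list[GenomicInterval] | None,
    est_policy: str = "strict",
) -> ParalogCandidate:
    """Set the transcription/exon evidence flags (>=1 bp overlap each)."""
    if ests is None:
        cand.transcribed = est_policy == "pass"
    else:
        cand.transcribed = any(cand.interval.overlaps(e) for e in ests)
    cand.exonic = bool(exons) and any(cand.interval.overlaps(e) for e in exons)
    return cand


def scan_paralogs(
    genome: list[SequenceRecord] | dict[str, str],
    elements: list[RepeatAnnotation],
    mature: str,
    ests: list[GenomicInterval] | None,
    exons: list[GenomicInterval] | None,
    cfg: ScanConfig | None = None,
) -> list[ParalogCandidate]:
    """Run the full three-step scan and return all audited candidates.

    Candidates are deduplicated by (interval, arm); the returned list keeps
    every candidate with its filter flags — callers select on
    ``final_call`` for the positive set.
    """
    cfg = cfg or ScanConfig()
    chroms = genome if isinstance(genome, dict) else genome_dict(genome)
    seed = seed_of(mature)
    matches = find_seed_matches(
        chroms, elements, seed, both_strands=cfg.both_strands
    )
    candidates: list[ParalogCandidate] = []
    seen: set[tuple] = set()
    for match in matches:
        for cand in excise_precursors(chroms, match, cfg):
            key = (
                cand.interval.chrom, cand.interval.start, cand.interval.end,
                cand.interval.strand, cand.arm,
            )
            if key in seen:
                continue
            seen.add(key)
            cand.hairpin = is_premirna_like(cand.seq, cfg.hairpin)
            transcribed_not_exonic(cand, ests, exons, cfg.est_policy)
            candidates.append(cand)
    n_final = sum(c.final_call for c in candidates)
    n_hp = sum(c.hairpin.accepted for c in candidates if c.hairpin)
    log.info(
        "scan: %d elements, %d seed matches, %d candidates, "
        "%d hairpin-passed, %d final",
        len(elements), len(matches), len(candidates), n_hp, n_final,
    )
    return candidates
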