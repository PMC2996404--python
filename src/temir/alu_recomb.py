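"""Alu-mediated recombination test on segmental duplications.

Alu-Alu recombination between duplication units leaves mosaic Alu elements
at the duplication boundaries, so junction Alus (those overlapping a +-5 bp
window around either terminus of a duplicated region) should be more
diverged between the two copies of a duplication pair than the internal Alus
they flank.  Divergence is the K2P distance between family- and rank-matched
Alu copies across a pair; divergences are compared with a tie-corrected
Kruskal-Wallis rank test — once across the internal families alone (df =
n_families - 1) and once with the junction Alus added as an extra group
(df = n_families).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    GenomicInterval,
    RepeatAnnotation,
    SegDupPair,
    SequenceRecord,
    genome_dict,
)
from .phylo import k2p_distance, needleman_wunsch

log = logging.getLogger("temir")

__all__ = [
    "JUNCTION_FLANK",
    "JunctionWindow",
    "AluAssignment",
    "KWResult",
    "AluTestResult",
    "junction_windows",
    "assign_alus",
    "family_pair_divergence",
    "kruskal_wallis",
    "run_alu_test",
    "link_table",
]

JUNCTION_FLANK = 5  # bp each side of a duplication terminus


@dataclass(frozen=True)
class JunctionWindow:
    side: str       # "sd1" | "sd2"
    terminus: str   # "5prime" | "3prime"
    interval: GenomicInterval


@dataclass(frozen=True)
class AluAssignment:
    alu: RepeatAnnotation
    role: str       # "junction" | "internal"
    side: str       # "sd1" | "sd2"
    pair_id: str


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    group_sizes: list[int]


@dataclass
class AluTestResult:
    internal: KWResult
    combined: KWResult
    divergences: pd.DataFrame  # pair_id, role, family, divergence


def junction_windows(
    sd: SegDupPair, flank: int = JUNCTION_FLANK
) -> list[JunctionWindow]:
    """The four +-``flank`` bp windows around the termini of both regions.

    Windows running past position 1 are truncated with a warning; orientation
    does not move the termini.
    """
    out: list[JunctionWindow] = []
    for side_name, iv in (("sd1", sd.sd1), ("sd2", sd.sd2)):
        for terminus, center in (("5prime", iv.start), ("3prime", iv.end)):
            start = center - flank
            if start < 1:
                log.warning(
                    "junction window at %s:%d truncated at chromosome start",
                    iv.chrom, center,
                )
                start = 1
            out.append(
                JunctionWindow(
                    side=side_name,
                    terminus=terminus,
                    interval=GenomicInterval(
                        chrom=iv.chrom, start=start, end=center + flank,
                        strand=iv.strand,
                    ),
                )
            )
    return out


def assign_alus(
    alus: list[RepeatAnnotation], sd: SegDupPair, flank: int = JUNCTION_FLANK
) -> list[AluAssignment]:
    """Classify each Alu of a duplication pair as junction or internal.

    Junction: >=1 bp overlap with any terminus window of its region.
    Internal: fully inside a region and clear of every window.
    Alus outside both regions are ignored.
    """
    windows = junction_windows(sd, flank=flank)
    out: list[AluAssignment] = []
    for alu in alus:
        for side_name, region in (("sd1", sd.sd1), ("sd2", sd.sd2)):
            side_windows = [w for w in windows if w.side == side_name]
            touches = any(
                alu.interval.overlaps(w.interval) for w in side_windows
            )
            if touches:
                out.append(
                    AluAssignment(alu=alu, role="junction", side=side_name,
                                  pair_id=sd.pair_id)
                )
                break
            if region.contains(alu.interval):
                out.append(
                    AluAssignment(alu=alu, role="internal", side=side_name,
                                  pair_id=sd.pair_id)
                )
                break
    return out


def _oriented_order(assignments: list[AluAssignment], region: GenomicInterval):
    """Alus of one side sorted 5'->3' along the region's strand."""
    ordered = sorted(assignments, key=lambda a: a.alu.interval.start)
    return ordered[::-1] if region.strand == "-" else ordered


def family_pair_divergence(
    sd: SegDupPair,
    assignments: list[AluAssignment],
    chroms: dict[str, str],
) -> list[tuple[str, str, float]]:
    """K2P divergence of matched Alu copies across one duplication pair.

    Matching: within each role, Alus are matched across the two regions by
    family name and rank order along the region (5'->3' on the region's
    strand); mismatched counts are truncated to the shorter list.  Sequences
    are extracted strand-aware, globally aligned when their lengths differ,
    and compared under K2P with pairwise gap deletion.  Saturated or
    unmatched Alus are excluded with a log message.

    Returns (role, family, divergence) triples.
    """
    by_side: dict[str, list[AluAssignment]] = {"sd1": [], "sd2": []}
    for a in assignments:
        by_side[a.side].append(a)
    region = {"sd1": sd.sd1, "sd2": sd.sd2}
    ordered = {
        s: _oriented_order(by_side[s], region[s]) for s in ("sd1", "sd2")
    }

    out: list[tuple[str, str, float]] = []
    for role in ("junction", "internal"):
        def ranked(side: str) -> dict[str, list[AluAssignment]]:
            groups: dict[str, list[AluAssignment]] = {}
            for a in ordered[side]:
                if a.role == role:
                    groups.setdefault(a.alu.family, []).append(a)
            return groups
        g1, g2 = ranked("sd1"), ranked("sd2")
        for family in g1:
            if family not in g2:
                log.info("unmatched %s Alu family %s in pair %s",
                         role, family, sd.pair_id)
                continue
            for a1, a2 in zip(g1[family], g2[family]):
                s1 = a1.alu.interval.slice_of(chroms[a1.alu.interval.chrom])
                s2 = a2.alu.interval.slice_of(chroms[a2.alu.interval.chrom])
                if len(s1) != len(s2):
                    s1, s2 = needleman_wunsch(s1, s2)
                d = k2p_distance(s1, s2)
                if math.isnan(d):
                    log.info("saturated %s Alu pair in %s excluded",
                             role, sd.pair_id)
                    continue
                out.append((role, family, d))
    return out


def kruskal_wallis(groups: list[list[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square upper-tail p-value.

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N))
    with mid-ranks for ties; if all pooled values are identical H := 0 and
    p = 1.  df = number of groups - 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    H = 12.0 / (N * (N + 1)) * sum(
        np.sum(ranks[i0:i0 + n]) ** 2 / n
        for i0, n in zip(np.cumsum([0] + sizes[:-1]), sizes)
    ) - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if tie_corr == 0.0:  # all values identical
        H = 0.0
    else:
        H = H / tie_corr
    H = max(H, 0.0)
    df = len(groups) - 1
    p = float(stats.chi2.sf(H, df))
    return KWResult(H=float(H), df=df, p=p, group_sizes=sizes)


def run_alu_test(
    segdups: list[SegDupPair],
    alus: list[RepeatAnnotation],
    genome: list[SequenceRecord] | dict[str, str],
    internal_families: tuple[str, ...] | list[str],
) -> AluTestResult:
    """Internal-only and junction+internal Kruskal-Wallis tests.

    Internal divergences are grouped by Alu family (one group per family in
    *internal_families*); the combined test adds all junction divergences as
    one extra group, so the degrees of freedom are ``len(families) - 1`` and
    ``len(families)`` respectively.
    """
    chroms = genome if isinstance(genome, dict) else genome_dict(genome)
    rows: list[dict] = []
    for sd in segdups:
        assignments = assign_alus(alus, sd)
        for role, family, d in family_pair_divergence(sd, assignments, chroms):
            rows.append(
                {"pair_id": sd.pair_id, "role": role, "family": family,
                 "divergence": d}
            )
    table = pd.DataFrame(rows, columns=["pair_id", "role", "family",
                                        "divergence"])
    internal_groups = []
    for fam in internal_families:
        vals = table.query("role == 'internal' and family == @fam")[
            "divergence"].tolist()
        if not vals:
            raise ValueError(f"no internal divergences for family {fam!r}")
        internal_groups.append(vals)
    junction_vals = table.query("role == 'junction'")["divergence"].tolist()
    if not junction_vals:
        raise ValueError("no junction Alu divergences found")
    internal_kw = kruskal_wallis(internal_groups)
    combined_kw = kruskal_wallis(internal_groups + [junction_vals])
    return AluTestResult(internal=internal_kw, combined=combined_kw,
                         divergences=table)


def link_table(segdups: list[SegDupPair]) -> pd.DataFrame:
    """Circos-compatible link table (one row per duplication pair)."""
    return pd.DataFrame(
        [
            {
                "pair_id": sd.pair_id,
                "chrom1": sd.sd1.chrom, "start1": sd.sd1.start,
                "end1": sd.sd1.end,
                "chrom2": sd.sd2.chrom, "start2": sd.sd2.start,
                "end2": sd.sd2.end,
            }
            for sd in segdups
        ]
    )
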