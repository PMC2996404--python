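"""Synthetic genomes, duplications and gene-family histories with ground truth.

The generator emulates the data the analysis consumes:

* a background genome (i.i.d., human-like GC) with implanted copies of a
  193-bp palindromic transposon-like consensus — terminal inverted repeats
  around a short loop, flanked by TA target-site duplications — a fraction of
  which carry the 21-nt mature miRNA on the 5' arm, plus dinucleotide-shuffled
  decoy copies that preserve composition but destroy the hairpin;
* segmental-duplication pairs whose two copies descend from a common ancestor
  region carrying an internal Alu array in a fixed family order, with mosaic
  (recombined) Alus at both boundaries mutating at a configurable multiple of
  the internal rate;
* gene presence/absence evolved by birth and death along a rooted species
  tree (single gain per gene, independent losses on descendant branches) with
  per-leaf sequences mutated along the path length.

Substitutions follow a K2P scheme (transition/transversion ratio
``kappa``, default 2).  Every simulator is deterministic given its seed, and
every emitted annotation indexes valid positions of the emitted sequences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genome_io import (
    GenomicInterval,
    RepeatAnnotation,
    SegDupPair,
    SequenceRecord,
    revcomp,
    write_fasta,
    write_interval_table,
)
from .phylo import PresenceMatrix

log = logging.getLogger("temir")

__all__ = [
    "MATURE_MIR1302",
    "DEFAULT_SPECIES_TREE",
    "GenomeSimConfig",
    "SegDupSimConfig",
    "FamilyEvoConfig",
    "make_consensus_element",
    "mutate",
    "dinucleotide_shuffle",
    "simulate_genome",
    "simulate_segdups",
    "simulate_family_evolution",
]

#: the mature miRNA produced by every family member (RNA spelling)
MATURE_MIR1302 = "UUGGGACAUACUUAUGCUAAA"

#: eight-taxon primate-like rooted species tree (branch lengths in subst/site)
DEFAULT_SPECIES_TREE = (
    "(((((((human:0.006,chimp:0.006):0.002,gorilla:0.008):0.007,"
    "orangutan:0.015):0.010,rhesus:0.025):0.035,marmoset:0.060):0.025,"
    "tarsier:0.085):0.015,mouse_lemur:0.100);"
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_IDX = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().replace("U", "T").encode(), dtype="S1")
    out = np.zeros(len(arr), dtype=np.int8)
    for b, i in _IDX.items():
        out[arr == b] = i
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _decode(rng.choice(4, size=n, p=p))


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
    protect: np.ndarray | None = None,
) -> str:
    """Point-mutate *seq* at per-base probability *rate* under a K2P scheme.

    A substituted base becomes the transition partner with probability
    kappa/(kappa+2), otherwise one of its two transversion partners.
    ``protect`` is a boolean mask of positions exempt from mutation.
    """
    codes = _encode(seq)
    hit = rng.random(len(codes)) < rate
    if protect is not None:
        hit &= ~protect
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq.upper().replace("U", "T")
    is_ts = rng.random(len(idx)) < kappa / (kappa + 2.0)
    new = codes[idx].copy()
    new[is_ts] = _TRANSITION[codes[idx][is_ts]]
    tv = ~is_ts
    # transversion partners of {A,G} are {C,T}; of {C,T} are {A,G}
    pick = rng.integers(0, 2, size=int(tv.sum()))
    purine = np.isin(codes[idx][tv], (0, 2))
    new[tv] = np.where(purine, np.where(pick == 0, 1, 3),
                       np.where(pick == 0, 0, 2))
    codes[idx] = new
    return _decode(codes)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Doublet-preserving shuffle (Altschul–Erickson).

    Preserves the exact multiset of overlapping dinucleotides (hence mono-
    and dinucleotide composition) while randomizing the order, destroying
    secondary-structure palindromes.
    """
    s = seq.upper().replace("U", "T")
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges.keys())
    for _ in range(10_000):
        # choose a candidate last-edge for every vertex except the terminal
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(0, len(edges[v]))]
        # the chosen last edges must lead every vertex to the terminal vertex
        for v in last_edge:
            seen = {v}
            w = v
            while w != last:
                w = last_edge.get(w)
                if w is None or w in seen:
                    ok = False
                    break
                seen.add(w)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - retry bound never hit for DNA alphabets
        raise RuntimeError("dinucleotide shuffle failed to converge")
    out_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = [rest[i] for i in rng.permutation(len(rest))]
        if v in last_edge:
            perm.append(last_edge[v])
        out_edges[v] = perm
    walk = [s[0]]
    ptr = {v: 0 for v in out_edges}
    v = s[0]
    for _ in range(len(s) - 1):
        nxt = out_edges[v][ptr[v]]
        ptr[v] += 1
        walk.append(nxt)
        v = nxt
    return "".join(walk)


def make_consensus_element(
    length: int = 193,
    loop: int = 9,
    rng: np.random.Generator | None = None,
    mature: str | None = None,
    mature_offset: int | None = None,
    gc: float = 0.41,
) -> str:
    """A palindromic transposon-like consensus of *length* bp.

    Layout: TA + arm + loop + reverse-complement(arm) + TA, so the element
    folds into a single long hairpin.  The loop is poly-A, which cannot pair
    with itself even under wobble rules.  When *mature* is given, the 21-mer
    (DNA spelling) is written into the 5' arm at *mature_offset*; its reverse
    complement lands on the 3' arm automatically.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    stem2 = length - loop - 4
    if stem2 < 2 or stem2 % 2:
        raise ValueError(
            f"infeasible geometry: length {length} with loop {loop} leaves "
            f"no valid stem"
        )
    stem = stem2 // 2
    arm = list(_random_seq(stem, gc, rng))
    if mature is not None:
        m = mature.upper().replace("U", "T")
        off = mature_offset if mature_offset is not None else 0
        if off < 0 or off + len(m) > stem:
            raise ValueError("mature sequence does not fit in the arm")
        arm[off : off + len(m)] = list(m)
    arm_s = "".join(arm)
    return "TA" + arm_s + "A" * loop + revcomp(arm_s) + "TA"


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    """Study conditions for the implant/decoy genome."""

    genome_length: int = 2_000_000
    n_elements: int = 20              # implanted intact element copies
    element_length: int = 193
    element_loop: int = 9
    element_mutation_rate: float = 0.02
    protect_mature: bool = True       # the mature 21-mer never mutates
    seed_carrier_fraction: float = 1.0
    n_decoys: int = 30
    mature: str = MATURE_MIR1302
    mature_arm_offset: int = 49       # mature placement within the 5' arm
    gc: float = 0.41
    est_fraction: float = 1.0         # fraction of carriers covered by an EST
    exon_fraction: float = 0.0        # fraction of carriers inside an exon
    kappa: float = 2.0
    rng_seed: int = 0


@dataclass
class ImplantTruth:
    interval: GenomicInterval
    carrier: bool
    decoy: bool
    mature_interval: GenomicInterval | None = None
    arm: str = ""


@dataclass
class GenomeSim:
    records: list[SequenceRecord]
    repeats: list[RepeatAnnotation]
    ests: list[GenomicInterval]
    exons: list[GenomicInterval]
    truth: list[ImplantTruth]
    config: GenomeSimConfig


def _place_nonoverlapping(
    n: int, item_len: int, genome_len: int, margin: int,
    rng: np.random.Generator, max_tries: int = 2000,
) -> list[int]:
    """Non-overlapping 0-based start positions, `margin` bp apart and from ends."""
    lo, hi = margin, genome_len - margin - item_len
    if hi <= lo:
        raise ValueError("genome too short for the requested implants")
    starts: list[int] = []
    for _ in range(max_tries):
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - s) >= item_len + margin for s in starts):
            starts.append(cand)
            if len(starts) == n:
                return starts
    raise ValueError("could not place implants without overlap")


def simulate_genome(cfg: GenomeSimConfig) -> GenomeSim:
    """Background genome with implanted elements, decoys and EST/exon tracks."""
    rng = np.random.default_rng(cfg.rng_seed)
    chrom = "chr1"
    background = _encode(_random_seq(cfg.genome_length, cfg.gc, rng))
    consensus = make_consensus_element(
        cfg.element_length, cfg.element_loop, rng,
        mature=cfg.mature, mature_offset=cfg.mature_arm_offset, gc=cfg.gc,
    )
    n_carriers = round(cfg.seed_carrier_fraction * cfg.n_elements)
    total = cfg.n_elements + cfg.n_decoys
    margin = 300  # room for excision windows at implant edges
    starts = _place_nonoverlapping(
        total, cfg.element_length, cfg.genome_length, margin, rng
    )

    mature_dna = cfg.mature.upper().replace("U", "T")
    m_off = 2 + cfg.mature_arm_offset  # element coords: after the TA flank
    protect = np.zeros(cfg.element_length, dtype=bool)
    if cfg.protect_mature:
        protect[m_off : m_off + len(mature_dna)] = True

    repeats: list[RepeatAnnotation] = []
    truth: list[ImplantTruth] = []
    for k, start0 in enumerate(starts):
        is_decoy = k >= cfg.n_elements
        is_carrier = (not is_decoy) and k < n_carriers
        if is_decoy:
            seq = dinucleotide_shuffle(consensus, rng)
        else:
            base = consensus if is_carrier else make_consensus_element(
                cfg.element_length, cfg.element_loop, rng, gc=cfg.gc
            )
            seq = mutate(base, cfg.element_mutation_rate, rng,
                         kappa=cfg.kappa,
                         protect=protect if is_carrier else None)
        background[start0 : start0 + cfg.element_length] = _encode(seq)
        iv = GenomicInterval(
            chrom=chrom, start=start0 + 1, end=start0 + cfg.element_length,
            strand="+", name=f"{'decoy' if is_decoy else 'MER53L'}_{k}",
        )
        repeats.append(RepeatAnnotation(interval=iv, family="MER53"))
        mat_iv = None
        if is_carrier:
            mat_iv = GenomicInterval(
                chrom=chrom, start=iv.start + m_off,
                end=iv.start + m_off + len(mature_dna) - 1, strand="+",
            )
        truth.append(
            ImplantTruth(interval=iv, carrier=is_carrier, decoy=is_decoy,
                         mature_interval=mat_iv, arm="left")
        )

    carriers = [t for t in truth if t.carrier]
    n_est = round(cfg.est_fraction * len(carriers))
    ests = [
        GenomicInterval(chrom=chrom, start=max(1, t.interval.start - 50),
                        end=t.interval.end + 50, strand="+",
                        name=f"est_{i}")
        for i, t in enumerate(carriers[:n_est])
    ]
    n_exon = round(cfg.exon_fraction * len(carriers))
    exons = [
        GenomicInterval(chrom=chrom, start=t.interval.start,
                        end=t.interval.end, strand="+", name=f"exon_{i}")
        for i, t in enumerate(carriers[:n_exon])
    ]
    records = [SequenceRecord(id=chrom, seq=_decode(background))]
    _check_annotations(records, repeats, ests, exons)
    return GenomeSim(records=records, repeats=repeats, ests=ests,
                     exons=exons, truth=truth, config=cfg)


def _check_annotations(records, *annotation_lists) -> None:
    lengths = {r.id: len(r.seq) for r in records}
    for annotations in annotation_lists:
        for a in annotations:
            iv = a.interval if isinstance(a, RepeatAnnotation) else a
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise AssertionError(
                    f"emitted annotation {iv.to_string()} outside genome"
                )


# ---------------------------------------------------------------------------
# Segmental duplications with mosaic junction Alus
# ---------------------------------------------------------------------------

@dataclass
class SegDupSimConfig:
    """Study conditions for the duplication / Alu-recombination experiment."""

    n_pairs: int = 6
    alu_length: int = 300
    internal_families: tuple[str, ...] = (
        "AluSp", "AluJo", "AluYc", "AluJr", "AluSx"
    )
    internal_mutation_rate: float = 0.01   # per copy, per base
    junction_rate_multiplier: float = 5.0
    n_junction_alus: int = 2               # one mosaic per boundary
    orientation: str = "same"              # or "inverted"
    spacer: int = 40
    flank: int = 120
    element_length: int = 193
    element_loop: int = 9
    mature: str = MATURE_MIR1302
    mature_arm_offset: int = 49
    gc: float = 0.41
    kappa: float = 2.0
    rng_seed: int = 0


@dataclass
class SegDupSim:
    records: list[SequenceRecord]
    segdups: list[SegDupPair]
    alus: list[RepeatAnnotation]
    elements: list[RepeatAnnotation]
    truth: dict
    config: SegDupSimConfig


def simulate_segdups(cfg: SegDupSimConfig) -> SegDupSim:
    """Duplication pairs descending from common ancestors with Alu arrays.

    Each ancestor region is: mosaic Alu | spacer | AluSp | spacer | miRNA
    element | spacer | AluJo..AluSx array | spacer | mosaic Alu, where the
    mosaic junction Alus are half-and-half recombinants of two internal
    family consensus sequences.  The two copies of a pair are independent
    mutants of the ancestor; junction Alus mutate at
    ``junction_rate_multiplier`` times the internal rate.  Each copy lands on
    its own contig with the duplication boundary exactly at the outer edges
    of the two mosaics, so the mosaics overlap the +-5 bp terminus windows
    and the internal Alus do not.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    fams = cfg.internal_families
    consensus_alu = {
        fam: _random_seq(cfg.alu_length, 0.55, rng) for fam in fams
    }
    half = cfg.alu_length // 2
    if not 1 <= cfg.n_junction_alus <= 2:
        raise ValueError("n_junction_alus must be 1 (5' boundary only) or 2")

    records: list[SequenceRecord] = []
    segdups: list[SegDupPair] = []
    alus: list[RepeatAnnotation] = []
    elements: list[RepeatAnnotation] = []
    truth: dict = {"pairs": []}

    for k in range(cfg.n_pairs):
        element = make_consensus_element(
            cfg.element_length, cfg.element_loop, rng,
            mature=cfg.mature, mature_offset=cfg.mature_arm_offset, gc=cfg.gc,
        )
        # assemble the ancestor with a feature map (name, family, role, span)
        parts: list[tuple[str, str, str, str]] = []  # (seq, name, family, role)
        j5_fams, j3_fams = (fams[0], fams[1]), (fams[2], fams[3])
        j5 = consensus_alu[j5_fams[0]][:half] + consensus_alu[j5_fams[1]][half:]
        j3 = consensus_alu[j3_fams[1]][:half] + consensus_alu[j3_fams[0]][half:]

        def spacer() -> tuple[str, str, str, str]:
            return (_random_seq(cfg.spacer, cfg.gc, rng), "", "", "")

        parts.append((j5, "junction5", f"{j5_fams[0]}/{j5_fams[1]}", "junction"))
        parts.append(spacer())
        parts.append((consensus_alu[fams[0]], fams[0], fams[0], "internal"))
        parts.append(spacer())
        parts.append((element, f"mir_{k}", "MER53", "element"))
        parts.append(spacer())
        for fam in fams[1:]:
            parts.append((consensus_alu[fam], fam, fam, "internal"))
            parts.append(spacer())
        if cfg.n_junction_alus >= 2:
            parts.pop()  # the 3' mosaic itself ends the region
            parts.append(
                (j3, "junction3", f"{j3_fams[1]}/{j3_fams[0]}", "junction")
            )

        ancestor = "".join(p[0] for p in parts)
        # per-base rate mask: junction spans mutate faster
        rates = np.full(len(ancestor), cfg.internal_mutation_rate)
        pos = 0
        feature_spans: list[tuple[int, int, str, str, str]] = []
        for seq, name, family, role in parts:
            if role:
                feature_spans.append((pos, pos + len(seq), name, family, role))
                if role == "junction":
                    rates[pos : pos + len(seq)] *= cfg.junction_rate_multiplier
            pos += len(seq)

        pair_copies = []
        for side in ("a", "b"):
            # positionwise rates: mutate in two passes (uniform base rate,
            # then the junction excess) to keep a single rng stream
            copy = _mutate_rates(ancestor, rates, rng, cfg.kappa)
            chrom_name = f"sd{k + 1}{side}"
            inverted = side == "b" and cfg.orientation == "inverted"
            copy_emitted = revcomp(copy) if inverted else copy
            contig = (
                _random_seq(cfg.flank, cfg.gc, rng) + copy_emitted
                + _random_seq(cfg.flank, cfg.gc, rng)
            )
            records.append(SequenceRecord(id=chrom_name, seq=contig))
            region_start = cfg.flank + 1
            region_end = cfg.flank + len(ancestor)
            strand = "-" if inverted else "+"
            region = GenomicInterval(chrom=chrom_name, start=region_start,
                                     end=region_end, strand=strand)
            for f_start, f_end, name, family, role in feature_spans:
                if inverted:
                    a_start = region_start + (len(ancestor) - f_end)
                    a_end = region_start + (len(ancestor) - f_start) - 1
                else:
                    a_start = region_start + f_start
                    a_end = region_start + f_end - 1
                iv = GenomicInterval(chrom=chrom_name, start=a_start,
                                     end=a_end, strand=strand, name=name)
                ann = RepeatAnnotation(interval=iv, family=family)
                (elements if role == "element" else alus).append(ann)
            pair_copies.append(region)
        sd = SegDupPair(sd1=pair_copies[0], sd2=pair_copies[1],
                        pair_id=str(k + 1))
        segdups.append(sd)
        truth["pairs"].append(
            {"pair_id": sd.pair_id,
             "junction_rate": cfg.internal_mutation_rate
             * cfg.junction_rate_multiplier,
             "internal_rate": cfg.internal_mutation_rate}
        )
    _check_annotations(records, alus, elements)
    return SegDupSim(records=records, segdups=segdups, alus=alus,
                     elements=elements, truth=truth, config=cfg)


def _mutate_rates(
    seq: str, rates: np.ndarray, rng: np.random.Generator, kappa: float
) -> str:
    codes = _encode(seq)
    hit = rng.random(len(codes)) < rates
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq
    is_ts = rng.random(len(idx)) < kappa / (kappa + 2.0)
    new = codes[idx].copy()
    new[is_ts] = _TRANSITION[codes[idx][is_ts]]
    tv = ~is_ts
    pick = rng.integers(0, 2, size=int(tv.sum()))
    purine = np.isin(codes[idx][tv], (0, 2))
    new[tv] = np.where(purine, np.where(pick == 0, 1, 3),
                       np.where(pick == 0, 0, 2))
    codes[idx] = new
    return _decode(codes)


# ---------------------------------------------------------------------------
# Birth-and-death family evolution
# ---------------------------------------------------------------------------

@dataclass
class FamilyEvoConfig:
    """Study conditions for gene birth and death along the species tree."""

    tree_newick: str = DEFAULT_SPECIES_TREE
    n_genes: int = 200
    gain_rate: float = 0.15      # per-branch gain probability
    loss_rate: float = 0.02      # per-branch loss probability below the gain
    seq_length: int = 138        # evolving precursor length
    kappa: float = 2.0
    gc: float = 0.41
    rng_seed: int = 0


@dataclass
class FamilyEvoSim:
    presence: PresenceMatrix
    sequences: dict[tuple[str, str], str]  # (species, gene) -> sequence
    truth: dict  # per gene: true gain branch + loss branches
    config: FamilyEvoConfig


def simulate_family_evolution(cfg: FamilyEvoConfig) -> FamilyEvoSim:
    """Evolve gene presence/absence (and sequences) by birth and death.

    Every branch of the rooted tree (including the root edge) may acquire the
    gene with probability ``gain_rate``; the first branch in preorder that
    fires is the single gain (Dollo semantics).  Below the gain each live
    branch loses the gene independently with probability ``loss_rate``; a
    loss silences the entire subtree.  Present leaves receive sequences
    mutated from a per-gene ancestral sequence along the total path length.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick",
                             rooting="force-rooted",
                             preserve_underscores=True)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    nodes = list(tree.preorder_node_iter())

    def branch_id(node) -> tuple[str, ...]:
        return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))

    states: dict[tuple[str, str], str] = {}
    sequences: dict[tuple[str, str], str] = {}
    truth: dict = {"genes": {}}
    genes: list[str] = []
    for g in range(cfg.n_genes):
        gene = f"gene{g:03d}"
        genes.append(gene)
        gains = rng.random(len(nodes)) < cfg.gain_rate
        gain_node = None
        for node, fired in zip(nodes, gains):
            if fired:
                gain_node = node
                break
        if gain_node is None:
            truth["genes"][gene] = {"gain": None, "losses": []}
            for sp in species:
                states[(sp, gene)] = "absent"
            continue
        ancestral = _random_seq(cfg.seq_length, cfg.gc, rng)
        losses: list[tuple[str, ...]] = []
        present: set[str] = set()

        def descend(node, alive: bool, dist: float) -> None:
            if node is not gain_node:
                if alive and rng.random() < cfg.loss_rate:
                    losses.append(branch_id(node))
                    alive = False
            if node.is_leaf():
                if alive:
                    present.add(node.taxon.label)
                    seq = mutate(ancestral, min(dist, 0.75), rng,
                                 kappa=cfg.kappa)
                    sequences[(node.taxon.label, gene)] = seq
                return
            for child in node.child_nodes():
                edge = child.edge.length or 0.0
                descend(child, alive, dist + edge)

        descend(gain_node, True, 0.0)
        truth["genes"][gene] = {
            "gain": branch_id(gain_node), "losses": losses,
        }
        for sp in species:
            states[(sp, gene)] = "present" if sp in present else "absent"
    presence = PresenceMatrix(
        species=species, genes=genes, states=states, tree=tree
    )
    return FamilyEvoSim(presence=presence, sequences=sequences, truth=truth,
                        config=cfg)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_genome_sim(sim: GenomeSim, outdir: str | Path) -> dict[str, Path]:
    """Emit genome.fa, repeats.tsv, est.tsv, exons.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "repeats": outdir / "repeats.tsv",
        "est": outdir / "est.tsv",
        "exons": outdir / "exons.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(sim.records, paths["genome"])
    write_interval_table(sim.repeats, paths["repeats"])
    write_interval_table(sim.ests, paths["est"])
    write_interval_table(sim.exons, paths["exons"])
    truth = [
        {
            "interval": t.interval.to_string(),
            "carrier": t.carrier,
            "decoy": t.decoy,
            "mature": t.mature_interval.to_string() if t.mature_interval else None,
            "arm": t.arm,
        }
        for t in sim.truth
    ]
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def write_segdup_sim(sim: SegDupSim, outdir: str | Path) -> dict[str, Path]:
    """Emit sd_genome.fa, segdups.tsv, alus.tsv and sd_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "sd_genome.fa",
        "segdups": outdir / "segdups.tsv",
        "alus": outdir / "alus.tsv",
        "truth": outdir / "sd_truth.json",
    }
    write_fasta(sim.records, paths["genome"])
    write_interval_table(sim.segdups, paths["segdups"])
    write_interval_table(sim.alus + sim.elements, paths["alus"])
    paths["truth"].write_text(json.dumps(sim.truth, indent=1))
    return paths


def write_family_sim(sim: FamilyEvoSim, outdir: str | Path) -> dict[str, Path]:
    """Emit presence.tsv and tree.nwk."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"presence": outdir / "presence.tsv", "tree": outdir / "tree.nwk"}
    pm = sim.presence
    df = pd.DataFrame(
        {g: [pm.state(sp, g) for sp in pm.species] for g in pm.genes},
        index=pm.species,
    )
    df.to_csv(paths["presence"], sep="\t")
    paths["tree"].write_text(sim.config.tree_newick + "\n")
    return paths
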