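"""Distances, neighbor-joining trees, bootstrap, Dollo gain/loss and the
birth-and-death clustering diagnostic.

Distances are uncorrected p-distances (pairwise or complete deletion of
gapped/ambiguous sites) or Kimura two-parameter corrected distances
d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) with P the transition and Q the transversion
proportion over compared sites.  Trees come from Saitou–Nei neighbor joining
with a deterministic label-order tie-break, negative branch lengths clamped
to zero with the length transferred to the sibling edge.  Edge reliability is
assessed by column-resampling bootstrap with bipartition counting.

Gene gain and loss on a rooted species tree is reconstructed under Dollo
parsimony (a transposon-derived gene originates once; losses are free), with
a Fitch unordered-parsimony scorer used both as an alternative event model
and as the clustering diagnostic for birth-and-death versus concerted
evolution: genes evolving by birth-and-death cluster by gene type across
species, so the Fitch score of the type labeling on the gene tree is smaller
than that of the species labeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PresenceMatrix",
    "GainLossReconstruction",
    "ClusteringDiagnostic",
    "p_distance",
    "k2p_distance",
    "k2p_from_counts",
    "nj_tree",
    "bootstrap_support",
    "tree_bipartitions",
    "dollo_gain_loss",
    "fitch_score",
    "clustering_pattern",
    "needleman_wunsch",
    "read_presence_table",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PURINE = {0, 2}


@dataclass
class Alignment:
    """Equal-length gap-containing rows keyed by unique labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """(n_taxa, n_sites) uint8 matrix; 255 marks gap/N/unknown."""
        out = np.full((len(self.rows), self.n_sites), 255, dtype=np.uint8)
        for i, row in enumerate(self.rows):
            for j, c in enumerate(row.upper()):
                out[i, j] = _ENC.get(c, 255)
        return out

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        return Alignment(
            labels=list(self.labels),
            rows=["".join(r[j] for j in idx) for r in self.rows],
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; NaN flags undefined/saturated entries."""

    labels: list[str]
    d: np.ndarray
    method: str = "p"
    n_sites: np.ndarray | None = None  # compared sites per pair

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")

    def entry(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) under pairwise deletion."""
    valid = (x != 255) & (y != 255)
    xi, yi = x[valid], y[valid]
    diff = xi != yi
    both_purine = np.isin(xi, (0, 2)) & np.isin(yi, (0, 2))
    both_pyrim = np.isin(xi, (1, 3)) & np.isin(yi, (1, 3))
    transitions = int(np.sum(diff & (both_purine | both_pyrim)))
    transversions = int(np.sum(diff)) - transitions
    return int(valid.sum()), transitions, transversions


def p_distance(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected proportion of differing sites between every pair.

    ``pairwise`` deletion excludes sites gapped/ambiguous in either member of
    the pair; ``complete`` drops every column containing any gap/ambiguity
    before comparison.  Pairs with zero comparable sites get NaN.
    """
    if len(aln.labels) < 2:
        raise ValueError("need at least 2 taxa")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    enc = aln.encoded()
    if deletion == "complete":
        keep = ~np.any(enc == 255, axis=0)
        enc = enc[:, keep]
    n = len(aln.labels)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m, ts, tv = _pair_counts(enc[i], enc[j])
            sites[i, j] = sites[j, i] = m
            d[i, j] = d[j, i] = (ts + tv) / m if m else math.nan
    return DistanceMatrix(labels=list(aln.labels), d=d, method="p", n_sites=sites)


def k2p_from_counts(n_sites: int, transitions: int, transversions: int) -> float:
    """K2P distance from site counts; NaN when the correction saturates."""
    if n_sites == 0:
        return math.nan
    P = transitions / n_sites
    Q = transversions / n_sites
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return math.nan  # saturated
    return -0.5 * math.log(a * math.sqrt(b))


def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two aligned sequences (pairwise gap deletion).

    Returns NaN when the logarithm's argument is non-positive (saturation).
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    enc = Alignment(labels=["a", "b"], rows=[a, b]).encoded()
    m, ts, tv = _pair_counts(enc[0], enc[1])
    return k2p_from_counts(m, ts, tv)


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    n = len(aln.labels)
    enc = aln.encoded()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_from_counts(*_pair_counts(enc[i], enc[j]))
    return DistanceMatrix(labels=list(aln.labels), d=d, method="K2P")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _fmt_len(x: float) -> str:
    return f"{max(x, 0.0):.10g}"


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the lexicographic order of the
    sorted descendant-leaf label tuples of the two candidate nodes, so the
    result is invariant to the input row order.  Negative branch lengths are
    clamped to zero and the length transferred to the sibling edge.
    """
    if len(m.labels) < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    if np.isnan(m.d).any():
        raise ValueError(
            "distance matrix has undefined entries; impute or drop taxa first"
        )
    # active nodes: (sort_key, newick_fragment); distances in a dict-of-dict
    keys: list[tuple[str, ...]] = [(lab,) for lab in m.labels]
    news: dict[tuple[str, ...], str] = {(lab,): lab for lab in m.labels}
    dist: dict[tuple[str, ...], dict[tuple[str, ...], float]] = {
        keys[i]: {
            keys[j]: float(m.d[i, j]) for j in range(len(keys)) if j != i
        }
        for i in range(len(keys))
    }
    active = sorted(keys)

    while len(active) > 3:
        n = len(active)
        r = {k: sum(dist[k][o] for o in active if o != k) for k in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist[a][b] - r[a] - r[b]
                cand = (q, min(a, b), max(a, b))
                if best is None or cand < best:
                    best = cand
                    pick = (a, b)
        a, b = pick
        dab = dist[a][b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        if lb < 0:
            la, lb = dab, 0.0
        new_key = tuple(sorted(a + b))
        news[new_key] = f"({news[a]}:{_fmt_len(la)},{news[b]}:{_fmt_len(lb)})"
        dist[new_key] = {}
        for k in active:
            if k in (a, b):
                continue
            duk = 0.5 * (dist[a][k] + dist[b][k] - dab)
            dist[new_key][k] = dist[k][new_key] = duk
        active = sorted(k for k in active if k not in (a, b)) + [new_key]
        active.sort()
        for k in (a, b):
            del dist[k]

    x, y, z = active
    lx = 0.5 * (dist[x][y] + dist[x][z] - dist[y][z])
    ly = 0.5 * (dist[x][y] + dist[y][z] - dist[x][z])
    lz = 0.5 * (dist[x][z] + dist[y][z] - dist[x][y])
    newick = (
        f"({news[x]}:{_fmt_len(lx)},{news[y]}:{_fmt_len(ly)},"
        f"{news[z]}:{_fmt_len(lz)});"
    )
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-unrooted",
                             preserve_underscores=True)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label frozensets.

    Each internal edge splits the leaves in two; the side not containing the
    alphabetically first leaf is the canonical representative.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        side = below if ref not in below else leaves - below
        out.add(frozenset(side))
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    support: dict[frozenset[str], float]  # percent, on internal edges
    n_reps: int

    def annotated_newick(self) -> str:
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        ref = min(leaves)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            if len(below) <= 1 or len(below) >= len(leaves) - 1:
                continue
            side = below if ref not in below else leaves - below
            pct = self.support.get(frozenset(side))
            if pct is not None:
                node.label = f"{pct:g}"
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def bootstrap_support(
    aln: Alignment, n_reps: int = 1000, rng_seed: int = 0
) -> BootstrapResult:
    """Column-resampling bootstrap supports for the p-distance NJ tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    base = nj_tree(p_distance(aln))
    target = tree_bipartitions(base)
    counts = {bp: 0 for bp in target}
    for _ in range(n_reps):
        rep = nj_tree(p_distance(aln.resample_columns(rng)))
        for bp in tree_bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return BootstrapResult(tree=base, support=support, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Presence/absence, Dollo gain/loss, Fitch
# ---------------------------------------------------------------------------

STATES = ("present", "absent", "unknown")


@dataclass
class PresenceMatrix:
    """Species x gene-locus presence states on a rooted species tree."""

    species: list[str]
    genes: list[str]
    states: dict[tuple[str, str], str]  # (species, gene) -> state
    tree: dendropy.Tree

    def __post_init__(self) -> None:
        tree_leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if set(self.species) != tree_leaves:
            raise ValueError(
                "presence-matrix species do not match the species-tree leaves"
            )
        for key, st in self.states.items():
            if st not in STATES:
                raise ValueError(f"illegal state {st!r} for {key}")

    def state(self, species: str, gene: str) -> str:
        return self.states.get((species, gene), "unknown")


_FIG2_STATE_MAP = {
    "mir": "present", "present": "present",
    "ortholog": "absent",        # default: an ortholog not validated as a
    "absent": "absent",          # miRNA does not count as a miRNA gene
    "gap": "unknown", "unknown": "unknown", "insertion": "unknown",
}


def read_presence_table(
    path: str | Path,
    tree: dendropy.Tree,
    ortholog_counts_as: str = "absent",
) -> PresenceMatrix:
    """Read a species x gene TSV of states into a :class:`PresenceMatrix`.

    Cell vocabulary: ``miR``/``present``, ``ortholog`` (an ortholog present
    but not validated as a miRNA — mapped per *ortholog_counts_as*),
    ``absent``, ``gap``/``unknown``/``insertion``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    mapping = dict(_FIG2_STATE_MAP)
    mapping["ortholog"] = ortholog_counts_as
    states: dict[tuple[str, str], str] = {}
    for sp in df.index:
        for gene in df.columns:
            raw = str(df.loc[sp, gene]).strip().lower()
            if raw not in mapping:
                raise ValueError(f"unknown presence state {raw!r}")
            states[(str(sp), str(gene))] = mapping[raw]
    return PresenceMatrix(
        species=[str(s) for s in df.index],
        genes=[str(g) for g in df.columns],
        states=states,
        tree=tree,
    )


BranchId = tuple[str, ...]  # sorted leaf labels below the branch


def _branch_id(node: dendropy.Node) -> BranchId:
    return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))


@dataclass
class GainLossReconstruction:
    """Per-gene Dollo events; branches named by their descendant leaf sets."""

    gains: dict[str, BranchId | None] = field(default_factory=dict)
    losses: dict[str, list[BranchId]] = field(default_factory=dict)

    @property
    def total_gains(self) -> int:
        return sum(1 for g in self.gains.values() if g is not None)

    @property
    def total_losses(self) -> int:
        return sum(len(v) for v in self.losses.values())

    def events_for(self, gene: str) -> int:
        return (self.gains.get(gene) is not None) + len(self.losses.get(gene, []))


def dollo_gain_loss(pm: PresenceMatrix) -> GainLossReconstruction:
    """Minimum gain/loss reconstruction under the Dollo criterion.

    Each gene originates exactly once, on the branch above the most recent
    common ancestor of all its present species; losses are the minimal set of
    branches below that ancestor whose removal explains the absent leaves.
    Unknown leaves are free to take either state and never force a loss.
    """
    rec = GainLossReconstruction()
    tree = pm.tree
    for gene in pm.genes:
        present = {s for s in pm.species if pm.state(s, gene) == "present"}
        if not present:
            rec.gains[gene] = None
            rec.losses[gene] = []
            continue
        mrca = tree.mrca(taxon_labels=present)
        rec.gains[gene] = _branch_id(mrca)
        losses: list[BranchId] = []

        def visit(node: dendropy.Node) -> None:
            below = {lf.taxon.label for lf in node.leaf_iter()}
            if below & present:
                for child in node.child_nodes():
                    visit(child)
                return
            absent_below = {
                s for s in below if pm.state(s, gene) == "absent"
            }
            if absent_below:
                losses.append(_branch_id(node))
            # all-unknown subtrees need no event

        for child in mrca.child_nodes():
            visit(child)
        rec.losses[gene] = losses
    return rec


def fitch_score(tree: dendropy.Tree, label_of: dict[str, str]) -> int:
    """Fitch small-parsimony score of an unordered leaf labeling."""
    changes = 0

    def post(node: dendropy.Node) -> frozenset[str]:
        nonlocal changes
        if node.is_leaf():
            label = label_of.get(node.taxon.label)
            if label is None:
                raise ValueError(f"leaf {node.taxon.label!r} is untagged")
            return frozenset([label])
        sets = [post(c) for c in node.child_nodes()]
        inter = frozenset.intersection(*sets)
        if inter:
            return inter
        changes += len(sets) - 1  # multifurcations charged per extra child
        return frozenset.union(*sets)

    post(tree.seed_node)
    return changes


@dataclass
class ClusteringDiagnostic:
    type_score: int
    species_score: int
    verdict: str  # birth-and-death-like | concerted-like | undetermined


def clustering_pattern(
    tree: dendropy.Tree,
    species_of: dict[str, str],
    type_of: dict[str, str],
) -> ClusteringDiagnostic:
    """Birth-and-death vs concerted evolution from leaf clustering.

    Under birth-and-death evolution paralogous gene types predate
    speciations, so the gene tree clusters by type (few type-label changes,
    many species-label changes); under concerted evolution paralogs
    homogenize within genomes and the tree clusters by species.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for leaf in leaves:
        if leaf not in species_of or leaf not in type_of:
            raise ValueError(f"leaf {leaf!r} is untagged")
    n_species = len(set(species_of[l] for l in leaves))
    n_types = len(set(type_of[l] for l in leaves))
    t_score = fitch_score(tree, type_of)
    s_score = fitch_score(tree, species_of)
    if n_species < 2 or n_types < 2:
        verdict = "undetermined"
    elif t_score < s_score:
        verdict = "birth-and-death-like"
    elif t_score > s_score:
        verdict = "concerted-like"
    else:
        verdict = "undetermined"
    return ClusteringDiagnostic(
        type_score=t_score, species_score=s_score, verdict=verdict
    )


# ---------------------------------------------------------------------------
# Pairwise alignment utility (for near-identical copies in the test harness
# and the Alu divergence pipeline)
# ---------------------------------------------------------------------------

def needleman_wunsch(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[str, str]:
    """Global alignment with linear gap cost; deterministic traceback
    (diagonal preferred over up over left)."""
    n, m = len(a), len(b)
    au = a.upper()
    bu = np.frombuffer(b.upper().encode(), dtype="S1")
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    move[0, 1:] = 2
    move[1:, 0] = 1
    for i in range(1, n + 1):
        sub = np.where(bu == au[i - 1].encode(), match, mismatch)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] + gap
        row = score[i]
        prev = score[i - 1]
        # left dependency forces a scalar scan within the row
        for j in range(1, m + 1):
            best = diag[j - 1]
            mv = 0
            if up[j - 1] > best:
                best, mv = up[j - 1], 1
            if row[j - 1] + gap > best:
                best, mv = row[j - 1] + gap, 2
            row[j] = best
            move[i, j] = mv
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif mv == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))
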