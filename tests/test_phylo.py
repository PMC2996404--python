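import itertools
import math

import dendropy
import numpy as np
import pytest

from temir import (
    Alignment,
    DistanceMatrix,
    PresenceMatrix,
    bootstrap_support,
    clustering_pattern,
    dollo_gain_loss,
    fitch_score,
    k2p_distance,
    needleman_wunsch,
    nj_tree,
    p_distance,
)
from temir.phylo import tree_bipartitions


def rooted(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted",
                           preserve_underscores=True)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert p_distance(aln).entry("a", "b") == 0.0

    def test_two_mismatches_in_ten(self):
        aln = Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTTT"])
        assert p_distance(aln).entry("a", "b") == pytest.approx(0.2)

    def test_pairwise_deletion_excludes_gaps(self):
        aln = Alignment(["a", "b"], ["AC-T", "ACGT"])
        dm = p_distance(aln, deletion="pairwise")
        assert dm.entry("a", "b") == 0.0
        assert dm.n_sites[0, 1] == 3

    def test_complete_deletion_drops_gapped_columns_for_all(self):
        aln = Alignment(["a", "b", "c"], ["AC-T", "ACGT", "TCGT"])
        dm = p_distance(aln, deletion="complete")
        # column 3 (gap in a) removed for every pair: a vs c differs at 1/3
        assert dm.entry("a", "c") == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_undefined(self):
        aln = Alignment(["a", "b"], ["A---", "-CGT"])
        assert math.isnan(p_distance(aln).entry("a", "b"))


class TestK2P:
    def test_identical_is_zero(self):
        assert k2p_distance("ACGT" * 5, "ACGT" * 5) == 0.0

    def test_one_transition_in_ten(self):
        # P=0.1, Q=0: d = -1/2 ln(0.8) = 0.1116
        d = k2p_distance("ACGTACGTAC", "GCGTACGTAC")
        assert d == pytest.approx(0.11157, abs=5e-5)

    def test_closed_form_at_quarter_quarter(self):
        # P=0.25, Q=0.25: argument (1-2P-Q)sqrt(1-2Q) > 0, still defined
        a = "A" * 20
        b = "G" * 5 + "C" * 5 + "A" * 10
        d = k2p_distance(a, b)
        expected = -0.5 * math.log(0.25 * math.sqrt(0.5))
        assert d == pytest.approx(expected)

    def test_saturation_flagged_as_nan(self):
        # P=0.4, Q=0.25 makes 1-2P-Q negative
        a = "A" * 20
        b = "G" * 8 + "C" * 5 + "A" * 7
        assert math.isnan(k2p_distance(a, b))

    def test_k2p_dominates_p_distance_when_defined(self, rng):
        alpha = np.array(list("ACGT"))
        for _ in range(60):
            n = int(rng.integers(20, 60))
            a = "".join(rng.choice(alpha, n))
            b = "".join(rng.choice(alpha, n))
            d = k2p_distance(a, b)
            if math.isnan(d):
                continue
            p = np.mean([x != y for x, y in zip(a, b)])
            assert d >= p - 1e-12


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies as edge lists (leaf insertion)."""
    # nodes: leaf labels are strings, internal nodes ints
    base = [("__i0", labels[0]), ("__i0", labels[1]), ("__i0", labels[2])]
    trees = [base]
    for k, leaf in enumerate(labels[3:], start=1):
        new_trees = []
        for edges in trees:
            for idx in range(len(edges)):
                u, v = edges[idx]
                mid = f"__i{k}_{idx}"
                rest = edges[:idx] + edges[idx + 1:]
                new_trees.append(
                    rest + [(u, mid), (mid, v), (mid, leaf)]
                )
        trees = new_trees
    return trees


def additive_matrix(edges, labels, lengths):
    """Leaf-to-leaf path length matrix for the given edge lengths."""
    adj = {}
    for (u, v), w in zip(edges, lengths):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return d


def path_matrix(tree: dendropy.Tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(DistanceMatrix(labels, d))
        got = path_matrix(tree, labels)
        assert np.allclose(got, d)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_exact_on_all_additive_topologies(self, n_taxa):
        labels = [chr(65 + i) for i in range(n_taxa)]
        topologies = enumerate_unrooted_topologies(labels)
        assert len(topologies) == {4: 3, 5: 15}[n_taxa]
        rng = np.random.default_rng(n_taxa)
        for edges in topologies:
            for _ in range(3):
                lengths = rng.uniform(0.5, 3.0, size=len(edges))
                d = additive_matrix(edges, labels, lengths)
                tree = nj_tree(DistanceMatrix(labels, d))
                assert np.allclose(path_matrix(tree, labels), d, atol=1e-9)

    def test_tie_break_stable_under_input_permutation(self):
        labels = ["a", "b", "c", "d"]
        # ultrametric with two equal Q minima
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        ref = nj_tree(DistanceMatrix(labels, d))
        ref_bip = tree_bipartitions(ref)
        ref_paths = path_matrix(ref, labels)
        for perm in itertools.permutations(range(4)):
            pl = [labels[i] for i in perm]
            pd_ = d[np.ix_(perm, perm)]
            tree = nj_tree(DistanceMatrix(pl, pd_))
            assert tree_bipartitions(tree) == ref_bip
            assert np.allclose(path_matrix(tree, labels), ref_paths)

    def test_matches_scikit_bio_on_random_matrices(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        for _ in range(5):
            n = 8
            x = rng.random((n, n))
            d = (x + x.T) / 2 + 1.0
            np.fill_diagonal(d, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, d))
            theirs = dendropy.Tree.get(
                data=str(sknj(SkDM(d, ids=labels))), schema="newick",
                rooting="force-unrooted", preserve_underscores=True,
            )
            assert tree_bipartitions(mine) == tree_bipartitions(theirs)

    def test_undefined_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = math.nan
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))


class TestBootstrap:
    @staticmethod
    def two_clade_alignment(n_sites=80, seed=0):
        """Ten taxa in two clades of five, high divergence between clades,
        low but resolving divergence within (every internal edge carries
        several dedicated substitutions)."""
        rng = np.random.default_rng(seed)
        alpha = np.array(list("ACGT"))

        def bump(base, sites, step=1):
            s = base.copy()
            for i in sites:
                s[i] = alpha[(np.where(alpha == s[i])[0][0] + step) % 4]
            return s

        root = rng.choice(alpha, n_sites)
        clade_a = root
        clade_b = bump(root, range(0, 20))          # deep split: 20 sites
        groups = {
            f"t{i:02d}": [56 + i] for i in range(10)  # private singletons
        }
        sub = {
            ("t00", "t01"): range(20, 26), ("t02", "t03"): range(26, 32),
            ("t05", "t06"): range(32, 38), ("t07", "t08"): range(38, 44),
            ("t00", "t01", "t02", "t03"): range(44, 50),
            ("t05", "t06", "t07", "t08"): range(50, 56),
        }
        rows = {}
        for label in groups:
            base = clade_a if label < "t05" else clade_b
            for pair, sites in sub.items():
                if label in pair:
                    base = bump(base, sites, step=2)
            rows[label] = "".join(bump(base, groups[label], step=3))
        labels = sorted(rows)
        return (
            Alignment(labels, [rows[l] for l in labels]),
            frozenset(labels[5:]),
        )

    def test_single_replicate_supports_are_0_or_100(self):
        aln, _ = self.two_clade_alignment()
        result = bootstrap_support(aln, n_reps=1, rng_seed=4)
        assert set(result.support.values()) <= {0.0, 100.0}

    def test_same_seed_is_reproducible(self):
        aln, _ = self.two_clade_alignment()
        a = bootstrap_support(aln, n_reps=50, rng_seed=11)
        b = bootstrap_support(aln, n_reps=50, rng_seed=11)
        assert a.support == b.support

    def test_clean_split_is_strongly_supported_and_converges(self):
        aln, split = self.two_clade_alignment()
        run1 = bootstrap_support(aln, n_reps=1000, rng_seed=1)
        run2 = bootstrap_support(aln, n_reps=1000, rng_seed=2)
        assert run1.support[split] >= 95.0
        for bp, s1 in run1.support.items():
            assert abs(s1 - run2.support[bp]) <= 3.0


# ---------------------------------------------------------------------------
# Dollo gain/loss
# ---------------------------------------------------------------------------

def presence(tree, pattern: dict[str, str], gene="g") -> PresenceMatrix:
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    states = {(sp, gene): pattern.get(sp, "unknown") for sp in species}
    return PresenceMatrix(species=species, genes=[gene], states=states,
                          tree=tree)


def brute_force_dollo_minimum(tree, pattern: dict[str, str]) -> int:
    """Minimum events over all single-gain labelings (exhaustive)."""
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    best = math.inf
    for bits in itertools.product([0, 1], repeat=len(internal)):
        state = {id(n): b for n, b in zip(internal, bits)}
        feasible_leaf_states = []
        for leaf in leaves:
            want = pattern.get(leaf.taxon.label, "unknown")
            if want == "present":
                feasible_leaf_states.append([1])
            elif want == "absent":
                feasible_leaf_states.append([0])
            else:
                feasible_leaf_states.append([0, 1])
        for leaf_bits in itertools.product(*feasible_leaf_states):
            full = dict(state)
            for leaf, b in zip(leaves, leaf_bits):
                full[id(leaf)] = b
            gains = losses = 0
            root_state = full[id(tree.seed_node)]
            gains += root_state  # gain on the root edge
            ok = True
            for node in nodes:
                for child in node.child_nodes():
                    a, b = full[id(node)], full[id(child)]
                    if a == 0 and b == 1:
                        gains += 1
                    elif a == 1 and b == 0:
                        losses += 1
            if gains <= 1:
                best = min(best, gains + losses)
    return best


class TestDolloGainLoss:
    def test_paper_pattern_gain_in_simiiform_ancestor_lost_in_tarsier(self):
        tree = rooted(
            "(((human:1,marmoset:1):1,tarsier:2):1,mouse_lemur:3);"
        )
        pm = presence(tree, {
            "human": "present", "marmoset": "present",
            "tarsier": "absent", "mouse_lemur": "present",
        })
        rec = dollo_gain_loss(pm)
        assert rec.gains["g"] == ("human", "marmoset", "mouse_lemur",
                                  "tarsier")
        assert rec.losses["g"] == [("tarsier",)]
        assert rec.total_gains == 1 and rec.total_losses == 1

    def test_present_everywhere_is_one_root_gain(self):
        tree = rooted("((a:1,b:1):1,(c:1,d:1):1);")
        pm = presence(tree, {s: "present" for s in "abcd"})
        rec = dollo_gain_loss(pm)
        assert rec.gains["g"] == ("a", "b", "c", "d")
        assert rec.losses["g"] == []

    def test_absent_everywhere_has_no_events(self):
        tree = rooted("((a:1,b:1):1,c:2);")
        pm = presence(tree, {s: "absent" for s in "abc"})
        rec = dollo_gain_loss(pm)
        assert rec.gains["g"] is None and rec.losses["g"] == []

    def test_unknown_leaves_never_force_losses(self):
        tree = rooted("((a:1,b:1):1,(c:1,d:1):1);")
        pm = presence(tree, {"a": "present", "b": "unknown",
                             "c": "unknown", "d": "unknown"})
        rec = dollo_gain_loss(pm)
        assert rec.gains["g"] == ("a",)
        assert rec.losses["g"] == []

    def test_event_counts_match_exhaustive_minimum(self, rng):
        tree = rooted(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        )
        species = list("abcdefgh")
        for _ in range(40):
            pattern = {
                sp: ("present", "absent", "unknown")[rng.integers(0, 3)]
                for sp in species
            }
            if not any(v == "present" for v in pattern.values()):
                continue
            pm = presence(tree, pattern)
            rec = dollo_gain_loss(pm)
            mine = rec.events_for("g")
            assert mine == brute_force_dollo_minimum(tree, pattern), pattern


class TestClusteringDiagnostic:
    def test_type_monophyletic_tree_is_birth_and_death_like(self):
        # two type clades, each mixing three species
        tree = rooted(
            "(((s1_tA:1,s2_tA:1):1,s3_tA:1):1,"
            "((s1_tB:1,s2_tB:1):1,s3_tB:1):1);"
        )
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        species_of = {l: l.split("_")[0] for l in leaves}
        type_of = {l: l.split("_")[1] for l in leaves}
        diag = clustering_pattern(tree, species_of, type_of)
        assert diag.type_score == 1
        assert diag.species_score >= 3
        assert diag.verdict == "birth-and-death-like"

    def test_species_monophyletic_tree_is_concerted_like(self):
        tree = rooted(
            "(((s1_tA:1,s1_tB:1):1,s1_tC:1):1,"
            "((s2_tA:1,s2_tB:1):1,s2_tC:1):1);"
        )
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        species_of = {l: l.split("_")[0] for l in leaves}
        type_of = {l: l.split("_")[1] for l in leaves}
        diag = clustering_pattern(tree, species_of, type_of)
        assert diag.verdict == "concerted-like"

    def test_single_species_is_undetermined(self):
        tree = rooted("((x_tA:1,x_tB:1):1,x_tC:2);")
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        diag = clustering_pattern(
            tree, {l: "x" for l in leaves},
            {l: l.split("_")[1] for l in leaves},
        )
        assert diag.verdict == "undetermined"

    def test_untagged_leaf_rejected(self):
        tree = rooted("((a:1,b:1):1,c:2);")
        with pytest.raises(ValueError, match="untagged"):
            clustering_pattern(tree, {"a": "x", "b": "x"}, {})

    def test_fitch_score_hand_example(self):
        tree = rooted("((a:1,b:1):1,(c:1,d:1):1);")
        assert fitch_score(tree, {"a": "X", "b": "X", "c": "Y", "d": "Y"}) == 1
        assert fitch_score(tree, {"a": "X", "b": "Y", "c": "X", "d": "Y"}) == 2


class TestNeedlemanWunsch:
    def test_identical_sequences_align_without_gaps(self):
        a, b = needleman_wunsch("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_single_deletion_recovered(self):
        a, b = needleman_wunsch("ACGTACGT", "ACGACGT")
        assert a.replace("-", "") == "ACGTACGT"
        assert b.replace("-", "") == "ACGACGT"
        assert len(a) == len(b) == 8
        assert b.count("-") == 1
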