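"""Distances, neighbor-joining correctness and bootstrap behavior."""

import itertools
import math

import numpy as np
import pytest

from mitocensus.genome_io import SequenceRecord
from mitocensus.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    distance_matrix,
    kmer_distance_matrix,
    neighbor_joining,
    pairwise_distance,
)
from mitocensus.simulate import make_genome, make_genome_family


class TestDistances:
    def test_identical_zero_under_all_models(self):
        for model in ("p", "JC69", "K2P"):
            assert pairwise_distance("ACGTACGT", "ACGTACGT", model) == 0.0

    def test_k2p_closed_form_all_transitions(self):
        # p = 0.1, all transitions: K2P = -1/2 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        got = pairwise_distance(a, b, "K2P")
        assert got == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_jc69_saturation(self):
        a = "A" * 100
        b = "C" * 75 + "A" * 25
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, "JC69")

    def test_model_ordering_p_le_jc_le_k2p(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), size=2000))
        # transition-biased mutations
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        mutated = list(base)
        for i in rng.choice(2000, 200, replace=False):
            mutated[i] = ts[mutated[i]]
        b = "".join(mutated)
        p = pairwise_distance(base, b, "p")
        jc = pairwise_distance(base, b, "JC69")
        k2p = pairwise_distance(base, b, "K2P")
        assert p <= jc <= k2p

    def test_gap_and_ambiguous_columns_ignored(self):
        assert pairwise_distance("AC-GN", "ACCGA", "p") == 0.0


def _random_additive_matrix(n_taxa: int, rng) -> tuple[DistanceMatrix, set[frozenset]]:
    """Random binary tree -> exact leaf-to-leaf path distances + true splits."""
    nodes = [{"leaves": {f"t{i}"}, "dist": {f"t{i}": 0.0}} for i in range(n_taxa)]
    splits: list[set] = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 0.5, size=2)
        merged = {
            "leaves": a["leaves"] | b["leaves"],
            "dist": {
                **{k: v + la for k, v in a["dist"].items()},
                **{k: v + lb for k, v in b["dist"].items()},
            },
        }
        splits.append(set(a["leaves"]))
        splits.append(set(b["leaves"]))
        pairs = {}
        for x in a["leaves"]:
            for y in b["leaves"]:
                pairs[(x, y)] = a["dist"][x] + la + lb + b["dist"][y]
        merged["pairs"] = {**a.get("pairs", {}), **b.get("pairs", {}), **pairs}
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    root = nodes[0]
    taxa = sorted(root["leaves"])
    m = np.zeros((n_taxa, n_taxa))
    for (x, y), v in root["pairs"].items():
        ix, iy = taxa.index(x), taxa.index(y)
        m[ix, iy] = m[iy, ix] = v
    anchor = min(taxa)
    true_splits = set()
    for s in splits:
        if 1 < len(s) < n_taxa - 1:
            side = s if anchor not in s else set(taxa) - s
            true_splits.add(frozenset(side))
    return DistanceMatrix(taxa=taxa, d=m), true_splits


class TestNeighborJoining:
    def test_three_taxon_exact_branches(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_four_taxon_additive_recovery(self):
        # additive matrix from tree ((A:1,B:2):1,(C:3,D:4)): AB=3, AC=5,
        # AD=6, BC=6, BD=7, CD=7; NJ must reproduce topology and path lengths
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        assert frozenset({"C", "D"}) in tree.bipartitions() or \
            frozenset({"A", "B"}) in tree.bipartitions()

        def leaf_depths(node, acc, out):
            for child in node.children:
                if child.is_leaf:
                    out[child.name] = (acc + child.length, node)
                else:
                    leaf_depths(child, acc + child.length, out)
            return out

        # recompute pairwise path lengths on the recovered tree
        def tree_dist(x, y):
            depths = leaf_depths(tree, 0.0, {})
            # lowest common ancestor via leaf sets
            def walk(node, acc):
                below = node.leaves()
                if x in below and y in below:
                    for c in node.children:
                        r = walk(c, acc + c.length) if not c.is_leaf else None
                        if r is not None:
                            return r
                    return acc
                return None
            lca_depth = walk(tree, 0.0)
            return depths[x][0] + depths[y][0] - 2 * lca_depth

        for x, y, want in [("A", "B", 3), ("A", "C", 5), ("A", "D", 6),
                           ("B", "C", 6), ("B", "D", 7), ("C", "D", 7)]:
            assert tree_dist(x, y) == pytest.approx(want, abs=1e-9)

    def test_all_zero_matrix_star(self):
        dm = DistanceMatrix(list("ABCD"), np.zeros((4, 4)))
        tree = neighbor_joining(dm)
        assert sorted(tree.leaves()) == list("ABCD")
        def all_lengths(node):
            for c in node.children:
                yield c.length
                yield from all_lengths(c)
        assert all(l == 0 for l in all_lengths(tree))

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_six_taxon_topology_recovered(self, seed):
        rng = np.random.default_rng(seed)
        dm, true_splits = _random_additive_matrix(6, rng)
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == true_splits

    def test_agrees_with_dendropy_on_additive_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(99)
        dm, true_splits = _random_additive_matrix(7, rng)
        tree = neighbor_joining(dm)
        csv = "," + ",".join(dm.taxa) + "\n"
        for t, row in zip(dm.taxa, dm.d):
            csv += t + "," + ",".join(str(x) for x in row) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        anchor = min(dm.taxa)
        dsplits = set()
        for edge in dtree.preorder_edge_iter():
            leaves = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
            if 1 < len(leaves) < len(dm.taxa) - 1:
                side = leaves if anchor not in leaves else set(dm.taxa) - leaves
                dsplits.add(frozenset(side))
        assert tree.bipartitions() == dsplits


class TestBootstrap:
    def _two_clade_alignment(self, seed=5):
        rng = np.random.default_rng(seed)
        ancestral = "".join(rng.choice(list("ACGT"), size=1500))
        rec = SequenceRecord("root", ancestral)
        newick = "((A:0.01,B:0.01):0.15,(C:0.01,D:0.01):0.15,E:0.02);"
        leaves, _ = make_genome_family(newick, rec, seed=seed)
        return {k: v.seq for k, v in leaves.items()}

    def test_separating_edge_highly_supported(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, n_replicates=200, seed=11)
        splits = tree.bipartitions()
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits
        supports = []
        def collect(node):
            if node.support is not None:
                supports.append(node.support)
            for c in node.children:
                collect(c)
        collect(tree)
        assert max(supports) >= 95

    def test_single_replicate_supports_binary(self):
        aln = self._two_clade_alignment(seed=6)
        tree = bootstrap_support(aln, n_replicates=1, seed=3)
        supports = []
        def collect(node):
            if node.support is not None:
                supports.append(node.support)
            for c in node.children:
                collect(c)
        collect(tree)
        assert set(supports) <= {0, 100}

    def test_same_seed_identical(self):
        aln = self._two_clade_alignment(seed=7)
        t1 = bootstrap_support(aln, n_replicates=50, seed=21)
        t2 = bootstrap_support(aln, n_replicates=50, seed=21)
        assert t1.newick() == t2.newick()


class TestFamilyRecovery:
    def test_nj_recovers_generating_topology(self):
        rng = np.random.default_rng(13)
        root = SequenceRecord("root", "".join(rng.choice(list("ACGT"), size=3000)))
        newick = "((A:0.03,B:0.03):0.05,(C:0.03,D:0.03):0.05,E:0.06);"
        leaves, _ = make_genome_family(newick, root, seed=17)
        dm = distance_matrix({k: v.seq for k, v in leaves.items()}, model="K2P")
        tree = neighbor_joining(dm)
        splits = tree.bipartitions()
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_kmer_distance_orders_relatedness(self):
        rng = np.random.default_rng(14)
        root = SequenceRecord("root", "".join(rng.choice(list("ACGT"), size=5000)))
        newick = "((A:0.01,B:0.01):0.10,C:0.11);"
        leaves, _ = make_genome_family(newick, root, seed=15)
        dm = kmer_distance_matrix({k: v.seq for k, v in leaves.items()})
        i = {t: k for k, t in enumerate(dm.taxa)}
        assert dm.d[i["A"], i["B"]] < dm.d[i["A"], i["C"]]
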