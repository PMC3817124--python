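"""Nei distances, neighbor joining, bootstrap consensus, Newick output."""

import io
import math

import dendropy
import numpy as np
import pytest

from popstruct.data import MISSING
from popstruct.njtree import (
    DistanceMatrix,
    TreeNode,
    allele_frequencies,
    bipartitions,
    bootstrap_consensus,
    consensus_tree,
    nei_distance,
    nei_distance_matrix,
    neighbor_joining,
    to_newick,
    write_newick,
)
from popstruct.simulate import SimulationConfig, simulate_subpopulations

from conftest import toy_matrix


def path_distances(newick: str, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths via dendropy (independent of our tree code)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestAlleleFrequencies:
    def test_simple_frequency(self):
        gm = toy_matrix([[0], [1], [2]])
        aft = allele_frequencies(gm, {"S1": "P", "S2": "P", "S3": "P"})
        assert aft.freq[0, 0] == pytest.approx(0.5)

    def test_all_missing_group_is_nan(self):
        gm = toy_matrix([[MISSING], [1]])
        aft = allele_frequencies(gm, {"S1": "P", "S2": "Q"})
        assert np.isnan(aft.freq[list(aft.populations).index("P"), 0])

    def test_large_sample_matches_generating_frequency(self):
        cfg = SimulationConfig(
            n_subpops=1, n_per_subpop=10000, n_loci=30, drift_f=0.0, seed=30
        )
        gm, truth = simulate_subpopulations(cfg)
        aft = allele_frequencies(gm, truth.membership)
        assert np.allclose(aft.freq[0], truth.true_freqs[0], atol=0.01)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        x = np.array([0.2, 0.5, 0.9])
        assert nei_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_single_locus_worked_value(self):
        assert nei_distance(np.array([0.9]), np.array([0.1])) == pytest.approx(
            math.log(0.82 / 0.18), abs=1e-10
        )

    def test_fixed_difference_clamped(self):
        assert nei_distance(np.array([1.0]), np.array([0.0])) == 10.0

    def test_nan_loci_excluded(self):
        x = np.array([0.9, np.nan])
        y = np.array([0.1, 0.5])
        assert nei_distance(x, y) == pytest.approx(math.log(0.82 / 0.18))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        got = path_distances(to_newick(tree), ["A", "B", "C"])
        assert np.allclose(got, d, atol=1e-9)

    def test_four_taxon_worked_example(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        # topology AB|CD with exact branch lengths reproduces the input
        assert frozenset(["A", "B"]) in bipartitions(tree) or frozenset(
            ["C", "D"]
        ) in bipartitions(tree)
        got = path_distances(to_newick(tree), ["A", "B", "C", "D"])
        assert np.allclose(got, d, atol=1e-9)

    def test_fewer_than_three_labels_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_recovers_random_additive_trees(self):
        """NJ is consistent on additive distances (100 random trees)."""
        rng = np.random.default_rng(42)
        for rep in range(100):
            n = int(rng.integers(6, 11))
            labels = [f"T{i}" for i in range(n)]
            # random binary tree by sequential leaf attachment
            newick = _random_tree_newick(labels, rng)
            ref = dendropy.Tree.get(data=newick, schema="newick")
            pdm = ref.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in ref.taxon_namespace}
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.patristic_distance(
                        taxa[labels[i]], taxa[labels[j]]
                    )
            tree = neighbor_joining(DistanceMatrix(labels, d))
            got = path_distances(to_newick(tree), labels)
            assert np.allclose(got, d, atol=1e-8), f"replicate {rep}"


def _random_tree_newick(labels, rng) -> str:
    """Random additive tree with branch lengths in [0.1, 1]."""
    nodes = [f"{l}:{rng.uniform(0.1, 1):.6f}" for l in labels[:3]]
    tree = f"({nodes[0]},{nodes[1]},{nodes[2]})"
    parts = [labels[0], labels[1], labels[2]]
    for l in labels[3:]:
        # attach to a random existing leaf by splitting its branch
        target = parts[int(rng.integers(len(parts)))]
        old = f"{target}:"
        # replace first occurrence of "target:" with a new cherry
        b1, b2, b3 = rng.uniform(0.1, 1, 3)
        tree = tree.replace(
            f"{target}:", f"({target}:{b1:.6f},{l}:{b2:.6f}):", 1
        )
        parts.append(l)
    return tree + ";"


class TestConsensus:
    def _trees(self):
        t_ab = neighbor_joining(
            DistanceMatrix(
                ["A", "B", "C", "D"],
                np.array([[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float),
            )
        )
        t_ac = neighbor_joining(
            DistanceMatrix(
                ["A", "B", "C", "D"],
                np.array([[0, 5, 2, 5], [5, 0, 5, 2], [2, 5, 0, 5], [5, 2, 5, 0]], float),
            )
        )
        return t_ab, t_ac

    def test_single_replicate_full_support(self):
        t_ab, _ = self._trees()
        cons = consensus_tree([t_ab])
        sups = [
            n.support
            for n, _ in _walk_internal(cons)
            if n.support is not None
        ]
        assert sups and all(s == 100 for s in sups)

    def test_majority_bipartition_wins(self):
        t_ab, t_ac = self._trees()
        cons = consensus_tree([t_ab, t_ab, t_ac])
        assert frozenset(["C", "D"]) in bipartitions(cons)

    def test_supports_are_percentages(self):
        t_ab, t_ac = self._trees()
        cons = consensus_tree([t_ab, t_ab, t_ab, t_ac])
        clades = {
            frozenset(n.leaves()): n.support
            for n, _ in _walk_internal(cons)
            if n.support is not None
        }
        assert clades[frozenset(["C", "D"])] == 75

    def test_bootstrap_recovers_hierarchical_pairs(self):
        """Two drifted pairs of subpopulations appear with high support."""
        rng = np.random.default_rng(31)
        p = rng.uniform(0.1, 0.5, 3000)
        # two clades: (P1,P2) and (P3,P4), within-pair frequencies close
        def drift(base, f):
            a = base * (1 - f) / f
            b = (1 - base) * (1 - f) / f
            return np.clip(rng.beta(a, b), 0.01, 0.99)

        clade1 = drift(p, 0.05)
        clade2 = drift(p, 0.05)
        freqs = {
            "P1": drift(clade1, 0.01),
            "P2": drift(clade1, 0.01),
            "P3": drift(clade2, 0.01),
            "P4": drift(clade2, 0.01),
        }
        calls = np.vstack(
            [rng.binomial(2, freqs[pop], size=(30, 3000)) for pop in freqs]
        ).astype(np.int16)
        gm = toy_matrix(calls, sample_ids=[f"S{i}" for i in range(120)],
                        rs_ids=[f"rs{j}" for j in range(3000)])
        grouping = {f"S{i}": f"P{i // 30 + 1}" for i in range(120)}
        cons = bootstrap_consensus(gm, grouping, n_replicates=100, seed=7)
        clades = {
            frozenset(n.leaves()): n.support
            for n, _ in _walk_internal(cons)
            if n.support is not None
        }
        pair = clades.get(frozenset(["P1", "P2"])) or clades.get(
            frozenset(["P3", "P4"])
        )
        assert pair is not None and pair >= 95

    def test_bootstrap_deterministic(self):
        cfg = SimulationConfig(
            n_subpops=4, n_per_subpop=20, n_loci=500, drift_f=0.05, seed=32
        )
        gm, truth = simulate_subpopulations(cfg)
        t1 = bootstrap_consensus(gm, truth.membership, n_replicates=20, seed=5)
        t2 = bootstrap_consensus(gm, truth.membership, n_replicates=20, seed=5)
        assert to_newick(t1) == to_newick(t2)

    def test_outgroup_rooting(self):
        cfg = SimulationConfig(
            n_subpops=4, n_per_subpop=20, n_loci=500, drift_f=0.05, seed=33
        )
        gm, truth = simulate_subpopulations(cfg)
        cons = bootstrap_consensus(
            gm, truth.membership, n_replicates=10, seed=5, outgroup="SP1"
        )
        first_children = [c.label for c, _ in cons.children]
        assert "SP1" in first_children

    def test_missing_outgroup_error(self):
        cfg = SimulationConfig(n_subpops=3, n_per_subpop=10, n_loci=100, seed=34)
        gm, truth = simulate_subpopulations(cfg)
        with pytest.raises(ValueError):
            bootstrap_consensus(gm, truth.membership, 5, 0, outgroup="Pygmy")


def _walk_internal(tree):
    stack = [(tree, None)]
    while stack:
        node, length = stack.pop()
        yield node, length
        for child, l in node.children:
            if not child.is_leaf():
                stack.append((child, l))


class TestNewick:
    def test_star_round_trip(self):
        star = TreeNode(
            children=[
                (TreeNode(label="A"), 1.0),
                (TreeNode(label="B"), 1.0),
                (TreeNode(label="C"), 1.0),
            ]
        )
        text = to_newick(star)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == ["A", "B", "C"]

    def test_labels_with_metacharacters_quoted(self):
        star = TreeNode(
            children=[
                (TreeNode(label="Pop (C)"), 1.0),
                (TreeNode(label="B"), 1.0),
                (TreeNode(label="C"), 1.0),
            ]
        )
        text = to_newick(star)
        assert "'Pop (C)'" in text
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert "Pop (C)" in [t.label for t in parsed.taxon_namespace]

    def test_supports_readable_by_viewer(self):
        inner = TreeNode(
            support=87,
            children=[(TreeNode(label="A"), 1.0), (TreeNode(label="B"), 1.0)],
        )
        root = TreeNode(
            children=[(inner, 0.5), (TreeNode(label="C"), 1.0), (TreeNode(label="D"), 1.0)]
        )
        text = to_newick(root)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        internal_labels = [
            n.label for n in parsed.preorder_node_iter() if not n.is_leaf()
        ]
        assert "87" in internal_labels

    def test_write_to_buffer(self):
        buf = io.StringIO()
        write_newick(TreeNode(children=[(TreeNode(label="A"), 1.0),
                                        (TreeNode(label="B"), 1.0),
                                        (TreeNode(label="C"), 1.0)]), buf)
        assert buf.getvalue().endswith(";\n")
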