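import math

import dendropy
import numpy as np
import pytest

from bandpop.distances import (
    DistanceMatrix,
    nei_distance,
    nei_identity,
    pairwise_matrix,
    read_distance_matrix,
    upgma,
    write_distance_matrix,
)
from bandpop.io_core import MISSING
from bandpop.synthetic_data import GroupSpec, SimulationConfig, simulate


def brute_force_nei(x, y):
    """Direct transcription of the definition, looping over loci and states."""
    jxy = jx = jy = 0.0
    L = len(x)
    for xl, yl in zip(x, y):
        for state_x, state_y in ((xl, yl), (1 - xl, 1 - yl)):
            jxy += state_x * state_y / L
        jx += (xl**2 + (1 - xl) ** 2) / L
        jy += (yl**2 + (1 - yl) ** 2) / L
    return -math.log(jxy / math.sqrt(jx * jy))


class TestNeiDistance:
    def test_identical_profiles_distance_zero(self):
        x = np.array([0.2, 0.9, 0.5])
        assert nei_identity(x, x) == pytest.approx(1.0)
        assert nei_distance(x, x) == 0.0

    def test_symmetry_on_binary_vectors(self):
        x = np.array([1, 1, 0, 0], dtype=float)
        y = np.array([1, 0, 1, 0], dtype=float)
        d = nei_distance(x, y)
        assert d > 0
        assert d == pytest.approx(nei_distance(y, x))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        freqs = rng.random((4, 30))
        for i in range(4):
            for j in range(i + 1, 4):
                assert nei_distance(freqs[i], freqs[j]) == pytest.approx(
                    brute_force_nei(freqs[i], freqs[j]), abs=1e-12
                )

    def test_band_presence_only_variant(self):
        x = np.array([1, 1, 1, 0], dtype=float)
        y = np.array([1, 0, 0, 0], dtype=float)
        both = nei_distance(x, y, both_states=True)
        # presence-only: Jxy=1/4, Jx=3/4, Jy=1/4 -> I_N = 1/sqrt(3)
        presence = nei_distance(x, y, both_states=False)
        assert presence == pytest.approx(-math.log(1 / math.sqrt(3)))
        assert presence != pytest.approx(both)

    def test_undefined_identity_raises(self):
        with pytest.raises(ValueError, match="zero homozygosity"):
            nei_identity(np.array([0.0, 0.0]), np.array([1.0, 0.0]),
                         both_states=False)
        with pytest.raises(ValueError, match="undefined"):
            nei_distance(np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                         both_states=False)


class TestPairwiseMatrix:
    def test_identical_rows_zero_matrix(self, two_block_matrix):
        m = two_block_matrix
        m.calls[1] = m.calls[0]
        d = pairwise_matrix(m, metric="squared-euclidean")
        assert d.values[0, 1] == 0.0

    def test_squared_euclidean_is_mismatch_count(self, tiny_matrix):
        d = pairwise_matrix(tiny_matrix, metric="squared-euclidean")
        # rows (1,0,1),(0,0,1) pattern: count positions that differ
        brute = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                brute[i, j] = np.sum(tiny_matrix.calls[i] != tiny_matrix.calls[j])
        assert np.allclose(d.values, brute)

    def test_random_matrix_against_loop_oracle(self):
        rng = np.random.default_rng(23)
        cfg = SimulationConfig(
            n_clusters=1,
            groups=[GroupSpec("g", 10, (1.0,))],
            primers=[("P1", 50)],
            seed=23,
        )
        m, _, _ = simulate(cfg)
        d = pairwise_matrix(m, metric="squared-euclidean")
        for i in range(10):
            for j in range(10):
                assert d.values[i, j] == sum(
                    (int(a) - int(b)) ** 2 for a, b in zip(m.calls[i], m.calls[j])
                )

    def test_missing_calls_use_pairwise_complete_rescaled(self, tiny_matrix):
        tiny_matrix.calls[0, 0] = MISSING
        d = pairwise_matrix(tiny_matrix, metric="squared-euclidean")
        # a1 vs a2 over complete loci 2..5 scaled by 5/4
        x, y = tiny_matrix.calls[0, 1:], tiny_matrix.calls[1, 1:]
        expected = np.sum((x - y) ** 2) * 5 / 4
        assert d.values[0, 1] == pytest.approx(expected)

    def test_population_level_uses_group_frequencies(self, tiny_matrix, tiny_pops):
        d = pairwise_matrix(
            tiny_matrix, level="populations", metric="nei", pops=tiny_pops
        )
        assert d.labels == ["g1", "g2"]
        f1 = tiny_matrix.calls[:2].mean(axis=0)
        f2 = tiny_matrix.calls[2:].mean(axis=0)
        assert d.values[0, 1] == pytest.approx(nei_distance(f1, f2))

    def test_round_trip_tsv(self, tiny_matrix, tmp_path):
        d = pairwise_matrix(tiny_matrix, metric="nei")
        p = tmp_path / "d.tsv"
        write_distance_matrix(d, p)
        again = read_distance_matrix(p)
        assert again.labels == d.labels
        assert np.allclose(again.values, d.values)


class TestUpgma:
    def test_two_leaves_split_distance(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma(d)
        depths = tree.leaf_depths()
        assert depths == {"A": pytest.approx(1.5), "B": pytest.approx(1.5)}

    def test_three_leaf_hand_computation(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6 -> ((A:1,B:1):2,C:3)
        vals = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
        tree = upgma(DistanceMatrix(["A", "B", "C"], vals))
        newick = tree.to_newick()
        t = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        dist = {l.taxon.label: l.distance_from_root() for l in t.leaf_node_iter()}
        assert dist == {
            "A": pytest.approx(3.0),
            "B": pytest.approx(3.0),
            "C": pytest.approx(3.0),
        }
        ab = t.mrca(taxon_labels=["A", "B"])
        assert ab.distance_from_root() == pytest.approx(2.0)

    def test_ultrametric_on_simulated_panel(self, two_block_matrix):
        d = pairwise_matrix(two_block_matrix, metric="nei")
        tree = upgma(d)
        assert tree.is_ultrametric(tol=1e-9)

    def test_two_block_structure_bipartitioned(self, two_block_matrix):
        d = pairwise_matrix(two_block_matrix, metric="squared-euclidean")
        tree = upgma(d)
        # the root's two children must separate the x- and y-blocks exactly
        sides = [
            {leaf.label for leaf in child.leaves()} for child in tree.root.children
        ]
        assert {frozenset(s) for s in sides} == {
            frozenset({"x0", "x1", "x2", "x3"}),
            frozenset({"y0", "y1", "y2", "y3"}),
        }

    def test_clones_merge_first(self):
        cfg = SimulationConfig(
            n_clusters=2,
            groups=[
                GroupSpec("c", 3, (1.0, 0.0), clonal=True),
                GroupSpec("o", 3, (0.0, 1.0)),
            ],
            primers=[("P1", 60)],
            divergence=0.4,
            noise_rate=0.0,
            seed=31,
        )
        m, _, _ = simulate(cfg)
        tree = upgma(pairwise_matrix(m, metric="nei"))
        clone_mrca_children = None
        depths = tree.leaf_depths()
        assert all(depths[f"c{i}"] == pytest.approx(depths["c1"]) for i in (2, 3))
        # identical clones sit at height 0 of their common ancestor
        for child in tree.root.children:
            labels = {l.label for l in child.leaves()}
            if {"c1", "c2", "c3"} <= labels:
                clone_mrca_children = labels
        assert clone_mrca_children is not None

    def test_newick_parses_with_branch_lengths(self, tiny_matrix):
        tree = upgma(pairwise_matrix(tiny_matrix, metric="nei"))
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(
            tiny_matrix.accession_ids
        )
        root_dists = [l.distance_from_root() for l in t.leaf_node_iter()]
        assert max(root_dists) - min(root_dists) < 1e-9

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
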