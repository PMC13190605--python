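"""Neighbor joining, clade assignment, summaries and ordination."""

import random

import numpy as np
import pytest
from skbio import TreeNode
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from pily_profiler.align import DistanceMatrix
from pily_profiler.motifs import FeatureProfile
from pily_profiler.phylo import (assign_clades, clade_summary, nj_tree,
                                 pca_identity)


def random_additive_tree(n_taxa, rng):
    """Random topology with branch lengths on a grid; returns (tree, ids)."""
    lengths = [0.5, 1.0, 1.5, 2.0, 3.0]
    ids = [chr(ord("A") + i) for i in range(n_taxa)]
    nodes = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        a, b = nodes[j], nodes[i]
        a.length = rng.choice(lengths)
        b.length = rng.choice(lengths)
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    for node in nodes:
        node.length = rng.choice(lengths)
    return TreeNode(children=nodes), ids


def to_identity_matrix(tree, ids):
    dm = tree.tip_tip_distances()
    n = len(ids)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                M[i, j] = dm[ids[i], ids[j]]
    return DistanceMatrix(ids=ids, identity=100.0 - M)


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_matrix_recovery(self, n_taxa):
        """NJ must reproduce the generating tree's tip-to-tip distances
        exactly for additive inputs (topology + branch lengths)."""
        rng = random.Random(2024)
        for _ in range(25):
            true_tree, ids = random_additive_tree(n_taxa, rng)
            dm = to_identity_matrix(true_tree, ids)
            recovered = nj_tree(dm)
            want = true_tree.tip_tip_distances()
            got = recovered.tip_tip_distances()
            for i in ids:
                for j in ids:
                    if i != j:
                        assert got[i, j] == pytest.approx(want[i, j],
                                                          abs=1e-9)

    def test_four_taxon_known_tree(self):
        # ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        M = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        dm = DistanceMatrix(ids=list("ABCD"), identity=100.0 - M)
        tree = nj_tree(dm)
        got = tree.tip_tip_distances()
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i != j:
                    assert got[x, y] == pytest.approx(M[i, j], abs=1e-9)
        # A and B are sisters
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_identical_sequences_zero_length_sisters(self):
        M = np.array([[0, 0, 50, 50],
                      [0, 0, 50, 50],
                      [50, 50, 0, 10],
                      [50, 50, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=list("ABCD"),
                                      identity=100.0 - M))
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}
        for tip in ab.children:
            assert tip.length == pytest.approx(0.0, abs=1e-12)

    def test_leafset_conserved_and_topology_matches_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 7
            M = rng.uniform(10, 90, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            ids = [f"t{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(ids=ids, identity=100.0 - M))
            assert {t.name for t in mine.tips()} == set(ids)
            ref = skbio_nj(SkbioDM(M, ids))
            assert mine.compare_rfd(ref) == 0.0

    def test_too_few_taxa_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"],
                                   identity=np.full((2, 2), 100.0)))


def make_profile(pid, domains=(), n_cys=10, length=100):
    flags = {"vWFA": False, "DUF4114": False, "beta_propeller": True}
    for d in domains:
        flags[d] = True
    return FeatureProfile(protein_id=pid, length=length, n_cys=n_cys,
                          cys_positions=list(range(1, n_cys + 1)),
                          hits={}, domain_flags=flags)


@pytest.fixture()
def two_clade_setup():
    ids = ["x1", "x2", "q", "y1", "y2"]
    # q lies between the two clade-1.1 exemplars, inside their subtree
    M = np.array([
        [100, 85, 92, 20, 20],
        [85, 100, 91, 20, 20],
        [92, 91, 100, 21, 20],
        [20, 20, 21, 100, 91],
        [20, 20, 20, 91, 100]], dtype=float)
    matrix = DistanceMatrix(ids=ids, identity=M)
    tree = nj_tree(matrix)
    exemplars = {"1.1": ["x1", "x2"], "1.3": ["y1", "y2"]}
    return tree, matrix, exemplars


class TestAssignClades:
    def test_subtree_containment(self, two_clade_setup):
        tree, matrix, exemplars = two_clade_setup
        profiles = [make_profile("q", domains=["DUF4114"])]
        out = {a.protein_id: a for a in
               assign_clades(tree, profiles, exemplars, matrix)}
        assert out["q"].clade == "1.1"
        assert out["q"].via == "subtree"
        assert out["q"].domain_consistent

    def test_exemplar_assigned_to_own_clade_distance_zero(self,
                                                          two_clade_setup):
        tree, matrix, exemplars = two_clade_setup
        out = {a.protein_id: a for a in
               assign_clades(tree, [], exemplars, matrix)}
        assert out["y1"].clade == "1.3"
        assert out["y1"].nearest_distance == 0.0

    def test_inconsistent_domain_flagged(self, two_clade_setup):
        tree, matrix, exemplars = two_clade_setup
        # DUF4114-bearing query inside the vWFA clade's subtree
        exemplars = {"1.1": ["y1", "y2"], "1.3": ["x1", "x2"]}
        profiles = [make_profile("q", domains=["DUF4114"])]
        out = {a.protein_id: a for a in
               assign_clades(tree, profiles, exemplars, matrix)}
        assert out["q"].clade == "1.3"
        assert not out["q"].domain_consistent

    def test_no_exemplars_error(self, two_clade_setup):
        tree, matrix, _ = two_clade_setup
        with pytest.raises(ValueError):
            assign_clades(tree, [], {}, matrix)

    def test_input_order_does_not_change_assignments(self, small_proteome):
        from pily_profiler.align import identity_matrix
        records, manifest = small_proteome
        sub = [r for r in records if r.id.startswith(("1.1_", "1.3_",
                                                      "1.4a_"))]
        exemplars = {r.ref_clade: [r.id] for r in sub if r.ref_clade}
        m1 = identity_matrix(sub)
        a1 = {a.protein_id: a.clade for a in
              assign_clades(nj_tree(m1), [], exemplars, m1)}
        rev = sub[::-1]
        m2 = identity_matrix(rev)
        a2 = {a.protein_id: a.clade for a in
              assign_clades(nj_tree(m2), [], exemplars, m2)}
        assert a1 == a2
        for pid, clade in a1.items():
            assert clade == manifest["proteins"][pid]["clade"]


class TestCladeSummary:
    def test_medians(self):
        from pily_profiler.phylo import CladeAssignment
        profiles = [make_profile(f"p{i}", n_cys=c, length=100 + i)
                    for i, c in enumerate([22, 23, 24, 17, 18])]
        assignments = [
            CladeAssignment(p.protein_id, "1.1" if i < 3 else "1.4c",
                            "e", 0.0, "subtree")
            for i, p in enumerate(profiles)]
        table = clade_summary(assignments, profiles).set_index("clade")
        assert table.loc["1.1", "n_cys_median"] == 23
        assert table.loc["1.4c", "n_cys_median"] == 17.5  # even count
        assert table.loc["1.1", "n"] == 3


class TestPca:
    def test_group_separation_on_pc1(self):
        ids = [f"g{i}" for i in range(6)]
        M = np.full((6, 6), 20.0)
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    M[i, j] = 90.0
        np.fill_diagonal(M, 100.0)
        scores, explained = pca_identity(
            DistanceMatrix(ids=ids, identity=M), k=2)
        g1, g2 = scores[:3, 0], scores[3:, 0]
        gap = abs(g1.mean() - g2.mean())
        spread = max(np.ptp(g1), np.ptp(g2))
        assert gap > spread
        assert 0 < explained.sum() <= 1.0 + 1e-12

    def test_identical_rows_collapse_to_origin(self):
        M = np.full((4, 4), 100.0)
        scores, _ = pca_identity(DistanceMatrix(ids=list("abcd"),
                                                identity=M), k=2)
        assert np.allclose(scores, 0.0)

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(12)
        M = rng.uniform(20, 90, size=(5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 100.0)
        dm = DistanceMatrix(ids=[f"r{i}" for i in range(5)], identity=M)
        scores, explained = pca_identity(dm, k=2)
        X = M - M.mean(axis=0, keepdims=True)
        evals, evecs = np.linalg.eigh(X.T @ X / 1.0)
        order = np.argsort(evals)[::-1]
        for comp in range(2):
            v = evecs[:, order[comp]]
            proj = X @ v
            # same axis up to sign
            assert np.allclose(np.abs(proj), np.abs(scores[:, comp]),
                               atol=1e-8)
        assert np.allclose(explained,
                           evals[order][:2] / evals.sum(), atol=1e-9)

    def test_k_too_large_error(self):
        M = np.full((3, 3), 100.0)
        with pytest.raises(ValueError):
            pca_identity(DistanceMatrix(ids=list("abc"), identity=M), k=3)
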