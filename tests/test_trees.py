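"""NJ, UPGMA, bootstrap supports, and outgroup rooting."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from barcodelim.distances import DistanceMatrix, distance_matrix
from barcodelim.seqio import Alignment
from barcodelim.simulate import SimulationConfig, simulate
from barcodelim.trees import (
    TreeInferenceConfig,
    bootstrap_supports,
    internal_split_keys,
    is_ultrametric,
    neighbor_joining,
    node_heights,
    root_with_outgroup,
    upgma,
)
from conftest import random_additive_matrix


def path_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(tax)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            out[(a, b)] = pdm.distance(tax[a], tax[b])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        dm = DistanceMatrix(ids=["A", "B", "C"], d=D, defined=np.ones((3, 3), bool))
        tree = neighbor_joining(dm)
        dists = path_distances(tree)
        assert dists[("A", "B")] == pytest.approx(0.3)
        assert dists[("A", "C")] == pytest.approx(0.5)
        assert dists[("B", "C")] == pytest.approx(0.6)

    def test_exact_on_known_four_taxon_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive matrix -> exact inversion
        D = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(ids=list("ABCD"), d=D, defined=np.ones((4, 4), bool))
        tree = neighbor_joining(dm)
        dists = path_distances(tree)
        for (a, b), want in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
            ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4,
        }.items():
            assert dists[(a, b)] == pytest.approx(want, abs=1e-12)
        keys = set(internal_split_keys(tree).values())
        assert frozenset({"C", "D"}) in keys or frozenset({"A", "B"}) in keys

    def test_consistency_on_random_additive_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            dm, _ = random_additive_matrix(n, rng)
            tree = neighbor_joining(dm)
            dists = path_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = sorted((dm.ids[i], dm.ids[j]))
                    assert dists[(a, b)] == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_duplicate_haplotypes_joined_first(self):
        # two identical rows: brute-force Q check says they pair with length 0
        # (dyadic values so the 4-taxon Q tie is exact and broken by index)
        D = np.array(
            [
                [0.0, 0.0, 1.0, 1.0],
                [0.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.5],
                [1.0, 1.0, 0.5, 0.0],
            ]
        )
        n = 4
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        assert divmod(int(np.argmin(Q)), n) == (0, 1)  # brute-force Q minimum
        dm = DistanceMatrix(ids=list("wxyz"), d=D, defined=np.ones((4, 4), bool))
        tree = neighbor_joining(dm)
        assert path_distances(tree)[("w", "x")] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_entries_rejected(self):
        defined = np.ones((3, 3), bool)
        defined[0, 1] = defined[1, 0] = False
        dm = DistanceMatrix(ids=list("abc"), d=np.zeros((3, 3)), defined=defined)
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(dm)


class TestUpgma:
    def test_two_taxa_root_at_half_distance(self):
        D = np.array([[0.0, 0.1], [0.1, 0.0]])
        dm = DistanceMatrix(ids=["a", "b"], d=D, defined=np.ones((2, 2), bool))
        tree = upgma(dm)
        heights = node_heights(tree)
        assert heights[tree.seed_node] == pytest.approx(0.05)

    def test_exact_on_ultrametric_input(self):
        # ((a:1,b:1):2,(c:2,d:2):1) heights: ab=1, cd=2, root=3
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 4],
                [6, 6, 4, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(ids=list("abcd"), d=D, defined=np.ones((4, 4), bool))
        tree = upgma(dm)
        hs = sorted(
            node_heights(tree)[n] for n in tree.preorder_node_iter() if not n.is_leaf()
        )
        assert hs == pytest.approx([1.0, 2.0, 3.0])

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 8
            M = rng.uniform(0.1, 1.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            dm = DistanceMatrix(ids=[f"t{i}" for i in range(n)], d=D, defined=np.ones((n, n), bool))
            tree = upgma(dm)
            ours = sorted(
                node_heights(tree)[nd] for nd in tree.preorder_node_iter() if not nd.is_leaf()
            )
            Z = sch.linkage(squareform(D, checks=False), method="average")
            theirs = sorted(Z[:, 2] / 2.0)
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_always_ultrametric(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            M = rng.uniform(0.05, 1.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            dm = DistanceMatrix(ids=[f"t{i}" for i in range(n)], d=D, defined=np.ones((n, n), bool))
            assert is_ultrametric(upgma(dm), tol=1e-9)


def _clean_two_clade_alignment(seed=0):
    cfg = SimulationConfig(
        n_species=2,
        specimens_per_species=(5, 5),
        references_per_species=0,
        outgroup_tips=0,
        outgroup_specimens=0,
        delta_intra=0.003,
        delta_inter=0.12,
        n_discordant=0,
        n_synonym_pairs=0,
        locus_names=("L",),
        locus_rate_multipliers=(1.0,),
        locus_lengths=(800,),
        seed=seed,
    )
    return simulate(cfg)


class TestBootstrap:
    def test_well_separated_clades_get_high_support(self):
        ds = _clean_two_clade_alignment()
        aln = ds.alignments[0]
        tree = bootstrap_supports(aln, TreeInferenceConfig(n_bootstrap=100, seed=1))
        truth = ds.truth.species_by_locus[0]
        clade_a = frozenset(s for s, sp in truth.items() if sp == "Species_01")
        keys = internal_split_keys(tree)
        supports = {
            keys[n]: float(n.label) for n in keys if n.label is not None
        }
        match = [v for k, v in supports.items() if k in (clade_a, frozenset(truth) - clade_a)]
        assert match and all(v >= 95 for v in match)

    def test_identical_sequences_have_no_supports(self):
        aln = Alignment(ids=list("abcd"), sequences=["ACGTACGT"] * 4)
        tree = bootstrap_supports(aln, TreeInferenceConfig(n_bootstrap=50, seed=0))
        assert all(n.label is None for n in tree.preorder_node_iter())

    def test_fixed_seed_reproducible(self):
        aln = _clean_two_clade_alignment().alignments[0]
        cfg = TreeInferenceConfig(n_bootstrap=30, seed=7)
        t1 = bootstrap_supports(aln, cfg)
        t2 = bootstrap_supports(aln, cfg)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_invariant_to_sequence_order(self):
        ds = _clean_two_clade_alignment(seed=4)
        aln = ds.alignments[0]
        perm = list(reversed(aln.ids))
        aln2 = aln.subset(perm)
        cfg = TreeInferenceConfig(n_bootstrap=40, seed=2)

        def support_map(tree):
            keys = internal_split_keys(tree)
            return {keys[n]: n.label for n in keys if n.label is not None}

        s1 = support_map(bootstrap_supports(aln, cfg))
        s2 = support_map(bootstrap_supports(aln2, cfg))
        shared = set(s1) & set(s2)
        assert shared
        assert all(s1[k] == s2[k] for k in shared)

    def test_zero_bootstrap_gives_point_tree(self):
        aln = _clean_two_clade_alignment().alignments[0]
        tree = bootstrap_supports(aln, TreeInferenceConfig(n_bootstrap=0, seed=0))
        assert all(n.label is None for n in tree.preorder_node_iter())


class TestRooting:
    def test_single_outgroup_bisects_pendant_edge(self):
        D = np.array(
            [
                [0, 0.2, 0.5, 0.9],
                [0.2, 0, 0.5, 0.9],
                [0.5, 0.5, 0, 0.8],
                [0.9, 0.9, 0.8, 0],
            ]
        )
        dm = DistanceMatrix(ids=["A", "B", "C", "O"], d=D, defined=np.ones((4, 4), bool))
        tree = root_with_outgroup(neighbor_joining(dm), ["O"])
        assert tree.is_rooted
        children = tree.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert frozenset({"O"}) in sides

    def test_outgroup_cherry_rooted_on_stem(self):
        ds = SimulationConfig(
            n_species=2,
            specimens_per_species=(3, 3),
            references_per_species=0,
            outgroup_tips=2,
            outgroup_specimens=0,
            delta_intra=0.003,
            delta_inter=0.08,
            n_discordant=0,
            n_synonym_pairs=0,
            locus_names=("L",),
            locus_rate_multipliers=(1.0,),
            locus_lengths=(600,),
            seed=2,
        )
        data = simulate(ds)
        aln = data.alignments[0]
        og = aln.ids_with_role("outgroup")
        tree = root_with_outgroup(neighbor_joining(distance_matrix(aln)), og)
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in tree.seed_node.child_nodes()
        ]
        assert frozenset(og) in sides

    def test_non_monophyletic_outgroup_errors(self):
        # outgroup {A, C} split across the additive tree ((A,B),(C,D))
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(ids=list("ABCD"), d=D, defined=np.ones((4, 4), bool))
        tree = neighbor_joining(dm)
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(tree, ["A", "C"])
        rooted = root_with_outgroup(tree, ["A", "C"], fallback_midpoint=True)
        assert rooted.is_rooted
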