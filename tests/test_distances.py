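"""K2P distances: hand cases, brute-force agreement, deletion modes, summaries."""

import math

import numpy as np
import pytest

from barcodelim.distances import (
    complete_deletion_columns,
    distance_matrix,
    divergence_summary,
    k2p,
)
from barcodelim.seqio import Alignment
from barcodelim.simulate import SimulationConfig, simulate

TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def brute_force_k2p(a: str, b: str):
    """Independent character-by-character K2P (same formula, naive counting)."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                if (x, y) in TS:
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        return None
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


class TestK2P:
    def test_identical_sequences(self):
        e = k2p("ACGTACGTAC", "ACGTACGTAC")
        assert e.defined and e.d == 0.0 and e.p_transitions == 0.0

    def test_hand_case_one_transition_one_transversion(self):
        # 10 sites, P = Q = 0.1: d = -1/2 ln(0.7 * sqrt(0.8)) = 0.2341235
        e = k2p("AAAAAAAAGC", "AAAAAAAAAA")
        assert e.p_transitions == pytest.approx(0.1)
        assert e.q_transversions == pytest.approx(0.1)
        assert e.d == pytest.approx(0.2341235, abs=1e-5)

    def test_saturated_pair_is_undefined_not_nan(self):
        # P = 0.5, Q = 0 violates the log domain
        e = k2p("AAGG", "GGAA")
        assert not e.defined
        assert np.isfinite(e.d)

    def test_no_comparable_sites(self):
        e = k2p("NN--", "AAAA")
        assert not e.defined and e.n_sites_compared == 0

    def test_monotone_in_p_and_q(self):
        grid = np.linspace(0.0, 0.2, 11)
        for q in grid:
            ds = []
            for p in grid:
                w1, w2 = 1 - 2 * p - q, 1 - 2 * q
                if w1 > 0 and w2 > 0:
                    ds.append(-0.5 * math.log(w1 * math.sqrt(w2)))
            assert all(a <= b + 1e-12 for a, b in zip(ds, ds[1:]))

    def test_close_to_jukes_cantor_at_ts_tv_one_to_two(self):
        # transitions:transversions generated 1:2 = the JC expectation
        for total in np.linspace(0.005, 0.09, 10):
            p, q = total / 3, 2 * total / 3
            d_k2p = -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
            d_jc = -0.75 * math.log(1 - 4 * total / 3)
            if d_k2p <= 0.1:
                assert d_k2p == pytest.approx(d_jc, rel=0.05)


class TestDistanceMatrix:
    def test_identical_sequences_all_zero(self):
        aln = Alignment(ids=list("abc"), sequences=["ACGTAC"] * 3)
        dm = distance_matrix(aln)
        assert np.all(dm.d == 0) and dm.defined.all()

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(7)
        chars = np.array(list("ACGTN-"))
        for _ in range(40):
            n = rng.integers(2, 7)
            L = rng.integers(20, 60)
            seqs = ["".join(rng.choice(chars, size=L, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06])) for _ in range(n)]
            aln = Alignment(ids=[f"s{i}" for i in range(n)], sequences=seqs)
            dm = distance_matrix(aln, "pairwise")
            for i in range(n):
                for j in range(i + 1, n):
                    want = brute_force_k2p(seqs[i], seqs[j])
                    if want is None:
                        assert not dm.defined[i, j]
                    else:
                        assert dm.d[i, j] == pytest.approx(want, abs=1e-10)

    def test_complete_deletion_equals_manual_reduction(self):
        aln = Alignment(
            ids=["a", "b"],
            sequences=["ACGTAC-TAC", "ACGTACGTAA"],
        )
        cols = complete_deletion_columns(aln)
        assert len(cols) == 9  # the gap column removed
        dm = distance_matrix(aln, "complete")
        manual = k2p(aln.sequences[0], aln.sequences[1], deletion_columns=cols)
        assert dm.d[0, 1] == pytest.approx(manual.d, abs=1e-12)

    def test_complete_deletion_random_oracle(self):
        rng = np.random.default_rng(11)
        chars = np.array(list("ACGT-"))
        for _ in range(25):
            n = rng.integers(2, 6)
            L = rng.integers(30, 60)
            seqs = ["".join(rng.choice(chars, size=L, p=[0.23, 0.23, 0.23, 0.23, 0.08])) for _ in range(n)]
            aln = Alignment(ids=[f"s{i}" for i in range(n)], sequences=seqs)
            cols = complete_deletion_columns(aln)
            if len(cols) == 0:
                with pytest.raises(ValueError, match="pairwise"):
                    distance_matrix(aln, "complete")
                continue
            dm = distance_matrix(aln, "complete")
            reduced = aln.take_columns(cols)
            dm2 = distance_matrix(reduced, "pairwise")
            np.testing.assert_allclose(dm.d, dm2.d, atol=1e-12)

    def test_all_gap_columns_instructs_pairwise(self):
        aln = Alignment(ids=["a", "b"], sequences=["A-", "-A"])
        with pytest.raises(ValueError, match="pairwise"):
            distance_matrix(aln, "complete")

    def test_exports(self):
        aln = Alignment(ids=["a", "b"], sequences=["ACGT", "ACGA"])
        dm = distance_matrix(aln)
        assert dm.to_phylip().startswith("2\n")
        assert "a\t" in dm.to_tsv()


class TestDivergenceSummary:
    def test_two_clean_groups(self):
        # two groups of identical pairs, cross-distance fixed
        aln = Alignment(
            ids=["a1", "a2", "b1", "b2"],
            sequences=["A" * 40, "A" * 40, "A" * 20 + "G" * 4 + "A" * 16, "A" * 20 + "G" * 4 + "A" * 16],
        )
        dm = distance_matrix(aln)
        s = divergence_summary(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, n_boot=0)
        assert s.mean_within["A"] == 0.0 and s.mean_within["B"] == 0.0
        assert s.mean_between[("A", "B")] > 0.09

    def test_singleton_group_within_mean_is_missing(self):
        aln = Alignment(ids=["a", "b", "c"], sequences=["ACGT" * 5, "ACGA" * 5, "ACGC" * 5])
        dm = distance_matrix(aln)
        s = divergence_summary(dm, {"a": "A", "b": "B", "c": "B"}, n_boot=0)
        assert s.mean_within["A"] is None
        assert s.mean_within["B"] is not None

    def test_simulator_ground_truth_within_means(self):
        cfg = SimulationConfig(
            n_species=9,
            specimens_per_species=tuple([6] * 9),
            references_per_species=0,
            outgroup_tips=0,
            outgroup_specimens=0,
            delta_intra=0.005,
            delta_inter=0.06,
            n_discordant=0,
            n_synonym_pairs=0,
            locus_names=("L",),
            locus_rate_multipliers=(1.0,),
            locus_lengths=(813,),
            seed=3,
        )
        ds = simulate(cfg)
        dm = distance_matrix(ds.alignments[0])
        grouping = ds.truth.species_by_locus[0]
        s = divergence_summary(dm, grouping, n_boot=100, seed=1, alignment=ds.alignments[0])
        within = [v for v in s.mean_within.values() if v is not None]
        assert np.mean(within) == pytest.approx(0.005, abs=0.002)
        assert s.standard_error is not None and s.standard_error >= 0
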