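"""Reference curation, tree-based assignment, and the consensus decision rules."""

import numpy as np
import pandas as pd
import pytest

from barcodelim.assignment import (
    DISCORDANT,
    UNIDENTIFIED,
    CurationConfig,
    FinalCall,
    SynonymMap,
    assign_on_tree,
    build_synonym_map,
    combine_genes,
    composition_report,
    curate_references,
    delimitation_comparison,
    gene_majority,
)
from barcodelim.abgd import Partition
from barcodelim.distances import DistanceMatrix, distance_matrix
from barcodelim.seqio import Alignment, parse_newick
from barcodelim.simulate import SimulationConfig, simulate


def _dm(ids, pairs):
    n = len(ids)
    D = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(ids)}
    for (a, b), v in pairs.items():
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = v
    return DistanceMatrix(ids=list(ids), d=D, defined=np.ones((n, n), bool))


def _refs(mapping):
    return pd.DataFrame(
        [{"sequence_id": k, "species": v, "locus": "L", "accession": ""} for k, v in mapping.items()]
    )


class TestAssignOnTree:
    def test_specimen_sister_to_single_reference(self):
        tree = parse_newick("((U1:0.01,R1:0.01):0.1,(R2:0.01,O:0.2):0.1);")
        tree.is_rooted = True
        refs = _refs({"R1": "S1", "R2": "S2"})
        dm = _dm(["U1", "R1", "R2", "O"], {("U1", "R1"): 0.002})
        calls = assign_on_tree(tree, refs, dm, ["U1"])
        assert calls["U1"] == "S1"

    def test_multi_species_clade_resolved_by_lowest_k2p(self):
        tree = parse_newick("(((U1:0.01,R1:0.01):0.01,R2:0.02):0.1,O:0.3);")
        tree.is_rooted = True
        refs = _refs({"R1": "S1", "R2": "S2"})
        dm = _dm(
            ["U1", "R1", "R2", "O"],
            {("U1", "R1"): 0.004, ("U1", "R2"): 0.031},
        )
        # walking up from U1, the first reference-containing clade holds only R1
        assert assign_on_tree(tree, refs, dm, ["U1"])["U1"] == "S1"
        # force the multi-reference case: specimen sister to both references
        tree2 = parse_newick("((U1:0.01,(R1:0.01,R2:0.01):0.004):0.1,O:0.3);")
        tree2.is_rooted = True
        assert assign_on_tree(tree2, refs, dm, ["U1"])["U1"] == "S1"
        dm_flip = _dm(
            ["U1", "R1", "R2", "O"],
            {("U1", "R1"): 0.031, ("U1", "R2"): 0.004},
        )
        assert assign_on_tree(tree2, refs, dm_flip, ["U1"])["U1"] == "S2"

    def test_specimen_below_all_reference_clades_unassigned(self):
        tree = parse_newick("(U1:0.2,((R1:0.01,R2:0.01):0.05,U2:0.02):0.1);")
        tree.is_rooted = True
        refs = _refs({"R1": "S1", "R2": "S1"})
        dm = _dm(["U1", "U2", "R1", "R2"], {})
        calls = assign_on_tree(tree, refs, dm, ["U1", "U2"])
        assert calls["U1"] is None  # first reference clade above U1 is the root
        assert calls["U2"] == "S1"

    def test_missing_specimen_tip_errors(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tree.is_rooted = True
        with pytest.raises(ValueError, match="not a tip"):
            assign_on_tree(tree, _refs({"A": "S"}), _dm(["A", "B", "C"], {}), ["zzz"])


class TestGeneMajority:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["S1", "S1", "S2"], "S1"),
            (["S1", "S2", None], None),
            (["S1"], "S1"),
            ([None, None, None], None),
            (["S1", "S1", "S2", "S2"], None),
        ],
    )
    def test_strict_majority(self, calls, expected):
        assert gene_majority(calls) == expected


class TestCombineGenes:
    def test_agreement_after_synonym_mapping(self):
        syn = SynonymMap({"U. pertusa": "U. australis"})
        call = combine_genes("U. australis", "U. pertusa", syn)
        assert call.status == "U. australis" and not call.single_gene

    def test_disagreement_is_discordant(self):
        call = combine_genes("U. ohnoi", "U. australis")
        assert call.status == DISCORDANT
        assert call.gene_calls == ("U. ohnoi", "U. australis")

    def test_single_gene_fallback(self):
        call = combine_genes(None, "U. torta")
        assert call.status == "U. torta" and call.single_gene

    def test_neither_gene_unidentified(self):
        assert combine_genes(None, None).status == UNIDENTIFIED

    def test_symmetric_in_gene_order(self):
        a = combine_genes("S1", "S2")
        b = combine_genes("S2", "S1")
        assert a.status == b.status == DISCORDANT
        assert combine_genes("S1", None).status == combine_genes(None, "S1").status


class TestSynonymMap:
    def test_near_zero_pairs_merged_distant_kept(self):
        refs = _refs({"r1": "laetevirens", "r2": "rigida", "r3": "australis",
                      "r4": "pertusa", "r5": "ohnoi", "r6": "fasciata"})
        dm = _dm(
            ["r1", "r2", "r3", "r4", "r5", "r6"],
            {
                ("r1", "r2"): 0.000,   # merged
                ("r3", "r4"): 0.001,   # merged
                ("r5", "r6"): 0.007,   # kept distinct
                ("r1", "r3"): 0.08, ("r1", "r4"): 0.08, ("r1", "r5"): 0.08,
                ("r1", "r6"): 0.08, ("r2", "r3"): 0.08, ("r2", "r4"): 0.08,
                ("r2", "r5"): 0.08, ("r2", "r6"): 0.08, ("r3", "r5"): 0.08,
                ("r3", "r6"): 0.08, ("r4", "r5"): 0.08, ("r4", "r6"): 0.08,
            },
        )
        syn = build_synonym_map(refs, dm, threshold=0.002)
        assert syn.apply("rigida") == "laetevirens"
        assert syn.apply("pertusa") == "australis"
        assert syn.apply("fasciata") == "fasciata"
        assert syn.apply("ohnoi") == "ohnoi"

    def test_alias_overrides_alphabetical_canonical(self):
        refs = _refs({"r1": "australis", "r2": "aaa_first"})
        dm = _dm(["r1", "r2"], {("r1", "r2"): 0.0005})
        syn = build_synonym_map(refs, dm, threshold=0.002, aliases={"aaa_first": "australis"})
        assert syn.apply("aaa_first") == "australis"

    def test_idempotent(self):
        syn = SynonymMap({"b": "a", "c": "b"})
        assert syn.apply("c") == "a"
        assert syn.apply(syn.apply("c")) == "a"


class TestCuration:
    @staticmethod
    def _candidate_alignment(mislabel=False, seed=0):
        cfg = SimulationConfig(
            n_species=3,
            specimens_per_species=(0, 0, 0),
            references_per_species=3,
            outgroup_tips=2,
            outgroup_specimens=0,
            delta_intra=0.004,
            delta_inter=0.09,
            n_discordant=0,
            n_synonym_pairs=0,
            locus_names=("L",),
            locus_rate_multipliers=(1.0,),
            locus_lengths=(700,),
            seed=seed,
        )
        ds = simulate(cfg)
        aln = ds.alignments[0]
        labels = dict(zip(ds.references["sequence_id"], ds.references["species"]))
        labels = {k: v for k, v in labels.items() if v != "Outgroup_sp"}
        if mislabel:
            # claim a Species_02 sequence belongs to Species_01
            victim = [k for k, v in labels.items() if v == "Species_02"][0]
            labels[victim] = "Species_01"
        return aln, labels

    def test_supported_species_keep_two_most_divergent(self):
        aln, labels = self._candidate_alignment()
        refs, report = curate_references(
            aln, labels, CurationConfig(n_bootstrap=50, seed=1)
        )
        counts = refs.groupby("species")["sequence_id"].count()
        assert (counts == 2).all()
        assert report["rejected_species"] == []
        dm = distance_matrix(aln)
        for sp, grp in refs.groupby("species"):
            kept = list(grp["sequence_id"])
            cands = [k for k, v in labels.items() if v == sp]
            best = max(
                dm.get(a, b)
                for i, a in enumerate(cands)
                for b in cands[i + 1:]
            )
            assert dm.get(kept[0], kept[1]) == pytest.approx(best)

    def test_mislabeled_candidate_discarded(self):
        aln, labels = self._candidate_alignment(mislabel=True)
        refs, report = curate_references(
            aln, labels, CurationConfig(n_bootstrap=50, seed=1)
        )
        discarded = report["discarded"]
        mislabeled = [d for d in discarded if labels[d] == "Species_01" and d.startswith("R02")]
        assert mislabeled  # the falsely claimed sequence was thrown out
        assert not set(refs.loc[refs["species"] == "Species_01", "sequence_id"]) & set(
            mislabeled
        )
        assert {"Species_01", "Species_02", "Species_03"} <= set(refs["species"])


class TestReports:
    def test_composition_toy_percentages(self):
        calls = {
            "u1": FinalCall("S1", ("S1", "S1")),
            "u2": FinalCall("S1", ("S1", "S1")),
            "u3": FinalCall("S2", ("S2", "S2")),
            "u4": FinalCall(DISCORDANT, ("S1", "S2")),
        }
        meta = pd.DataFrame(
            {"specimen_id": ["u1", "u2", "u3", "u4"],
             "site_code": ["s1", "s2", "s1", "s2"]}
        )
        table = composition_report(calls, meta)
        by_cat = table.set_index("category")
        assert by_cat.loc["S1", "n_specimens"] == 2
        assert by_cat.loc["S1", "rel_freq_pct"] == 50.0
        assert by_cat.loc["S2", "rel_freq_pct"] == 25.0
        assert by_cat.loc[DISCORDANT, "rel_freq_pct"] == 25.0
        assert by_cat.loc["total", "n_specimens"] == 4
        assert by_cat.loc["S1", "n_sites"] == 2

    def test_missing_site_codes_error(self):
        calls = {"u1": FinalCall("S1", ("S1", None))}
        meta = pd.DataFrame({"specimen_id": ["u1"], "site_code": [""]})
        with pytest.raises(ValueError, match="site"):
            composition_report(calls, meta)

    def test_comparison_congruent_and_split(self):
        calls = {
            "u1": FinalCall("S1", ("S1", "S1")),
            "u2": FinalCall("S1", ("S1", "S1")),
            "u3": FinalCall("S2", ("S2", "S2")),
        }
        congruent = Partition({"u1": 1, "u2": 1, "u3": 2, "ref1": 3})
        split = Partition({"u1": 1, "u2": 2, "u3": 3, "ref1": 4})
        table = delimitation_comparison(
            calls, {"abgd": congruent, "abgd_small_p": split}
        )
        by = table.set_index("species")
        assert by.loc["S1", "abgd"] == 1
        assert by.loc["S1", "abgd_small_p"] == 2  # species split at small prior
        assert by.loc["reference-only groups", "abgd"] == 1
        assert by.loc["total groups", "abgd"] == 3
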