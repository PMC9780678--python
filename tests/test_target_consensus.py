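"""Vote-state assignment, consensus counting, networks, similarity fishing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoscreen.errors import ConfigurationError, DataError
from phytoscreen.target_consensus import (
    PredictionRecord,
    ToolManifest,
    VoteState,
    apply_topk,
    assign_vote_states,
    build_network,
    export_edge_list,
    load_predictions,
    similarity_target_predictor,
    tanimoto,
    write_predictions_tsv,
)


def rec(tool, cid, tid, rank, in_topk=False):
    return PredictionRecord(tool, cid, tid, rank, in_topk=in_topk)


class TestLoadPredictions:
    def test_explicit_ranks_preserved(self, tmp_path):
        records = [rec("t", "C_01", f"P{i:05d}", i) for i in range(1, 31)]
        path = tmp_path / "preds.tsv"
        write_predictions_tsv(records, path)
        loaded = load_predictions(path, "t")
        assert sorted(r.rank for r in loaded) == list(range(1, 31))

    def test_score_only_ranked_descending_ties_by_target(self, tmp_path):
        path = tmp_path / "preds.csv"
        path.write_text(
            "compound_id,target_id,score\nC_01,P2,0.5\nC_01,P1,0.9\nC_01,P3,0.5\n"
        )
        loaded = load_predictions(path, "t")
        by_target = {r.target_id: r.rank for r in loaded}
        assert by_target == {"P1": 1, "P2": 2, "P3": 3}

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "preds.csv"
        path.write_text("compound_id,target_id,rank\nC_01,P1,1\nC_01,P1,2\n")
        with pytest.raises(DataError, match="C_01"):
            load_predictions(path, "t")

    def test_alias_map_normalizes_target_ids(self, tmp_path):
        path = tmp_path / "preds.csv"
        path.write_text("compound_id,target_id,rank\nC_01,ACHE,1\nC_01,CHEMBL220,2\n")
        with pytest.raises(DataError):  # both aliases collapse to one accession
            load_predictions(
                path, "t", alias_map={"ACHE": "P22303", "CHEMBL220": "P22303"}
            )
        loaded = load_predictions(path, "t", alias_map={"ACHE": "P22303"})
        assert {r.target_id for r in loaded} == {"P22303", "CHEMBL220"}

    def test_needs_rank_or_score(self, tmp_path):
        path = tmp_path / "preds.csv"
        path.write_text("compound_id,target_id\nC_01,P1\n")
        with pytest.raises(ConfigurationError):
            load_predictions(path, "t")


class TestApplyTopk:
    def test_marks_first_twenty(self):
        records = [rec("t", "C", f"P{i}", i) for i in range(1, 31)]
        marked = apply_topk(records, k=20)
        assert sum(r.in_topk for r in marked) == 20
        assert all(r.in_topk == (r.rank <= 20) for r in marked)
        assert len(marked) == 30  # nothing dropped

    def test_short_list_fully_marked(self):
        records = [rec("t", "C", f"P{i}", i) for i in range(1, 16)]
        assert all(r.in_topk for r in apply_topk(records, k=20))

    def test_k_one_marks_only_rank_one(self):
        records = [rec("t", "C", f"P{i}", i) for i in range(1, 5)]
        marked = apply_topk(records, k=1)
        assert [r.target_id for r in marked if r.in_topk] == ["P1"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_topk([], k=0)


class TestVoteStates:
    def test_six_tool_state_tally(self):
        """2 top-k hits, 1 beyond, 2 covered misses, 1 not covering -> (2,1,2,1)."""
        target = "P05067"
        records = [
            rec("t1", "C", target, 3, in_topk=True),
            rec("t2", "C", target, 7, in_topk=True),
            rec("t3", "C", target, 25, in_topk=False),
        ]
        manifests = [ToolManifest(f"t{i}", frozenset({target})) for i in range(1, 6)]
        manifests.append(ToolManifest("t6", frozenset()))  # does not cover
        vm = assign_vote_states(records, manifests, targets_of_interest=[target])
        counts = vm.vote_counts("C", target)
        assert counts[VoteState.HIT] == 2
        assert counts[VoteState.HIT_BEYOND_TOPK] == 1
        assert counts[VoteState.NO_HIT] == 2
        assert counts[VoteState.NOT_COVERED] == 1
        assert vm.consensus_votes("C", target) == 2

    def test_two_tool_consensus_for_amyloid_beta_precursor(self):
        """Two similarity tools agreeing on P05067 give a consensus of 2."""
        tools = ["SEA", "SwissTargetPrediction", "TargetNet", "PPB2", "PharmMapper", "SuperPred"]
        records = [
            rec("TargetNet", "Ma3gal", "P05067", 5, in_topk=True),
            rec("SwissTargetPrediction", "Ma3gal", "P05067", 11, in_topk=True),
        ]
        manifests = [ToolManifest(t, frozenset({"P05067", "P22303"})) for t in tools]
        vm = assign_vote_states(records, manifests, targets_of_interest=["P05067"])
        assert vm.consensus_votes("Ma3gal", "P05067") == 2

    def test_three_tool_consensus_for_acetylcholinesterase(self):
        tools = ["SEA", "SwissTargetPrediction", "TargetNet", "PPB2", "PharmMapper", "SuperPred"]
        records = [
            rec("TargetNet", "Ma3gal", "P22303", 2, in_topk=True),
            rec("SwissTargetPrediction", "Ma3gal", "P22303", 4, in_topk=True),
            rec("PPB2", "Ma3gal", "P22303", 9, in_topk=True),
        ]
        manifests = [ToolManifest(t, frozenset({"P05067", "P22303"})) for t in tools]
        vm = assign_vote_states(records, manifests, targets_of_interest=["P22303"])
        assert vm.consensus_votes("Ma3gal", "P22303") == 3

    def test_tool_without_manifest_rejected(self):
        records = [rec("t1", "C", "P1", 1, in_topk=True)]
        with pytest.raises(ConfigurationError, match="t1"):
            assign_vote_states(records, [])

    def test_unknown_universe_requires_policy(self):
        records = [rec("t1", "C", "P1", 1, in_topk=True)]
        manifests = [ToolManifest("t1", None)]
        # the observed pair is fine, but an absent pair is ambiguous
        with pytest.raises(ConfigurationError, match="unknown"):
            assign_vote_states(records, manifests, targets_of_interest=["P1", "P2"])
        vm = assign_vote_states(
            records,
            manifests,
            targets_of_interest=["P1", "P2"],
            unknown_universe_policy="assume_covered",
        )
        assert vm.state("C", "P2", "t1") == VoteState.NO_HIT

    def test_prediction_outside_manifest_rejected(self):
        records = [rec("t1", "C", "P1", 1, in_topk=True)]
        manifests = [ToolManifest("t1", frozenset({"P9"}))]
        with pytest.raises(DataError, match="outside"):
            assign_vote_states(records, manifests, targets_of_interest=["P1"])


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_vote_state_conservation(seed):
    """Per pair, the four state counts always sum to the number of tools."""
    rng = np.random.default_rng(seed)
    tools = [f"t{i}" for i in range(1, 5)]
    targets = [f"P{i}" for i in range(1, 5)]
    compounds = ["C_a", "C_b", "C_c"]
    manifests = [
        ToolManifest(t, frozenset(x for x in targets if rng.random() < 0.7)) for t in tools
    ]
    covered = {m.tool_id: m.covered_targets for m in manifests}
    records = []
    for tool, c in itertools.product(tools, compounds):
        hits = [t for t in covered[tool] if rng.random() < 0.5]
        for rank, t in enumerate(sorted(hits), start=1):
            records.append(rec(tool, c, t, rank))
    vm = assign_vote_states(
        apply_topk(records, k=2), manifests, targets_of_interest=targets, compounds=compounds
    )
    for c, t in itertools.product(compounds, targets):
        assert sum(vm.vote_counts(c, t).values()) == len(tools)


def test_consensus_votes_monotone_in_k():
    """Raising the cutoff can only convert states toward hit, never away."""
    rng = np.random.default_rng(3)
    records = [rec("t1", "C", f"P{i}", i) for i in range(1, 31)]
    manifests = [ToolManifest("t1", frozenset(f"P{i}" for i in range(1, 31)))]
    targets = [f"P{i}" for i in range(1, 31)]
    votes = []
    for k in (1, 5, 20, 30):
        vm = assign_vote_states(apply_topk(records, k=k), manifests, targets_of_interest=targets)
        votes.append(sum(vm.consensus_votes("C", t) for t in targets))
        for t in targets:
            assert vm.state("C", t, "t1") in (VoteState.HIT, VoteState.HIT_BEYOND_TOPK)
    assert votes == sorted(votes)


class TestNetwork:
    @staticmethod
    def full_matrix(n_compounds=10, n_targets=3, votes=2):
        compounds = [f"C_{i:02d}" for i in range(n_compounds)]
        targets = [f"P{i}" for i in range(n_targets)]
        tools = [f"t{i}" for i in range(1, 7)]
        states = {}
        for c, t in itertools.product(compounds, targets):
            for j, tool in enumerate(tools):
                states[(c, t, tool)] = VoteState.HIT if j < votes else VoteState.NO_HIT
        from phytoscreen.target_consensus import VoteMatrix

        return VoteMatrix(compounds, targets, tools, states)

    def test_complete_bipartite_counts(self):
        graph = build_network(self.full_matrix(), min_votes=1)
        assert graph.number_of_nodes() == 13
        assert graph.number_of_edges() == 30

    def test_min_votes_above_max_gives_empty_edge_set(self):
        graph = build_network(self.full_matrix(votes=3), min_votes=4)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 13  # isolated nodes retained

    def test_single_pair_edge_weight(self):
        graph = build_network(self.full_matrix(n_compounds=1, n_targets=1, votes=2))
        assert graph["C_00"]["P0"]["votes"] == 2

    def test_edge_list_export_is_byte_deterministic(self, tmp_path):
        vm = self.full_matrix()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_edge_list(build_network(vm), p1)
        export_edge_list(build_network(vm), p2)
        assert p1.read_bytes() == p2.read_bytes()


REFERENCE_LIGANDS = [
    "O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O",
    "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",
    "COc1ccc(C=CC(=O)O)cc1O",
    "Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1",
    "OCC1OC(Oc2ccccc2)C(O)C(O)C1O",
    "O=C(O)c1cc(O)c(O)c(O)c1",
    "CC(C)=CCc1c(O)cc(O)c2c1OC(c1ccc(O)cc1)CC2=O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "c1ccc2ccccc2c1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CCN(CC)C(=O)c1ccccc1",
    "OCC(O)CO",
    "NCC(=O)O",
    "CC(N)Cc1ccccc1",
    "OC(=O)CCc1ccccc1",
    "COc1cc(C=O)ccc1O",
    "CC1=CC(=O)c2ccccc2O1",
    "OCC1OC(O)C(O)C(O)C1O",
]


class TestSimilarityPredictor:
    @staticmethod
    def reference():
        targets = [f"P{i:05d}" for i in range(5)]
        return [(smi, targets[i % 5]) for i, smi in enumerate(REFERENCE_LIGANDS)]

    def test_self_query_retrieves_own_target_first(self):
        ref = self.reference()
        query, target = ref[3][0], ref[3][1]
        out = similarity_target_predictor(query, ref, k=5)
        assert out[0].target_id == target
        assert out[0].score == pytest.approx(1.0)
        assert out[0].rank == 1

    def test_single_target_reference(self):
        out = similarity_target_predictor("CCO", [("CCO", "P1"), ("CCN", "P1")], k=10)
        assert len(out) == 1 and out[0].target_id == "P1"

    def test_matches_exhaustive_pairwise_loop(self):
        """Ranking equals a brute-force max-Tanimoto loop over all ligands."""
        ref = self.reference()
        query = "COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O"
        out = similarity_target_predictor(query, ref, k=5)
        best = {}
        for smi, tid in ref:
            sim = tanimoto(query, smi)
            best[tid] = max(best.get(tid, 0.0), sim)
        expected = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        assert [(r.target_id, pytest.approx(r.score)) for r in out] == [
            (tid, pytest.approx(sim)) for tid, sim in expected
        ]

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError):
            similarity_target_predictor("CCO", [])


@settings(max_examples=30, derandomize=True)
@given(
    a=st.sampled_from(REFERENCE_LIGANDS),
    b=st.sampled_from(REFERENCE_LIGANDS),
)
def test_tanimoto_identity_symmetry_bounds(a, b):
    assert tanimoto(a, a) == pytest.approx(1.0)
    s_ab, s_ba = tanimoto(a, b), tanimoto(b, a)
    assert s_ab == pytest.approx(s_ba)
    assert 0.0 <= s_ab <= 1.0
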