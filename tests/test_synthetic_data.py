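"""Ground-truth guarantees and determinism of the synthetic generators."""

import math

import pytest

from phytoscreen import admet_rules, descriptors, library_io, target_consensus
from phytoscreen.bioassay_stats import tht_lag_time
from phytoscreen.errors import ConfigurationError, DataError
from phytoscreen.synthetic_data import (
    AssaySimConfig,
    LibraryConfig,
    PredictorSimConfig,
    generate_assay_data,
    generate_library,
    generate_predictions,
)


class TestGenerateLibrary:
    def test_counts_and_labels(self):
        lib = generate_library(LibraryConfig(n_compounds=100, n_planted=10, seed=7))
        assert len(lib.compounds) == 100
        assert len(lib.active_ids) == 10
        decoys = {r.compound_id for r in lib.compounds} - set(lib.active_ids)
        assert set(lib.violated_rules) == decoys
        assert all(lib.violated_rules[d] for d in lib.violated_rules if d in lib.descriptors)

    def test_same_seed_reproduces_identical_output(self):
        a = generate_library(LibraryConfig(n_compounds=60, n_planted=5, seed=11))
        b = generate_library(LibraryConfig(n_compounds=60, n_planted=5, seed=11))
        assert a.compounds == b.compounds
        assert a.descriptors == b.descriptors
        assert a.active_ids == b.active_ids

    def test_distinct_seeds_differ(self):
        a = generate_library(LibraryConfig(n_compounds=60, n_planted=5, seed=1))
        b = generate_library(LibraryConfig(n_compounds=60, n_planted=5, seed=2))
        assert a.descriptors != b.descriptors

    def test_actives_achieve_maximal_score_by_scoring_engine(self):
        lib = generate_library(LibraryConfig(n_compounds=80, n_planted=8, seed=3))
        ruleset = admet_rules.default_ruleset()
        full = sum(r.weight for r in ruleset)
        for cid in lib.active_ids:
            card = admet_rules.evaluate_rules(
                lib.descriptors[cid], lib.admet[cid], ruleset, compound_id=cid
            )
            assert card.raw_score == full

    def test_every_decoy_fails_at_least_one_rule(self):
        lib = generate_library(LibraryConfig(n_compounds=80, n_planted=8, seed=3))
        ruleset = admet_rules.default_ruleset()
        full = sum(r.weight for r in ruleset)
        for rec in lib.compounds:
            if rec.compound_id in set(lib.active_ids):
                continue
            card = admet_rules.evaluate_rules(
                lib.descriptors.get(rec.compound_id),
                lib.admet[rec.compound_id],
                ruleset,
                compound_id=rec.compound_id,
            )
            assert card.raw_score < full

    def test_stage_truth_partitions_the_library(self):
        lib = generate_library(LibraryConfig(n_compounds=120, n_planted=10, seed=9))
        all_ids = [r.compound_id for r in lib.compounds]
        partition = (
            lib.removed_by_class + lib.removed_by_inorganic + lib.removed_by_mw + lib.survivor_ids
        )
        assert sorted(partition) == sorted(all_ids)

    def test_impossible_descriptor_range_rejected(self):
        with pytest.raises(ConfigurationError, match="mw"):
            generate_library(
                LibraryConfig(
                    n_compounds=10,
                    n_planted=2,
                    descriptor_ranges={"mw": (900.0, 1000.0)},
                    seed=0,
                )
            )

    def test_overfull_config_rejected(self):
        with pytest.raises(ConfigurationError):
            LibraryConfig(n_compounds=5, n_planted=4, n_invalid=2)

    def test_round_trip_through_pipeline_file_formats(self, tmp_path):
        lib = generate_library(LibraryConfig(n_compounds=40, n_planted=4, n_invalid=1, seed=5))
        library_io.write_compound_table(lib.compounds, tmp_path / "library.csv")
        descriptors.write_descriptor_csv(lib.descriptors, tmp_path / "descriptors.csv")
        admet_rules.write_admet_table(lib.admet, tmp_path / "admet.csv")
        assert library_io.read_compound_table(tmp_path / "library.csv") == lib.compounds
        assert descriptors.read_descriptor_csv(tmp_path / "descriptors.csv") == lib.descriptors
        loaded = admet_rules.load_admet_table(tmp_path / "admet.csv")
        assert set(loaded) == set(lib.admet)
        for cid in loaded:
            for name in admet_rules.ENDPOINTS:
                assert loaded[cid].get(name).value == pytest.approx(
                    lib.admet[cid].get(name).value
                )


class TestGeneratePredictions:
    TARGETS = ("P05067", "P22303", "P42574")

    def pairs(self, n=10):
        return [(f"C_{i:03d}", t) for i in range(n) for t in self.TARGETS]

    def test_perfect_sensitivity_gives_full_votes(self):
        config = PredictorSimConfig(sensitivity=1.0, coverage=1.0, false_hit_rate=0.0, seed=1)
        predictions, manifests = generate_predictions(config, self.pairs())
        records = [
            rec
            for tool in sorted(predictions)
            for rec in target_consensus.apply_topk(predictions[tool], k=config.topk)
        ]
        vm = target_consensus.assign_vote_states(
            records, manifests, targets_of_interest=list(self.TARGETS)
        )
        for c, t in self.pairs():
            assert vm.consensus_votes(c, t) == config.n_tools

    def test_zero_rates_give_all_no_hit(self):
        config = PredictorSimConfig(
            sensitivity=0.0, false_hit_rate=0.0, beyond_topk_rate=0.0, coverage=1.0, seed=1
        )
        predictions, manifests = generate_predictions(config, self.pairs())
        assert all(not recs for recs in predictions.values())
        vm = target_consensus.assign_vote_states(
            [],
            manifests,
            targets_of_interest=list(self.TARGETS),
            compounds=sorted({c for c, _ in self.pairs()}),
        )
        for c, t in self.pairs():
            assert vm.vote_counts(c, t)[target_consensus.VoteState.NO_HIT] == config.n_tools

    def test_ranks_are_collision_free_within_tool_and_compound(self):
        config = PredictorSimConfig(sensitivity=0.8, false_hit_rate=0.3, coverage=0.9, seed=4)
        predictions, _ = generate_predictions(
            config, self.pairs(), decoy_targets=[f"P{i:05d}" for i in range(10)]
        )
        for tool, records in predictions.items():
            seen = {}
            for rec in records:
                key = (rec.compound_id, rec.rank)
                assert key not in seen, f"rank collision in {tool}"
                seen[key] = rec

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            generate_predictions(PredictorSimConfig(), [], [])

    def test_vote_distribution_matches_binomial_closed_form(self):
        """Mean votes and P(votes >= 2) track Binomial(n_tools, sensitivity)."""
        from scipy import stats as sps

        config = PredictorSimConfig(
            n_tools=6, sensitivity=0.8, coverage=1.0, false_hit_rate=0.0,
            beyond_topk_rate=0.0, topk=20, seed=13,
        )
        pairs = [(f"C_{i:04d}", self.TARGETS[i % 3]) for i in range(2000)]
        predictions, _ = generate_predictions(config, pairs)
        hits: dict[tuple[str, str], int] = {p: 0 for p in pairs}
        for records in predictions.values():
            for rec in records:
                if rec.rank <= config.topk:
                    hits[(rec.compound_id, rec.target_id)] += 1
        votes = list(hits.values())
        n = len(votes)
        mean = sum(votes) / n
        mean_expected = config.n_tools * config.sensitivity
        se_mean = math.sqrt(config.n_tools * 0.8 * 0.2 / n)
        assert abs(mean - mean_expected) <= 3 * se_mean
        p_ge2 = sum(v >= 2 for v in votes) / n
        p_expected = float(sps.binom(config.n_tools, config.sensitivity).sf(1))
        se_p = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(p_ge2 - p_expected) <= 3 * se_p


class TestGenerateAssayData:
    def test_zero_noise_reproduces_true_means(self):
        config = AssaySimConfig(noise_sd=0.0, seed=2)
        data = generate_assay_data(config)
        for label, mean in config.group_means.items():
            assert data.groups[label].values == (mean,) * config.n_replicates
            assert data.groups[label].n == 3  # triplicate design

    def test_noise_free_logistic_lag_matches_analytic_crossing(self):
        config = AssaySimConfig(tht_noise_sd=0.0, seed=2)
        data = generate_assay_data(config)
        lag = tht_lag_time(data.tht, threshold_fraction=0.1)
        s = lambda t: 1.0 / (1.0 + math.exp(-config.tht_rate * (t - config.tht_midpoint)))  # noqa: E731
        s_star = s(config.tht_times[0]) + 0.1 * (s(max(config.tht_times)) - s(config.tht_times[0]))
        expected = config.tht_midpoint - math.log(1.0 / s_star - 1.0) / config.tht_rate
        assert abs(lag - expected) <= 6.0  # one sampling interval at the crossing
        assert lag == pytest.approx(expected, abs=1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            AssaySimConfig(noise_sd=-1.0)

    def test_seed_determinism(self):
        a = generate_assay_data(AssaySimConfig(seed=5))
        b = generate_assay_data(AssaySimConfig(seed=5))
        assert a.groups == b.groups and a.tht == b.tht
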