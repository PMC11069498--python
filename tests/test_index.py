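"""Index construction, cross-cohort matching and log-rank-ratio scoring."""

import numpy as np
import pandas as pd
import pytest

from microidx import (
    DAConfig,
    IndexDefinition,
    build_index_definition,
    compare_index_between_groups,
    differential_features,
    match_features,
    run_index_pipeline,
    score_index,
    simulate_reference_cohort,
    simulate_target_cohort,
    SimulationConfig,
)
from microidx.index import IndexError_
from microidx.tables import FeatureTable

SEQ = {  # distinct 150-nt sequences for matching tests
    name: (base * 50) for name, base in
    [("p1", "ACG"), ("p2", "CGT"), ("n1", "GTA"), ("n2", "TAC"), ("x1", "AAC"), ("x2", "GGA")]
}


def seq_table(values, feature_names, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return FeatureTable(
        pd.DataFrame(values, index=samples, columns=[SEQ[n] for n in feature_names]), "log"
    )


class TestIndexDefinition:
    def test_sets_must_be_disjoint_and_nonempty(self):
        with pytest.raises(IndexError_, match="nonempty"):
            IndexDefinition("i", frozenset(), frozenset({"A"}))
        with pytest.raises(IndexError_, match="overlap"):
            IndexDefinition("i", frozenset({"A"}), frozenset({"A", "B"}))

    def test_json_round_trip(self, tmp_path):
        idx = IndexDefinition("rural", frozenset({SEQ["p1"]}), frozenset({SEQ["n1"]}), {"alpha": 0.1})
        path = tmp_path / "idx.json"
        idx.to_json(path)
        assert IndexDefinition.from_json(path) == idx

    def test_build_from_da_result(self):
        da = pd.DataFrame(
            {
                "effect": [5.0, 4.0, 3.0, -2.0, -6.0, 1.0],
                "significant": [True, True, True, True, True, False],
            },
            index=[SEQ[k] for k in ("p1", "p2", "x1", "n1", "n2", "x2")],
        )
        idx = build_index_definition(da, "rural_index")
        assert idx.positive_features == frozenset(SEQ[k] for k in ("p1", "p2", "x1"))
        assert idx.negative_features == frozenset(SEQ[k] for k in ("n1", "n2"))

    def test_build_fails_without_both_directions(self):
        da = pd.DataFrame({"effect": [5.0, 2.0], "significant": [True, False]},
                          index=[SEQ["p1"], SEQ["n1"]])
        with pytest.raises(IndexError_, match="relaxing alpha"):
            build_index_definition(da, "rural_index")


class TestMatchFeatures:
    def index(self):
        return IndexDefinition("i", frozenset({SEQ["p1"], SEQ["p2"]}), frozenset({SEQ["n1"]}))

    def test_identical_universe_full_coverage(self):
        table = seq_table(np.ones((2, 3)), ["p1", "p2", "n1"])
        matched, coverage = match_features(self.index(), table)
        assert coverage == {"positive_matched_fraction": 1.0, "negative_matched_fraction": 1.0}
        assert matched.positive_features == self.index().positive_features

    def test_longer_table_sequences_match_by_prefix(self):
        table = FeatureTable(
            pd.DataFrame(
                np.ones((2, 3)),
                columns=[SEQ["p1"] + "ACGTACGTAC", SEQ["p2"] + "GGGGGGGGGG", SEQ["n1"] + "TTTTTTTTTT"],
                index=["s0", "s1"],
            ),
            "log",
        )
        matched, coverage = match_features(self.index(), table)
        assert coverage["positive_matched_fraction"] == 1.0
        assert SEQ["p1"] + "ACGTACGTAC" in matched.positive_features

    def test_disjoint_universes_error(self):
        table = seq_table(np.ones((2, 2)), ["x1", "x2"])
        with pytest.raises(IndexError_, match="does not match"):
            match_features(self.index(), table)


class TestScoreIndex:
    def test_hand_computed_log_rank_ratios(self):
        # relative abundances; ranks per feature across 3 samples computed by hand
        values = [
            [0.40, 0.30, 0.20, 0.10],
            [0.10, 0.20, 0.30, 0.40],
            [0.25, 0.25, 0.25, 0.25],
        ]
        table = FeatureTable(
            pd.DataFrame(values, index=["s1", "s2", "s3"],
                         columns=[SEQ[k] for k in ("p1", "p2", "n1", "n2")]),
            "relative",
        )
        idx = IndexDefinition("i", frozenset({SEQ["p1"], SEQ["p2"]}), frozenset({SEQ["n1"], SEQ["n2"]}))
        scores = score_index(table, idx)
        # s1: pos ranks (3,3) neg (1,1) -> ln(3); s2 mirrored -> -ln(3); s3 all rank 2 -> 0
        np.testing.assert_allclose(scores.to_numpy(), [np.log(3), -np.log(3), 0.0], atol=1e-12)

    def test_antisymmetry_under_set_swap(self, small_cohort):
        _, table, metadata, truth = small_cohort
        idx = IndexDefinition("i", frozenset(truth.planted_positive), frozenset(truth.planted_negative))
        scores = score_index(table, idx)
        swapped = score_index(table, idx.swapped())
        np.testing.assert_allclose(scores.to_numpy(), -swapped.to_numpy(), atol=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.random((6, 4))
        cols = [SEQ[k] for k in ("p1", "p2", "n1", "n2")]
        base = FeatureTable(pd.DataFrame(values, columns=cols), "log")
        trans = FeatureTable(pd.DataFrame(np.expm1(values) ** 3 + 1, columns=cols), "log")
        idx = IndexDefinition("i", frozenset(cols[:2]), frozenset(cols[2:]))
        np.testing.assert_allclose(
            score_index(base, idx).to_numpy(), score_index(trans, idx).to_numpy(), atol=1e-12
        )

    def test_scores_always_finite(self, small_cohort):
        _, table, _, truth = small_cohort
        idx = IndexDefinition("i", frozenset(truth.planted_positive), frozenset(truth.planted_negative))
        assert np.isfinite(score_index(table, idx)).all()

    def test_added_sample_changes_scores_only_via_reranking(self):
        """Scores recomputed on an extended cohort match a brute-force re-rank."""
        rng = np.random.default_rng(9)
        cols = [SEQ[k] for k in ("p1", "p2", "n1", "n2")]
        values = rng.random((5, 4))
        extended = np.vstack([values, rng.random((1, 4))])
        table = FeatureTable(pd.DataFrame(extended, columns=cols), "log")
        idx = IndexDefinition("i", frozenset(cols[:2]), frozenset(cols[2:]))
        scores = score_index(table, idx)
        # independent oracle: loop-based average ranks
        from scipy.stats import rankdata

        for i in range(6):
            pos = np.mean([rankdata(extended[:, j])[i] for j in range(2)])
            neg = np.mean([rankdata(extended[:, j])[i] for j in (2, 3)])
            assert scores.iloc[i] == pytest.approx(np.log(pos / neg))

    def test_unmatched_index_rejected(self):
        table = seq_table(np.ones((3, 2)), ["p1", "n1"])
        idx = IndexDefinition("i", frozenset({SEQ["p1"], SEQ["x1"]}), frozenset({SEQ["n1"]}))
        with pytest.raises(IndexError_, match="match_features"):
            score_index(table, idx)


class TestGroupComparison:
    def test_perfect_separation_matches_exact_tail(self):
        scores = pd.Series(np.r_[np.arange(10) + 100.0, np.arange(10)],
                           index=[f"s{i}" for i in range(20)])
        metadata = pd.DataFrame({"group": ["hi"] * 10 + ["lo"] * 10}, index=scores.index)
        res = compare_index_between_groups(scores, metadata, "hi", "lo", method="exact")
        from math import comb
        assert res["p_value"] == pytest.approx(2 / comb(20, 10))
        assert res["direction"] == "A_higher"

    def test_identical_distributions_p_near_one(self):
        scores = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 2), index=[f"s{i}" for i in range(8)])
        metadata = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4}, index=scores.index)
        res = compare_index_between_groups(scores, metadata, "a", "b")
        assert res["p_value"] > 0.9

    def test_missing_group_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["s0", "s1"])
        metadata = pd.DataFrame({"group": ["a", "a"]}, index=scores.index)
        with pytest.raises(IndexError_):
            compare_index_between_groups(scores, metadata, "a", "zzz")


class TestPipeline:
    def test_monotone_gradient_recovered(self):
        cfg = SimulationConfig(n_samples_per_group=30, n_features=150, n_pos_effect=20,
                               n_neg_effect=15, effect_log2fc=2.5, depth_mean=8000, seed=21)
        ref_table, ref_meta, truth = simulate_reference_cohort(cfg)
        scale = {"rural": 1.0, "rural_urban": 0.5, "urban": 0.4, "CD": 0.0}
        tgt_table, tgt_meta = simulate_target_cohort(cfg, truth, scale)
        report = run_index_pipeline(
            ref_table, ref_meta, tgt_table, tgt_meta,
            da_config=DAConfig(n_permutations=500, seed=3),
            group_comparisons=[("rural", "rural_urban"), ("urban", "CD")],
        )
        medians = report["scores"].groupby(tgt_meta["group"]).median()
        assert medians["rural"] > medians["rural_urban"] > medians["CD"]
        assert medians["urban"] > medians["CD"]

    def test_zero_effect_simulation_errors_out(self):
        cfg = SimulationConfig(n_samples_per_group=15, n_features=80, n_pos_effect=0,
                               n_neg_effect=0, effect_log2fc=0.0, depth_mean=3000, seed=5)
        ref_table, ref_meta, truth = simulate_reference_cohort(cfg)
        tgt_table, tgt_meta = simulate_target_cohort(cfg, truth, {"rural": 0.0, "urban": 0.0})
        with pytest.raises((IndexError_, RuntimeError)):
            run_index_pipeline(ref_table, ref_meta, tgt_table, tgt_meta,
                               da_config=DAConfig(n_permutations=200, seed=6))
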