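"""Feature-table data model, I/O round-trips, and preprocessing filters."""

import numpy as np
import pandas as pd
import pytest

from microidx import (
    FeatureTable,
    filter_contaminants,
    filter_prevalence,
    normalize_metabolites,
    prep_metabolites_for_correlation,
    rarefy,
    read_contaminant_scores,
    read_feature_table,
    write_contaminant_scores,
    write_feature_table,
    write_metadata,
    read_metadata,
)
from microidx.tables import TableError


def make_table(values, kind="counts", samples=None, features=None):
    values = np.asarray(values)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=samples, columns=features), kind)


class TestFeatureTable:
    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["s1", "s1"], columns=["f1", "f2"])
        with pytest.raises(TableError, match="duplicate sample"):
            FeatureTable(df, "counts")

    def test_rejects_negative_counts(self):
        with pytest.raises(TableError, match="negative"):
            make_table([[1, -2], [3, 4]])

    def test_relative_requires_unit_rows(self):
        with pytest.raises(TableError, match="sum to 1"):
            make_table([[0.5, 0.2], [0.5, 0.5]], kind="relative")

    def test_to_relative_rows_sum_to_one(self, toy_counts):
        rel = toy_counts.to_relative()
        assert rel.kind == "relative"
        np.testing.assert_allclose(rel.data.sum(axis=1), 1.0)


class TestIO:
    def test_round_trip(self, tmp_path, toy_counts):
        path = tmp_path / "table.tsv"
        write_feature_table(toy_counts, path)
        back = read_feature_table(path)
        assert back.kind == "counts"
        pd.testing.assert_frame_equal(back.data, toy_counts.data, check_dtype=False)

    def test_qiime2_comment_line_skipped(self, tmp_path, toy_counts):
        path = tmp_path / "table.tsv"
        write_feature_table(toy_counts, path, qiime2_comment=True)
        assert open(path).readline().startswith("# Constructed from biom file")
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(back.data, toy_counts.data, check_dtype=False)

    def test_negative_value_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\ts1\ts2\nf1\t3\t-1\n")
        with pytest.raises(TableError, match="negative"):
            read_feature_table(path)

    def test_metadata_round_trip_and_validation(self, tmp_path):
        md = pd.DataFrame(
            {"group": ["rural", "urban"], "age": [51.0, 27.0], "gender": ["female", "male"], "site": ["x", "x"]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
        path = tmp_path / "md.tsv"
        write_metadata(md, path)
        back = read_metadata(path)
        pd.testing.assert_frame_equal(back, md)
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample_id\tage\ns1\t20\n")
        with pytest.raises(TableError, match="group"):
            read_metadata(bad)

    def test_contaminant_scores_round_trip(self, tmp_path):
        scores = pd.DataFrame(
            {"f_water": [0.9, 0.1], "f_soil": [0.8, 0.2], "f_mouse": [0.7, 0.1], "f_human": [0.5, 0.9]},
            index=pd.Index(["AAA", "CCC"], name="feature_id"),
        )
        path = tmp_path / "scores.tsv"
        write_contaminant_scores(scores, path)
        pd.testing.assert_frame_equal(read_contaminant_scores(path), scores)


class TestPrevalenceFilter:
    def test_boundary_exactly_at_threshold_kept(self):
        # 1 nonzero sample of 100 = fraction 0.01, not < 0.01 -> kept
        values = np.zeros((100, 2), dtype=int)
        values[0, 0] = 5  # f0 in exactly 1 sample
        values[:, 1] = 1
        table = make_table(values)
        filtered, report = filter_prevalence(table, 0.01)
        assert filtered.feature_ids == ["f0", "f1"]
        assert report.n_removed == 0

    def test_never_observed_feature_removed(self):
        values = np.zeros((100, 2), dtype=int)
        values[:, 1] = 1
        filtered, report = filter_prevalence(make_table(values), 0.01)
        assert filtered.feature_ids == ["f1"]
        assert report.removed == ("f0",)

    def test_matches_brute_force_recount(self, rng):
        values = (rng.random((40, 200)) < 0.05).astype(int) * rng.integers(1, 50, (40, 200))
        table = make_table(values)
        filtered, _ = filter_prevalence(table, 0.1)
        survivors = {
            f for j, f in enumerate(table.feature_ids)
            if sum(1 for i in range(40) if values[i, j] > 0) / 40 >= 0.1
        }
        assert set(filtered.feature_ids) == survivors

    def test_samples_preserved(self, small_cohort):
        _, table, _, _ = small_cohort
        filtered, _ = filter_prevalence(table, 0.2)
        assert filtered.sample_ids == table.sample_ids


class TestContaminantFilter:
    @staticmethod
    def scores_for(rows):
        return pd.DataFrame(rows, index=pd.Index([r.pop("feature_id") for r in rows], name="feature_id"))

    def test_mean_environment_rule(self):
        table = make_table([[1, 1, 1]], features=["removed", "kept", "tie"])
        scores = pd.DataFrame(
            {
                "f_water": [0.9, 0.6, 0.5],
                "f_soil": [0.8, 0.3, 0.5],
                "f_mouse": [0.7, 0.3, 0.5],
                "f_human": [0.5, 0.5, 0.5],  # means: 0.8 > 0.5; 0.4 <= 0.5; 0.5 == 0.5 (tie kept)
            },
            index=pd.Index(["removed", "kept", "tie"], name="feature_id"),
        )
        filtered, report = filter_contaminants(table, scores)
        assert set(filtered.feature_ids) == {"kept", "tie"}
        assert report.removed == ("removed",)

    def test_unscored_features_kept_and_logged(self):
        table = make_table([[1, 1]], features=["scored", "unscored"])
        scores = pd.DataFrame(
            {"f_water": [0.1], "f_soil": [0.1], "f_mouse": [0.1], "f_human": [0.9]},
            index=pd.Index(["scored"], name="feature_id"),
        )
        filtered, report = filter_contaminants(table, scores)
        assert set(filtered.feature_ids) == {"scored", "unscored"}
        assert report.details["unscored"] == ("unscored",)


class TestRarefy:
    def test_rows_sum_exactly_to_depth(self, small_cohort):
        _, table, _, _ = small_cohort
        rare, _ = rarefy(table, 1000, seed=1)
        assert (rare.data.sum(axis=1) == 1000).all()

    def test_shallow_sample_dropped_and_reported(self):
        table = make_table([[50, 30], [500, 600]])
        rare, report = rarefy(table, 100, seed=0)
        assert rare.sample_ids == ["s1"]
        assert report.removed == ("s0",)

    def test_subsample_never_exceeds_original(self):
        table = make_table([[120, 3, 0, 77]])
        rare, _ = rarefy(table, 100, seed=5)
        assert (rare.data.to_numpy() <= table.data.to_numpy()).all()
        assert rare.data.to_numpy()[0, 2] == 0

    def test_seed_determinism(self, small_cohort):
        _, table, _, _ = small_cohort
        a, _ = rarefy(table, 800, seed=9)
        b, _ = rarefy(table, 800, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_depth_must_be_positive(self, toy_counts):
        with pytest.raises(TableError, match="depth"):
            rarefy(toy_counts, 0, seed=0)


class TestMetabolitePrep:
    def test_sum_normalization(self):
        table = make_table([[2.0, 3.0, 5.0]], kind="log")
        norm = normalize_metabolites(table)
        np.testing.assert_allclose(norm.data.to_numpy(), [[0.2, 0.3, 0.5]])
        assert norm.kind == "relative"

    def test_normalization_idempotent(self, rng):
        table = make_table(rng.random((5, 8)) + 0.1, kind="log")
        once = normalize_metabolites(table)
        twice = normalize_metabolites(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(TableError, match="s1"):
            normalize_metabolites(make_table([[1.0, 2.0], [0.0, 0.0]], kind="log"))

    def test_zero_replaced_by_fifth_of_minimum(self):
        table = make_table([[0.0], [5.0], [10.0]], kind="log")
        prepped = prep_metabolites_for_correlation(table)
        assert prepped.kind == "log"
        assert prepped.data.iloc[0, 0] == pytest.approx(np.log(1.0))  # 5/5 = 1 before log

    def test_outlier_clipped_to_four_sd(self, rng):
        base = np.exp(rng.normal(0, 0.1, size=200))
        col = np.append(base, np.exp(30.0))  # extreme outlier on the log scale
        table = make_table(col.reshape(-1, 1), kind="log")
        prepped = prep_metabolites_for_correlation(table)
        logged = np.log(col)
        bound = logged.mean() + 4 * logged.std(ddof=1)
        assert prepped.data.iloc[-1, 0] == pytest.approx(bound)

    def test_clean_column_equals_plain_log(self, rng):
        values = rng.random((30, 3)) + 0.5  # no zeros, no extreme outliers
        table = make_table(values, kind="log")
        prepped = prep_metabolites_for_correlation(table)
        np.testing.assert_allclose(prepped.data.to_numpy(), np.log(values))

    def test_all_zero_metabolite_rejected(self):
        with pytest.raises(TableError, match="f1"):
            prep_metabolites_for_correlation(make_table([[1.0, 0.0], [2.0, 0.0]], kind="log"))
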