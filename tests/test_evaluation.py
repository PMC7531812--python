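"""Metrics, date-error summaries, tuning, rate series and rasters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migdetect import (
    ConfusionCounts,
    GeneratorConfig,
    MigrationEvent,
    SegmentParams,
    active_users_by_month,
    adjudicate_labels,
    build_daily_presence,
    confusion_metrics,
    crossval_tune,
    date_error_summary,
    generate_cohort,
    make_grid,
    migration_rate_series,
    parameter_sweep,
    parse_text_raster,
    render_trajectory,
    score_binary,
    stratified_folds,
    text_raster,
)
from migdetect.evaluation import detect_cohort

from conftest import make_presence


class TestConfusionMetrics:
    def test_reference_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)
        assert not m.degenerate

    def test_degenerate_all_negative_flagged(self):
        m = confusion_metrics(ConfusionCounts(tn=10))
        assert m.accuracy == 1.0
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.degenerate

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, tn=5))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts())

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_identities(self, tp, fp, fn, tn):
        counts = ConfusionCounts(tp, fp, fn, tn)
        if counts.total == 0:
            return
        m = confusion_metrics(counts)
        assert m.accuracy * counts.total == pytest.approx(tp + tn)
        if m.precision > 0 and m.recall > 0:
            assert m.f1 == pytest.approx(
                2 / (1 / m.precision + 1 / m.recall)
            )  # harmonic mean
        for v in (m.accuracy, m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0


def test_score_binary_counts_missing_predictions_as_negative():
    counts = score_binary({"a": True}, {"a": True, "b": False, "c": True})
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 0, 1, 1)


def ev(user, day):
    return MigrationEvent(user, "A", "B", day, 0)


class TestDateErrorSummary:
    truth = pd.DataFrame(
        {"user_id": ["u1", "u2", "u3"], "is_migrant": [True, True, False],
         "true_migration_day": [100, 110, None]}
    )

    def test_exact_and_offset_errors(self):
        s = date_error_summary({"u1": [ev("u1", 100)], "u2": [ev("u2", 100)]}, self.truth)
        assert s.errors.tolist() == [0, 10]
        assert s.share_within == {2: 0.5, 15: 1.0}
        assert s.histogram().to_dict() == {0: 1, 10: 1}

    def test_unmatched_migrants_are_excluded(self):
        s = date_error_summary({"u1": [ev("u1", 101)]}, self.truth)
        assert s.n == 1 and s.share_within[2] == 1.0

    def test_no_matches_is_an_error(self):
        with pytest.raises(ValueError, match="no matched"):
            date_error_summary({}, self.truth)


def test_adjudication_majority_vote_and_median_date():
    table = pd.DataFrame(
        {
            "user_id": ["u1"] * 3 + ["u2"] * 3,
            "labeler_id": ["l1", "l2", "l3"] * 2,
            "is_migrant": [True, True, False, False, False, True],
            "migration_day": [100, 104, None, None, None, 50],
            "confidence": [3, 2, 1, 3, 3, 1],
        }
    )
    adj = adjudicate_labels(table).set_index("user_id")
    assert bool(adj.loc["u1", "is_migrant"]) and adj.loc["u1", "migration_day"] == 102
    assert not bool(adj.loc["u2", "is_migrant"])


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = GeneratorConfig(n_users=30, n_days=320, p_obs=1.0, p_noise=0.0, seed=3)
    records, truth = generate_cohort(cfg, {"migrant": 0.5, "stayer": 0.5})
    return build_daily_presence(records), truth


class TestParameterSweep:
    def test_singleton_grid_on_noiseless_cohort_is_perfect(self, tiny_cohort):
        presences, truth = tiny_cohort
        table = parameter_sweep(presences, truth, [SegmentParams(7, 30, 0.6)])
        assert table["f1"].tolist() == [1.0]

    def test_all_f1_in_unit_interval(self, small_cohort):
        grid = make_grid([3, 7], [30, 60], [0.4, 0.8])
        table = parameter_sweep(small_cohort["presences"], small_cohort["truth"], grid)
        assert len(table) == 8
        assert ((table["f1"] >= 0) & (table["f1"] <= 1)).all()

    def test_sparse_cohort_punishes_extreme_prop_days(self):
        """At 30% daily observation, requiring presence on 95% of a
        segment's days starves segment formation, so F1 cannot beat the
        moderate 0.6 setting."""
        cfg = GeneratorConfig(n_users=60, n_days=400, p_obs=0.3, p_noise=0.0, seed=17)
        records, truth = generate_cohort(cfg, {"migrant": 0.5, "stayer": 0.5})
        presences = build_daily_presence(records)
        table = parameter_sweep(
            presences, truth,
            [SegmentParams(7, 30, 0.6), SegmentParams(7, 30, 0.95)],
        )
        f1_mid, f1_high = table["f1"].tolist()
        assert f1_high <= f1_mid

    def test_empty_grid_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            parameter_sweep(*tiny_cohort, grid=[])


class TestCrossval:
    def samples(self, truth):
        df = truth[["user_id", "is_migrant"]].copy()
        df["group"] = ["g" + str(i % 2) for i in range(len(df))]
        return df

    def test_noiseless_singleton_grid_perfect_train_and_test(self, tiny_cohort):
        presences, truth = tiny_cohort
        res = crossval_tune(presences, self.samples(truth), [SegmentParams(7, 30, 0.6)])
        assert res.mean_train_f1 == 1.0 and res.mean_test_f1 == 1.0
        assert res.best_params == SegmentParams(7, 30, 0.6)

    def test_stratified_folds_balanced_and_exhaustive(self, tiny_cohort):
        _, truth = tiny_cohort
        samples = self.samples(truth)
        folds = stratified_folds(samples, n_folds=5, seed=0)
        assert set(folds) == set(samples["user_id"])
        for g, grp in samples.groupby("group"):
            sizes = pd.Series([folds[u] for u in grp["user_id"]]).value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_fold_assignment_deterministic_under_seed(self, tiny_cohort):
        _, truth = tiny_cohort
        samples = self.samples(truth)
        assert stratified_folds(samples, 5, seed=7) == stratified_folds(samples, 5, seed=7)
        assert stratified_folds(samples, 5, seed=7) != stratified_folds(samples, 5, seed=8)

    def test_too_small_stratum_rejected(self):
        samples = pd.DataFrame(
            {"user_id": ["a", "b", "c"], "is_migrant": [True, False, True],
             "group": ["g1", "g1", "g2"]}
        )
        with pytest.raises(ValueError, match="stratum"):
            stratified_folds(samples, n_folds=2)


class TestMigrationRateSeries:
    def test_rate_arithmetic_and_missing_months(self):
        months = {pd.Period("1970-01", "M"): 100, pd.Period("1970-02", "M"): 0}
        events = [ev("u1", 5), ev("u2", 20)]  # both in Jan 1970
        series = migration_rate_series(events, months)
        assert series[pd.Period("1970-01", "M")] == pytest.approx(0.02)
        assert np.isnan(series[pd.Period("1970-02", "M")])

    def test_active_user_counting(self):
        presences = {
            "u1": make_presence("u1", {"A": [0, 40]}),
            "u2": make_presence("u2", {"B": [1]}),
        }
        counts = active_users_by_month(presences)
        assert counts[pd.Period("1970-01", "M")] == 2
        assert counts[pd.Period("1970-02", "M")] == 1


class TestTrajectoryRaster:
    def test_text_raster_complementary_rows(self):
        pres = make_presence("u9", {"A": [1, 2, 3, 4, 5], "B": [6, 7, 8, 9, 10]})
        text = text_raster(pres)
        lines = text.splitlines()
        assert lines[0] == "user u9" and lines[1] == "days 1 10"
        assert lines[2] == "A |#####.....|"
        assert lines[3] == "B |.....#####|"

    def test_round_trip_through_text(self):
        rng = np.random.default_rng(12)
        pres = make_presence(
            "u", {f"L{i}": sorted({int(d) for d in rng.integers(0, 50, 20)}) for i in range(3)}
        )
        back = parse_text_raster(text_raster(pres))
        assert back.user_id == pres.user_id and back.presence == pres.presence

    def test_event_marker_column(self):
        pres = make_presence("u", {"A": [1, 2, 3], "B": [4, 5, 6]})
        text = text_raster(pres, events=[ev("u", 3)])
        marker = text.splitlines()[-1]
        assert marker.count("^") == 1
        assert marker.split("|")[1].index("^") == 2  # day 3 in window [1, 6]
        assert parse_text_raster(text).presence == pres.presence

    def test_empty_presence_rejected(self):
        from migdetect import DailyPresence

        with pytest.raises(ValueError):
            text_raster(DailyPresence("u", {}))

    def test_render_figure_smoke(self, tmp_path):
        pres = make_presence("u", {"A": list(range(0, 30)), "B": list(range(30, 60))})
        from migdetect.segments import Segment

        segs = [Segment("u", "A", 0, 29, tuple(range(0, 30)))]
        out = tmp_path / "traj.png"
        fig = render_trajectory(pres, segments=segs, events=[ev("u", 29)], out=str(out))
        assert out.exists() and out.stat().st_size > 0
        assert len(fig.axes) == 1
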