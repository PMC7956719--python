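import numpy as np
import pandas as pd
import pytest

from ecgauth import (ConfusionCounts, DriftSpec, ProtocolConfig,
                     compute_metrics, extract_cohort_features, generate_cohort,
                     run_batch_baseline, run_incremental_protocol,
                     run_template_baseline, timing_benchmark)
from ecgauth.authpipe import MetricUndefinedError, majority_vote
from ecgauth.isvm import batch_qp_oracle


class TestMetrics:
    def test_textbook_confusion_table(self):
        acc, far, tar = compute_metrics(ConfusionCounts(TP=90, FP=6, TN=94, FN=10))
        assert (acc, far, tar) == (92.0, 6.0, 90.0)

    def test_no_false_accepts_gives_zero_far(self):
        _, far, _ = compute_metrics(ConfusionCounts(TP=5, FP=0, TN=10, FN=5))
        assert far == 0.0

    def test_no_true_accepts_gives_zero_tar(self):
        _, _, tar = compute_metrics(ConfusionCounts(TP=0, FP=1, TN=10, FN=7))
        assert tar == 0.0

    def test_missing_negatives_flagged(self):
        with pytest.raises(MetricUndefinedError):
            compute_metrics(ConfusionCounts(TP=5, FP=0, TN=0, FN=5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)

    def test_rate_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 200, 4)
            c = ConfusionCounts(TP=int(tp), FP=int(fp), TN=int(tn), FN=int(fn))
            _, far, tar = compute_metrics(c)
            fnr = 100.0 * c.FN / (c.TP + c.FN)
            tnr = 100.0 * c.TN / (c.TN + c.FP)
            assert tar + fnr == pytest.approx(100.0)
            assert far + tnr == pytest.approx(100.0)


@pytest.fixture(scope="module")
def result(small_cohort_table):
    return run_incremental_protocol(small_cohort_table, seed=1)


class TestIncrementalProtocol:
    def test_report_covers_all_subjects_and_stages(self, result, small_cohort_table):
        subjects = small_cohort_table["subject"].nunique()
        assert len(result.report) == subjects * 5 * 2  # 5 stages x 2 schedules

    def test_beat_conservation(self, result, small_cohort_table):
        for _, row in result.report.iterrows():
            n_beats = (small_cohort_table["day"] == row["test_day"]).sum()
            assert row[["TP", "FP", "TN", "FN"]].sum() == n_beats

    def test_final_models_satisfy_kkt(self, result):
        for model in result.models.values():
            rep = model.audit()
            assert rep.ok, str(rep)

    def test_reproducible(self, result, small_cohort_table):
        again = run_incremental_protocol(small_cohort_table, seed=1)
        pd.testing.assert_frame_equal(result.report, again.report)

    def test_set_sizes_logged_per_stage(self, result):
        assert set(result.set_sizes.columns) == {"subject", "stage", "R", "S", "E"}
        assert (result.set_sizes.groupby("subject").size() == 5).all()

    def test_single_subject_cohort_rejected(self, small_cohort_table):
        solo = small_cohort_table[small_cohort_table["subject"] == "S01"]
        with pytest.raises(ValueError):
            run_incremental_protocol(solo, seed=0)

    def test_missing_day_rejected(self, small_cohort_table):
        partial = small_cohort_table[small_cohort_table["day"] != 3]
        with pytest.raises(ValueError, match="missing"):
            run_incremental_protocol(partial, seed=0)


class TestNoDriftControl:
    def test_stage_tar_stable_without_drift(self):
        recs = generate_cohort(n_subjects=3, n_days=6, minutes=0.7, seed=21,
                               drift=DriftSpec.none())
        table = extract_cohort_features(recs)
        res = run_incremental_protocol(table, seed=2)
        day6 = res.report[res.report["schedule"] == "day6"]
        tar = day6.groupby("stage")["TAR"].mean()
        assert np.max(np.abs(np.diff(tar.to_numpy()))) < 3.0


class TestBatchBaseline:
    def test_day1_batch_equals_day1_incremental(self, small_cohort_table):
        inc = run_incremental_protocol(small_cohort_table, seed=3)
        bat = run_batch_baseline(small_cohort_table, seed=3, train_through_day=1)
        inc1 = inc.report[(inc.report["stage"] == 1)
                          & (inc.report["schedule"] == "day6")]
        assert abs(inc1["ACC"].mean() - bat.report["ACC"].mean()) <= 0.5

    def test_repeated_runs_identical(self, small_cohort_table):
        a = run_batch_baseline(small_cohort_table, seed=4)
        b = run_batch_baseline(small_cohort_table, seed=4)
        pd.testing.assert_frame_equal(a.report, b.report)


class TestTemplateBaseline:
    def test_zero_update_rate_is_static(self, small_cohort_table):
        cfg = ProtocolConfig(template_update_rate=0.0)
        a = run_template_baseline(small_cohort_table, cfg, seed=5)
        b = run_template_baseline(small_cohort_table, cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_huge_threshold_accepts_everything(self, small_cohort_table):
        cfg = ProtocolConfig(template_threshold=1e9)
        rep = run_template_baseline(small_cohort_table, cfg, seed=6)
        assert np.allclose(rep["FAR"], 100.0)
        assert np.allclose(rep["TAR"], 100.0)


class TestTiming:
    def test_schema_and_zero_adds(self, two_gaussians):
        X, y = two_gaussians(200, seed=15, spread=1.5)
        model = batch_qp_oracle(X, y)
        Xn, yn = two_gaussians(10, seed=16, spread=1.5)
        out = timing_benchmark(model, Xn, yn, n_added=(0, 5))
        assert list(out.columns) == ["n_added", "t_incremental_s", "t_batch_s"]
        assert out.iloc[0][["t_incremental_s", "t_batch_s"]].sum() == 0.0
        assert (out.iloc[1][["t_incremental_s", "t_batch_s"]] > 0).all()


class TestVote:
    def test_window_one_is_identity(self):
        acc = np.array([True, False, True])
        assert np.array_equal(majority_vote(acc, 1), acc)

    def test_majority_smooths_isolated_flip(self):
        acc = np.array([True, True, False, True, True])
        assert majority_vote(acc, 3).all()
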