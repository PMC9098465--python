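"""Fold construction, accuracy measures, and the CV driver contract."""

import numpy as np
import pandas as pd
import pytest

from maltpred import (
    MBLUPPredictor,
    accuracy_line_mean,
    accuracy_plot,
    make_folds,
    run_cv,
    summarize_replicates,
)


def toy_meta(n_lines=3, plots_per_line=2, n_locations=2):
    rows = []
    k = 0
    for i in range(n_lines):
        for j in range(plots_per_line):
            rows.append(
                {
                    "plot_id": f"P{k:03d}",
                    "line_id": f"L{i}",
                    "location": f"Loc{j % n_locations}",
                    "year": 2014,
                    "trial": "T1",
                }
            )
            k += 1
    return pd.DataFrame(rows)


class TestMakeFolds:
    def test_line_strategy_partitions_by_line(self):
        meta = toy_meta(n_lines=3, plots_per_line=2)
        plan = make_folds("LINE", meta)
        assert len(plan.folds) == 3
        for fold in plan.folds:
            line = fold.fold_id.split("_")[1]
            expected = set(meta.loc[meta["line_id"] == line, "plot_id"])
            assert set(fold.val_ids) == expected
            assert set(fold.train_ids) == set(meta["plot_id"]) - expected
        # validation sets partition all plots
        all_val = [p for f in plan.folds for p in f.val_ids]
        assert sorted(all_val) == sorted(meta["plot_id"])

    def test_loc_strategy_partitions_by_location(self):
        meta = toy_meta(n_lines=4, plots_per_line=2)
        plan = make_folds("LOC", meta)
        assert len(plan.folds) == 2
        all_val = [p for f in plan.folds for p in f.val_ids]
        assert sorted(all_val) == sorted(meta["plot_id"])

    def test_size_strategy_sizes_and_disjointness(self):
        meta = toy_meta(n_lines=50, plots_per_line=2)  # 100 plots
        plan = make_folds("SIZE", meta, tp_size=50, n_replicates=4, seed=0)
        for fold in plan.folds:
            assert len(fold.train_ids) == 50
            assert len(fold.val_ids) == 50
            assert not set(fold.train_ids) & set(fold.val_ids)

    def test_size_deterministic_and_seed_sensitive(self):
        meta = toy_meta(n_lines=30, plots_per_line=2)
        a = make_folds("SIZE", meta, tp_size=20, n_replicates=15, seed=11)
        b = make_folds("SIZE", meta, tp_size=20, n_replicates=15, seed=11)
        c = make_folds("SIZE", meta, tp_size=20, n_replicates=15, seed=12)
        assert all(
            fa.train_ids == fb.train_ids for fa, fb in zip(a.folds, b.folds)
        )
        assert any(
            fa.train_ids != fc.train_ids for fa, fc in zip(a.folds, c.folds)
        )

    def test_invalid_requests_rejected(self):
        meta = toy_meta()
        with pytest.raises(ValueError):
            make_folds("SIZE", meta, tp_size=len(meta))
        with pytest.raises(ValueError):
            make_folds("BOGUS", meta)
        with pytest.raises(ValueError):
            make_folds("LINE", toy_meta(n_lines=1))


class TestAccuracies:
    def test_perfect_and_anti_perfect(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert accuracy_plot(obs, obs) == pytest.approx(1.0)
        assert accuracy_plot(obs, -obs) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        assert accuracy_plot([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(accuracy_plot([1, 2, 3], [5, 5, 5]))

    def test_line_mean_degenerates_to_plot_accuracy(self, rng):
        obs = rng.normal(size=6)
        pred = rng.normal(size=6)
        lines = [f"L{i}" for i in range(6)]  # one plot per line
        assert accuracy_line_mean(obs, pred, lines) == pytest.approx(
            accuracy_plot(obs, pred)
        )

    def test_identical_line_means_give_one(self, rng):
        lines = np.repeat([f"L{i}" for i in range(4)], 3)
        means = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        obs = means + rng.normal(0, 0.1, 12)
        pred = means + rng.normal(0, 0.1, 12)
        # force exact equality of within-line means
        for l in np.unique(lines):
            sel = lines == l
            obs[sel] += means[sel][0] - obs[sel].mean()
            pred[sel] += means[sel][0] - pred[sel].mean()
        assert accuracy_line_mean(obs, pred, lines) == pytest.approx(1.0)

    def test_line_mean_matches_two_step_recomputation(self, rng):
        lines = np.repeat([f"L{i}" for i in range(5)], 3)
        obs = rng.normal(size=15)
        pred = rng.normal(size=15)
        got = accuracy_line_mean(obs, pred, lines)
        mo = [obs[lines == l].mean() for l in sorted(set(lines))]
        mp = [pred[lines == l].mean() for l in sorted(set(lines))]
        assert got == pytest.approx(np.corrcoef(mo, mp)[0, 1], abs=1e-12)

    def test_fewer_than_three_lines_flagged(self, rng):
        assert np.isnan(
            accuracy_line_mean(rng.normal(size=4), rng.normal(size=4), ["A", "A", "B", "B"])
        )


class TestSummarizeReplicates:
    def test_constant_replicates(self):
        mean, sd, n = summarize_replicates([0.8, 0.8, 0.8])
        assert (mean, sd, n) == (pytest.approx(0.8), pytest.approx(0.0), 3)

    def test_two_replicates_hand_value(self):
        mean, sd, _ = summarize_replicates([0.7, 0.9])
        assert mean == pytest.approx(0.8)
        assert sd == pytest.approx(np.sqrt(0.02), abs=1e-12)  # ~0.1414

    def test_matches_numpy_recomputation(self, rng):
        accs = rng.uniform(0, 1, size=9).tolist()
        mean, sd, n = summarize_replicates(accs)
        assert mean == pytest.approx(np.mean(accs), abs=1e-15)
        assert sd == pytest.approx(np.std(accs, ddof=1), abs=1e-15)
        assert n == 9

    def test_single_replicate_spread_missing(self):
        mean, sd, n = summarize_replicates([0.6])
        assert mean == pytest.approx(0.6)
        assert np.isnan(sd) and n == 1


class _TrainMeanPredictor:
    name = "train-mean stub"

    def fit_predict(self, y, train_ids, val_ids):
        return np.full(len(val_ids), y.loc[train_ids].mean())


class TestRunCV:
    def test_stub_predictor_returns_fold_training_mean(self):
        meta = toy_meta(n_lines=6, plots_per_line=2)
        y = pd.Series(
            np.arange(len(meta), dtype=float), index=meta["plot_id"].tolist()
        )
        plan = make_folds("LINE", meta)
        res = run_cv(y, meta, plan, _TrainMeanPredictor())
        for fold in plan.folds:
            expected = y.loc[fold.train_ids].mean()
            got = res.predictions.loc[
                res.predictions["fold"] == fold.fold_id, "predicted"
            ]
            assert np.allclose(got, expected)

    def test_identical_partitions_for_both_predictor_families(self, small_dataset,
                                                              small_standardized,
                                                              small_kernel):
        from maltpred import PLSRPredictor

        Q, _ = small_standardized
        y = small_dataset.phenotypes.set_index("plot_id")["WC"]
        plan = make_folds("SIZE", small_dataset.meta, tp_size=40, n_replicates=2, seed=5)
        r1 = run_cv(y, small_dataset.meta, plan, MBLUPPredictor(small_kernel))
        r2 = run_cv(y, small_dataset.meta, plan, PLSRPredictor(Q, n_components=10))
        a = r1.predictions[["plot_id", "fold"]].sort_values(["fold", "plot_id"])
        b = r2.predictions[["plot_id", "fold"]].sort_values(["fold", "plot_id"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_line_and_loc_pool_every_plot_exactly_once(self, small_dataset, small_kernel):
        y = small_dataset.phenotypes.set_index("plot_id")["BG"]
        for strategy in ("LINE", "LOC"):
            plan = make_folds(strategy, small_dataset.meta)
            res = run_cv(y, small_dataset.meta, plan, MBLUPPredictor(small_kernel))
            assert sorted(res.predictions["plot_id"]) == sorted(
                small_dataset.meta["plot_id"]
            )
            assert np.isfinite(res.pooled_plot_accuracy)
            assert np.isfinite(res.pooled_line_mean_accuracy)

    def test_failed_fold_logged_not_fatal(self):
        meta = toy_meta(n_lines=5, plots_per_line=2)
        y = pd.Series(np.arange(10.0), index=meta["plot_id"].tolist())

        class Flaky:
            name = "flaky"

            def fit_predict(self, y, train_ids, val_ids):
                if "P000" in val_ids:
                    raise RuntimeError("boom")
                return np.zeros(len(val_ids))

        plan = make_folds("LINE", meta)
        res = run_cv(y, meta, plan, Flaky())
        assert res.failed_folds == ["line_L0"]
        assert set(res.predictions["fold"]) == {f"line_L{i}" for i in range(1, 5)}

    def test_missing_phenotypes_excluded_per_trait(self, small_dataset, small_kernel):
        y = small_dataset.phenotypes.set_index("plot_id")["WV"].copy()
        y.iloc[0] = np.nan
        plan = make_folds("LOC", small_dataset.meta)
        res = run_cv(y, small_dataset.meta, plan, MBLUPPredictor(small_kernel))
        assert len(res.predictions) == len(y) - 1
        assert y.index[0] not in set(res.predictions["plot_id"])
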