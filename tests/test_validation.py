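"""Error statistics, cross-validation protocols and significance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forestagb import (ConfigError, ModelConfig, compare_to_baseline,
                       cross_predict, ecdf, error_stats, fit, loocv_predict,
                       predict, run_design)
from forestagb.presets import PRESETS
from forestagb.synthetic import make_metric_table
from forestagb.validation import regime_replication


class TestErrorStats:
    def test_perfect_prediction(self):
        es = error_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert es.rmse == 0 and es.d == 0 and es.r2 == pytest.approx(1.0)

    def test_constant_shift(self):
        es = error_stats(np.array([10.0, 20.0]) + 7.0, [10.0, 20.0])
        assert es.d == pytest.approx(7.0)
        assert es.rmse == pytest.approx(7.0)

    def test_three_point_worked_example(self):
        es = error_stats([110.0, 190.0, 330.0], [100.0, 200.0, 300.0])
        assert es.d == pytest.approx(10.0)
        assert es.mean_reference == pytest.approx(200.0)
        assert es.d_pct == pytest.approx(5.0)
        assert es.rmse == pytest.approx(np.sqrt(1100 / 3), rel=1e-9)
        assert es.rmse_pct == pytest.approx(100 * np.sqrt(1100 / 3) / 200,
                                            rel=1e-9)

    def test_rmse_bounds_mean_difference(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 30)
            pred = rng.normal(200, 80, n)
            truth = np.abs(rng.normal(200, 80, n)) + 1.0
            es = error_stats(pred, truth)
            assert es.rmse >= abs(es.d)

    def test_relative_forms_scale_invariant(self, rng):
        pred = rng.uniform(50, 400, 25)
        truth = rng.uniform(50, 400, 25)
        a = error_stats(pred, truth)
        b = error_stats(3.7 * pred, 3.7 * truth)
        assert b.rmse_pct == pytest.approx(a.rmse_pct)
        assert b.d_pct == pytest.approx(a.d_pct)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            error_stats([1.0], [1.0, 2.0])

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ConfigError):
            error_stats([1.0, -1.0], [1.0, -1.0])


class TestLoocv:
    def test_exact_linear_signal_recovered(self, linear_dataset):
        cfg = ModelConfig(explanation_ratio=1.0, tau=1e8)
        preds = loocv_predict(linear_dataset, cfg)
        np.testing.assert_allclose(preds, linear_dataset["agb"], rtol=1e-6)

    def test_matches_brute_force_refits(self):
        gen = np.random.default_rng(5)
        table = pd.DataFrame({
            "plot_id": list("abcde"),
            "agb": gen.uniform(100, 300, 5),
            "f1": gen.normal(size=5), "f2": gen.normal(size=5),
        })
        cfg = ModelConfig()
        preds = loocv_predict(table, cfg)
        for i in range(5):
            rest = table.drop(index=i)
            m = fit(rest[["f1", "f2"]], rest["agb"], cfg)
            expect = predict(m, table.iloc[[i]][["f1", "f2"]])[0]
            assert preds[i] == pytest.approx(expect)

    def test_invariant_to_row_order(self, linear_dataset):
        perm = np.random.default_rng(1).permutation(len(linear_dataset))
        shuffled = linear_dataset.iloc[perm].reset_index(drop=True)
        a = loocv_predict(linear_dataset)
        b = loocv_predict(shuffled)
        np.testing.assert_allclose(b, a[perm])

    def test_minimum_size_enforced(self, linear_dataset):
        with pytest.raises(ConfigError):
            loocv_predict(linear_dataset.head(2))


class TestCrossPredict:
    def test_self_validation_equals_loocv(self, linear_dataset):
        cfg = ModelConfig()
        np.testing.assert_allclose(
            cross_predict(linear_dataset, linear_dataset, cfg),
            loocv_predict(linear_dataset, cfg))

    def test_combined_training_uses_loocv_per_plot(self, linear_dataset):
        # validation plots inside the training set never predict themselves
        other = linear_dataset.copy()
        other["plot_id"] = [f"q{i}" for i in range(len(other))]
        combined = pd.concat([linear_dataset, other], ignore_index=True)
        cfg = ModelConfig()
        got = cross_predict(combined, linear_dataset, cfg)
        loo = loocv_predict(combined, cfg)
        np.testing.assert_allclose(got, loo[:len(linear_dataset)])

    def test_disjoint_sets_with_exact_signal(self, linear_dataset):
        cfg = ModelConfig(explanation_ratio=1.0, tau=1e8)
        train = linear_dataset.iloc[:25]
        valid = linear_dataset.iloc[25:].assign(
            plot_id=lambda d: "v" + d["plot_id"])
        preds = cross_predict(train, valid, cfg)
        np.testing.assert_allclose(preds, valid["agb"], rtol=1e-6)

    def test_weak_signal_cross_bias_is_training_mean_offset(self):
        # with uncorrelated predictors, predictions collapse to the training
        # mean, so D ~ mean(train) - mean(valid)
        gen = np.random.default_rng(8)
        n = 400
        train = pd.DataFrame({"plot_id": [f"t{i}" for i in range(n)],
                              "agb": gen.gamma(4, 60, n),
                              "f1": gen.normal(size=n),
                              "f2": gen.normal(size=n)})
        valid = pd.DataFrame({"plot_id": [f"v{i}" for i in range(n)],
                              "agb": gen.gamma(4, 80, n),
                              "f1": gen.normal(size=n),
                              "f2": gen.normal(size=n)})
        preds = cross_predict(train, valid, ModelConfig(tau=1.0))
        es = error_stats(preds, valid["agb"].to_numpy())
        offset = train["agb"].mean() - valid["agb"].mean()
        assert es.d == pytest.approx(offset, abs=0.15 * valid["agb"].std())

    def test_empty_sets_rejected(self, linear_dataset):
        with pytest.raises(ConfigError):
            cross_predict(linear_dataset.head(0), linear_dataset)


class TestCompareToBaseline:
    def test_identical_vectors_give_p_one(self, rng):
        err = rng.normal(0, 10, 40)
        t_res, f_res = compare_to_baseline(err, err)
        assert t_res.p_value == 1.0
        assert f_res.p_value == pytest.approx(1.0)
        assert not t_res.significant_at_5pct

    def test_pure_mean_shift_detected_by_t_not_f(self, rng):
        base = rng.normal(0, 10, 500)
        t_res, f_res = compare_to_baseline(base, base + 5.0)
        assert t_res.p_value < 0.05
        assert f_res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        a = rng.normal(0, 8, 31)
        b = rng.normal(3, 12, 44)
        t_res, f_res = compare_to_baseline(a, b)
        # Welch t with Welch-Satterthwaite degrees of freedom
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / a.size + vb / b.size
        t_stat = (b.mean() - a.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((va / a.size) ** 2 / (a.size - 1)
                         + (vb / b.size) ** 2 / (b.size - 1))
        assert t_res.statistic == pytest.approx(t_stat)
        assert t_res.p_value == pytest.approx(2 * stats.t.sf(abs(t_stat), df))
        # variance-ratio F, two-sided
        f_stat = vb / va
        p = 2 * min(stats.f.cdf(f_stat, b.size - 1, a.size - 1),
                    stats.f.sf(f_stat, b.size - 1, a.size - 1))
        assert f_res.statistic == pytest.approx(f_stat)
        assert f_res.p_value == pytest.approx(p)

    def test_type_i_error_near_nominal_level(self):
        gen = np.random.default_rng(123)
        hits = 0
        reps = 2000
        for _ in range(reps):
            t_res, _ = compare_to_baseline(gen.normal(0, 1, 50),
                                           gen.normal(0, 1, 50))
            hits += t_res.significant_at_5pct
        assert 0.03 <= hits / reps <= 0.07

    def test_degenerate_vectors_rejected(self):
        with pytest.raises(ConfigError):
            compare_to_baseline([1.0, 1.0], [1.0, 2.0])


class TestRunDesign:
    def _dataset(self, n_comm=40, n_prof=20, seed=0):
        comm = make_metric_table(PRESETS["GorkhaComm"], n_comm, seed=seed)
        prof = make_metric_table(PRESETS["GorkhaProf"], n_prof, seed=seed + 1)
        return pd.concat([comm.assign(team="Comm"), prof.assign(team="Prof")],
                         ignore_index=True)

    def test_grid_shape_and_baseline_rows(self):
        design = run_design(self._dataset())
        assert len(design) == 6
        assert design["baseline"].sum() == 2
        base = design[design["baseline"]]
        assert base["t_test_p"].isna().all()

    def test_self_rows_equal_manual_loocv_composition(self):
        data = self._dataset()
        design = run_design(data)
        comm = data[data["team"] == "Comm"].reset_index(drop=True)
        preds = loocv_predict(comm)
        es = error_stats(preds, comm["agb"].to_numpy())
        row = design[(design["validation_set"] == "Comm")
                     & design["baseline"]].iloc[0]
        assert row["rmse_pct"] == pytest.approx(es.rmse_pct)
        assert row["bias_pct"] == pytest.approx(es.d_pct)

    def test_identical_subsets_collapse_to_baseline(self):
        comm = make_metric_table(PRESETS["GorkhaComm"], 30, seed=3)
        data = pd.concat([comm.assign(team="Comm"), comm.assign(team="Prof")],
                         ignore_index=True)
        design = run_design(data)
        for vteam in ("Comm", "Prof"):
            grp = design[design["validation_set"] == vteam]
            base = grp[grp["baseline"]].iloc[0]
            cross = grp[grp["training_set"].isin(["Comm", "Prof"])
                        & ~grp["baseline"]].iloc[0]
            # the cross source holds exactly the same plots: LOOCV agrees
            # exactly and the tests cannot distinguish the error vectors
            assert cross["rmse_pct"] == base["rmse_pct"]
            assert cross["t_test_p"] == 1.0
            # the combined set duplicates every plot; leave-plot-out fits
            # see the same 29 unique plots, so the row agrees closely (the
            # doubled row count only perturbs the shrinkage strength)
            comb = grp[~grp["training_set"].isin(["Comm", "Prof"])].iloc[0]
            assert comb["rmse_pct"] == pytest.approx(base["rmse_pct"],
                                                     rel=0.02)
            assert comb["t_test_p"] > 0.9

    def test_tiny_team_rejected(self):
        data = self._dataset(n_prof=3).iloc[:-1]
        with pytest.raises(ConfigError):
            run_design(data)


class TestEcdf:
    def test_single_value_step(self):
        f = ecdf([5.0])
        assert f(4.999) == 0.0 and f(5.0) == 1.0

    def test_extremes(self, rng):
        vals = rng.uniform(0, 100, 50)
        f = ecdf(vals)
        assert f(vals.max()) == 1.0
        assert f(vals.min() - 1e-9) == 0.0

    def test_counting_example(self):
        assert ecdf([100.0, 200.0, 300.0])(250.0) == pytest.approx(2 / 3)

    def test_report_table_grid(self):
        table = ecdf([5.0, 25.0]).table(step=10.0)
        assert table["agb"].tolist() == [0.0, 10.0, 20.0, 30.0]
        assert table["cdf"].tolist() == [0.0, 0.5, 0.5, 1.0]

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            ecdf([])


class TestRegimeReplication:
    def test_single_replicate_rates_are_zero_or_one(self):
        p = PRESETS["GorkhaProf"]
        rates = regime_replication(p, p, 20, 10, n_reps=1, seed=2)
        for cell in rates.values():
            assert cell["t_significance_rate"] in (0.0, 1.0)
            assert cell["n_reps"] == 1

    def test_identical_presets_hold_nominal_level(self):
        # same regime for both teams: t significance ~ the 5 % level
        p = PRESETS["GorkhaProf"]
        rates = regime_replication(p, p, 40, 40, n_reps=60, seed=4)
        for cell in rates.values():
            assert cell["t_significance_rate"] <= 0.15
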