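import numpy as np
import pytest

from mixbalance import simulation as sim
from mixbalance.el import ELConvergenceError
from mixbalance.simulation import (
    SimulationSetting,
    make_dataset,
    run_replicate,
    run_simulation,
    simulate_covariates,
    simulate_exposures,
    simulate_outcome,
    summarize,
)


class TestCovariates:
    def test_large_sample_moments(self):
        rng = np.random.default_rng(1)
        X = simulate_covariates(100_000, rng)
        cont = X[:, [0, 2, 3, 4, 5]]
        var = cont.var(axis=0)
        assert np.all((var > 0.99) & (var < 1.01))
        cov = np.cov(cont, rowvar=False)
        off = cov[~np.eye(5, dtype=bool)]
        assert np.all((off > 0.18) & (off < 0.22))
        assert 0.494 < X[:, 1].mean() < 0.506
        assert set(np.unique(X[:, 1])) == {0.0, 1.0}
        # the binary covariate is independent of the normal block
        assert np.abs(np.corrcoef(X[:, 1], X[:, 0])[0, 1]) < 0.02

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_covariates(50, np.random.default_rng(7))
        b = simulate_covariates(50, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_single_row(self):
        assert simulate_covariates(1, np.random.default_rng(0)).shape == (1, 6)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            simulate_covariates(0, np.random.default_rng(0))


class TestExposures:
    def test_noiseless_linear_model_reads_coefficients(self):
        rng = np.random.default_rng(2)
        X = simulate_covariates(100, rng)
        T = simulate_exposures(X, "E1", 0.2, rng, noise_scale=0.0)
        assert np.allclose(T[:, 2], X[:, 0])  # third exposure loads on X1 only
        assert np.allclose(T[:, 0], X[:, [0, 1, 3, 4]].sum(axis=1))
        assert np.allclose(T[:, 1], X[:, [0, 2, 3, 5]].sum(axis=1))

    def test_quadratic_model_adds_x1_squared_to_every_exposure(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        X = simulate_covariates(80, np.random.default_rng(4))
        t1 = simulate_exposures(X, "E1", 0.5, rng1)
        t2 = simulate_exposures(X, "E2", 0.5, rng2)
        for k in range(3):
            assert np.allclose(t2[:, k] - t1[:, k], X[:, 0] ** 2, atol=1e-12)

    def test_residual_correlation_matches_trho(self):
        rng = np.random.default_rng(5)
        X = simulate_covariates(100_000, rng)
        T = simulate_exposures(X, "E1", 0.5, rng)
        resid = T - X @ sim.ALPHA1.T
        corr = np.corrcoef(resid, rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all((off > 0.49) & (off < 0.51))

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="6 columns"):
            simulate_exposures(np.zeros((5, 4)), "E1", 0.2, rng)
        with pytest.raises(ValueError, match="unknown exposure model"):
            simulate_exposures(np.zeros((5, 6)), "E9", 0.2, rng)


class TestOutcome:
    def test_pointwise_arithmetic(self):
        T = np.array([[1.0, 1.0, 1.0]])
        X = np.zeros((1, 6))
        y = simulate_outcome(T, X, "Y1", np.random.default_rng(0), noise_scale=0.0)
        assert np.isclose(y[0], 0.6 - 0.5 + 0.8)

    def test_interaction_and_quadratic_increments(self):
        rng = np.random.default_rng(6)
        X = simulate_covariates(60, rng)
        T = simulate_exposures(X, "E1", 0.2, rng)
        kw = dict(rng=np.random.default_rng(0), noise_scale=0.0)
        y1 = simulate_outcome(T, X, "Y1", **kw)
        y2 = simulate_outcome(T, X, "Y2", **kw)
        y3 = simulate_outcome(T, X, "Y3", **kw)
        y4 = simulate_outcome(T, X, "Y4", **kw)
        assert np.allclose(y2 - y1, 0.2 * T[:, 0] * T[:, 2])
        assert np.allclose(y3 - y1, X[:, 0] ** 2)
        assert np.allclose(y4 - y2, X[:, 0] ** 2)

    def test_unknown_model_code(self):
        with pytest.raises(ValueError, match="unknown outcome model"):
            simulate_outcome(np.zeros((2, 3)), np.zeros((2, 6)), "Y9", np.random.default_rng(0))


class TestSetting:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationSetting("E3", "Y1")
        with pytest.raises(ValueError):
            SimulationSetting("E1", "Y1", trho=0.99999, n=0)
        with pytest.raises(ValueError, match="positive definite|trho"):
            SimulationSetting("E1", "Y1", trho=-0.6)
        with pytest.raises(ValueError, match="unknown methods"):
            SimulationSetting("E1", "Y1", methods=("magic",))

    def test_truth_includes_interaction_only_for_y2_y4(self):
        assert "T1:T3" not in SimulationSetting("E1", "Y1").truth
        assert SimulationSetting("E1", "Y4").truth["T1:T3"] == 0.2

    def test_replicate_seeds_differ_by_setting_and_rep(self):
        s1 = SimulationSetting("E1", "Y1", n=200, seed=1)
        s2 = SimulationSetting("E1", "Y2", n=200, seed=1)
        assert s1.replicate_seed(0).entropy != s1.replicate_seed(1).entropy
        assert s1.replicate_seed(0).entropy != s2.replicate_seed(0).entropy


class TestReplicates:
    def test_replicate_is_deterministic(self):
        setting = SimulationSetting("E1", "Y1", n=200, reps=1, seed=11)
        r1 = run_replicate(setting, 3)
        r2 = run_replicate(setting, 3)
        assert r1 == r2

    def test_all_methods_report_three_coefficients(self):
        setting = SimulationSetting("E1", "Y1", n=200, reps=1, seed=11)
        rec = run_replicate(setting, 0)
        for method in ("npmvCBGPS", "mvGPS", "linear"):
            assert rec[method]["ok"]
            assert set(rec[method]["terms"]) == {"T1", "T2", "T3"}
            assert np.isfinite(rec[method]["balance"])

    def test_linear_only_never_invokes_weighting(self, monkeypatch):
        from mixbalance import gps

        def boom(*a, **k):  # pragma: no cover - would fail the test if called
            raise AssertionError("weighting invoked")

        monkeypatch.setattr(gps, "npmvcbgps_weights", boom)
        monkeypatch.setattr(gps, "mvgps_weights", boom)
        setting = SimulationSetting("E1", "Y1", n=200, reps=1, seed=5, methods=("linear",))
        rec = run_replicate(setting, 0)
        assert rec["linear"]["ok"]

    def test_solver_failure_is_recorded_not_fatal(self, monkeypatch):
        from mixbalance import gps

        def fail(*a, **k):
            raise ELConvergenceError("forced failure", max_abs_moment=1.0)

        monkeypatch.setattr(gps, "npmvcbgps_weights", fail)
        setting = SimulationSetting("E1", "Y1", n=200, reps=1, seed=5, methods=("npmvCBGPS", "linear"))
        rec = run_replicate(setting, 0)
        assert not rec["npmvCBGPS"]["ok"]
        assert rec["linear"]["ok"]


class TestSummarize:
    @staticmethod
    def _fake_record(est, se=0.1, p=0.01, balance=0.05):
        lo, hi = est - 1.96 * se, est + 1.96 * se
        return {
            "fake": {
                "ok": True,
                "balance": balance,
                "terms": {
                    "T1": {"est": est, "se": se, "p": p, "ci_low": lo, "ci_high": hi},
                    "T2": {"est": -0.5, "se": se, "p": p, "ci_low": -0.7, "ci_high": -0.3},
                    "T3": {"est": 0.8, "se": se, "p": p, "ci_low": 0.6, "ci_high": 1.0},
                },
            }
        }

    def test_hand_arithmetic_on_four_fake_replicates(self):
        ests = [0.5, 0.6, 0.7, 0.8]
        records = [self._fake_record(e) for e in ests]
        setting = SimulationSetting("E1", "Y1", n=200, reps=4, seed=0, methods=("npmvCBGPS",))
        object.__setattr__(setting, "methods", ("fake",))
        res = summarize(records, setting)
        row = res.summary.set_index("term").loc["T1"]
        assert np.isclose(row["bias"], np.mean(ests) - 0.6)
        assert np.isclose(row["rmse"], np.sqrt(np.mean((np.array(ests) - 0.6) ** 2)))
        # CIs at est +- 0.196 contain 0.6 for est in {0.5, 0.6, 0.7}
        assert np.isclose(row["coverage"], 3 / 4)
        assert row["power"] == 1.0
        assert res.balance["mean_balance"].iloc[0] == 0.05

    def test_exact_estimates_give_perfect_metrics(self):
        rec = {
            "fake": {
                "ok": True,
                "balance": 0.0,
                "terms": {
                    t: {"est": v, "se": 1e-9, "p": 1e-12, "ci_low": v - 1e-8, "ci_high": v + 1e-8}
                    for t, v in sim.TRUE_EFFECTS.items()
                },
            }
        }
        setting = SimulationSetting("E1", "Y1", n=200, reps=2, seed=0)
        object.__setattr__(setting, "methods", ("fake",))
        res = summarize([rec, rec], setting)
        assert np.allclose(res.summary["bias"], 0.0)
        assert np.allclose(res.summary["rmse"], 0.0)
        assert np.all(res.summary["coverage"] == 1.0)
        assert np.all(res.summary["power"] == 1.0)

    def test_all_failed_raises(self):
        setting = SimulationSetting("E1", "Y1", n=200, reps=1, seed=0, methods=("npmvCBGPS",))
        with pytest.raises(RuntimeError, match="all replicates failed"):
            summarize([{"npmvCBGPS": {"ok": False, "terms": None, "balance": np.nan}}], setting)

    def test_metrics_recomputable_from_replicate_audit_trail(self):
        setting = SimulationSetting("E1", "Y1", n=200, reps=8, seed=21, methods=("linear",))
        res = run_simulation(setting)
        sub = res.replicates[res.replicates["term"] == "T1"]
        row = res.summary.set_index("term").loc["T1"]
        assert np.isclose(row["bias"], sub["est"].mean() - 0.6)
        assert np.isclose(row["rmse"], np.sqrt(((sub["est"] - 0.6) ** 2).mean()))
        assert np.isclose(row["coverage"], ((sub["ci_low"] <= 0.6) & (0.6 <= sub["ci_high"])).mean())
        assert np.isclose(row["power"], (sub["p"] < 0.05).mean())
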