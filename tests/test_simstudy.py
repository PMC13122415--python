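"""Simulation harness: generation hyperparameters, performance measures."""

import numpy as np
import pytest

from intervalconsensus.simstudy import (
    GenerationConfig,
    absolute_bias,
    bootstrap_mcse,
    derive_generation_hyperparams,
    mse,
    recovery_correlation,
    simulate_condition,
)
from intervalconsensus.transform import interval_to_unbounded


class TestGenerationHyperparams:
    def test_centre_anchor_gives_zero_mean_location(self):
        cfg = GenerationConfig(typical=(1 / 3, 2 / 3))
        mean, sd = derive_generation_hyperparams(cfg)
        np.testing.assert_allclose(mean, (0.0, 0.0), atol=1e-12)

    def test_four_sd_rule(self):
        cfg = GenerationConfig()
        mean, sd = derive_generation_hyperparams(cfg)
        z_loc = interval_to_unbounded(*cfg.extreme_location)
        z_wid = interval_to_unbounded(*cfg.extreme_width)
        assert sd[0] == pytest.approx(abs(z_loc[0] - mean[0]) / 4)
        assert sd[1] == pytest.approx(abs(z_wid[1] - mean[1]) / 4)

    def test_degenerate_anchor_rejected(self):
        cfg = GenerationConfig(extreme_location=(0.4, 0.6), typical=(0.4, 0.6))
        with pytest.raises(ValueError, match="zero SD"):
            derive_generation_hyperparams(cfg)

    def test_invalid_anchor_rejected(self):
        with pytest.raises(ValueError):
            GenerationConfig(typical=(0.7, 0.3))


class TestSimulateCondition:
    def test_deterministic_per_seed_and_condition(self):
        cfg = GenerationConfig(base_seed=3)
        d1, t1 = simulate_condition(8, 5, 2, cfg)
        d2, t2 = simulate_condition(8, 5, 2, cfg)
        assert d1.equals(d2)
        np.testing.assert_array_equal(t1["T_loc"], t2["T_loc"])
        d3, _ = simulate_condition(8, 5, 3, cfg)
        assert not d1.equals(d3)

    def test_empirical_consensus_sd_matches_configuration(self):
        cfg = GenerationConfig()
        mean, sd = derive_generation_hyperparams(cfg)
        locs = np.concatenate(
            [simulate_condition(2, 40, r, cfg)[1]["T_loc"] for r in range(40)]
        )
        assert locs.std() == pytest.approx(sd[0], rel=0.15)
        assert locs.mean() == pytest.approx(mean[0], abs=4 * sd[0] / np.sqrt(len(locs)))

    def test_simulated_widths_bounded_away_from_full_scale(self):
        cfg = GenerationConfig()
        data, _ = simulate_condition(30, 10, 0, cfg)
        widths = (data["upper"] - data["lower"]).to_numpy()
        assert np.quantile(widths, 0.99) < 0.98
        assert widths.mean() < 0.6


class TestRunStudy:
    def test_incremental_mode_adds_repetitions(self):
        from intervalconsensus.inference import FitConfig
        from intervalconsensus.simstudy import run_study

        cfg = GenerationConfig(respondents=(6,), items=(4,), reps=2, base_seed=5)
        tiny = FitConfig(chains=1, warmup=80, draws=60, rejuvenation_sweeps=1)
        # unreachable target: every condition runs to max_reps
        report = run_study(cfg, tiny, mcse_target=1e-9, batch=2, max_reps=4)
        icm_rows = report.per_rep[report.per_rep.method == "icm"]
        assert len(icm_rows) == 4
        assert sorted(icm_rows["rep"]) == [0, 1, 2, 3]
        # trivially satisfied target: stays at the configured repetitions
        report2 = run_study(cfg, tiny, mcse_target=10.0, batch=2, max_reps=4)
        assert len(report2.per_rep[report2.per_rep.method == "icm"]) == 2
        # deterministic overlap: shared repetitions score identically
        merged = report.per_rep.merge(
            report2.per_rep, on=["N", "J", "rep", "method"], suffixes=("_a", "_b")
        )
        np.testing.assert_allclose(merged["bias_joint_a"], merged["bias_joint_b"])


class TestMeasures:
    def test_zero_error(self):
        x = np.random.default_rng(0).normal(size=(4, 6, 2))
        assert absolute_bias(x, x) == {"loc": 0.0, "wid": 0.0, "joint": 0.0}
        assert mse(x, x) == {"loc": 0.0, "wid": 0.0, "joint": 0.0}

    def test_single_case_arithmetic(self):
        est = np.array([[0.2, -0.4]])
        tru = np.zeros((1, 2))
        ab = absolute_bias(est, tru)
        assert (ab["loc"], ab["wid"], ab["joint"]) == (0.2, 0.4, pytest.approx(0.3))
        ms = mse(est, tru)
        assert ms["loc"] == pytest.approx(0.04)
        assert ms["wid"] == pytest.approx(0.16)
        assert ms["joint"] == pytest.approx(0.10)

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(1)
        est, tru = rng.normal(size=(2, 5, 7, 2))
        ab = absolute_bias(est, tru)
        ms = mse(est, tru)
        acc_abs = np.zeros(2)
        acc_sq = np.zeros(2)
        n = 0
        for r in range(5):
            for j in range(7):
                for d in range(2):
                    acc_abs[d] += abs(est[r, j, d] - tru[r, j, d])
                    acc_sq[d] += (est[r, j, d] - tru[r, j, d]) ** 2
                n += 1
        assert ab["loc"] == pytest.approx(acc_abs[0] / n)
        assert ab["wid"] == pytest.approx(acc_abs[1] / n)
        assert ab["joint"] == pytest.approx(acc_abs.sum() / (2 * n))
        assert ms["loc"] == pytest.approx(acc_sq[0] / n)
        assert ms["joint"] == pytest.approx(acc_sq.sum() / (2 * n))

    def test_standardised_bias(self):
        est = np.array([[1.0, 2.0]])
        tru = np.zeros((1, 2))
        ab = absolute_bias(est, tru, sd=(2.0, 4.0))
        assert ab["loc"] == pytest.approx(0.5)
        assert ab["wid"] == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            absolute_bias(np.zeros((3, 2)), np.zeros((4, 2)))


class TestRecoveryCorrelation:
    def test_perfect_and_inverted(self):
        x = np.arange(5.0)[None, :]
        assert recovery_correlation(x, x) == pytest.approx(1.0)
        assert recovery_correlation(-x, x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        est, tru = rng.normal(size=(2, 4, 9))
        got = recovery_correlation(est, tru)
        rs = []
        for e, t in zip(est, tru):
            num = np.sum((e - e.mean()) * (t - t.mean()))
            den = np.sqrt(np.sum((e - e.mean()) ** 2) * np.sum((t - t.mean()) ** 2))
            rs.append(num / den)
        assert got == pytest.approx(np.mean(rs))

    def test_zero_variance_rep_excluded(self):
        est = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        tru = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        r, excluded = recovery_correlation(est, tru, return_excluded=True)
        assert excluded == 1
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 matched pairs"):
            recovery_correlation(np.zeros((1, 2)), np.zeros((1, 2)))


class TestBootstrapMcse:
    def test_constant_input_gives_zero(self):
        assert bootstrap_mcse(np.full(20, 3.7), B=200, seed=1) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_scales_as_inverse_sqrt_reps(self):
        rng = np.random.default_rng(3)
        sds = {}
        for reps in (50, 200):
            vals = rng.normal(0, 1, reps)
            sds[reps] = bootstrap_mcse(vals, B=2000, seed=4)
            # bootstrap SE of the mean approximates sigma/sqrt(reps)
            assert sds[reps] == pytest.approx(vals.std() / np.sqrt(reps), rel=0.1)
        assert sds[200] < sds[50]

    def test_reproducible_for_fixed_seed(self):
        vals = np.random.default_rng(5).normal(size=30)
        assert bootstrap_mcse(vals, seed=9) == bootstrap_mcse(vals, seed=9)

    def test_minimum_inputs(self):
        with pytest.raises(ValueError):
            bootstrap_mcse([1.0], B=100)
        with pytest.raises(ValueError):
            bootstrap_mcse([1.0, 2.0], B=1)
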