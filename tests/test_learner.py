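"""Projected delta rule, NNLS oracle, empirical capacity and weight stats."""

import numpy as np
import pytest

from excitatory_perceptron import (
    AssociationStatistics,
    InstabilityError,
    LearnerConfig,
    empirical_weight_stats,
    estimate_capacity_empirical,
    evaluate_mse,
    make_distribution,
    output,
    sample_patterns,
    solve_nnls,
    solve_unconstrained,
    theta_fixed,
    train_projected_delta,
)
from conftest import make_manual_patterns


class TestOutput:
    def test_zero_weights_give_minus_theta(self):
        assert output(np.zeros(4), np.ones(4), theta=0.0) == 0.0
        assert output(np.zeros(4), np.ones(4), theta=2.0) == -2.0

    def test_single_active_synapse(self):
        w = np.array([1.0, 0.0, 0.0])
        x = np.array([2.0, 5.0, 7.0])
        # theta = mu_x * sum(w) with mu_x = 1 cancels the mean: output = x1 - mu_x
        assert output(w, x, theta=1.0 * w.sum()) == pytest.approx(1.0)

    def test_mean_cancel_is_shift_invariant(self):
        """With theta = mu_x*sum(w), adding a constant to every input moves
        mu_x by the same constant and the output is unchanged."""
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, 20)
        x = rng.exponential(1.0, 20)
        mu = 1.0
        c = 3.7
        y0 = output(w, x, theta=mu * w.sum())
        y1 = output(w, x + c, theta=(mu + c) * w.sum())
        assert y1 == pytest.approx(y0, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            output(np.zeros(3), np.zeros(4), 0.0)


class TestProjectedDeltaRule:
    def test_single_attainable_constraint(self):
        # one pattern, one effective direction: fixed point w1 = z/x1
        ps = make_manual_patterns([[3.0, 1.0]], [2.0])  # mean-cancel: A = x - 1
        cfg = LearnerConfig(theta_mode="mean_cancel", max_epochs=4000, target_mse=1e-16, seed=0)
        fit = train_projected_delta(ps, cfg)
        assert fit.converged and fit.mse < 1e-12
        assert np.all(fit.weights >= 0)

    def test_unreachable_target_clips_to_boundary(self):
        # effective input is negative, target positive: optimum is w = 0
        ps = make_manual_patterns([[0.0]], [1.0])  # mean-cancel: A = -1, b = 1
        cfg = LearnerConfig(theta_mode="mean_cancel", max_epochs=200, seed=0, learning_rate=0.05)
        fit = train_projected_delta(ps, cfg)
        assert fit.weights[0] == 0.0
        assert fit.mse == pytest.approx(1.0)

    def test_matches_oracle_on_both_sides_of_capacity(self, exp_dist):
        """With an annealed rate the rule lands on the constrained optimum,
        below capacity (zero error) and above (positive error floor)."""
        for alpha in (0.3, 0.8):
            ps = sample_patterns(exp_dist, exp_dist, 150, alpha, seed=5)
            oracle = solve_nnls(ps)
            cfg = LearnerConfig(max_epochs=8000, anneal_gamma=0.999, target_mse=1e-12, seed=5)
            fit = train_projected_delta(ps, cfg)
            scale = float(np.mean(ps.targets**2))
            assert fit.mse >= oracle.mse - 1e-8  # the rule never beats the oracle
            assert (fit.mse - oracle.mse) / max(oracle.mse, scale) < 5e-3
            assert np.all(fit.weights >= 0)

    def test_seeded_determinism(self, exp_exp_patterns):
        cfg = LearnerConfig(max_epochs=20, seed=9, shuffle=True)
        a = train_projected_delta(exp_exp_patterns, cfg)
        b = train_projected_delta(exp_exp_patterns, cfg)
        assert np.array_equal(a.weights, b.weights)
        assert a.mse == b.mse and a.epochs_run == b.epochs_run

    def test_divergence_raises(self, exp_exp_patterns):
        # centered inputs let an oversized step grow the weights without bound
        cfg = LearnerConfig(learning_rate=10.0, max_epochs=50, seed=0, theta_mode="mean_cancel")
        with pytest.raises(InstabilityError):
            train_projected_delta(exp_exp_patterns, cfg)


class TestNNLSOracle:
    def test_identity_design(self):
        # inputs = I + mu_x so the mean-cancelled design is the identity
        targets = np.array([0.5, 2.0, 0.0, 1.5])
        ps = make_manual_patterns(np.eye(4) + 1.0, targets)
        fit = solve_nnls(ps, theta_mode="mean_cancel")
        assert np.allclose(fit.weights, targets, atol=1e-12)
        assert fit.mse < 1e-24

    def test_boundary_optimum_for_negative_target(self):
        ps = make_manual_patterns([[2.0]], [-1.0])  # mean-cancel design = [1]
        fit = solve_nnls(ps, theta_mode="mean_cancel")
        assert fit.weights[0] == 0.0
        assert fit.mse == pytest.approx(1.0)

    def test_degenerate_all_zero_inputs(self):
        ps = make_manual_patterns(np.zeros((2, 3)), [1.0, 2.0])
        fit = solve_nnls(ps, theta_mode="fixed")
        assert np.all(fit.weights == 0.0)
        assert fit.silent_fraction_empirical == 1.0

    def test_theta_fixed_scale(self, exp_exp_patterns):
        assert theta_fixed(exp_exp_patterns) == pytest.approx(np.sqrt(200) * 1.0)


class TestEmpiricalCapacity:
    def test_deep_feasible_regime(self, exp_dist):
        dist_z = make_distribution("constant", 1.0)  # B = 0
        df = estimate_capacity_empirical(exp_dist, dist_z, 150, [0.1], trials=10, seed=0)
        assert df["fraction_solvable"].iloc[0] == 1.0
        assert df.attrs["warning"] is not None  # grid does not straddle the transition

    def test_unconstrained_transition_at_one(self, exp_dist):
        df = estimate_capacity_empirical(
            exp_dist, exp_dist, 100, [0.9, 1.1], trials=10, seed=1, constrained=False
        )
        assert df["fraction_solvable"].tolist() == [1.0, 0.0]
        assert df.attrs["alpha_c_estimate"] == pytest.approx(1.0, abs=0.1)

    def test_trials_validation(self, exp_dist):
        with pytest.raises(ValueError):
            estimate_capacity_empirical(exp_dist, exp_dist, 100, [0.5], trials=5, seed=0)

    def test_mean_cancel_dialect_transitions_at_half(self, exp_dist):
        """Exact per-step cancellation leaves the weight scale free, so the
        solvability transition sits at 1/2 even for variable targets."""
        df = estimate_capacity_empirical(
            exp_dist, exp_dist, 300, [0.4, 0.6], trials=10, seed=2, theta_mode="mean_cancel"
        )
        assert df["fraction_solvable"].tolist() == [1.0, 0.0]


class TestWeightStats:
    def test_all_zero_weights(self):
        from excitatory_perceptron import FitResult

        fit = FitResult(np.zeros(10), 1.0, 1.0, 0, True)
        silent, hist = empirical_weight_stats(fit)
        assert silent == 1.0
        assert len(hist) == 0

    def test_silent_fraction_decreases_beyond_capacity(self, exp_dist):
        dist_z = make_distribution("constant", 1.0)  # B = 0
        fractions = []
        for alpha in (0.6, 1.0, 2.0):
            ps = sample_patterns(exp_dist, dist_z, 300, alpha, seed=21)
            silent, _ = empirical_weight_stats(solve_nnls(ps))
            fractions.append(silent)
        assert fractions[0] > fractions[1] > fractions[2]

    def test_histogram_is_a_density(self, exp_exp_patterns):
        silent, hist = empirical_weight_stats(solve_nnls(exp_exp_patterns))
        widths = hist["bin_right"] - hist["bin_left"]
        assert (hist["density"] * widths).sum() == pytest.approx(1.0)


class TestNoiseAdditivity:
    def test_recall_noise_adds_its_variance(self, exp_dist):
        """Uncorrelated Gaussian noise on the recalled output raises the mean
        squared error by its variance (above capacity, where the error floor
        is positive)."""
        dist_z = make_distribution("constant", 1.0)
        ps = sample_patterns(exp_dist, dist_z, 400, 1.0, seed=3)
        fit = solve_nnls(ps)
        v = 0.25
        rng = np.random.default_rng(7)
        noisy = [evaluate_mse(fit.weights, ps, noise_sd=np.sqrt(v), rng=rng) for _ in range(30)]
        shift = np.mean(noisy) - fit.mse
        se = np.std(noisy, ddof=1) / np.sqrt(len(noisy))
        assert abs(shift - v) < 3 * se
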