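"""Finite-N learning with non-negative synaptic weights.

Two solvers for the same convex problem, minimizing the per-pattern
squared error sum_mu (y^mu - z^mu)^2 over the closed orthant w >= 0:

* :func:`train_projected_delta` -- the biological learning rule: cyclic
  pattern presentation, delta-rule updates eta*(z - y)*x, and clipping
  of any weight the update would drive negative (projected stochastic
  gradient descent).
* :func:`solve_nnls` -- the exact oracle, a Lawson-Hanson active-set
  non-negative least-squares solve.

The inhibitory term theta comes in two dialects.  ``"fixed"`` (default)
uses the constant theta = sqrt(N) * mu_z, which cancels the leading
O(sqrt(N)) mean excitatory drive and pins the total synaptic weight near
sqrt(N) * mu_z / mu_x; this is the circuit the capacity theory
describes, and the one whose solvability transition tracks alpha_c(B).
``"mean_cancel"`` recomputes theta = mu_x * sum_i w_i at every
presentation, so the output is exactly sum_i w_i (x_i - mu_x); the exact
cancellation leaves the overall weight scale unconstrained, and the
transition then sits at alpha = 1/2 for every target distribution (the
B-dependence disappears).  The second dialect is kept for sensitivity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .patterns import PatternSet, RateDistribution, sample_patterns

__all__ = [
    "LearnerConfig",
    "FitResult",
    "InstabilityError",
    "output",
    "theta_fixed",
    "train_projected_delta",
    "solve_nnls",
    "solve_unconstrained",
    "evaluate_mse",
    "estimate_capacity_empirical",
    "empirical_weight_stats",
]

ThetaMode = Literal["fixed", "mean_cancel"]

SOLVABLE_MSE = 1e-10  # per-pattern mse below which an instance counts as exactly learnable


class InstabilityError(RuntimeError):
    """Learning diverged; decrease the learning rate."""


@dataclass(frozen=True)
class LearnerConfig:
    """Settings for the projected delta rule.

    ``learning_rate=None`` selects the stability default
    0.1 / (N * E[x_eff^2]) with x_eff the effective (theta-resolved)
    input.  A constant rate leaves the rule hovering at an O(eta) error
    floor above capacity; ``anneal_tau`` applies a 1/(1 + t/tau) decay
    over epochs t and ``anneal_gamma`` a geometric gamma**t decay, either
    of which drives the rule to the exact constrained optimum.
    """

    learning_rate: float | None = None
    max_epochs: int = 1000
    target_mse: float = 0.0
    theta_mode: ThetaMode = "fixed"
    seed: int = 0
    shuffle: bool = False
    anneal_tau: float | None = None
    anneal_gamma: float | None = None

    def __post_init__(self):
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.target_mse < 0:
            raise ValueError("target_mse must be >= 0")


@dataclass(frozen=True)
class FitResult:
    weights: np.ndarray
    mse: float
    silent_fraction_empirical: float
    epochs_run: int
    converged: bool
    solver: str = "nnls"
    theta_mode: ThetaMode = "fixed"
    zero_threshold: float = 0.0


def theta_fixed(patterns: PatternSet) -> float:
    """The fixed inhibitory offset sqrt(N) * mu_z for a pattern set."""
    return float(np.sqrt(patterns.N) * patterns.stats.mu_z)


def output(weights: np.ndarray, pattern: np.ndarray, theta: float) -> float:
    """Linear perceptron output sum_i w_i x_i - theta for one pattern."""
    weights = np.asarray(weights, dtype=float)
    pattern = np.asarray(pattern, dtype=float)
    if weights.shape != pattern.shape:
        raise ValueError(f"dimension mismatch: weights {weights.shape} vs pattern {pattern.shape}")
    return float(weights @ pattern - theta)


def _design(patterns: PatternSet, theta_mode: ThetaMode):
    """Effective design matrix A and targets b such that residual = A w - b."""
    if theta_mode == "fixed":
        return patterns.inputs, patterns.targets + theta_fixed(patterns)
    if theta_mode == "mean_cancel":
        return patterns.inputs - patterns.stats.mu_x, patterns.targets
    raise ValueError(f"unknown theta_mode {theta_mode!r}")


def _zero_threshold(weights: np.ndarray, solver: str) -> float:
    # active-set solutions have exact zeros; SGD weights only approach zero
    nz = weights[weights > 0]
    if nz.size == 0:
        return 0.0
    rel = 1e-8 if solver == "nnls" else 1e-3
    return rel * float(nz.mean())


def _silent_fraction(weights: np.ndarray, threshold: float) -> float:
    return float(np.mean(weights <= threshold))


def evaluate_mse(
    weights: np.ndarray,
    patterns: PatternSet,
    theta_mode: ThetaMode = "fixed",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Per-pattern mean squared output error, optionally with recall noise.

    ``noise_sd`` adds i.i.d. Gaussian noise to the perceptron output at
    evaluation time (after learning); on average this raises the mse by
    exactly the noise variance.
    """
    A, b = _design(patterns, theta_mode)
    y = A @ weights
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, y.shape)
    r = y - b
    return float(r @ r / patterns.p)


def train_projected_delta(patterns: PatternSet, config: LearnerConfig) -> FitResult:
    """Learn by the projected delta rule.

    Per presentation of pattern mu: dw_i = eta * (z^mu - y^mu) * x_i^mu,
    and any weight driven negative is set to zero.  This is projected
    gradient descent on the summed squared error over w >= 0.  Stops when
    the per-pattern mse falls to ``target_mse`` or after ``max_epochs``
    cyclic sweeps.
    """
    if patterns.p < 1:
        raise ValueError("empty pattern set")
    N, p = patterns.N, patterns.p
    st = patterns.stats
    A, b = _design(patterns, config.theta_mode)
    ex2 = st.mu_x**2 + st.sigma_x**2 if config.theta_mode == "fixed" else st.sigma_x**2
    eta0 = config.learning_rate if config.learning_rate is not None else 0.1 / (N * ex2)

    rng = np.random.default_rng(config.seed)
    # initial weights uniform on [0, 2*wbar0] with wbar0 the pinned mean scale,
    # so the initial total drive already sits near theta
    wbar0 = st.mu_z / (np.sqrt(N) * st.mu_x)
    w = rng.uniform(0.0, 2.0 * wbar0, N)

    def mse_of(w):
        r = A @ w - b
        return float(r @ r / p)

    mse0 = max(mse_of(w), 1e-300)
    mse = mse0
    epochs = 0
    for epoch in range(config.max_epochs):
        eta = eta0
        if config.anneal_tau is not None:
            eta /= 1.0 + epoch / config.anneal_tau
        if config.anneal_gamma is not None:
            eta *= config.anneal_gamma**epoch
        order = rng.permutation(p) if config.shuffle else range(p)
        for mu in order:
            a = A[mu]
            err = b[mu] - a @ w
            w += eta * err * a
            np.maximum(w, 0.0, out=w)
        epochs = epoch + 1
        mse = mse_of(w)
        if mse <= config.target_mse:
            break
        if mse > 1e6 * mse0:
            raise InstabilityError(
                f"mse grew from {mse0:.3g} to {mse:.3g}; decrease the learning rate (eta={eta0:.3g})"
            )
    thr = _zero_threshold(w, "sgd")
    return FitResult(
        weights=w,
        mse=mse,
        silent_fraction_empirical=_silent_fraction(w, thr),
        epochs_run=epochs,
        converged=mse <= config.target_mse,
        solver="sgd",
        theta_mode=config.theta_mode,
        zero_threshold=thr,
    )


def solve_nnls(patterns: PatternSet, theta_mode: ThetaMode = "fixed") -> FitResult:
    """Exact minimizer of the summed squared error over w >= 0 (active set)."""
    if patterns.p < 1:
        raise ValueError("empty pattern set")
    A, b = _design(patterns, theta_mode)
    if not np.any(A):
        w = np.zeros(patterns.N)
        return FitResult(w, float(b @ b / patterns.p), 1.0, 0, True, "nnls", theta_mode, 0.0)
    w, rnorm = _scipy_nnls(A, b, maxiter=max(30 * patterns.N, 3000))
    thr = _zero_threshold(w, "nnls")
    return FitResult(
        weights=w,
        mse=float(rnorm * rnorm / patterns.p),
        silent_fraction_empirical=_silent_fraction(w, thr),
        epochs_run=0,
        converged=True,
        solver="nnls",
        theta_mode=theta_mode,
        zero_threshold=thr,
    )


def solve_unconstrained(patterns: PatternSet, theta_mode: ThetaMode = "fixed") -> FitResult:
    """Least squares with the sign constraint disabled (weights may go negative)."""
    A, b = _design(patterns, theta_mode)
    w, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = A @ w - b
    return FitResult(
        weights=w,
        mse=float(r @ r / patterns.p),
        silent_fraction_empirical=float(np.mean(w <= 0)),
        epochs_run=0,
        converged=True,
        solver="lstsq",
        theta_mode=theta_mode,
        zero_threshold=0.0,
    )


def estimate_capacity_empirical(
    dist_x: RateDistribution,
    dist_z: RateDistribution,
    N: int,
    alpha_grid,
    trials: int,
    seed: int,
    theta_mode: ThetaMode = "fixed",
    constrained: bool = True,
) -> pd.DataFrame:
    """Fraction of exactly learnable instances along an alpha grid.

    An instance counts as solvable when the NNLS (or unconstrained least
    squares) per-pattern mse falls below 1e-10.  The returned frame has
    columns (alpha, fraction_solvable) and carries the interpolated 50%
    crossing in ``df.attrs["alpha_c_estimate"]`` (NaN, with
    ``df.attrs["warning"]`` set, when the grid does not straddle the
    transition).
    """
    if trials < 10:
        raise ValueError("trials must be >= 10")
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(len(alpha_grid), trials))
    fractions = []
    for i, alpha in enumerate(alpha_grid):
        n_ok = 0
        for t in range(trials):
            ps = sample_patterns(dist_x, dist_z, N, alpha, int(seeds[i, t]))
            fit = solve_nnls(ps, theta_mode) if constrained else solve_unconstrained(ps, theta_mode)
            n_ok += fit.mse < SOLVABLE_MSE
        fractions.append(n_ok / trials)
    df = pd.DataFrame({"alpha": alpha_grid, "fraction_solvable": fractions})
    f = df["fraction_solvable"].to_numpy()
    crossing = np.nan
    for i in range(len(f) - 1):
        if f[i] >= 0.5 > f[i + 1]:
            a0, a1 = alpha_grid[i], alpha_grid[i + 1]
            crossing = a0 + (f[i] - 0.5) / (f[i] - f[i + 1]) * (a1 - a0)
            break
    df.attrs["alpha_c_estimate"] = float(crossing)
    df.attrs["warning"] = (
        None if np.isfinite(crossing) else "alpha grid lies entirely on one side of the transition"
    )
    return df


def empirical_weight_stats(fit: FitResult, zero_threshold: float | None = None):
    """Silent fraction and a density-normalized histogram of non-silent weights.

    ``zero_threshold=None`` uses the solver-appropriate default recorded
    in the fit (exact zeros for the active-set oracle, a 1e-3 relative
    threshold for gradient descent).
    """
    if zero_threshold is None:
        zero_threshold = fit.zero_threshold
    if zero_threshold < 0:
        raise ValueError("zero_threshold must be >= 0")
    w = np.asarray(fit.weights)
    silent = _silent_fraction(w, zero_threshold)
    nz = w[w > zero_threshold]
    if nz.size == 0:
        hist = pd.DataFrame({"bin_left": [], "bin_right": [], "density": []})
    else:
        counts, edges = np.histogram(nz, bins="auto", density=True)
        hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "density": counts})
    return silent, hist
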