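"""Replica-symmetric saddle-point theory of the excitatory analog perceptron.

The perceptron output is y = sum_i w_i x_i - theta with linear transfer,
w_i >= 0, and an inhibitory term theta that cancels the O(sqrt(N)) mean
excitatory drive so the output is of the order of the target rates.  In
the large-N limit the whole problem collapses onto a single
dimensionless parameter B (see :func:`excitatory_perceptron.patterns.compute_B`).

All saddle-point conditions reduce to closed-form Gaussian moments.  With
Phi/phi the standard normal CDF/PDF, define the truncated moments

    I1(k) = E[(k - t)_+]   = k*Phi(k) + phi(k)
    I2(k) = E[(k - t)_+^2] = (1 + k^2)*Phi(k) + k*phi(k),   t ~ N(0, 1).

Maximal capacity (number of associations per synapse):

    alpha_c = Phi(kappa),   with kappa <= 0 the root of  B * I1(kappa) + kappa = 0,

so alpha_c(0) = 1/2 and alpha_c decreases monotonically with B.  At
capacity the weight distribution, in units of the mean weight, is

    P(w) = (1 - Phi(kappa)) * delta(w) + Gaussian(c*kappa, c) truncated to w > 0,

with c = 1/I1(kappa); the silent fraction is F = 1 - Phi(kappa) = 1 - alpha_c.

Above capacity the minimal squared error per pattern, in units of the
squared output-fluctuation scale (sigma_x * mu_z / mu_x)^2, is

    E(alpha, B) = (alpha - Phi(kappa))^2 / (alpha * I1(kappa)^2),

where kappa now solves (alpha - I2(kappa)) / I1(kappa)^2 = B.  At
alpha = alpha_c this reduces to the capacity condition, so E vanishes
continuously at the transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import truncnorm

__all__ = [
    "CapacityResult",
    "WeightDistributionTheory",
    "MSEResult",
    "solve_capacity",
    "capacity_curve",
    "weight_distribution_theory",
    "solve_mse",
]

_ROOT_XTOL = 1e-14
_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x: float) -> float:
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _Phi(x: float) -> float:
    return float(ndtr(x))


def _I1(k: float) -> float:
    return k * _Phi(k) + _phi(k)


def _I2(k: float) -> float:
    return (1.0 + k * k) * _Phi(k) + k * _phi(k)


class SaddlePointError(RuntimeError):
    """Raised when a saddle-point root cannot be bracketed or refined."""


@dataclass(frozen=True)
class CapacityResult:
    B: float
    alpha_c: float
    aux: dict
    silent_fraction: float


@dataclass(frozen=True)
class WeightDistributionTheory:
    """Two-component weight law at maximal capacity.

    ``silent_fraction`` is the mass of the atom at w = 0; the continuous
    part is a Gaussian of location ``gaussian_loc`` and scale
    ``gaussian_scale`` truncated to w > 0 (both in absolute weight units,
    proportional to ``wbar``).  The total first moment equals ``wbar``.
    """

    B: float
    wbar: float
    silent_fraction: float
    gaussian_loc: float
    gaussian_scale: float

    def _trunc(self):
        a = -self.gaussian_loc / self.gaussian_scale
        return truncnorm(a, np.inf, loc=self.gaussian_loc, scale=self.gaussian_scale)

    def pdf(self, w) -> np.ndarray:
        """Density of the continuous (non-silent) component, carrying mass 1 - F."""
        w = np.asarray(w, dtype=float)
        out = np.zeros_like(w)
        pos = w > 0
        out[pos] = (1.0 - self.silent_fraction) * self._trunc().pdf(w[pos])
        return out

    def cdf_nonsilent(self, w) -> np.ndarray:
        """CDF of the weight conditioned on w > 0 (for comparisons with data)."""
        return self._trunc().cdf(np.asarray(w, dtype=float))

    def mean(self) -> float:
        return float((1.0 - self.silent_fraction) * self._trunc().mean())


def _capacity_kappa(B: float) -> float:
    """Root kappa <= 0 of B*I1(kappa) + kappa = 0, bracketed bisection-safe."""
    if B == 0.0:
        return 0.0
    f = lambda k: B * _I1(k) + k
    lo = -0.5
    # f(0) = B*I1(0) > 0; expand the bracket on a geometric grid until f(lo) < 0
    for _ in range(200):
        if f(lo) < 0.0:
            break
        lo *= 1.5
    else:
        raise SaddlePointError(f"could not bracket capacity root for B={B} (scanned down to kappa={lo})")
    return brentq(f, lo, 0.0, xtol=_ROOT_XTOL)


def solve_capacity(B: float) -> CapacityResult:
    """Maximal capacity alpha_c and weight-law parameters for statistics B.

    Raises for B < 0.  alpha_c(0) = 0.5 and alpha_c is strictly
    decreasing in B; the silent fraction at capacity is 1 - alpha_c.
    """
    if not np.isfinite(B) or B < 0:
        raise ValueError(f"B must be finite and >= 0, got {B}")
    kappa = _capacity_kappa(float(B))
    alpha_c = _Phi(kappa)
    c = 1.0 / _I1(kappa)
    return CapacityResult(
        B=float(B),
        alpha_c=alpha_c,
        aux={"kappa": kappa, "c": c},
        silent_fraction=1.0 - alpha_c,
    )


def capacity_curve(B_grid) -> pd.DataFrame:
    """Tidy table (B, alpha_c, silent_fraction, kappa) along a sorted B grid."""
    B_grid = np.asarray(B_grid, dtype=float)
    if B_grid.ndim != 1 or np.any(np.diff(B_grid) < 0):
        raise ValueError("B_grid must be a sorted 1-d array")
    rows = []
    for B in B_grid:
        try:
            r = solve_capacity(B)
        except (ValueError, SaddlePointError) as err:
            raise type(err)(f"capacity solve failed at B={B}: {err}") from err
        rows.append((B, r.alpha_c, r.silent_fraction, r.aux["kappa"]))
    return pd.DataFrame(rows, columns=["B", "alpha_c", "silent_fraction", "kappa"])


def weight_distribution_theory(B: float, wbar: float = 1.0) -> WeightDistributionTheory:
    """Weight distribution at maximal capacity alpha_c(B).

    The theory fixes only the shape; ``wbar`` (the average synaptic
    weight) sets the scale.  In units of wbar the continuous part is a
    Gaussian of mean c*kappa (non-positive) and sd c truncated to w > 0,
    and the atom at zero carries mass 1 - alpha_c(B).
    """
    if wbar <= 0:
        raise ValueError(f"wbar must be > 0, got {wbar}")
    cap = solve_capacity(B)
    kappa, c = cap.aux["kappa"], cap.aux["c"]
    return WeightDistributionTheory(
        B=float(B),
        wbar=float(wbar),
        silent_fraction=cap.silent_fraction,
        gaussian_loc=wbar * c * kappa,
        gaussian_scale=wbar * c,
    )


@dataclass(frozen=True)
class MSEResult:
    alpha: float
    B: float
    mse: float
    silent_fraction: float
    extra_order_param: float
    aux: dict

    def mse_physical(self, stats) -> float:
        """MSE in squared rate units, (sigma_x * mu_z / mu_x)^2 * E(alpha, B)."""
        scale = stats.sigma_x * stats.mu_z / stats.mu_x
        return self.mse * scale * scale

    def mse_in_sigma_z_units(self) -> float:
        """MSE normalized by the target variance (requires B > 0)."""
        if self.B == 0:
            raise ValueError("sigma_z = 0 when B = 0; use mse_physical instead")
        return self.mse / self.B


def _mse_kappa(alpha: float, B: float) -> float:
    """Root of (alpha - I2(k)) - B*I1(k)^2 = 0, bracketed on an expanding grid."""
    f = lambda k: alpha - _I2(k) - B * _I1(k) ** 2
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) > 0.0:
            break
        lo *= 1.5
    else:
        raise SaddlePointError(f"no lower bracket for mse root (alpha={alpha}, B={B})")
    for _ in range(200):
        if f(hi) < 0.0:
            break
        hi *= 1.5
    else:
        raise SaddlePointError(f"no upper bracket for mse root (alpha={alpha}, B={B})")
    return brentq(f, lo, hi, xtol=_ROOT_XTOL)


def solve_mse(alpha: float, B: float) -> MSEResult:
    """Minimal mean squared error per pattern at load alpha and statistics B.

    Below capacity the associations are exactly learnable and the error
    is zero (the saddle-point system reduces to the capacity equations);
    there the silent fraction of the typical solution is not described by
    this saddle point and is reported as NaN.  Above capacity the error
    is strictly positive and increases with alpha, while the silent
    fraction 1 - Phi(kappa) decreases and tends to zero at large load.
    The ``extra_order_param`` is the zero-temperature response
    chi = c * Phi(kappa), the combination that stays finite when the
    inverse temperature of the underlying free energy diverges.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not np.isfinite(B) or B < 0:
        raise ValueError(f"B must be finite and >= 0, got {B}")
    cap = solve_capacity(B)
    if alpha <= cap.alpha_c:
        return MSEResult(
            alpha=float(alpha), B=float(B), mse=0.0,
            silent_fraction=float("nan"), extra_order_param=float("nan"),
            aux={"kappa": float("nan"), "c": float("nan"), "alpha_c": cap.alpha_c},
        )
    kappa = _mse_kappa(float(alpha), float(B))
    i1 = _I1(kappa)
    c = 1.0 / i1
    mse = (alpha - _Phi(kappa)) ** 2 / (alpha * i1 * i1)
    return MSEResult(
        alpha=float(alpha), B=float(B), mse=float(mse),
        silent_fraction=1.0 - _Phi(kappa),
        extra_order_param=c * _Phi(kappa),
        aux={"kappa": kappa, "c": c, "alpha_c": cap.alpha_c},
    )
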