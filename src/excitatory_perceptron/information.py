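"""Information transmitted through the noisy readout, per synapse.

Capacity alone would push the target variability to zero (B -> 0,
alpha_c -> 1/2), but a Purkinje cell whose output never varies conveys
nothing about which input was presented.  With additive Gaussian output
noise of standard deviation sigma_noise, each stored association
transmits the Gaussian-channel information

    I_pattern = 1/2 * log2(1 + sigma_z^2 / sigma_noise^2)   bits,

and the perceptron stores alpha_c(B(sigma_z)) associations per synapse,
so the information per synapse is the product

    I_synapse = alpha_c(B(sigma_z)) * I_pattern.

Increasing sigma_z raises the channel term but lowers the capacity term
through B; the product vanishes at sigma_z = 0 and attains a maximum at
a finite output standard deviation, which grows roughly linearly with
sigma_noise when the noise is large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .patterns import AssociationStatistics, compute_B
from .theory import solve_capacity

__all__ = ["InfoResult", "information_per_synapse", "optimal_output_std"]


@dataclass(frozen=True)
class InfoResult:
    sigma_z: float
    sigma_noise: float
    alpha_c: float
    bits_per_pattern: float
    bits_per_synapse: float


def information_per_synapse(
    sigma_z: float, sigma_noise: float, base_stats: AssociationStatistics
) -> InfoResult:
    """Bits per synapse at output variability sigma_z and noise sigma_noise.

    ``base_stats`` supplies the sigma_z-independent moments (mu_x,
    sigma_x, mu_z); its own sigma_z entry is ignored and replaced by the
    ``sigma_z`` argument when forming B.
    """
    if sigma_noise <= 0:
        raise ValueError("sigma_noise must be > 0 (information is unbounded otherwise)")
    if sigma_z < 0:
        raise ValueError("sigma_z must be >= 0")
    B = compute_B(base_stats.mu_x, base_stats.sigma_x, base_stats.mu_z, sigma_z)
    alpha_c = solve_capacity(B).alpha_c
    snr = (sigma_z / sigma_noise) ** 2
    bits_pattern = 0.5 * np.log2(1.0 + snr)
    return InfoResult(
        sigma_z=float(sigma_z),
        sigma_noise=float(sigma_noise),
        alpha_c=alpha_c,
        bits_per_pattern=float(bits_pattern),
        bits_per_synapse=float(alpha_c * bits_pattern),
    )


def optimal_output_std(
    sigma_noise: float, base_stats: AssociationStatistics, n_scan: int = 64, decades: float = 6.0
) -> tuple[float, float]:
    """Output standard deviation maximizing the information per synapse.

    Coarse log-spaced scan (``n_scan`` points over ``decades`` decades
    centred on the noise/target scale) followed by golden-section
    refinement; returns (sigma_z_opt, bits_per_synapse at the optimum).
    """
    if sigma_noise <= 0:
        raise ValueError("sigma_noise must be > 0")

    def objective(log_s):
        return -information_per_synapse(np.exp(log_s), sigma_noise, base_stats).bits_per_synapse

    center = max(sigma_noise, base_stats.mu_z)
    grid = np.log(center) + np.linspace(-0.5, 0.5, n_scan) * decades * np.log(10.0)
    vals = np.array([objective(g) for g in grid])
    if np.allclose(vals, vals[0]):
        raise RuntimeError("flat information objective; degenerate statistics")
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_scan - 1)]
    res = minimize_scalar(objective, bracket=(lo, grid[i], hi) if lo < grid[i] < hi else None,
                          bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    s_opt = float(np.exp(res.x))
    return s_opt, float(-res.fun)
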