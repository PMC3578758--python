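"""Input/output rate distributions and random association sets.

A single granule-cell-to-Purkinje-cell learning problem is a set of p
random associations between N-dimensional input rate vectors and scalar
target rates.  Rates are non-negative by construction.  The replica
theory consumes only the first two moments of the input and target
distributions, collapsed into a single dimensionless parameter B
(:func:`compute_B`); the samplers here provide finite-size realizations
for the learning experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats as _sps

__all__ = [
    "RateDistribution",
    "AssociationStatistics",
    "PatternSet",
    "make_distribution",
    "compute_B",
    "sample_patterns",
    "save_pattern_set",
    "load_pattern_set",
]

DistributionKind = Literal["exponential", "sparse_binary", "clipped_gaussian", "constant"]


@dataclass(frozen=True)
class RateDistribution:
    """A non-negative firing-rate distribution with declared moments.

    ``mean`` and ``sd`` are the *declared* moments the theory consumes.
    For ``clipped_gaussian`` they parameterize the Gaussian before
    truncation at zero; the realized moments after truncation are
    available from :meth:`truncated_moments`.
    """

    kind: DistributionKind
    mean: float
    sd: float
    r_max: float | None = None

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.kind == "exponential":
            return rng.exponential(self.mean, size)
        if self.kind == "sparse_binary":
            p_on = self.mean / self.r_max
            return np.where(rng.random(size) < p_on, self.r_max, 0.0)
        if self.kind == "clipped_gaussian":
            x = rng.normal(self.mean, self.sd, size)
            # rejection keeps the distribution a renormalized truncation
            neg = x < 0.0
            while np.any(neg):
                x[neg] = rng.normal(self.mean, self.sd, int(neg.sum()))
                neg = x < 0.0
            return x
        if self.kind == "constant":
            return np.full(size, self.mean)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def truncated_moments(self) -> tuple[float, float]:
        """Realized (mean, sd) of the sampler.

        Identical to the declared moments except for ``clipped_gaussian``,
        where truncation at zero shifts the mean up and shrinks the sd.
        """
        if self.kind != "clipped_gaussian":
            return self.mean, self.sd
        if self.sd == 0.0:
            return self.mean, 0.0
        a = -self.mean / self.sd
        d = _sps.truncnorm(a, np.inf, loc=self.mean, scale=self.sd)
        return float(d.mean()), float(d.std())


def make_distribution(kind: DistributionKind, mean: float, sd_or_rmax: float = 0.0) -> RateDistribution:
    """Build a rate distribution from its declared parameters.

    For ``sparse_binary`` the second argument is the burst rate r_max and
    the sd follows from the binary closed form sqrt(mean*(r_max - mean));
    for the other kinds it is the standard deviation.
    """
    if mean <= 0 and kind != "constant":
        raise ValueError(f"mean must be > 0, got {mean}")
    if kind == "sparse_binary":
        r_max = sd_or_rmax
        if r_max < mean:
            raise ValueError(f"sparse_binary requires r_max >= mean, got r_max={r_max} < mean={mean}")
        sd = float(np.sqrt(mean * (r_max - mean)))
        return RateDistribution("sparse_binary", float(mean), sd, float(r_max))
    sd = sd_or_rmax
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if kind == "exponential":
        if sd and not np.isclose(sd, mean):
            raise ValueError("an exponential distribution has sd equal to its mean")
        return RateDistribution("exponential", float(mean), float(mean))
    if kind == "constant":
        if sd != 0:
            raise ValueError("constant distribution has sd = 0")
        if mean < 0:
            raise ValueError("constant rate must be >= 0")
        return RateDistribution("constant", float(mean), 0.0)
    if kind == "clipped_gaussian":
        return RateDistribution("clipped_gaussian", float(mean), float(sd))
    raise ValueError(f"unknown distribution kind {kind!r}")


def compute_B(mu_x: float, sigma_x: float, mu_z: float, sigma_z: float) -> float:
    """Pattern-statistics parameter B = (mu_x * sigma_z / (sigma_x * mu_z))**2.

    The single dimensionless combination of the input moments (mu_x,
    sigma_x) and target moments (mu_z, sigma_z) that the storage capacity
    depends on.  It is invariant under a joint rescaling of all rates,
    vanishes when the targets are noiseless (sigma_z = 0, the
    capacity-optimal limit), decreases when the input variability
    sigma_x/mu_x grows, and increases with the target variability
    sigma_z/mu_z.
    """
    if mu_x <= 0 or sigma_x <= 0 or mu_z <= 0:
        raise ValueError("compute_B requires mu_x > 0, sigma_x > 0, mu_z > 0")
    if sigma_z < 0:
        raise ValueError("sigma_z must be >= 0")
    return (mu_x * sigma_z / (sigma_x * mu_z)) ** 2


@dataclass(frozen=True)
class AssociationStatistics:
    """The four moments of an association ensemble plus the derived B."""

    mu_x: float
    sigma_x: float
    mu_z: float
    sigma_z: float
    B: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        try:
            b = compute_B(self.mu_x, self.sigma_x, self.mu_z, self.sigma_z)
        except ValueError:
            b = float("nan")  # degenerate moments (e.g. constant inputs); B undefined
        if self.B is None:
            object.__setattr__(self, "B", b)
        elif not (np.isnan(b) and np.isnan(self.B)) and not np.isclose(self.B, b, rtol=1e-12, atol=1e-300):
            raise ValueError(f"declared B={self.B} inconsistent with moments (expected {b})")

    @classmethod
    def from_distributions(cls, dist_x: RateDistribution, dist_z: RateDistribution) -> "AssociationStatistics":
        return cls(dist_x.mean, dist_x.sd, dist_z.mean, dist_z.sd)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PatternSet:
    """p x N matrix of input rates with a length-p target-rate vector.

    ``stats`` carries the moments of the *generating* distributions, not
    the empirical moments of the sample.
    """

    inputs: np.ndarray
    targets: np.ndarray
    stats: AssociationStatistics
    seed: int
    alpha: float

    @property
    def N(self) -> int:
        return self.inputs.shape[1]

    @property
    def p(self) -> int:
        return self.inputs.shape[0]


def sample_patterns(
    dist_x: RateDistribution,
    dist_z: RateDistribution,
    N: int,
    alpha: float,
    seed: int,
) -> PatternSet:
    """Draw p = round(alpha*N) i.i.d. associations (round half up).

    Deterministic given ``seed``: the same call yields a bit-identical
    pattern set.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    p = _round_half_up(alpha * N)
    if p < 1:
        raise ValueError(f"alpha*N = {alpha * N} rounds to zero patterns")
    rng = np.random.default_rng(seed)
    inputs = dist_x.sample(rng, (p, N))
    targets = dist_z.sample(rng, p)
    stats = AssociationStatistics.from_distributions(dist_x, dist_z)
    return PatternSet(inputs=inputs, targets=targets, stats=stats, seed=int(seed), alpha=float(alpha))


def save_pattern_set(ps: PatternSet, directory: str | Path) -> None:
    """Write inputs.csv, targets.csv and meta.json (17 significant digits)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "inputs.csv", ps.inputs, fmt="%.17g", delimiter=",")
    np.savetxt(d / "targets.csv", ps.targets, fmt="%.17g", delimiter=",")
    meta = {
        "mu_x": ps.stats.mu_x,
        "sigma_x": ps.stats.sigma_x,
        "mu_z": ps.stats.mu_z,
        "sigma_z": ps.stats.sigma_z,
        "B": ps.stats.B,
        "seed": ps.seed,
        "alpha": ps.alpha,
        "N": ps.N,
        "p": ps.p,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_pattern_set(directory: str | Path) -> PatternSet:
    d = Path(directory)
    inputs = np.atleast_2d(np.loadtxt(d / "inputs.csv", delimiter=","))
    targets = np.atleast_1d(np.loadtxt(d / "targets.csv", delimiter=","))
    meta = json.loads((d / "meta.json").read_text())
    stats = AssociationStatistics(meta["mu_x"], meta["sigma_x"], meta["mu_z"], meta["sigma_z"], meta["B"])
    return PatternSet(inputs=inputs, targets=targets, stats=stats, seed=meta["seed"], alpha=meta["alpha"])
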