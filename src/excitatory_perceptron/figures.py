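"""End-to-end figure reproduction: theory curves overlaid on simulations.

Each figure builder writes a tidy CSV, a PNG, and a JSON metadata record
(package version, seeds, solver tolerances) into the requested output
directory.  Runs are deterministic given the seeds in the configuration.
Default problem sizes are desk-scale (N <= 1000, <= 20 trials);
``full_scale=True`` switches to the larger simulation sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .patterns import AssociationStatistics, make_distribution, sample_patterns
from .learner import solve_nnls
from .theory import capacity_curve, solve_capacity, solve_mse, weight_distribution_theory
from .information import information_per_synapse, optimal_output_std

__all__ = ["RunConfig", "reproduce_figure", "KNOWN_FIGURES", "target_distribution_for_B"]

KNOWN_FIGURES = ("fig1a", "fig1b", "fig2a", "fig2b", "fig2c", "fig3a", "fig3b")


def target_distribution_for_B(B: float, mean: float = 1.0):
    """A non-negative target distribution with CV^2 = B (exponential-input convention).

    With unit-CV exponential inputs, B equals the squared target CV; a
    sparse-binary law with r_max = mean * (1 + B) realizes any B >= 0 and
    degenerates to a constant at B = 0.
    """
    return make_distribution("sparse_binary", mean, mean * (1.0 + B))


@dataclass
class RunConfig:
    figure: str
    output_dir: str | Path = "figures_out"
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    full_scale: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["output_dir"] = str(d["output_dir"])
        Path(path).write_text(yaml.safe_dump(d))


def _sim_sizes(cfg: RunConfig, desk: dict, full: dict) -> dict:
    base = dict(full if cfg.full_scale else desk)
    base.update(cfg.parameters)
    return base


def _fig1a(cfg: RunConfig):
    p = _sim_sizes(cfg, {"B_max": 5.0, "n_B": 51}, {"B_max": 5.0, "n_B": 201})
    df = capacity_curve(np.linspace(0.0, p["B_max"], p["n_B"]))[["B", "alpha_c"]]
    fig, ax = plt.subplots()
    ax.plot(df["B"], df["alpha_c"], "r-")
    ax.set(xlabel="B", ylabel=r"maximal capacity $\alpha_c$")
    return df, fig, p


def _fig2a(cfg: RunConfig):
    p = _sim_sizes(cfg, {"B_max": 5.0, "n_B": 51}, {"B_max": 5.0, "n_B": 201})
    df = capacity_curve(np.linspace(0.0, p["B_max"], p["n_B"]))[["B", "silent_fraction"]]
    fig, ax = plt.subplots()
    ax.plot(df["B"], df["silent_fraction"], "r-")
    ax.set(xlabel="B", ylabel="fraction of silent synapses F")
    return df, fig, p


def _fig1b(cfg: RunConfig):
    p = _sim_sizes(
        cfg,
        {"B": 1.0, "N": 400, "trials": 10, "alpha_grid": list(np.round(np.arange(0.2, 1.21, 0.1), 10))},
        {"B": 1.0, "N": 1000, "trials": 20, "alpha_grid": list(np.round(np.arange(0.2, 1.21, 0.05), 10))},
    )
    dist_x = make_distribution("exponential", 1.0)
    dist_z = make_distribution("exponential", 1.0)  # B = 1
    stats = AssociationStatistics.from_distributions(dist_x, dist_z)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for alpha in p["alpha_grid"]:
        th = solve_mse(alpha, p["B"]).mse_physical(stats)
        sims = []
        for _ in range(p["trials"]):
            ps = sample_patterns(dist_x, dist_z, p["N"], alpha, int(rng.integers(2**31 - 1)))
            sims.append(solve_nnls(ps).mse)
        rows.append((alpha, th, float(np.mean(sims)), float(np.std(sims))))
    df = pd.DataFrame(rows, columns=["alpha", "mse_theory", "mse_sim_mean", "mse_sim_sd"])
    fig, ax = plt.subplots()
    ax.plot(df["alpha"], df["mse_theory"], "r-", label="theory")
    ax.errorbar(df["alpha"], df["mse_sim_mean"], yerr=df["mse_sim_sd"], fmt="bo", label="simulation")
    ax.set(xlabel=r"$\alpha$", ylabel="mean squared error")
    ax.legend()
    return df, fig, p


def _fig2b(cfg: RunConfig):
    p = _sim_sizes(cfg, {"B": 1.0, "N": 800}, {"B": 1.0, "N": 2000})
    cap = solve_capacity(p["B"])
    dist_x = make_distribution("exponential", 1.0)
    dist_z = make_distribution("exponential", 1.0)
    ps = sample_patterns(dist_x, dist_z, p["N"], cap.alpha_c, cfg.seed)
    fit = solve_nnls(ps)
    nz = fit.weights[fit.weights > fit.zero_threshold]
    wn = nz / fit.weights.mean()  # weights in units of the mean synaptic weight
    theory = weight_distribution_theory(p["B"], wbar=1.0)
    counts, edges = np.histogram(wn, bins=30, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    df = pd.DataFrame(
        {
            "w_over_wbar": centers,
            # empirical histogram of non-silent weights, scaled to carry mass 1 - F
            "empirical_density": counts * (1.0 - fit.silent_fraction_empirical),
            "theory_density": theory.pdf(centers),
        }
    )
    fig, ax = plt.subplots()
    ax.bar(centers, df["empirical_density"], width=np.diff(edges), color="tab:blue", alpha=0.6,
           label=f"simulation (F={fit.silent_fraction_empirical:.2f})")
    ax.plot(centers, df["theory_density"], "r-", label=f"theory (F={theory.silent_fraction:.2f})")
    ax.set(xlabel=r"$w/\bar w$", ylabel="density")
    ax.legend()
    return df, fig, p


def _fig2c(cfg: RunConfig):
    p = _sim_sizes(
        cfg,
        {"B": 1.0, "N": 500, "trials": 10, "alpha_grid": list(np.round(np.arange(0.5, 2.01, 0.25), 10))},
        {"B": 1.0, "N": 1000, "trials": 10, "alpha_grid": list(np.round(np.arange(0.5, 2.01, 0.125), 10))},
    )
    dist_x = make_distribution("exponential", 1.0)
    dist_z = make_distribution("exponential", 1.0)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for alpha in p["alpha_grid"]:
        th = solve_mse(alpha, p["B"]).silent_fraction
        sims = []
        for _ in range(p["trials"]):
            ps = sample_patterns(dist_x, dist_z, p["N"], alpha, int(rng.integers(2**31 - 1)))
            sims.append(solve_nnls(ps).silent_fraction_empirical)
        rows.append((alpha, th, float(np.mean(sims)), float(np.std(sims))))
    df = pd.DataFrame(rows, columns=["alpha", "silent_theory", "silent_sim_mean", "silent_sim_sd"])
    fig, ax = plt.subplots()
    ax.plot(df["alpha"], df["silent_theory"], "r-", label="theory")
    ax.errorbar(df["alpha"], df["silent_sim_mean"], yerr=df["silent_sim_sd"], fmt="bo", label="simulation")
    ax.set(xlabel=r"$\alpha$", ylabel="fraction of silent synapses")
    ax.legend()
    return df, fig, p


def _base_stats(p: dict) -> AssociationStatistics:
    return AssociationStatistics(p.get("mu_x", 1.0), p.get("sigma_x", 1.0), p.get("mu_z", 1.0), 1.0)


def _fig3a(cfg: RunConfig):
    p = _sim_sizes(
        cfg,
        {"sigma_noise_levels": [0.1, 0.3, 1.0], "n_sigma": 60},
        {"sigma_noise_levels": [0.1, 0.3, 1.0], "n_sigma": 200},
    )
    stats = _base_stats(p)
    sigmas = np.logspace(-3, 2, p["n_sigma"])
    rows = []
    for sn in p["sigma_noise_levels"]:
        for sz in sigmas:
            r = information_per_synapse(sz, sn, stats)
            rows.append((sn, sz, r.bits_per_synapse))
    df = pd.DataFrame(rows, columns=["sigma_noise", "sigma_z", "bits_per_synapse"])
    fig, ax = plt.subplots()
    for sn, g in df.groupby("sigma_noise"):
        ax.semilogx(g["sigma_z"], g["bits_per_synapse"], label=f"$\\sigma$={sn}")
    ax.set(xlabel=r"$\sigma_z$", ylabel="bits per synapse")
    ax.legend()
    return df, fig, p


def _fig3b(cfg: RunConfig):
    p = _sim_sizes(cfg, {"n_noise": 25}, {"n_noise": 60})
    stats = _base_stats(p)
    noises = np.logspace(np.log10(0.05), np.log10(5.0), p["n_noise"])
    rows = []
    for sn in noises:
        s_opt, bits = optimal_output_std(sn, stats)
        rows.append((sn, s_opt, bits))
    df = pd.DataFrame(rows, columns=["sigma_noise", "sigma_z_opt", "bits_per_synapse"])
    fig, ax = plt.subplots()
    ax.plot(df["sigma_noise"], df["bits_per_synapse"], "b-", label="information")
    ax.set(xlabel=r"noise $\sigma$", ylabel="bits per synapse")
    ax2 = ax.twinx()
    ax2.plot(df["sigma_noise"], df["sigma_z_opt"], "g-", label=r"optimal $\sigma_z$")
    ax2.set_ylabel(r"optimal $\sigma_z$")
    return df, fig, p


_BUILDERS = {
    "fig1a": _fig1a,
    "fig1b": _fig1b,
    "fig2a": _fig2a,
    "fig2b": _fig2b,
    "fig2c": _fig2c,
    "fig3a": _fig3a,
    "fig3b": _fig3b,
}


def reproduce_figure(config: RunConfig) -> dict:
    """Build one figure; returns paths of the CSV/PNG/JSON artifacts."""
    if config.figure not in _BUILDERS:
        raise ValueError(f"unknown figure id {config.figure!r}; choose from {KNOWN_FIGURES}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df, fig, params = _BUILDERS[config.figure](config)
    csv_path = out / f"{config.figure}.csv"
    png_path = out / f"{config.figure}.png"
    json_path = out / f"{config.figure}.json"
    df.to_csv(csv_path, index=False, float_format="%.12g")
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    meta = {
        "figure": config.figure,
        "version": __version__,
        "seed": config.seed,
        "full_scale": config.full_scale,
        "parameters": {k: (v if not isinstance(v, np.ndarray) else v.tolist()) for k, v in params.items()},
        "root_xtol": 1e-14,
        "solvable_mse": 1e-10,
    }
    json_path.write_text(json.dumps(meta, indent=1, default=float))
    return {"csv": str(csv_path), "png": str(png_path), "json": str(json_path)}
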