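"""Headline analyses: floater-excess competition and fixation of aggression.

Two experiments connect the forcing to the evolutionary outcome:

* **Floater excess** — run the non-aggressive (dove-only) model over a
  changing island and compare the simulated number of floaters (birds
  without a territory) to the number expected at equilibrium for the
  instantaneous island size, F_eq(K) = N*(K) - K = K*(b - mu)/mu.  The
  ratio R(t) = F_sim/F_eq is a proxy for competitive pressure: R > 1 means
  more competition than a static island would produce.  Fast island
  shrinkage piles displaced birds into the floater pool faster than
  mortality can relax it, so the peak excess measures how strongly the
  deglacial coastline collapse intensified territory competition.

* **Fixation experiment** — seed a small aggressive minority into a
  population at the dove carrying capacity when the island is maximal
  (just before a deglaciation), run the two-strategy model through the
  cycle, and test whether the aggressive fraction fA reaches 1.  Fixation
  occurs iff the territory count falls below the tipping point K*; because
  fA = 1 is absorbing under pure-strategy inheritance, a recovering island
  does not undo it (hysteresis).

``run_report`` packages both experiments plus the bifurcation diagram into
a reproducible bundle (CSV tables, PNG figures, one JSON summary).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .equilibria import bifurcation_diagram, tipping_point_K
from .model import PopulationState, TerritorySeries, Trajectory, simulate
from .params import ModelParams
from .synthetic import ScenarioSpec, build_scenario, mauritius_like_spec, rodrigues_like_spec

__all__ = [
    "FloaterAnalysisResult",
    "FixationResult",
    "floater_excess",
    "fixation_experiment",
    "run_report",
    "load_config",
]

#: a population counts as fixed for aggression once fA exceeds this
FIXATION_THRESHOLD = 1.0 - 1e-6


@dataclasses.dataclass
class FloaterAnalysisResult:
    """Floater-ratio time series R(t) = F_sim/F_eq and its peak excess."""

    times_ybp: np.ndarray
    ratio: np.ndarray
    peak_excess_pct: float
    peak_times_ybp: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ybp": self.times_ybp, "floater_ratio": self.ratio})


@dataclasses.dataclass
class FixationResult:
    """Outcome of the two-strategy run: threshold crossing, fixation, hysteresis."""

    trajectory: Trajectory
    K_star: float
    area_star_km2: float
    threshold_crossing_ybp: float | None
    fixation: bool
    fixation_ybp: float | None
    hysteresis: bool | None  # None when K never recovered above K* after fixation

    @property
    def f_aggressive_final(self) -> float:
        return float(self.trajectory.f_aggressive[-1])


def floater_excess(
    series: TerritorySeries,
    params: ModelParams,
    burn_in_years: int | None = None,
) -> FloaterAnalysisResult:
    """Competition proxy from the dove-only model over a territory series.

    The run starts from the equilibrium at the initial territory count and
    is preceded by a burn-in at that constant K (default 10 mean lifespans,
    10/mu years) so that the equilibrium baseline is exact at the first
    forcing year.  The peak excess is the maximum of 100*(R(t) - 1) over
    the window.
    """
    if params.b <= params.mu:
        raise ValueError("b must exceed mu for a positive floater equilibrium")
    if burn_in_years is None:
        burn_in_years = int(np.ceil(10.0 / params.mu))
    b, mu = params.b, params.mu
    K0 = series.K[0]
    N = b * K0 / mu
    for _ in range(burn_in_years):
        N = b * min(N, K0) + (1.0 - mu) * N

    n = len(series)
    floaters = np.empty(n)
    Kv = series.K
    for i in range(n):
        floaters[i] = max(0.0, N - Kv[i])
        if i < n - 1:
            N = b * min(N, Kv[i]) + (1.0 - mu) * N

    f_eq = Kv * (b - mu) / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f_eq > 0, floaters / f_eq, np.nan)
    peak = float(np.nanmax(ratio))
    peak_times = series.times_ybp[np.isclose(ratio, peak, rtol=1e-12, atol=0.0)]
    return FloaterAnalysisResult(
        times_ybp=series.times_ybp.copy(),
        ratio=ratio,
        peak_excess_pct=100.0 * (peak - 1.0),
        peak_times_ybp=peak_times,
    )


def fixation_experiment(
    series: TerritorySeries,
    params: ModelParams,
    seed_fraction: float = 0.01,
    start_ybp: float | None = None,
) -> FixationResult:
    """Seed aggression into an equilibrium population and track its fate.

    The initial state is the dove carrying capacity at K(start) with
    ``seed_fraction`` of the birds converted to the aggressive strategy
    (the emergence of aggression itself is outside the model; the spread is
    what is simulated).  Reports the first time K(t) drops below the
    tipping point K*, whether and when fA crossed the fixation threshold,
    and whether fixation persisted after K recovered above K* (hysteresis).
    """
    if not (0.0 < seed_fraction < 0.5):
        raise ValueError("seed_fraction must be in (0, 0.5): a low aggressive minority")
    times = series.times_ybp
    if start_ybp is None:
        start_ybp = float(times[0])
    idx = np.nonzero(np.isclose(times, start_ybp, rtol=0, atol=0.5))[0]
    if idx.size == 0:
        raise ValueError(f"start time {start_ybp} years BP is not inside the series")
    i0 = int(idx[0])
    sub = TerritorySeries(times_ybp=times[i0:], K=series.K[i0:])

    n_star = params.b * sub.K[0] / params.mu
    initial = PopulationState(
        NA=seed_fraction * n_star, NF=(1.0 - seed_fraction) * n_star, t=sub.times_ybp[0]
    )
    traj = simulate(initial, sub, params)

    k_star, area_star = tipping_point_K(params)
    below = sub.K < k_star
    crossing = float(sub.times_ybp[np.argmax(below)]) if below.any() else None

    fa = traj.f_aggressive
    fixed_mask = fa > FIXATION_THRESHOLD
    fixation = bool(fixed_mask.any())
    fixation_t = float(sub.times_ybp[np.argmax(fixed_mask)]) if fixation else None

    hysteresis: bool | None = None
    if fixation:
        i_fix = int(np.argmax(fixed_mask))
        recovered = np.nonzero(~below[i_fix:])[0]
        if recovered.size:
            i_rec = i_fix + int(recovered[0])
            hysteresis = bool(np.all(fa[i_rec:] > FIXATION_THRESHOLD))
    return FixationResult(
        trajectory=traj,
        K_star=k_star,
        area_star_km2=area_star,
        threshold_crossing_ybp=crossing,
        fixation=fixation,
        fixation_ybp=fixation_t,
        hysteresis=hysteresis,
    )


# ---------------------------------------------------------------------------
# report bundle

_BUILTIN_SCENARIOS = {
    "rodrigues": rodrigues_like_spec,
    "mauritius": mauritius_like_spec,
}


def load_config(path_or_dict) -> dict:
    """Load a study config (YAML path or dict) and normalise scenario entries."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict)
    cfg.setdefault("model", {})
    cfg.setdefault("seed_fraction", 0.01)
    cfg.setdefault("bifurcation", {"k_min": 500.0, "k_max": 30000.0, "n_grid": 25})
    scenarios = cfg.get("scenarios") or []
    if not scenarios:
        raise ValueError("config must name at least one scenario")
    cfg["scenarios"] = scenarios
    return cfg


def _scenario_spec(entry, model_overrides: dict) -> ScenarioSpec:
    if isinstance(entry, str):
        if entry not in _BUILTIN_SCENARIOS:
            raise ValueError(
                f"unknown scenario '{entry}'; builtins are {sorted(_BUILTIN_SCENARIOS)}"
            )
        return _BUILTIN_SCENARIOS[entry](model_overrides=model_overrides)
    entry = dict(entry)
    entry.setdefault("model_overrides", model_overrides)
    if "window_ky" in entry:
        entry["window_ky"] = tuple(entry["window_ky"])
    return ScenarioSpec(**entry)


def run_report(config, out_dir: str | Path, make_plots: bool = True) -> dict:
    """Run all configured scenarios and write a reproducible report bundle.

    For each scenario: the floater-excess analysis and the fixation
    experiment, with trajectory/ratio CSVs.  Globally: the bifurcation
    diagram CSV over the configured K range and figures in the style of the
    competition, fixation and bifurcation summaries.  A ``summary.json``
    (sorted keys, no timestamps) makes reruns byte-identical.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = ModelParams(**cfg["model"])

    scen_results = {}
    floater_results = {}
    fix_results = {}
    for entry in cfg["scenarios"]:
        spec = _scenario_spec(entry, cfg["model"])
        territories, sparams, provenance = build_scenario(spec)
        fl = floater_excess(territories, sparams, cfg.get("burn_in_years"))
        fx = fixation_experiment(territories, sparams, cfg["seed_fraction"])
        fl.to_dataframe().to_csv(out / f"{spec.name}_floater_ratio.csv", index=False)
        fx.trajectory.to_csv(out / f"{spec.name}_trajectory.csv")
        floater_results[spec.name] = fl
        fix_results[spec.name] = fx
        scen_results[spec.name] = {
            "provenance": provenance,
            "peak_floater_excess_pct": round(fl.peak_excess_pct, 6),
            "fixation": fx.fixation,
            "fixation_ybp": fx.fixation_ybp,
            "threshold_crossing_ybp": fx.threshold_crossing_ybp,
            "hysteresis": fx.hysteresis,
            "f_aggressive_final": round(fx.f_aggressive_final, 9),
        }

    bif_cfg = cfg["bifurcation"]
    k_grid = np.linspace(bif_cfg["k_min"], bif_cfg["k_max"], int(bif_cfg["n_grid"]))
    bif = bifurcation_diagram(k_grid, params)
    bif.branches.to_csv(out / "bifurcation.csv", index=False)

    summary = {
        "package_version": __version__,
        "model_params": params.to_dict(),
        "seed_fraction": cfg["seed_fraction"],
        "K_star": round(bif.K_star, 6),
        "area_star_km2": round(bif.area_star_km2, 6),
        "K_star_numeric": round(bif.K_star_numeric, 4),
        "scenarios": scen_results,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if make_plots:
        _write_plots(out, floater_results, fix_results, bif)
    return summary


def _write_plots(out: Path, floater_results, fix_results, bif) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # competition proxy
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, fl in floater_results.items():
        ax.plot(fl.times_ybp / 1000.0, fl.ratio, label=name)
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("time (ky BP)")
    ax.set_ylabel("floaters / equilibrium floaters")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_floater_ratio.png", dpi=120)
    plt.close(fig)

    # island size and aggressive fraction
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for name, fx in fix_results.items():
        tr = fx.trajectory
        ax1.plot(tr.t_ybp / 1000.0, tr.K, label=name)
        ax2.plot(tr.t_ybp / 1000.0, tr.f_aggressive, label=name)
    any_fx = next(iter(fix_results.values()))
    ax1.axhline(any_fx.K_star, color="r", ls="-.", lw=1, label="tipping point K*")
    ax1.set_ylabel("territories K(t)")
    ax1.set_yscale("log")
    ax1.legend()
    ax2.set_ylabel("aggressive fraction fA")
    ax2.set_xlabel("time (ky BP)")
    ax2.invert_xaxis()
    fig.tight_layout()
    fig.savefig(out / "fig_fixation.png", dpi=120)
    plt.close(fig)

    # bifurcation diagram
    fig, ax = plt.subplots(figsize=(7, 4))
    for bid, grp in bif.branches.groupby("branch_id"):
        style = "-" if (grp["stability"] == "stable").all() else "--"
        ax.plot(grp["area_km2"], grp["fA"], style, label=bid)
    if np.isfinite(bif.area_star_km2):
        ax.axvline(bif.area_star_km2, color="r", ls="-.", lw=1)
    ax.set_xlabel("island area (km$^2$)")
    ax.set_ylabel("equilibrium aggressive fraction fA")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_bifurcation.png", dpi=120)
    plt.close(fig)
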