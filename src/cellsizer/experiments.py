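"""Experiment drivers: threshold sweeps, ploidy doubling, stochastic grids,
viability-band probes and mutant panels.

Each driver is a plain function returning a DataFrame or small dataclass;
:func:`run_experiment` wraps them with CSV/JSON output and a manifest
sufficient to re-run the experiment bit-identically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import mutant_comparison, size_summary
from .config import genome_to_dict, params_to_dict
from .lineage import (
    DivisionRule,
    delete_regulators,
    simulate_lineage,
)
from .model import Genome, GlobalParams
from .presets import build_default_genome
from .theory import (
    TheoryInputs,
    birth_volume,
    critical_thresholds,
    robust_threshold_band,
    stochastic_birth_moments,
)

__all__ = [
    "ExperimentSpec",
    "theta_sweep",
    "simulated_amplitude",
    "ploidy_experiment",
    "stochastic_moments_grid",
    "viability_edges",
    "mutant_panel",
    "run_experiment",
]


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment sweep."""

    name: str
    kind: str  # theta_sweep | ploidy | moments | band | mutants
    grid: Sequence[float] = field(default_factory=list)
    theta_bar: float = 0.7
    delta_theta: float = 0.1
    n_generations: int = 3
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind in ("theta_sweep", "ploidy", "moments") and len(self.grid) == 0:
            raise ValueError("grid must be non-empty for sweep experiments")


def theta_sweep(
    thetas: Sequence[float],
    genome: Genome,
    params: GlobalParams,
    n_generations: int = 3,
    burn_in: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic birth volume across a threshold grid, with theory.

    Points outside the stable window are recorded as failed rows rather
    than raising.
    """
    ti = TheoryInputs.from_genome(genome, params)
    th1, th2 = critical_thresholds(ti.K_act, ti.K_inh, ti.c_n)
    rows = []
    for th in thetas:
        try:
            vb_th = birth_volume(th, ti) if th1 < th < th2 else np.nan
        except ValueError:
            vb_th = np.nan
        res = simulate_lineage(
            n_generations, DivisionRule(theta=float(th)), genome, params,
            seed=seed, burn_in=burn_in,
        )
        vb = float(res.array("V_b").mean()) if res.records else np.nan
        rows.append(
            dict(theta=float(th), status=res.status, V_b_sim=vb, V_b_theory=vb_th)
        )
    return pd.DataFrame(rows)


def simulated_amplitude(
    theta: float,
    genome: Genome,
    params: GlobalParams,
    burn_in: int = 10,
    dt: float = 0.002,
) -> float:
    """Within-cycle amplitude ``theta - min(c_act/c_inh)`` from a steady cycle."""
    res = simulate_lineage(
        1, DivisionRule(theta=theta), genome, params, seed=0, burn_in=burn_in,
        record_trajectories=True, trajectory_dt=dt,
    )
    if res.status != "steady":
        raise RuntimeError(f"no steady cycle at theta={theta}")
    df = res.trajectories
    last = df.t > df.t.iloc[-1] - res.records[-1].T_D
    return theta - float((df.c_act[last] / df.c_inh[last]).min())


def ploidy_experiment(
    thetas: Sequence[float],
    n_generations: int = 3,
    seed: int = 0,
    **genome_options,
) -> pd.DataFrame:
    """Birth volumes of haploid vs diploid cells across a threshold grid.

    The diploid genome is the calibrated haploid genome with every gene
    copy number doubled; the model predicts an exact factor-two in V_b.
    """
    g1, params = build_default_genome(**genome_options)
    g2 = g1.with_ploidy(2)
    rows = []
    for th in thetas:
        rule = DivisionRule(theta=float(th))
        r1 = simulate_lineage(n_generations, rule, g1, params, seed=seed)
        ti1 = TheoryInputs.from_genome(g1, params)
        r2 = simulate_lineage(
            n_generations, rule, g2, params, seed=seed,
            initial_volume=2.0 * birth_volume(float(th), ti1),
        )
        v1 = float(r1.array("V_b").mean()) if r1.records else np.nan
        v2 = float(r2.array("V_b").mean()) if r2.records else np.nan
        rows.append(dict(theta=float(th), V_b_haploid=v1, V_b_diploid=v2,
                         ratio=v2 / v1))
    return pd.DataFrame(rows)


def _bootstrap_se(values: np.ndarray, stat, n_boot: int, rng) -> float:
    reps = np.empty(n_boot)
    n = values.size
    for b in range(n_boot):
        reps[b] = stat(values[rng.integers(0, n, n)])
    return float(reps.std(ddof=1))


def stochastic_moments_grid(
    theta_bars: Sequence[float],
    delta_theta: float,
    genome: Genome,
    params: GlobalParams,
    n_generations: int = 400,
    seed: int = 0,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Monte-Carlo mean/CV of birth size vs the first-order theory.

    Bootstrap standard errors accompany both sample statistics.
    """
    ti = TheoryInputs.from_genome(genome, params)
    rng = np.random.default_rng(seed)
    rows = []
    for i, tb in enumerate(theta_bars):
        rule = DivisionRule(theta_bar=float(tb), delta_theta=delta_theta,
                            noise="reset_normal")
        res = simulate_lineage(n_generations, rule, genome, params, seed=seed + 101 * i)
        vb = res.array("V_b")
        mean_th, cv_th = stochastic_birth_moments(float(tb), delta_theta, ti)
        row = dict(theta_bar=float(tb), status=res.status,
                   mean_theory=mean_th, cv_theory=cv_th,
                   mean_sim=np.nan, cv_sim=np.nan, se_mean=np.nan, se_cv=np.nan)
        if res.status == "steady" and vb.size > 10:
            row.update(
                mean_sim=float(vb.mean()),
                cv_sim=float(vb.std(ddof=1) / vb.mean()),
                se_mean=_bootstrap_se(vb, lambda v: v.mean(), n_boot, rng),
                se_cv=_bootstrap_se(vb, lambda v: v.std(ddof=1) / v.mean(),
                                    n_boot, rng),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def viability_edges(
    delta_theta: float,
    genome: Genome,
    params: GlobalParams,
    n_generations: int = 20,
    burn_in: int = 4,
    t_min: float = 0.01,
    tol: float = 2e-3,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Measured vs predicted viability band of the mean threshold.

    Drives lineages with the worst-case alternating threshold sequence
    ``theta_bar +- delta_theta`` (the sequence the robustness condition
    quantifies over) and bisects the steady/failed transition on each flank.
    ``t_min`` is kept small so event detection cannot mask a crossing.
    Returns ``((lo_sim, hi_sim), (lo_theory, hi_theory))``.
    """
    ti = TheoryInputs.from_genome(genome, params)
    lo_th, hi_th = robust_threshold_band(delta_theta, ti)

    def viable(tb: float) -> bool:
        rule = DivisionRule(theta_bar=tb, delta_theta=delta_theta,
                            noise="extremes", t_min=t_min)
        res = simulate_lineage(n_generations, rule, genome, params,
                               seed=0, burn_in=burn_in)
        return res.status == "steady"

    def bisect(a: float, b: float, want_viable_high: bool) -> float:
        while b - a > tol:
            mid = 0.5 * (a + b)
            v = viable(mid)
            if v == want_viable_high:
                b = mid
            else:
                a = mid
        return 0.5 * (a + b)

    margin = 0.05
    lo_sim = bisect(lo_th - margin, lo_th + margin, want_viable_high=True)
    hi_sim = bisect(hi_th - margin, hi_th + margin, want_viable_high=False)
    return (lo_sim, hi_sim), (lo_th, hi_th)


def mutant_panel(
    theta_bar: float = 0.45,
    delta_theta: float = 0.1,
    n_generations: int = 400,
    seed: int = 11,
    g_act: int = 10,
    g_inh: int = 10,
    K_inh: float = 1000.0,
    **genome_options,
) -> pd.DataFrame:
    """Wild type vs single-regulator deletions at the multi-regulator point.

    All strains share the same seed, i.e. the same per-generation threshold
    draws, so the mutant-to-wild-type contrasts are paired.
    """
    g_wt, params = build_default_genome(g_act=g_act, g_inh=g_inh, K_inh=K_inh,
                                        **genome_options)
    strains = {
        "WT": g_wt,
        "activatorD": delete_regulators(g_wt, "activator"),
        "inhibitorD": delete_regulators(g_wt, "inhibitor"),
    }
    rule = DivisionRule(theta_bar=theta_bar, delta_theta=delta_theta,
                        noise="reset_normal")
    results = {}
    rows = []
    for name, gen in strains.items():
        res = simulate_lineage(n_generations, rule, gen, params, seed=seed)
        results[name] = res
        s = size_summary(res.records)
        rows.append(dict(strain=name, status=res.status, n=len(res.records),
                         mean_V_b=s.mean, cv_V_b=s.cv,
                         delta_mean=np.nan, delta_cv=np.nan))
    df = pd.DataFrame(rows).set_index("strain")
    for name in ("activatorD", "inhibitorD"):
        cmp = mutant_comparison(results["WT"].records, results[name].records)
        df.loc[name, "delta_mean"] = cmp.delta_mean
        df.loc[name, "delta_cv"] = cmp.delta_cv
    return df.reset_index()


def run_experiment(spec: ExperimentSpec, out_dir: str | Path,
                   genome: Genome | None = None,
                   params: GlobalParams | None = None) -> Path:
    """Execute a spec, writing a CSV table, JSON summary and run manifest."""
    out = Path(out_dir) / spec.name
    out.mkdir(parents=True, exist_ok=True)
    if genome is None or params is None:
        genome, params = build_default_genome(**spec.options.get("genome", {}))

    summary: dict = {"kind": spec.kind}
    if spec.kind == "theta_sweep":
        df = theta_sweep(list(spec.grid), genome, params,
                         n_generations=spec.n_generations, seed=spec.seed)
    elif spec.kind == "ploidy":
        df = ploidy_experiment(list(spec.grid), n_generations=spec.n_generations,
                               seed=spec.seed, **spec.options.get("genome", {}))
        summary["mean_ratio"] = float(df["ratio"].mean())
    elif spec.kind == "moments":
        df = stochastic_moments_grid(list(spec.grid), spec.delta_theta, genome,
                                     params, n_generations=spec.n_generations,
                                     seed=spec.seed)
    elif spec.kind == "band":
        (lo_s, hi_s), (lo_t, hi_t) = viability_edges(
            spec.delta_theta, genome, params, **spec.options.get("band", {}))
        df = pd.DataFrame([dict(edge="lower", simulated=lo_s, predicted=lo_t),
                           dict(edge="upper", simulated=hi_s, predicted=hi_t)])
    elif spec.kind == "mutants":
        df = mutant_panel(theta_bar=spec.theta_bar, delta_theta=spec.delta_theta,
                          n_generations=spec.n_generations, seed=spec.seed,
                          **spec.options.get("panel", {}))
    else:
        raise ValueError(f"unknown experiment kind {spec.kind!r}")

    df.to_csv(out / "results.csv", index=False)
    manifest = {
        "name": spec.name,
        "kind": spec.kind,
        "grid": list(map(float, spec.grid)),
        "theta_bar": spec.theta_bar,
        "delta_theta": spec.delta_theta,
        "n_generations": spec.n_generations,
        "seed": spec.seed,
        "options": spec.options,
        "package_version": __version__,
        "python": platform.python_version(),
        "params": params_to_dict(params),
        "genome": genome_to_dict(genome),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if summary:
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
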