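"""Event-driven single-lineage simulation of growth and division.

A cycle integrates the expression ODEs from birth until the division rule
fires, then partitions molecules to the tracked daughter.  The base rule
divides when the (weighted) activator-to-inhibitor concentration ratio rises
to a threshold; variants cover accumulation/dilution/AND criteria, a
probabilistic hazard on the ratio, gene replication followed by a fixed
delay, asymmetric division with Whi5-like inhibitor partitioning, and
stochastic per-generation thresholds.

Division fires at the first *upward zero-crossing* of the division signal at
``t >= t_min``: the monitored quantity must dip below its threshold and rise
through it.  A signal that sits above threshold for a whole cycle never
fires — that is precisely how robustness violations (a freshly drawn
threshold below the cycle's ratio minimum) manifest — and the lineage ends
as ``failed_no_division``.  A lineage also fails if the cell collapses below
a single RNAP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    CellState,
    Genome,
    GenomeArrays,
    GlobalParams,
    _solve_balance,
    as_arrays,
    quasi_steady_mrna,
    rnap_concentration,
    solve_free_ribosome_fraction,
    solve_free_rnap_fraction,
    volume_of,
)

__all__ = [
    "DivisionRule",
    "CycleRecord",
    "LineageResult",
    "initialize_state",
    "draw_threshold",
    "division_signal",
    "simulate_cycle",
    "partition_at_division",
    "simulate_lineage",
    "hazard_sample_division",
    "power_law_hazard",
    "delete_regulators",
    "swap_promoters",
    "equivalent_threshold",
]

RULE_KINDS = ("ratio", "activator_only", "inhibitor_only", "and_logic", "hazard")


def power_law_hazard(C1: float = 1.0, C2: float = 2.0) -> Callable[[float, float], float]:
    """Default hazard family ``k(theta) = C1 max(0, theta - theta_b)^C2``.

    ``theta_b`` is the regulator ratio at which hazard monitoring starts.
    Large C1 with C2=2 gives an imperfect sizer (division ratio increments
    of a few percent); C2=1 with moderate C1 drifts toward adder-like
    behavior.  Both the functional form and the constants are package
    assumptions sized to the default threshold window; any callable
    ``k(theta, theta_b) -> rate`` may replace it.
    """

    def k(theta: float, theta_b: float) -> float:
        return C1 * max(0.0, theta - theta_b) ** C2

    return k


@dataclass
class DivisionRule:
    """Division criterion and its variant flags.

    kind 'ratio' divides when the weighted activator-to-inhibitor
    concentration ratio reaches ``theta``; 'activator_only' when the total
    activator concentration reaches ``theta`` [um^-3]; 'inhibitor_only'
    when the inhibitor concentration *falls* to ``theta``; 'and_logic' when
    both single-regulator conditions hold; 'hazard' samples the division
    ratio from an inverse-transform hazard.

    ``theta_bar``/``delta_theta`` with ``noise='reset_normal'`` draw a fresh
    threshold each generation; ``noise='extremes'`` alternates
    deterministically between ``theta_bar +- delta_theta``, the worst-case
    sequence against which the robustness condition guarantees division.  ``replication_delay`` switches on the
    gene-replication variant (genes double at the trigger, division follows
    after the delay).  ``gamma`` is the daughter volume fraction and ``eta``
    the inhibitor-protein partition fraction (asymmetric division).
    ``alpha`` is an opaque passthrough used by nondegradable-inhibitor
    parameterizations.
    """

    kind: str = "ratio"
    theta: float = 0.8
    theta_act: float | None = None
    theta_inh: float | None = None
    theta_bar: float | None = None
    delta_theta: float = 0.0
    noise: str = "none"
    hazard: Callable[[float, float], float] | None = None
    hazard_C1: float = 2000.0
    hazard_C2: float = 2.0
    t_min: float = 1.0 / 3.0
    replication_delay: float | None = None
    gamma: float = 0.5
    eta: float | None = None
    alpha: float | None = None
    horizon_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.noise not in ("none", "reset_normal", "extremes"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        if self.t_min < 0:
            raise ValueError("t_min must be nonnegative")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.eta is not None and not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.noise in ("reset_normal", "extremes"):
            if self.theta_bar is None:
                raise ValueError(f"{self.noise} noise needs theta_bar")
            if self.theta_bar - self.delta_theta <= 0:
                raise ValueError("require theta_bar - delta_theta > 0")
        if self.kind == "hazard" and self.hazard is None:
            self.hazard = power_law_hazard(self.hazard_C1, self.hazard_C2)
        if self.kind == "and_logic" and (self.theta_act is None or self.theta_inh is None):
            raise ValueError("and_logic needs theta_act and theta_inh")


@dataclass
class CycleRecord:
    """Birth/division sizes and timing of one recorded cell cycle."""

    index: int
    V_b: float
    V_d: float
    T_D: float
    theta_k: float

    @property
    def delta_V(self) -> float:
        return self.V_d - self.V_b


@dataclass
class LineageResult:
    """Outcome of a single-daughter lineage simulation."""

    records: list[CycleRecord]
    burn_in: int
    seed: int | None
    status: str  # 'steady' or 'failed_no_division'
    failed_generation: int | None = None
    trajectories: "object | None" = None  # pandas DataFrame when recorded

    def array(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], dtype=float)


# ---------------------------------------------------------------------------
# initial condition, threshold noise, partitioning
# ---------------------------------------------------------------------------

def initialize_state(V0: float, genome: Genome, params: GlobalParams) -> CellState:
    """Near-steady initial state at attempted volume ``V0``.

    RNAPs follow ``n(0) = c_n V0 / a``; nondegradable proteins take their
    dosage ratios relative to ``n``; mRNAs take their quasi-steady values;
    degradable regulators take the quasi-steady level set by the implied
    free fractions.
    """
    if V0 <= 0:
        raise ValueError("V0 must be positive")
    ga = as_arrays(genome, params)
    c_n = rnap_concentration(ga, params)
    n0 = c_n * V0 / params.a
    if n0 < 1:
        warnings.warn(f"initial volume implies n(0) = {n0:.3g} < 1 RNAP", stacklevel=2)
    F_n = solve_free_rnap_fraction(n0, V0, ga, params)
    m0 = quasi_steady_mrna(F_n, genome, params)
    gn = ga.Gamma_n * ga.g
    base = gn[ga.i_rnap]
    p0 = gn / base * n0  # dosage ratios (nondegradable steady state)
    degradable = ga.inv_tau_p > 0
    if np.any(degradable):
        r0 = p0[ga.i_ribo]
        F_r = solve_free_ribosome_fraction(r0, m0, V0, ga, params)
        c_r = F_r * r0 / (params.cytoplasm_fraction * V0)
        P_r = c_r / (c_r + ga.K_r)
        tau_p = 1.0 / ga.inv_tau_p[degradable]
        p0[degradable] = ga.Gamma_r[degradable] * m0[degradable] * P_r[degradable] * tau_p
    return CellState(t=0.0, m=m0, p=p0)


def draw_threshold(
    theta_bar: float, delta_theta: float, rng: np.random.Generator
) -> float:
    """One per-generation threshold: ``N(theta_bar, (delta/3)^2)``, reset to
    the mean if the draw leaves ``(theta_bar - delta, theta_bar + delta)``."""
    if delta_theta < 0 or theta_bar <= delta_theta:
        raise ValueError("require theta_bar > delta_theta >= 0")
    if delta_theta == 0:
        return theta_bar
    theta = rng.normal(theta_bar, delta_theta / 3.0)
    if not theta_bar - delta_theta < theta < theta_bar + delta_theta:
        return theta_bar
    return theta


def partition_at_division(
    state: CellState,
    rule: DivisionRule,
    genome: Genome | GenomeArrays,
    params: GlobalParams | None = None,
    rng: np.random.Generator | None = None,
) -> CellState:
    """Molecule content of the tracked daughter cell.

    Symmetric division halves every species.  Asymmetric division gives the
    daughter the fraction ``gamma`` of each species except inhibitor
    proteins, which follow the fraction ``eta`` (protein only, mirroring
    Whi5-like partitioning).
    """
    ga = genome if isinstance(genome, GenomeArrays) else as_arrays(genome, params)
    m = state.m * rule.gamma
    p = state.p * rule.gamma
    if rule.eta is not None and ga.i_inh.size:
        p[ga.i_inh] = state.p[ga.i_inh] * rule.eta
    return CellState(t=0.0, m=m, p=p)


# ---------------------------------------------------------------------------
# division signal
# ---------------------------------------------------------------------------

def _signal_from_vectors(
    p: np.ndarray, V: float, ga: GenomeArrays, rule: DivisionRule, theta: float
) -> float:
    if rule.kind in ("ratio", "hazard"):
        act = float(np.sum(ga.weight[ga.i_act] * p[ga.i_act]))
        inh = float(np.sum(ga.weight[ga.i_inh] * p[ga.i_inh]))
        if inh <= 0:
            raise ZeroDivisionError("zero inhibitor concentration in ratio rule")
        return act / inh - theta
    c_act = float(np.sum(p[ga.i_act])) / V
    c_inh = float(np.sum(p[ga.i_inh])) / V
    if rule.kind == "activator_only":
        return c_act - theta
    if rule.kind == "inhibitor_only":
        return theta - c_inh  # upward crossing as c_inh decays to theta
    # and_logic: both conditions must hold; min crosses zero last
    return min(c_act - rule.theta_act, rule.theta_inh - c_inh)


def division_signal(
    state: CellState,
    rule: DivisionRule,
    genome: Genome | GenomeArrays,
    params: GlobalParams,
    theta: float | None = None,
) -> float:
    """Monitored scalar minus its threshold; division fires at zero from below."""
    ga = as_arrays(genome, params)
    V = volume_of(state.p, ga, params)
    return _signal_from_vectors(state.p, V, ga, rule, rule.theta if theta is None else theta)


# ---------------------------------------------------------------------------
# hazard sampling
# ---------------------------------------------------------------------------

def hazard_sample_division(
    k: Callable[[float], float],
    theta_b: float,
    rng: np.random.Generator,
    max_span: float = 1e3,
) -> float:
    """Inverse-transform sample of the division ratio under hazard ``k``.

    Draws ``x ~ U(0,1)`` and solves ``1 - exp(-int_{theta_b}^{theta_d} k) = x``.
    The cumulative hazard is accumulated by Simpson panels of geometrically
    growing width; raises if the target is unreachable within ``max_span``.
    """
    x = float(rng.uniform())
    if x == 0.0:
        return theta_b
    target = -math.log1p(-x)
    acc = 0.0
    lo = theta_b
    width = 1e-4 * max(1.0, abs(theta_b))
    while lo < theta_b + max_span:
        hi = lo + width
        mid = 0.5 * (lo + hi)
        panel = (k(lo) + 4.0 * k(mid) + k(hi)) * width / 6.0
        if acc + panel >= target:
            from scipy.optimize import brentq
            from scipy.integrate import quad

            def H(t: float) -> float:
                return acc + quad(k, lo, t, limit=200)[0] - target

            return float(brentq(H, lo, hi, xtol=1e-12))
        acc += panel
        lo = hi
        width *= 1.5
    raise RuntimeError(
        "hazard cumulative integral never reaches the sampled quantile; "
        "the hazard decays too fast or is zero beyond theta_b"
    )


# ---------------------------------------------------------------------------
# cycle integration
# ---------------------------------------------------------------------------

class _Engine:
    """Reusable integrator context: genome arrays plus free-fraction warm starts."""

    def __init__(self, ga: GenomeArrays, params: GlobalParams,
                 rtol: float = 1e-7, method: str = "LSODA"):
        self.ga = ga
        self.params = params
        self.rtol = rtol
        self.method = method
        self.Fn = 0.5
        self.Fr = 0.5

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ga, params = self.ga, self.params
        kcl = ga.n_classes
        m = np.maximum(y[:kcl], 0.0)
        p = np.maximum(y[kcl:], 0.0)
        V = float(p @ ga.L) / params.rho
        n = float(p[ga.i_rnap])
        r = float(p[ga.i_ribo])
        F_n = _solve_balance(n, ga.b_n, ga.K_n, params.a * n / V, guess=self.Fn)
        F_r = _solve_balance(
            r, m * ga.load_r, ga.K_r, r / (params.cytoplasm_fraction * V), guess=self.Fr
        )
        self.Fn, self.Fr = F_n, F_r
        c_nf = F_n * params.a * n / V
        c_rf = F_r * r / (params.cytoplasm_fraction * V)
        dm = ga.Gamma_n * ga.g * c_nf / (c_nf + ga.K_n) - m * ga.inv_tau_m
        dp = ga.Gamma_r * m * c_rf / (c_rf + ga.K_r) - p * ga.inv_tau_p
        return np.concatenate((dm, dp))

    def free_fractions(self, y: np.ndarray) -> tuple[float, float]:
        ga, params = self.ga, self.params
        kcl = ga.n_classes
        m, p = y[:kcl], y[kcl:]
        V = float(p @ ga.L) / params.rho
        n, r = float(p[ga.i_rnap]), float(p[ga.i_ribo])
        F_n = _solve_balance(n, ga.b_n, ga.K_n, params.a * n / V)
        F_r = _solve_balance(r, m * ga.load_r, ga.K_r, r / (params.cytoplasm_fraction * V))
        return F_n, F_r

    def run(self, y0, t0, t1, event=None, dense=False):
        events = None
        if event is not None:
            event.terminal = True
            event.direction = 1
            events = [event]
        return solve_ivp(
            self.rhs, (t0, t1), y0, method=self.method, rtol=self.rtol,
            atol=1e-6, events=events, dense_output=dense,
        )


def _volume(y: np.ndarray, ga: GenomeArrays, params: GlobalParams) -> float:
    return float(y[ga.n_classes:] @ ga.L) / params.rho


class CycleFailure(RuntimeError):
    """Raised when a cycle ends without division (signal never fires)."""


def _integrate_cycle(
    engine: _Engine,
    state: CellState,
    rule: DivisionRule,
    theta: float,
    rng: np.random.Generator | None,
    engine_replicated: "_Engine | None" = None,
    collect: list | None = None,
):
    """Advance one cycle; returns (t_div, y_div, theta_effective)."""
    ga, params = engine.ga, engine.params
    kcl = ga.n_classes
    y0 = np.concatenate((state.m, state.p))
    horizon = rule.horizon_factor / params.mu
    segs = []

    sol = engine.run(y0, 0.0, rule.t_min, dense=collect is not None)
    segs.append(sol)
    y = sol.y[:, -1]
    t = rule.t_min

    theta_eff = theta
    if rule.kind == "hazard":
        p = y[kcl:]
        V = _volume(y, ga, params)
        act = float(np.sum(ga.weight[ga.i_act] * p[ga.i_act]))
        inh = float(np.sum(ga.weight[ga.i_inh] * p[ga.i_inh]))
        theta_b = act / inh
        if rng is None:
            raise ValueError("hazard rule needs an rng")
        theta_eff = hazard_sample_division(
            lambda th: rule.hazard(th, theta_b), theta_b, rng
        )

    def event(tt: float, yy: np.ndarray) -> float:
        return _signal_from_vectors(yy[kcl:], _volume(yy, ga, params), ga, rule, theta_eff)

    # Upward crossing only: if the signal is already nonnegative at t_min it
    # must first dip below zero before a division can fire.
    sol2 = engine.run(y, t, horizon, event=event, dense=collect is not None)
    segs.append(sol2)
    if not sol2.t_events or sol2.t_events[0].size == 0:
        if collect is not None:
            collect.extend(segs)
        raise CycleFailure(
            f"no upward crossing of the division signal within the horizon "
            f"{horizon:.1f} h (theta={theta_eff:.4g})"
        )
    t_div = float(sol2.t_events[0][0])
    y_div = sol2.y_events[0][0]

    if rule.replication_delay is not None:
        # crossing triggers gene replication; division follows after T_M
        eng2 = engine_replicated
        if eng2 is None:
            raise ValueError("replication variant needs a replicated-genome engine")
        sol3 = eng2.run(y_div, t_div, t_div + rule.replication_delay,
                        dense=collect is not None)
        segs.append(sol3)
        t_div = t_div + rule.replication_delay
        y_div = sol3.y[:, -1]

    if collect is not None:
        collect.extend(segs)
    return t_div, y_div, theta_eff


def simulate_cycle(
    state: CellState,
    rule: DivisionRule,
    genome: Genome,
    params: GlobalParams,
    rng: np.random.Generator | None = None,
    theta: float | None = None,
    index: int = 0,
) -> tuple[CycleRecord, CellState]:
    """One birth-to-division cycle from ``state``.

    Returns the cycle record and the (pre-partition) state at division.
    Deterministic rules are reproducible run-to-run; stochastic thresholds
    must be drawn by the caller (or pass ``theta``).  Raises
    :class:`CycleFailure` when the signal never fires within the horizon.
    """
    ga = as_arrays(genome, params)
    engine = _Engine(ga, params)
    eng2 = None
    if rule.replication_delay is not None:
        eng2 = _Engine(GenomeArrays(genome.with_ploidy(2 * genome.ploidy), params), params)
    if theta is None:
        if rule.noise == "reset_normal" and rng is not None:
            theta = draw_threshold(rule.theta_bar, rule.delta_theta, rng)
        else:
            theta = rule.theta
    V_b = volume_of(state.p, ga, params)
    t_div, y_div, theta_eff = _integrate_cycle(engine, state, rule, theta, rng, eng2)
    kcl = ga.n_classes
    div_state = CellState(t=t_div, m=y_div[:kcl].copy(), p=y_div[kcl:].copy())
    V_d = volume_of(div_state.p, ga, params)
    rec = CycleRecord(index=index, V_b=V_b, V_d=V_d, T_D=t_div, theta_k=theta_eff)
    return rec, div_state


def simulate_lineage(
    n_generations: int,
    rule: DivisionRule,
    genome: Genome,
    params: GlobalParams,
    seed: int | None = 0,
    burn_in: int = 10,
    initial_volume: float | None = None,
    record_trajectories: bool = False,
    trajectory_dt: float = 0.02,
) -> LineageResult:
    """Simulate ``burn_in + n_generations`` cycles tracking one daughter.

    Burn-in generations are excluded from the records.  The lineage status
    is 'steady' unless a cycle fails to divide within the horizon or the
    RNAP count at birth collapses below one molecule, in which case the
    failing generation index is reported.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    ga = as_arrays(genome, params)
    engine = _Engine(ga, params)
    eng2 = None
    if rule.replication_delay is not None:
        eng2 = _Engine(GenomeArrays(genome.with_ploidy(2 * genome.ploidy), params), params)

    if initial_volume is None:
        initial_volume = _default_initial_volume(rule, genome, ga, params)
    state = initialize_state(initial_volume, genome, params)

    records: list[CycleRecord] = []
    traj_segments: list = [] if record_trajectories else None
    t_origin = 0.0
    total = burn_in + n_generations
    for k in range(total):
        if rule.noise == "reset_normal":
            theta_k = draw_threshold(rule.theta_bar, rule.delta_theta, rng)
        elif rule.noise == "extremes":
            sign = 1.0 if k % 2 == 0 else -1.0
            theta_k = rule.theta_bar + sign * rule.delta_theta
        else:
            theta_k = rule.theta
        V_b = volume_of(state.p, ga, params)
        collect = [] if record_trajectories else None
        try:
            t_div, y_div, theta_eff = _integrate_cycle(
                engine, state, rule, theta_k, rng, eng2, collect
            )
        except CycleFailure:
            return LineageResult(records, burn_in, seed, "failed_no_division", k,
                                 _build_traj(traj_segments, engine))
        kcl = ga.n_classes
        div_state = CellState(t=t_div, m=y_div[:kcl].copy(), p=y_div[kcl:].copy())
        V_d = volume_of(div_state.p, ga, params)
        if k >= burn_in:
            records.append(CycleRecord(k - burn_in, V_b, V_d, t_div, theta_eff))
        if record_trajectories:
            for sol in collect:
                traj_segments.append((t_origin, sol))
        t_origin += t_div
        state = partition_at_division(div_state, rule, ga, params)
        if state.p[ga.i_rnap] < 1.0:
            return LineageResult(records, burn_in, seed, "failed_no_division", k,
                                 _build_traj(traj_segments, engine))
    return LineageResult(records, burn_in, seed, "steady", None,
                         _build_traj(traj_segments, engine, trajectory_dt))


def total_capacity_cached(ga: GenomeArrays) -> float:
    return float(np.sum(ga.b_n))


def _default_initial_volume(
    rule: DivisionRule, genome: Genome, ga: GenomeArrays, params: GlobalParams
) -> float:
    """Starting volume near the expected fixed point.

    Ratio-based rules start at the theoretical birth volume of the (mean,
    equivalent) threshold so the first cycle already begins below threshold;
    other rules fall back to the half-capacity volume ``a n_c / (2 c_n)``.
    """
    fallback = params.a * total_capacity_cached(ga) / (2.0 * rnap_concentration(ga, params))
    if rule.kind != "ratio":
        return fallback
    from .theory import TheoryInputs, birth_volume

    theta = rule.theta_bar if rule.noise in ("reset_normal", "extremes") else rule.theta
    sa = float(np.sum(ga.weight[ga.i_act] * ga.g[ga.i_act]))
    si = float(np.sum(ga.weight[ga.i_inh] * ga.g[ga.i_inh]))
    try:
        ti = TheoryInputs.from_genome(genome, params)
        return birth_volume(si / sa * theta, ti)
    except (ValueError, ZeroDivisionError):
        return fallback


def _build_traj(segments, engine: _Engine, dt: float = 0.02):
    """Resample stored dense segments onto a uniform grid as a DataFrame."""
    if not segments:
        return None
    import pandas as pd

    ga, params = engine.ga, engine.params
    rows = []
    for t0, sol in segments:
        if sol.sol is None:
            continue
        ts = np.arange(sol.t[0], sol.t[-1], dt)
        if ts.size == 0:
            ts = np.array([sol.t[0]])
        Y = sol.sol(ts)
        for tt, y in zip(ts, Y.T):
            p = y[ga.n_classes:]
            m = y[:ga.n_classes]
            V = float(p @ ga.L) / params.rho
            c_act = float(np.sum(p[ga.i_act])) / V
            c_inh = float(np.sum(p[ga.i_inh])) / V
            n, r = float(p[ga.i_rnap]), float(p[ga.i_ribo])
            F_n = _solve_balance(n, ga.b_n, ga.K_n, params.a * n / V)
            F_r = _solve_balance(r, m * ga.load_r, ga.K_r,
                                 r / (params.cytoplasm_fraction * V))
            rows.append((t0 + tt, V, c_act, c_inh, F_n, F_r))
    return pd.DataFrame(rows, columns=["t", "V", "c_act", "c_inh", "F_n", "F_r"])


# ---------------------------------------------------------------------------
# genome edits and the equivalent threshold
# ---------------------------------------------------------------------------

def delete_regulators(genome: Genome, labels: str | Sequence[str]) -> Genome:
    """Delete one regulator gene per given label.

    A class with ``copy_number > 1`` is decremented; a single-copy class is
    removed.  At least one activator and one inhibitor must survive.
    """
    if isinstance(labels, str):
        labels = [labels]
    classes = list(genome.classes)
    for label in labels:
        i = next((j for j, c in enumerate(classes) if c.label == label), None)
        if i is None:
            raise KeyError(f"no gene class labelled {label!r}")
        c = classes[i]
        if c.role not in ("activator", "inhibitor"):
            raise ValueError(f"{label!r} is not a regulator")
        if c.copy_number > 1:
            classes[i] = replace(c, copy_number=c.copy_number - 1)
        else:
            classes.pop(i)
    roles = [c.role for c in classes]
    if "activator" not in roles or "inhibitor" not in roles:
        raise ValueError("cannot delete the last activator or inhibitor")
    return Genome(classes, ploidy=genome.ploidy)


def swap_promoters(genome: Genome, act_label: str, inh_label: str) -> Genome:
    """Exchange the transcription MM constants of two regulator classes."""
    ia, ii = genome.index(act_label), genome.index(inh_label)
    classes = list(genome.classes)
    Ka, Ki = classes[ia].K_n, classes[ii].K_n
    classes[ia] = replace(classes[ia], K_n=Ki)
    classes[ii] = replace(classes[ii], K_n=Ka)
    return Genome(classes, ploidy=genome.ploidy)


def equivalent_threshold(
    g_act: int,
    g_inh: int,
    theta: float,
    act_weights: Sequence[float] | None = None,
    inh_weights: Sequence[float] | None = None,
) -> float:
    """Map a multi-regulator threshold onto the single-pair model.

    Unweighted: ``theta~ = (g_inh / g_act) theta``.  With per-regulator
    division weights chi the copy counts are replaced by weight sums.
    """
    if act_weights is not None or inh_weights is not None:
        sa = float(np.sum(act_weights)) if act_weights is not None else float(g_act)
        si = float(np.sum(inh_weights)) if inh_weights is not None else float(g_inh)
    else:
        sa, si = float(g_act), float(g_inh)
    if sa <= 0:
        raise ZeroDivisionError("activator count/weight sum must be positive")
    return si / sa * theta
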