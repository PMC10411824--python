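"""Closed-form steady-state theory of the regulator-ratio division cycle.

Everything here follows from three quasi-steady observations about the
expression model: (i) the nuclear total-RNAP concentration ``c_n`` is
constant; (ii) short-lived mRNAs and regulators track the instantaneous
free-RNAP fraction ``F_n``; (iii) the activator-to-inhibitor concentration
ratio is then a monotone function of ``F_n`` alone,

    c_act / c_inh  =  (F_n c_n + K_inh) / (F_n c_n + K_act).

Division at ratio ``theta`` therefore pins the free fraction at division,
and with it the RNAP count, the cell volume at division and birth, the
oscillation amplitude of the ratio, and — once the threshold is made
stochastic — the moments of the birth-size distribution and the condition
for robust division.  These formulas serve both as standalone predictions
and as oracles for the event-driven simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Genome, GenomeArrays, GlobalParams, _solve_balance, as_arrays
from .model import rnap_concentration, total_capacity

__all__ = [
    "TheoryInputs",
    "TheoryPrediction",
    "ktilde",
    "critical_thresholds",
    "free_fraction_at_division",
    "birth_volume",
    "division_state",
    "free_fraction_at_birth",
    "amplitude",
    "ratio_of_concentrations",
    "stochastic_birth_moments",
    "robust_division_condition",
    "robust_threshold_band",
    "predict",
]


@dataclass(frozen=True)
class TheoryInputs:
    """Reduced parameter set entering the closed-form theory.

    ``gamma`` is the volume fraction inherited by the tracked daughter
    (0.5 for symmetric division); the asymmetric theory replaces
    ``n_b = n_d / 2`` by ``n_b = gamma n_d`` and carries the same algebra.
    """

    K_act: float
    K_inh: float
    K_n: float
    c_n: float
    n_c: float
    a: float
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.K_act <= self.K_inh:
            raise ValueError("activator must have the weaker promoter: K_act > K_inh")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")

    @classmethod
    def from_genome(
        cls, genome: Genome, params: GlobalParams, gamma: float = 0.5
    ) -> "TheoryInputs":
        """Extract the reduced parameters from a calibrated genome.

        Multi-regulator genomes map onto the single-pair theory through the
        equivalent threshold, so only the (common) activator and inhibitor
        MM constants are read.
        """
        ga = as_arrays(genome, params)
        if ga.i_act.size == 0 or ga.i_inh.size == 0:
            raise ValueError("genome has no activator or no inhibitor class")
        K_act = float(np.mean(ga.K_n[ga.i_act]))
        K_inh = float(np.mean(ga.K_n[ga.i_inh]))
        # Effective MM constant of the lumped RNAP balance: the
        # capacity-weighted harmonic mean over non-regulator genes (exact
        # when all of them share one K_n; the right reduction of the
        # multi-K balance in its linear regime otherwise).
        others = [i for i in range(ga.n_classes)
                  if i not in set(ga.i_act) | set(ga.i_inh)]
        b = ga.b_n[others]
        K_bulk = float(b.sum() / np.sum(b / ga.K_n[others]))
        return cls(
            K_act=K_act,
            K_inh=K_inh,
            K_n=K_bulk,
            c_n=rnap_concentration(ga, params),
            n_c=total_capacity(ga, params),
            a=params.a,
            gamma=gamma,
        )


@dataclass
class TheoryPrediction:
    """Bundle of analytic predictions for one parameter point."""

    theta1: float
    theta2: float
    V_b: float | None = None
    F_n_d: float | None = None
    F_n_b: float | None = None
    n_d: float | None = None
    n_b: float | None = None
    m_d: np.ndarray | None = None
    A: float | None = None
    mean_V_b: float | None = None
    cv_V_b: float | None = None
    robust: bool | None = None


def ktilde(theta: float, K_act: float, K_inh: float) -> float:
    """Effective promoter-strength combination ``K~ = theta K_act - K_inh``."""
    return theta * K_act - K_inh


def critical_thresholds(K_act: float, K_inh: float, c_n: float) -> tuple[float, float]:
    """Bounds of the stable-cycle threshold window.

    ``theta_1 = K_inh / K_act`` (free fraction at division would hit 0) and
    ``theta_2 = (c_n + K_inh) / (c_n + K_act)`` (it would hit 1).
    """
    return K_inh / K_act, (c_n + K_inh) / (c_n + K_act)


def _require_in_window(theta: float, inputs: TheoryInputs) -> tuple[float, float]:
    th1, th2 = critical_thresholds(inputs.K_act, inputs.K_inh, inputs.c_n)
    if not th1 < theta < th2:
        raise ValueError(
            f"theta={theta:.4g} outside the stable-cycle window ({th1:.4g}, {th2:.4g})"
        )
    return th1, th2


def free_fraction_at_division(theta: float, inputs: TheoryInputs) -> float:
    """Free-RNAP fraction when the ratio reaches the threshold.

    ``F_n,d = K~ / ((1 - theta) c_n)``; spans (0, 1) across the window.
    """
    _require_in_window(theta, inputs)
    return ktilde(theta, inputs.K_act, inputs.K_inh) / ((1.0 - theta) * inputs.c_n)


def birth_volume(theta: float, inputs: TheoryInputs) -> float:
    """Cell volume at birth as a function of the division threshold [um^3].

    Strictly increasing across the window, vanishing at ``theta_1`` and
    diverging at ``theta_2``; proportional to the RNAP capacity ``n_c`` and
    hence to ploidy.
    """
    _require_in_window(theta, inputs)
    Kt = ktilde(theta, inputs.K_act, inputs.K_inh)
    one = 1.0 - theta
    d1 = one * inputs.c_n - Kt
    d2 = one * inputs.K_n + Kt
    return 2.0 * inputs.gamma * inputs.a * inputs.n_c * one * Kt / (2.0 * d1 * d2)


def division_state(
    theta: float,
    inputs: TheoryInputs,
    genome: Genome | GenomeArrays | None = None,
    params: GlobalParams | None = None,
) -> tuple[float, np.ndarray | None]:
    """RNAP count and mRNA vector at the moment of division.

    ``n_d = n_c c_n (1 - theta) K~ / (((1-theta) c_n - K~)((1-theta) K_n + K~))``;
    each quasi-steady mRNA evaluates at the division free fraction.  The mRNA
    vector needs the genome (per-class rates) and is ``None`` without one.
    """
    _require_in_window(theta, inputs)
    Kt = ktilde(theta, inputs.K_act, inputs.K_inh)
    one = 1.0 - theta
    n_d = inputs.n_c * inputs.c_n * one * Kt / (
        (one * inputs.c_n - Kt) * (one * inputs.K_n + Kt)
    )
    m_d = None
    if genome is not None:
        if params is None:
            raise ValueError("params required alongside genome")
        ga = as_arrays(genome, params)
        if np.any(ga.inv_tau_m == 0):
            raise ValueError("division-state mRNAs need finite mRNA lifetimes")
        # F_n,d c_n = K~ / (1 - theta)
        m_d = ga.Gamma_n * ga.g / ga.inv_tau_m * Kt / (Kt + one * ga.K_n)
    return n_d, m_d


def free_fraction_at_birth(n_b: float, inputs: TheoryInputs) -> float:
    """Free-RNAP fraction just after division.

    Unique root of ``n_b (1 - F) = n_c F c_n / (F c_n + K_n)``, increasing
    in ``n_b``; 0 at ``n_b = 0`` and approaching 1 as ``n_b`` diverges.
    """
    if n_b < 0:
        raise ValueError("n_b must be nonnegative")
    return _solve_balance(
        n_b, np.array([inputs.n_c]), np.array([inputs.K_n]), inputs.c_n
    )


def ratio_of_concentrations(F_n: float, inputs: TheoryInputs) -> float:
    """Quasi-steady activator-to-inhibitor concentration ratio at ``F_n``.

    ``(F_n c_n + K_inh) / (F_n c_n + K_act)``: strictly increasing in
    ``F_n`` from ``theta_1`` (F_n = 0) to ``theta_2`` (F_n = 1).
    """
    if not 0 <= F_n <= 1:
        raise ValueError("F_n must lie in [0, 1]")
    x = F_n * inputs.c_n
    return (x + inputs.K_inh) / (x + inputs.K_act)


def amplitude(theta: float, inputs: TheoryInputs) -> float:
    """Within-cycle oscillation amplitude of the regulator ratio.

    ``A = theta - ratio(F_n,b)`` where ``F_n,b`` is the free fraction at
    birth with ``n_b = gamma n_d``.  Positive strictly inside the window and
    zero at both critical thresholds.
    """
    _require_in_window(theta, inputs)
    n_d, _ = division_state(theta, inputs)
    F_nb = free_fraction_at_birth(inputs.gamma * n_d, inputs)
    return theta - ratio_of_concentrations(F_nb, inputs)


def stochastic_birth_moments(
    theta_bar: float, delta_theta: float, inputs: TheoryInputs
) -> tuple[float, float]:
    """First-order mean and CV of the birth volume under threshold noise.

    Thresholds are drawn per generation from ``N(theta_bar, (delta/3)^2)``
    truncated by resetting to the mean.  To first order in the noise,
    ``<V_b> = V_b(theta_bar)`` and ``CV = |d ln V_b / d theta| sigma`` with
    ``sigma = delta_theta / 3``, which has the closed form implemented here.
    """
    _require_in_window(theta_bar, inputs)
    sigma = delta_theta / 3.0
    mean = birth_volume(theta_bar, inputs)
    Kt = ktilde(theta_bar, inputs.K_act, inputs.K_inh)
    one = 1.0 - theta_bar
    cv = (
        (inputs.K_act - inputs.K_inh)
        * (one * one * inputs.c_n * inputs.K_n + Kt * Kt)
        * sigma
        / (one * Kt * (one * inputs.c_n - Kt) * (one * inputs.K_n + Kt))
    )
    return mean, cv


def robust_division_condition(
    theta_bar: float, delta_theta: float, inputs: TheoryInputs
) -> bool:
    """Whether threshold noise still permits robust division.

    Division in cycle k requires the ratio to dip below the freshly drawn
    threshold; since ``theta - A(theta)`` increases with ``theta``, the
    binding case pairs the largest previous threshold with the smallest new
    one, giving ``A(theta_bar + delta) > 2 delta``.  Thresholds reaching
    outside the stable window return False outright.
    """
    if delta_theta < 0 or theta_bar - delta_theta <= 0:
        raise ValueError("require theta_bar - delta_theta > 0")
    th1, th2 = critical_thresholds(inputs.K_act, inputs.K_inh, inputs.c_n)
    hi = theta_bar + delta_theta
    if not th1 < hi < th2:
        return False
    return bool(amplitude(hi, inputs) > 2.0 * delta_theta)


def robust_threshold_band(
    delta_theta: float, inputs: TheoryInputs, tol: float = 1e-6
) -> tuple[float, float]:
    """Interval of mean thresholds satisfying the robustness condition.

    Solves ``A(theta_bar + delta) = 2 delta`` on both flanks of the
    amplitude maximum by bisection.  Raises if no mean threshold is viable
    (noise exceeds half the peak amplitude).
    """
    th1, th2 = critical_thresholds(inputs.K_act, inputs.K_inh, inputs.c_n)
    eps = 1e-9 * (th2 - th1)
    grid = np.linspace(th1 + eps, th2 - eps, 400)
    amps = np.array([amplitude(t, inputs) for t in grid])
    k = int(np.argmax(amps))
    if amps[k] <= 2.0 * delta_theta:
        raise ValueError("no viable mean threshold: noise exceeds half the peak amplitude")

    def f(th: float) -> float:
        return amplitude(th, inputs) - 2.0 * delta_theta

    from scipy.optimize import brentq

    lo = brentq(f, grid[0], grid[k], xtol=tol)
    hi = brentq(f, grid[k], grid[-1], xtol=tol)
    return lo - delta_theta, hi - delta_theta


def predict(
    inputs: TheoryInputs,
    theta: float | None = None,
    theta_bar: float | None = None,
    delta_theta: float = 0.0,
    genome: Genome | None = None,
    params: GlobalParams | None = None,
) -> TheoryPrediction:
    """Evaluate the full prediction bundle at one parameter point."""
    th1, th2 = critical_thresholds(inputs.K_act, inputs.K_inh, inputs.c_n)
    pred = TheoryPrediction(theta1=th1, theta2=th2)
    if theta is not None:
        pred.V_b = birth_volume(theta, inputs)
        pred.F_n_d = free_fraction_at_division(theta, inputs)
        pred.n_d, pred.m_d = division_state(theta, inputs, genome, params)
        pred.n_b = inputs.gamma * pred.n_d
        pred.F_n_b = free_fraction_at_birth(pred.n_b, inputs)
        pred.A = amplitude(theta, inputs)
    if theta_bar is not None:
        pred.mean_V_b, pred.cv_V_b = stochastic_birth_moments(
            theta_bar, delta_theta, inputs
        )
        pred.robust = robust_division_condition(theta_bar, delta_theta, inputs)
    return pred
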