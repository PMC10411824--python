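"""Whole-cell gene-expression model with shared RNA-polymerase and ribosome pools.

The cell is described by mRNA and protein copy numbers for a small set of gene
*classes* (RNAP, ribosome, cell-cycle activators/inhibitors, and lumped bulk
genes).  Transcription initiation of each gene follows Michaelis-Menten
kinetics in the *free* RNAP concentration, and translation initiation follows
the same law in the free ribosome concentration.  Both free pools are obtained
self-consistently from conservation balances: polymerases are either free,
promoter-bound, or elongating; ribosomes are either free, bound at a ribosome
binding site, or translating.

Cell volume is proportional to total protein mass, ``V = sum_i p_i L_i / rho``,
so growth is an emergent property of the expression model rather than an input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

__all__ = [
    "GeneClass",
    "GlobalParams",
    "Genome",
    "CellState",
    "GenomeArrays",
    "volume_of",
    "total_capacity",
    "rnap_concentration",
    "solve_free_rnap_fraction",
    "solve_free_ribosome_fraction",
    "state_derivative",
    "quasi_steady_mrna",
    "steady_protein_ratio",
    "calibrate_rates",
]

ROLES = ("rnap", "ribosome", "activator", "inhibitor", "bulk")


@dataclass(frozen=True)
class GeneClass:
    """One class of identical genes.

    Parameters
    ----------
    label : str
        Unique name of the class.
    role : {'rnap', 'ribosome', 'activator', 'inhibitor', 'bulk'}
        Functional role.  Exactly one RNAP and one ribosome class per genome.
    length : int
        Gene length in codons.
    K_n : float
        Michaelis-Menten constant of transcription initiation [um^-3].
        Small values mean a strong promoter.
    K_r : float
        Michaelis-Menten constant of translation initiation [um^-3].
    Gamma_r : float
        Translation initiation rate per mRNA [1/h].
    copy_number : int
        Gene copies of this class (before ploidy).
    multiplicity : int
        Number of identical genes lumped into this class; mRNA/protein
        copy numbers of the class are totals over the lump.
    Gamma_n : float or None
        Transcription initiation rate per gene copy [1/h].  ``None`` until
        set by :func:`calibrate_rates`.
    tau_m : float
        mRNA lifetime [h].
    tau_p : float
        Protein lifetime [h]; ``math.inf`` for nondegradable proteins.
    weight : float
        Weight of this regulator in the division rule (chi).
    """

    label: str
    role: str
    length: int
    K_n: float
    K_r: float
    Gamma_r: float
    tau_m: float
    copy_number: int = 1
    multiplicity: int = 1
    Gamma_n: float | None = None
    tau_p: float = math.inf
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.length <= 0 or self.K_n <= 0 or self.K_r <= 0:
            raise ValueError(f"class {self.label!r}: lengths and MM constants must be positive")
        if self.Gamma_r <= 0 or self.tau_m <= 0 or self.tau_p <= 0:
            raise ValueError(f"class {self.label!r}: rates and lifetimes must be positive")
        if self.copy_number <= 0 or self.multiplicity <= 0:
            raise ValueError(f"class {self.label!r}: copy numbers must be positive")
        if self.Gamma_n is not None and self.Gamma_n <= 0:
            raise ValueError(f"class {self.label!r}: Gamma_n must be positive")
        if self.weight < 0:
            raise ValueError(f"class {self.label!r}: weight must be nonnegative")


@dataclass(frozen=True)
class GlobalParams:
    """Cell-level parameters shared by all gene classes.

    Attributes
    ----------
    a : float
        Ratio of cell volume to nuclear volume (dimensionless).
    rho : float
        Protein mass per cell volume [amino acids * um^-3].
    v_n : float
        RNAP elongation speed [codons/h].
    v_r : float
        Ribosome elongation speed [codons/h].
    mu : float
        Attempted growth rate used by rate calibration [1/h].
    nc_target : float
        Target for the maximum number of RNAPs the genome can hold.
    cytoplasm_fraction : float
        Fraction of cell volume used to convert ribosome number to
        concentration (<= 1).
    """

    a: float
    rho: float
    v_n: float
    v_r: float
    mu: float
    nc_target: float
    cytoplasm_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "rho", "v_n", "v_r", "mu", "nc_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cytoplasm_fraction <= 1:
            raise ValueError("cytoplasm_fraction must be in (0, 1]")


@dataclass
class Genome:
    """Ordered collection of gene classes plus a ploidy multiplier."""

    classes: list[GeneClass]
    ploidy: int = 1

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("gene class labels must be unique")
        for role in ("rnap", "ribosome"):
            if sum(c.role == role for c in self.classes) != 1:
                raise ValueError(f"genome must contain exactly one {role} class")

    # -- lookups ---------------------------------------------------------
    def index(self, label: str) -> int:
        for i, c in enumerate(self.classes):
            if c.label == label:
                return i
        raise KeyError(f"no gene class labelled {label!r}")

    def role_index(self, role: str) -> int:
        idx = [i for i, c in enumerate(self.classes) if c.role == role]
        if len(idx) != 1:
            raise ValueError(f"expected exactly one {role} class, found {len(idx)}")
        return idx[0]

    def role_indices(self, role: str) -> list[int]:
        return [i for i, c in enumerate(self.classes) if c.role == role]

    def copies(self) -> np.ndarray:
        """Effective gene copies per class: copy_number * multiplicity * ploidy."""
        return np.array(
            [c.copy_number * c.multiplicity * self.ploidy for c in self.classes],
            dtype=float,
        )

    def with_ploidy(self, ploidy: int) -> "Genome":
        return Genome([replace(c) for c in self.classes], ploidy=ploidy)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class CellState:
    """mRNA and protein copy numbers at a time point.

    ``p[rnap] = n`` (RNAP count) and ``p[ribosome] = r`` (ribosome count).
    """

    t: float
    m: np.ndarray
    p: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.t, self.m.copy(), self.p.copy())


class GenomeArrays:
    """Vectorised, read-only view of a genome used in inner loops.

    Precomputes the per-class arrays entering the conservation balances and
    the ODE right-hand side so that repeated solves avoid attribute chasing.
    """

    __slots__ = (
        "g", "L", "K_n", "Gamma_n", "K_r", "Gamma_r", "inv_tau_m", "inv_tau_p",
        "weight", "b_n", "load_r", "i_rnap", "i_ribo", "i_act", "i_inh",
        "n_classes", "params",
    )

    def __init__(self, genome: Genome, params: GlobalParams) -> None:
        cs = genome.classes
        self.params = params
        self.n_classes = len(cs)
        self.g = genome.copies()
        self.L = np.array([c.length for c in cs], dtype=float)
        self.K_n = np.array([c.K_n for c in cs], dtype=float)
        gn = [c.Gamma_n for c in cs]
        if any(v is None for v in gn):
            raise ValueError("genome is not calibrated: Gamma_n unset; run calibrate_rates first")
        self.Gamma_n = np.array(gn, dtype=float)
        self.K_r = np.array([c.K_r for c in cs], dtype=float)
        self.Gamma_r = np.array([c.Gamma_r for c in cs], dtype=float)
        with np.errstate(divide="ignore"):
            self.inv_tau_m = 1.0 / np.array([c.tau_m for c in cs], dtype=float)
            self.inv_tau_p = 1.0 / np.array([c.tau_p for c in cs], dtype=float)
        self.weight = np.array([c.weight for c in cs], dtype=float)
        # RNAPs held per gene copy when fully engaged: promoter + elongating.
        self.b_n = self.g * (1.0 + self.Gamma_n * self.L / params.v_n)
        # Ribosomes held per mRNA when fully engaged: RBS + elongating.
        self.load_r = 1.0 + self.Gamma_r * self.L / params.v_r
        self.i_rnap = genome.role_index("rnap")
        self.i_ribo = genome.role_index("ribosome")
        self.i_act = np.array(genome.role_indices("activator"), dtype=int)
        self.i_inh = np.array(genome.role_indices("inhibitor"), dtype=int)


def as_arrays(genome: Genome | GenomeArrays, params: GlobalParams) -> GenomeArrays:
    if isinstance(genome, GenomeArrays):
        return genome
    return GenomeArrays(genome, params)


# ---------------------------------------------------------------------------
# basic observables
# ---------------------------------------------------------------------------

def volume_of(p: np.ndarray, genome: Genome | GenomeArrays, params: GlobalParams) -> float:
    """Cell volume from the protein vector: ``V = sum_i p_i L_i / rho`` [um^3]."""
    ga = as_arrays(genome, params)
    p = np.asarray(p, dtype=float)
    if p.shape != ga.L.shape:
        raise ValueError(f"protein vector of length {p.size} does not match {ga.n_classes} classes")
    v = float(p @ ga.L) / params.rho
    if v <= 0:
        raise ValueError("all-zero protein vector: volume undefined")
    return v


def total_capacity(genome: Genome | GenomeArrays, params: GlobalParams) -> float:
    """Maximum number of RNAPs the genome can hold.

    Each gene copy holds one promoter-bound RNAP plus ``Gamma_n L / v_n``
    elongating ones; summed over the expanded gene set, this scales linearly
    with ploidy.
    """
    ga = as_arrays(genome, params)
    return float(np.sum(ga.b_n))


def rnap_concentration(genome: Genome | GenomeArrays, params: GlobalParams) -> float:
    """Steady-state total-RNAP concentration in the nucleus [um^-3].

    ``c_n = a rho Gamma_n,n g_n / sum_i Gamma_n,i g_i L_i``; the regulator
    contribution to protein mass is neglected.  Invariant under ploidy
    doubling because numerator and denominator both scale with gene dosage.
    """
    ga = as_arrays(genome, params)
    denom = float(np.sum(ga.Gamma_n * ga.g * ga.L))
    if denom <= 0:
        raise ZeroDivisionError("sum of Gamma_n,i g_i L_i vanishes")
    return params.a * params.rho * ga.Gamma_n[ga.i_rnap] * ga.g[ga.i_rnap] / denom


# ---------------------------------------------------------------------------
# free-fraction balances
# ---------------------------------------------------------------------------

def _solve_balance(
    total: float,
    b: np.ndarray,
    K: np.ndarray,
    conc: float,
    guess: float | None = None,
    xtol: float = 1e-12,
) -> float:
    """Solve ``total (1 - F) = sum_i b_i F conc / (F conc + K_i)`` for F in [0, 1].

    The left side decreases and the right side increases monotonically in F,
    so the root is unique.  Safeguarded Newton iteration on the bracket
    [0, 1]; ``guess`` warm-starts the iteration (the free fraction changes
    slowly along a trajectory, so quasi-static solves converge in a few
    steps).
    """
    if total <= 0:
        return 0.0  # convention: no molecules -> nothing free
    if conc <= 0 or b.size == 0 or not np.any(b > 0):
        return 1.0  # no binding sinks

    def h_and_deriv(F: float) -> tuple[float, float]:
        denom = F * conc + K
        bound = b * F * conc / denom
        h = total * (1.0 - F) - float(np.sum(bound))
        dh = -total - float(np.sum(b * conc * K / (denom * denom)))
        return h, dh

    lo, hi = 0.0, 1.0
    F = min(max(guess if guess is not None else 0.5, 1e-8), 1.0)
    for _ in range(200):
        h, dh = h_and_deriv(F)
        if h > 0:
            lo = F
        else:
            hi = F
        step = -h / dh
        F_new = F + step
        if not (lo < F_new < hi):
            F_new = 0.5 * (lo + hi)
        if abs(F_new - F) < xtol:
            return F_new
        F = F_new
    raise RuntimeError("free-fraction balance did not converge")


def solve_free_rnap_fraction(
    n: float,
    V: float,
    genome: Genome | GenomeArrays,
    params: GlobalParams,
    guess: float | None = None,
) -> float:
    """Self-consistent free fraction of RNAPs, ``F_n`` in [0, 1].

    Balances free against promoter-bound and elongating RNAPs:
    ``n (1 - F_n) = sum_i g_i (1 + Gamma_n,i L_i / v_n) F_n c_n / (F_n c_n + K_n,i)``
    with ``c_n = a n / V`` the nuclear total-RNAP concentration.  ``n = 0``
    returns 0 by convention so division events never raise here.
    """
    if V <= 0:
        raise ValueError("volume must be positive")
    if n < 0:
        raise ValueError("RNAP count must be nonnegative")
    ga = as_arrays(genome, params)
    c_n = params.a * n / V
    return _solve_balance(n, ga.b_n, ga.K_n, c_n, guess=guess)


def solve_free_ribosome_fraction(
    r: float,
    m: np.ndarray,
    V: float,
    genome: Genome | GenomeArrays,
    params: GlobalParams,
    guess: float | None = None,
) -> float:
    """Self-consistent free fraction of ribosomes, ``F_r`` in [0, 1].

    Balance over mRNAs: each message holds one RBS-bound ribosome plus
    ``Gamma_r L / v_r`` translating ones.  ``c_r = r / (cytoplasm_fraction V)``.
    """
    if V <= 0:
        raise ValueError("volume must be positive")
    if r < 0:
        raise ValueError("ribosome count must be nonnegative")
    ga = as_arrays(genome, params)
    m = np.asarray(m, dtype=float)
    c_r = r / (params.cytoplasm_fraction * V)
    return _solve_balance(r, m * ga.load_r, ga.K_r, c_r, guess=guess)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def state_derivative(
    state: CellState,
    genome: Genome | GenomeArrays,
    params: GlobalParams,
    _guesses: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dm/dt, dp/dt)`` of the expression model.

    Free fractions are solved quasi-statically from the current state.
    Infinite lifetimes contribute zero degradation.  ``_guesses`` is an
    optional mutable ``[F_n, F_r]`` warm-start shared across calls.
    """
    ga = as_arrays(genome, params)
    m, p = state.m, state.p
    V = volume_of(p, ga, params)
    n = float(p[ga.i_rnap])
    r = float(p[ga.i_ribo])
    g_n = _guesses[0] if _guesses else None
    g_r = _guesses[1] if _guesses else None
    F_n = solve_free_rnap_fraction(n, V, ga, params, guess=g_n)
    F_r = solve_free_ribosome_fraction(r, m, V, ga, params, guess=g_r)
    if _guesses is not None:
        _guesses[0], _guesses[1] = F_n, F_r
    c_n_free = F_n * params.a * n / V
    c_r_free = F_r * r / (params.cytoplasm_fraction * V)
    dm = ga.Gamma_n * ga.g * c_n_free / (c_n_free + ga.K_n) - m * ga.inv_tau_m
    dp = ga.Gamma_r * m * c_r_free / (c_r_free + ga.K_r) - p * ga.inv_tau_p
    return dm, dp


def quasi_steady_mrna(
    F_n: float, genome: Genome | GenomeArrays, params: GlobalParams
) -> np.ndarray:
    """Quasi-steady mRNA copy numbers at free-RNAP fraction ``F_n``.

    ``m_i = Gamma_n,i g_i tau_m,i F_n c_n / (F_n c_n + K_n,i)`` with the
    steady-state nuclear RNAP concentration ``c_n``.  Valid when mRNA
    lifetimes are short against the cell cycle; infinite ``tau_m`` is
    rejected.
    """
    if not 0 < F_n <= 1:
        raise ValueError("F_n must lie in (0, 1]")
    ga = as_arrays(genome, params)
    if np.any(ga.inv_tau_m == 0):
        raise ValueError("quasi-steady mRNA requires finite mRNA lifetimes")
    c = F_n * rnap_concentration(ga, params)
    return ga.Gamma_n * ga.g / ga.inv_tau_m * c / (c + ga.K_n)


def steady_protein_ratio(
    genome: Genome | GenomeArrays, params: GlobalParams, label_or_index: str | int
) -> float:
    """Steady-state ratio ``p_i / n`` for a nondegradable class.

    Nondegradable proteins equilibrate to ``Gamma_n,i g_i / (Gamma_n,n g_n)``
    relative to RNAP, set purely by gene dosage and transcription initiation
    rates.  Degradable classes are rejected: their levels depend on lifetimes
    and the instantaneous free fractions.
    """
    if isinstance(genome, GenomeArrays):
        raise TypeError("steady_protein_ratio needs a Genome (lifetime metadata)")
    i = genome.index(label_or_index) if isinstance(label_or_index, str) else label_or_index
    cls = genome.classes[i]
    if math.isfinite(cls.tau_p):
        raise ValueError(
            f"class {cls.label!r} is degradable; its steady level is not a pure dosage ratio"
        )
    ga = as_arrays(genome, params)
    return float(ga.Gamma_n[i] * ga.g[i] / (ga.Gamma_n[ga.i_rnap] * ga.g[ga.i_rnap]))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_rates(genome: Genome, params: GlobalParams) -> Genome:
    """Set transcription initiation rates from growth-rate and capacity targets.

    Three constraints pin the three unknown rate groups:

    1. the genome's total RNAP capacity equals ``params.nc_target``;
    2. RNAPs are 10% of ribosomes at steady state, i.e.
       ``Gamma_n,n g_n = 0.1 Gamma_n,r g_r``;
    3. the balanced growth rate (evaluated with the free-ribosome fraction
       set to zero, a calibration convenience) equals ``params.mu``.

    All genes other than RNAP and ribosome share one common rate.  The three
    constraints are linear in the ribosome-gene rate, so the system is solved
    exactly; this covers heterogeneous gene lengths as well as the common-
    length case.

    Raises
    ------
    ValueError
        If ``mu`` is infeasibly large (the growth-rate constraint would need
        ``mu * beta >= Gamma_r g_r``) or the capacity target is below the
        total gene count.
    """
    i_n = genome.role_index("rnap")
    i_r = genome.role_index("ribosome")
    g = genome.copies()
    L = np.array([c.length for c in genome.classes], dtype=float)
    Gamma_r = np.array([c.Gamma_r for c in genome.classes], dtype=float)
    others = [i for i in range(len(genome.classes)) if i not in (i_n, i_r)]
    if not others:
        raise ValueError("calibration needs at least one non-RNAP, non-ribosome class")

    nc = params.nc_target
    G = float(np.sum(g))
    if nc <= G:
        raise ValueError(
            f"violated inequality nc_target > total gene count ({nc} <= {G})"
        )
    g_n, g_r = g[i_n], g[i_r]
    L_n, L_r = L[i_n], L[i_r]
    S1 = float(np.sum(g[others] * L[others]))
    # ribosome-equivalents held per fully engaged mRNA, per class
    w = 1.0 + Gamma_r * L / params.v_r
    W_o = float(np.sum(g[others] * w[others]))

    # D(X) = beta * X + alpha with X = Gamma_n,r (per ribosome-gene copy)
    beta = 0.1 * g_r * w[i_n] + g_r * w[i_r] - g_r * (0.1 * L_n + L_r) / S1 * W_o
    alpha = params.v_n * (nc - G) / S1 * W_o
    denom = Gamma_r[i_r] * g_r - params.mu * beta
    if denom <= 0:
        raise ValueError(
            "violated inequality mu * beta < Gamma_r g_r: attempted growth rate "
            f"mu={params.mu} is too large for this genome"
        )
    X = float(params.mu * alpha / denom)
    Gamma_n_rnap = float(0.1 * X * g_r / g_n)
    Gamma_n_common = float(
        (params.v_n * (nc - G) - Gamma_n_rnap * g_n * L_n - X * g_r * L_r) / S1
    )
    if X <= 0 or Gamma_n_common <= 0:
        raise ValueError(
            "violated inequality Gamma_n > 0: capacity target leaves no "
            "transcription budget for bulk genes"
        )

    new_classes = []
    for i, c in enumerate(genome.classes):
        if i == i_n:
            new_classes.append(replace(c, Gamma_n=Gamma_n_rnap))
        elif i == i_r:
            new_classes.append(replace(c, Gamma_n=X))
        else:
            new_classes.append(replace(c, Gamma_n=Gamma_n_common))
    return Genome(new_classes, ploidy=genome.ploidy)
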