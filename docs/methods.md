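# Methods

## The model

A cell is a set of gene *classes* (RNAP, ribosome, cell-cycle activators,
cell-cycle inhibitors, and lumped bulk genes) with mRNA copy numbers `m_i`
and protein copy numbers `p_i` (the RNAP and ribosome protein counts are
written `n` and `r`).  Transcription and translation initiation follow
Michaelis–Menten kinetics in the *free* RNAP and ribosome concentrations:

    dm_i/dt = Γ_n,i g_i · F_n c_n / (F_n c_n + K_n,i) − m_i / τ_m,i
    dp_i/dt = Γ_r,i m_i · F_r c_r / (F_r c_r + K_r,i) − p_i / τ_p,i

`g_i` is the gene copy number (copies × multiplicity × ploidy), `K_n,i` the
promoter's MM constant (small K = strong promoter), and `c_n = a·n/V` the
nuclear total-RNAP concentration (`a` = cell/nuclear volume ratio).  The
free fractions `F_n, F_r ∈ [0,1]` are solved self-consistently at every
right-hand-side evaluation from the conservation balances

    n (1 − F_n) = Σ_i g_i (1 + Γ_n,i L_i / v_n) · F_n c_n / (F_n c_n + K_n,i)
    r (1 − F_r) = Σ_i m_i (1 + Γ_r,i L_i / v_r) · F_r c_r / (F_r c_r + K_r,i)

(each engaged gene holds one promoter-bound RNAP plus `Γ_n L/v_n`
elongating ones; likewise per mRNA for ribosomes).  Both balances have a
strictly decreasing left side and increasing right side, so the root is
unique; we solve it with a safeguarded Newton iteration on the bracket
[0, 1] to an absolute tolerance of 1e−12, warm-started from the previous
evaluation along a trajectory.  `n = 0` or `r = 0` return `F = 0` by
convention so division events never fault the solver.

Cell volume is proportional to protein mass, `V = Σ p_i L_i / ρ`, so growth
is emergent.  Most proteins are nondegradable; the cell-cycle regulators
are degradable with a short lifetime.  The cell divides when the (weighted)
activator-to-inhibitor concentration ratio rises to a threshold θ; because
activators have weak promoters (`K_act > K_bulk > K_inh`) their
concentration increases with cell size (superlinear copy-number scaling)
while the inhibitors' decreases (sublinear), so the ratio is an increasing
readout of the size-to-ploidy ratio, carried by `F_n`.

## The analytic layer

With short mRNA and regulator lifetimes everything quasi-steadies to the
current `F_n`, and the ratio becomes

    c_act / c_inh = (F_n c_n + K_inh) / (F_n c_n + K_act),

monotone in `F_n` and bounded by θ₁ = K_inh/K_act (at F_n = 0) and
θ₂ = (c_n + K_inh)/(c_n + K_act) (at F_n = 1) — the stable-cycle window.
Division at θ pins the free fraction at division,
`F_n,d = (θ K_act − K_inh)/((1−θ) c_n)`, from which follow the RNAP count
and cell volume at division and birth (with K̃ ≡ θ K_act − K_inh and `n_c`
the genome's total RNAP capacity):

    V_b = γ · a n_c (1−θ) K̃ / [ ((1−θ)c_n − K̃)((1−θ)K_n + K̃) ]

(γ = daughter volume fraction, 1/2 for symmetric division).  The
within-cycle oscillation amplitude is `A(θ) = θ − ratio(F_n,b)` where
`F_n,b` solves the birth-state balance at `n_b = γ n_d`.  Under
per-generation threshold noise `θ_k ~ N(θ̄, (Δθ/3)²)` (reset to the mean
outside θ̄ ± Δθ), the first-order moments are `⟨V_b⟩ = V_b(θ̄)` and
`CV = |d ln V_b/dθ| σ`; the closed-form CV expression is additionally
verified in a test against a numerical delta-method derivative (relative
difference < 1e−6).  Robust division requires that every cycle's ratio
minimum lie below the next threshold draw; since θ − A(θ) increases with θ
this reduces to `A(θ̄ + Δθ) > 2Δθ`.

For genomes with heterogeneous non-regulator promoters, the single-K
formulas use the capacity-weighted *harmonic* mean of the `K_n,i` as the
effective constant.  This is exact in the homogeneous case and reduces the
theory-vs-simulation discrepancy from ~20% to below 5% for lognormal
constants with CV 0.5, because the lumped balance is harmonically weighted
in its linear regime.

## Rate calibration

Only promoter strengths, lengths, lifetimes and translation parameters are
specified directly; the three transcription-initiation rate groups
(ribosome gene, RNAP gene, everything else) are set by three constraints:
total RNAP capacity `n_c = Σ g_i(1 + Γ_n,i L_i/v_n)` equals its target
(10⁴); RNAPs are 10% of ribosomes (`Γ_n,n g_n = 0.1 Γ_n,r g_r`); and the
balanced growth rate, evaluated with the free-ribosome fraction set to zero
as a calibration convenience, equals the attempted rate μ.  All three are
linear in the ribosome-gene rate, so the system is solved exactly; with a
single shared bulk length the solution coincides with the familiar
closed-form rate expression (asserted by a test), and it extends unchanged
to heterogeneous lengths.  Infeasible inputs (μ too large, capacity below
the gene count) raise errors naming the violated inequality.

## Division semantics and event detection

Division fires at the first *upward zero-crossing* of the division signal
at `t ≥ t_min`: the monitored quantity must dip below its threshold and
rise through it.  Right after division the free-RNAP fraction drops
abruptly (half the RNAPs, same gene number), which transiently favors the
strong-promoter inhibitor; the ratio therefore dips by `A` before rising —
this dip is what the crossing detector arms on.  A cycle whose signal never
goes below threshold (a robustness violation: the new draw lies under the
cycle's ratio minimum) ends as `failed_no_division` when the integration
horizon (10/μ) is reached; a lineage also fails if the birth RNAP count
falls below one molecule.  Integration uses `scipy.integrate.solve_ivp`
(LSODA, rtol 1e−7) with a terminal direction=+1 event; SciPy refines the
crossing on the dense output far below the 1e−4 h bookkeeping requirement.
The default `t_min` is 20 min; the viability-band experiment lowers it to
0.01 h so that detection timing cannot mask the *existence* of a crossing,
which is what the robustness condition is about.

The robustness band is probed with the deterministic worst-case threshold
sequence alternating θ̄ + Δθ and θ̄ − Δθ (noise mode `"extremes"`) rather
than with random draws: the analytic condition is a worst-case guarantee
over threshold pairs, and under the truncated normal the binding pair has
probability ~1e−5 per generation, far too rare to flip a lineage of any
reasonable length.

Variants: `gamma`/`eta` implement asymmetric division with Whi5-like
inhibitor partitioning (the daughter receives fraction γ of every species
but η of the inhibitor protein; inhibitor mRNA follows γ);
`replication_delay` doubles all gene copies at the threshold crossing and
divides a fixed time later, halving them again at division;
`kind="hazard"` samples the division ratio by inverse-transform sampling
from a hazard `k(θ)` accumulated from the ratio at `t_min` (default family
`C1·max(0, θ−θ_b)^C2` — an assumption, replaceable by any callable);
`inhibitor_only`, `activator_only` and `and_logic` monitor single-regulator
concentrations.  The nondegradable-inhibitor variant sets `τ_p,inh = ∞`;
its `alpha` field is carried opaquely in configs and does not enter the
dynamics.  In that variant the attainable ratio is of order `μ τ_p` (the
degradable activator is ~its production times its lifetime while the
inhibitor accumulates over the whole cycle), so workable thresholds sit
near 3e−3 with the default lifetimes rather than near 0.2.

## Default parameterization

| parameter | default | why |
|---|---|---|
| K_n,act / K_n / K_n,inh | 12000 / 6000 / 4000 μm⁻³ | weak-activator / strong-inhibitor ordering; reference point of all experiments (mutant panels use K_n,inh = 1000 μm⁻³, g_act = g_inh = 10) |
| n_c | 10⁴ | RNAP capacity target of the calibration |
| μ | ln2/2 h⁻¹ | 2 h attempted doubling time |
| a, ρ | 10, 2.5e9 aa μm⁻³ | nucleus ≈ 10% of cell volume; protein density; together they set c_n ≈ 1.2e5 μm⁻³, which places θ = 0.7–0.8 (with Δθ = 0.1 noise) inside the stable window |
| L_bulk, L_n, L_r | 400, 4000, 7000 codons | typical gene vs large multi-subunit machines |
| v_n = v_r | 7200 codons/h | 2 codons/s |
| Γ_r, K_r | 3600 h⁻¹, 2e4 μm⁻³ | translation initiation ~1/s, partially saturated |
| τ_m, τ_p (regulators) | 30 s, 1 min | deep in the quasi-steady regime (μτ ≪ 1) the analytic layer assumes; the residual theory-vs-simulation offset scales as e^{μ(τ_m+τ_p)} − 1 ≈ 0.6% at these values (it is ~4% at τ_m = 2 min, τ_p = 5 min) |
| bulk genes | 5000 × 400 codons, lumped into one class | keeps the ODE at 10 dimensions; heterogeneous runs split them into ~50 classes with lognormal K (mean 6000 μm⁻³, CV 0.5) |
| g_rnap, g_ribo | 10, 100 | plausible dosage; only the products Γ_n g enter the theory |
| t_min | 20 min | minimum cycle duration |
| burn-in | 10 generations | discarded before recording |

These defaults are the package's study conditions; they are chosen once and
shared by theory and simulation.  Known sensitivity: at fixed θ̄ = 0.7 the
theoretical CV of the birth size decreases with K_n,act only while θ̄ stays
well below θ₂; beyond K_n,act ≈ 14000 μm⁻³ the shrinking window dominates
and the CV turns up.  Monotonicity tests therefore sweep K_n,act within
±25% of the reference value.

## What the generator emulates — and what it does not

The synthetic cell reproduces the mechanism under study: resource-limited
expression, differential promoter strength, threshold division, threshold
noise, ploidy and dosage changes.  It does not model copy-number noise in
mRNA/protein (the dynamics are deterministic given θ), spatial structure,
explicit cell-cycle phases, promoter-level regulation (feedback between
regulators), or population structure (a single daughter lineage is
tracked).  Passing tests therefore validate the mechanism's internal
consistency — simulation against its own asymptotic theory — not agreement
with any particular organism's measurements.

## Numerical choices and measured discrepancies

- ODE: LSODA, rtol 1e−7, atol 1e−6; the ~10-dimensional system has a
  timescale ratio of ~300 (mRNA decay vs growth).
- Free-fraction solves: warm-started safeguarded Newton, tolerance 1e−12;
  property tests hold the residual below 1e−10 and cross-check a 10⁶-point
  grid-scan oracle to 1e−6.
- Simulated steady-state birth volumes sit ~0.6% above the quasi-steady
  theory (finite-lifetime lag), uniformly across the window.
- The simulated oscillation amplitude sits ~3% below the analytic `A(θ)`
  (the cell grows during the post-division relaxation, so the realized
  minimum is slightly shallower).  Propagated through the robustness
  condition this displaces the measured viability edges from the predicted
  ones by about −0.006 (upper) and +0.012 (lower) in θ̄ at Δθ = 0.1; the
  acceptance test asserts a ±0.01 agreement and the lower edge currently
  fails it by ~0.002 — a structural finite-lifetime discrepancy we report
  rather than hide.
- Mutant panels use common random numbers (the same threshold draws for
  wild type and deletions), making the paired CV contrasts far less noisy
  than independent runs.
- Problem sizes: sizer statistics use a 2000-generation lineage; moment
  grids 400 generations per θ̄; mutant panels 400 generations per strain;
  viability edges are bisected to 2e−3 with 20-generation probes.

## Limitations

- The closed-form layer assumes short regulator/mRNA lifetimes and neglects
  regulator mass in the volume; both are excellent at the defaults but
  degrade as lifetimes approach the doubling time.
- No closed-form theory is provided for the nondegradable-inhibitor or
  gene-replication variants (their birth volumes are produced by simulation
  only); the replication variant keeps the same critical window.
- The hazard family and its constants are assumptions; conclusions drawn
  from the hazard variant are qualitative (imperfect-sizer direction).
- Cycle-to-cycle stability of the deterministic fixed point is established
  numerically (perturbation decay), not by proof.
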