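"""Default parameter sets and genome builders.

The default parameterization is the package's reference condition: a single
activator and a single inhibitor embedded in a genome of 5000 lumped bulk
genes, calibrated so that the genome holds at most 10^4 RNAPs, RNAPs are 10%
of ribosomes, and the attempted growth rate is ln(2)/2 per hour (a 2 h
doubling time).  Promoter strengths follow the weak-activator /
strong-inhibitor pattern: K_n,act = 12000 um^-3 > K_n = 6000 um^-3 >
K_n,inh = 4000 um^-3, so the activator scales superlinearly and the
inhibitor sublinearly with cell size.

Values not fixed by those constraints (lengths, elongation speeds,
lifetimes, translation parameters, the cell-to-nuclear volume ratio ``a``
and the protein density ``rho``) are documented defaults chosen for
timescale separation (mRNA and regulator lifetimes of minutes against a
cell cycle of hours) and a nuclear RNAP concentration large enough that the
working thresholds theta = 0.7-0.8 sit inside the stable-cycle window; see
docs/methods.md.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .model import GeneClass, Genome, GlobalParams, calibrate_rates

__all__ = [
    "DEFAULTS",
    "default_params",
    "build_default_genome",
    "sample_heterogeneous_affinities",
]

#: Documented default parameter values (SI-style units as in the docstrings).
DEFAULTS: dict[str, float] = {
    "a": 10.0,                 # cell-to-nuclear volume ratio
    "rho": 2.5e9,              # amino acids per um^3
    "v_n": 7200.0,             # RNAP elongation, codons/h (2 codons/s)
    "v_r": 7200.0,             # ribosome elongation, codons/h
    "mu": math.log(2) / 2.0,   # attempted growth rate, 1/h
    "nc_target": 1.0e4,        # max RNAPs the genome can hold
    "cytoplasm_fraction": 1.0,
    "K_n": 6000.0,             # bulk transcription MM constant, um^-3
    "K_n_act": 12000.0,        # activator (weak promoter)
    "K_n_inh": 4000.0,         # inhibitor (strong promoter)
    "K_r": 2.0e4,              # translation MM constant, um^-3
    "Gamma_r": 3600.0,         # translation initiation rate, 1/h (1/s)
    "tau_m": 1.0 / 120.0,      # mRNA lifetime, h (30 s)
    "tau_p_reg": 1.0 / 60.0,   # regulator protein lifetime, h (1 min)
    "L_bulk": 400.0,           # codons
    "L_rnap": 4000.0,
    "L_ribo": 7000.0,
    "n_bulk_genes": 5000.0,    # lumped bulk multiplicity
    "g_rnap": 10.0,            # RNAP gene copies
    "g_ribo": 100.0,           # ribosome gene copies
}


def default_params(**overrides: float) -> GlobalParams:
    d = {k: DEFAULTS[k] for k in
         ("a", "rho", "v_n", "v_r", "mu", "nc_target", "cytoplasm_fraction")}
    d.update(overrides)
    return GlobalParams(**d)


def sample_heterogeneous_affinities(
    n_classes: int,
    mean: float = 6000.0,
    cv: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Lognormal promoter MM constants with given arithmetic mean and CV.

    ``cv = 0`` returns all values equal to ``mean``.  Reproducible for a
    fixed seed.
    """
    if mean <= 0 or cv < 0:
        raise ValueError("mean must be positive and cv nonnegative")
    if cv == 0:
        return np.full(n_classes, float(mean))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = math.log(1.0 + cv * cv)
    mu_log = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu_log, sigma=math.sqrt(sigma2), size=n_classes)


def build_default_genome(
    *,
    g_act: int = 1,
    g_inh: int = 1,
    K_act: float | None = None,
    K_inh: float | None = None,
    act_K: Sequence[float] | None = None,
    inh_K: Sequence[float] | None = None,
    act_weights: Sequence[float] | None = None,
    inh_weights: Sequence[float] | None = None,
    nondegradable_inhibitor: bool = False,
    heterogeneous_bulk: bool = False,
    n_bulk_classes: int = 50,
    bulk_cv: float = 0.5,
    seed: int = 0,
    ploidy: int = 1,
    params: GlobalParams | None = None,
) -> tuple[Genome, GlobalParams]:
    """Build and calibrate the reference genome.

    Parameters
    ----------
    g_act, g_inh : int
        Number of activator / inhibitor genes.  With scalar ``K_act`` /
        ``K_inh`` they become the copy number of a single class (all
        regulators identical); the multi-regulator panel uses
        ``g_act = g_inh = 10`` with ``K_inh = 1000``.
    act_K, inh_K : sequence of float, optional
        Per-regulator MM constants; overrides ``g_act``/``K_act`` style
        lumping with one class per regulator (used with per-regulator
        division weights).
    act_weights, inh_weights : sequence of float, optional
        Division-rule weights chi per regulator class (requires ``act_K`` /
        ``inh_K`` of the same length).
    nondegradable_inhibitor : bool
        Give inhibitors an infinite protein lifetime.
    heterogeneous_bulk : bool
        Replace the single lumped bulk class by ``n_bulk_classes`` classes
        whose MM constants are lognormal with mean ``K_n`` and CV
        ``bulk_cv``.
    ploidy : int
        Ploidy applied *after* calibration, so haploid and polyploid
        genomes share per-copy rates.

    Returns
    -------
    (Genome, GlobalParams)
        The calibrated genome and the global parameters used.
    """
    p = params or default_params()
    K_act = DEFAULTS["K_n_act"] if K_act is None else float(K_act)
    K_inh = DEFAULTS["K_n_inh"] if K_inh is None else float(K_inh)
    tau_m = DEFAULTS["tau_m"]
    tau_p = DEFAULTS["tau_p_reg"]
    K_r = DEFAULTS["K_r"]
    Gr = DEFAULTS["Gamma_r"]
    Lb = int(DEFAULTS["L_bulk"])

    common = dict(K_r=K_r, Gamma_r=Gr, tau_m=tau_m)
    classes: list[GeneClass] = [
        GeneClass(label="rnap", role="rnap", length=int(DEFAULTS["L_rnap"]),
                  K_n=DEFAULTS["K_n"], copy_number=int(DEFAULTS["g_rnap"]), **common),
        GeneClass(label="ribosome", role="ribosome", length=int(DEFAULTS["L_ribo"]),
                  K_n=DEFAULTS["K_n"], copy_number=int(DEFAULTS["g_ribo"]), **common),
    ]

    tau_p_inh = math.inf if nondegradable_inhibitor else tau_p
    if act_K is not None or inh_K is not None:
        if act_K is None or inh_K is None:
            raise ValueError("act_K and inh_K must be given together")
        aw = list(act_weights) if act_weights is not None else [1.0] * len(act_K)
        iw = list(inh_weights) if inh_weights is not None else [1.0] * len(inh_K)
        if len(aw) != len(act_K) or len(iw) != len(inh_K):
            raise ValueError("weights must match the number of regulator classes")
        for j, (k, wgt) in enumerate(zip(act_K, aw), start=1):
            classes.append(GeneClass(label=f"act{j}", role="activator", length=Lb,
                                     K_n=float(k), tau_p=tau_p, weight=wgt, **common))
        for j, (k, wgt) in enumerate(zip(inh_K, iw), start=1):
            classes.append(GeneClass(label=f"inh{j}", role="inhibitor", length=Lb,
                                     K_n=float(k), tau_p=tau_p_inh, weight=wgt, **common))
    else:
        classes.append(GeneClass(label="activator", role="activator", length=Lb,
                                 K_n=K_act, copy_number=g_act, tau_p=tau_p, **common))
        classes.append(GeneClass(label="inhibitor", role="inhibitor", length=Lb,
                                 K_n=K_inh, copy_number=g_inh, tau_p=tau_p_inh, **common))

    n_bulk = int(DEFAULTS["n_bulk_genes"])
    if heterogeneous_bulk:
        Ks = sample_heterogeneous_affinities(n_bulk_classes, DEFAULTS["K_n"], bulk_cv, seed)
        per, rem = divmod(n_bulk, n_bulk_classes)
        for j, k in enumerate(Ks):
            mult = per + (1 if j < rem else 0)
            classes.append(GeneClass(label=f"bulk{j + 1}", role="bulk", length=Lb,
                                     K_n=float(k), multiplicity=mult, **common))
    else:
        classes.append(GeneClass(label="bulk", role="bulk", length=Lb,
                                 K_n=DEFAULTS["K_n"], multiplicity=n_bulk, **common))

    genome = calibrate_rates(Genome(classes), p)
    if ploidy != 1:
        genome = genome.with_ploidy(ploidy)
    return genome, p
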