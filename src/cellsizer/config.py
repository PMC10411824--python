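"""Config-file round-tripping for genomes, global parameters and rules.

The on-disk schema is a plain mapping (YAML or JSON by file extension)::

    params:  {a, rho, v_n, v_r, mu, nc_target, cytoplasm_fraction}
    genome:
      ploidy: 1
      classes:
        - {label, role, length, K_n, K_r, Gamma_r, tau_m, copy_number,
           multiplicity, Gamma_n, tau_p, weight}
    rule:    {kind, theta, theta_bar, delta_theta, noise, t_min, gamma, ...}

Infinite lifetimes are stored as the string ``"inf"``.  ``Gamma_n`` may be
null for uncalibrated skeletons.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import yaml

from .lineage import DivisionRule
from .model import GeneClass, Genome, GlobalParams

__all__ = [
    "genome_to_dict", "genome_from_dict",
    "params_to_dict", "params_from_dict",
    "rule_to_dict", "rule_from_dict",
    "save_config", "load_config",
]


def _enc(v):
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    return v


def _dec_float(v):
    if v in ("inf", ".inf", "Infinity"):
        return math.inf
    return float(v)


def params_to_dict(params: GlobalParams) -> dict:
    return {k: v for k, v in asdict(params).items()}


def params_from_dict(d: dict) -> GlobalParams:
    return GlobalParams(**{k: float(v) for k, v in d.items()})


def genome_to_dict(genome: Genome) -> dict:
    classes = []
    for c in genome.classes:
        d = asdict(c)
        d["tau_m"] = _enc(d["tau_m"])
        d["tau_p"] = _enc(d["tau_p"])
        classes.append(d)
    return {"ploidy": genome.ploidy, "classes": classes}


def genome_from_dict(d: dict) -> Genome:
    classes = []
    for cd in d["classes"]:
        cd = dict(cd)
        cd["tau_m"] = _dec_float(cd["tau_m"])
        cd["tau_p"] = _dec_float(cd.get("tau_p", "inf"))
        if cd.get("Gamma_n") is not None:
            cd["Gamma_n"] = float(cd["Gamma_n"])
        classes.append(GeneClass(**cd))
    return Genome(classes, ploidy=int(d.get("ploidy", 1)))


def rule_to_dict(rule: DivisionRule) -> dict:
    d = {k: v for k, v in asdict(rule).items() if k != "hazard"}
    return d


def rule_from_dict(d: dict) -> DivisionRule:
    return DivisionRule(**d)


def save_config(
    path: str | Path,
    genome: Genome,
    params: GlobalParams,
    rule: DivisionRule | None = None,
) -> None:
    doc = {"params": params_to_dict(params), "genome": genome_to_dict(genome)}
    if rule is not None:
        doc["rule"] = rule_to_dict(rule)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path):
    """Returns ``(genome, params, rule-or-None)``."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    genome = genome_from_dict(doc["genome"])
    params = params_from_dict(doc["params"])
    rule = rule_from_dict(doc["rule"]) if "rule" in doc else None
    return genome, params, rule
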