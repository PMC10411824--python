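"""A deterministic cell cycle: periodic growth and division at a fixed threshold.

Builds the calibrated reference cell, runs a short lineage at theta = 0.8,
and compares the simulated birth volume and amplitude with the closed-form
predictions.
"""

from cellsizer import DivisionRule, TheoryInputs, amplitude, birth_volume, simulate_lineage
from cellsizer.experiments import simulated_amplitude
from cellsizer.presets import build_default_genome

genome, params = build_default_genome()
ti = TheoryInputs.from_genome(genome, params)

theta = 0.8
res = simulate_lineage(5, DivisionRule(theta=theta), genome, params, seed=0)
vb = res.array("V_b")
td = res.array("T_D")

print(f"status: {res.status}")
print(f"birth volume  simulated {vb.mean():.4f} um^3   theory {birth_volume(theta, ti):.4f} um^3")
print(f"doubling time {td.mean():.3f} h (all cycles identical to {td.std():.1e})")
print(f"amplitude     simulated {simulated_amplitude(theta, genome, params):.4f}"
      f"        theory {amplitude(theta, ti):.4f}")
print()
print("The cell divides whenever the activator-to-inhibitor concentration")
print("ratio rises back to theta; the simulated fixed point sits within a")
print("percent of the quasi-steady theory, and the amplitude is the depth")
print("of the ratio's dip after division.")
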