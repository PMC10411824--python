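"""Deleting one of many regulators shifts mean size but barely changes the CV.

Ten activators and ten inhibitors share the division rule.  Removing one
activator raises the equivalent threshold by 10/9 (cells get bigger);
removing one inhibitor lowers it by 9/10 (smaller).  Because birth volume is
nearly linear in the equivalent threshold, the relative width (CV) of the
size distribution is almost untouched.
"""

from cellsizer.experiments import mutant_panel

df = mutant_panel(theta_bar=0.45, delta_theta=0.1, n_generations=300, seed=11)
print(df.to_string(index=False, float_format=lambda v: f"{v:+.4f}"))
print()
print("delta_mean is the relative change of <V_b> vs wild type, delta_cv the")
print("relative change of its CV; |delta_cv| << |delta_mean| reproduces the")
print("observation that size distributions stay narrow after regulator knockouts.")
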