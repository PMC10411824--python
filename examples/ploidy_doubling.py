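"""Birth volume is proportional to ploidy.

Doubling every gene's copy number doubles the cell size at birth while the
free-RNAP fraction — the cell's size-to-ploidy sensor — is unchanged.
"""

from cellsizer.experiments import ploidy_experiment

df = ploidy_experiment([0.5, 0.7, 0.85], n_generations=3, seed=0)
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("The 'ratio' column is V_b(diploid)/V_b(haploid); the model predicts")
print("exactly 2 at every threshold because the total-RNAP concentration is")
print("gene-dosage invariant and the RNAP capacity n_c doubles with ploidy.")
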