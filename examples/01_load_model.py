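"""Mortality cost of within-generation selection at many loci.

Solves the codominant viability-selection recursion for the selection
coefficient that shifts an allele from 50% to 55% in one generation, and
compounds the implied cohort survival over independent loci.
"""

from glpanmix.loadmodel import load_table, joint_survival

table = load_table(p0=0.5, delta_p=0.05, loci=[1, 10, 100])
print(table.to_string(index=False, float_format=lambda x: f"{x:.6g}"))

sc = joint_survival(0.5, 0.05, 100)
print(f"\nAt 100 loci roughly 1 in 10^{sc.one_in_log10} individuals survives.")
print("Reading: s is the per-locus selection coefficient (fitnesses "
      "1 : 1-s/2 : 1-s), per_locus_survival the mean fitness relative to "
      "the fittest genotype, and mortality the fraction of the cohort "
      "that must die each generation to produce the shift at every locus.")
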