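"""Simulate low-coverage pileups and call SNPs from genotype likelihoods.

Builds a small panmictic cohort at 1.4x coverage, computes GATK-model
genotype likelihoods, estimates minor allele frequencies by EM and
applies the study's SNP-calling and MAF filters.
"""

import numpy as np

from glpanmix import SimConfig, simulate_all, compute_gls, call_snps

cfg = SimConfig(n_localities=4, n_per_locality=15, n_outgroup=0,
                n_sites=2_000, chrom_length=1_000_000,
                inversion_span=(400_000, 500_000), inversion_freq=0.0,
                outgroup_inversion_freq=0.0, seed=7)
freqs, truth, pileup = simulate_all(cfg)
print(f"{len(truth.individuals)} diploids, {cfg.n_sites} sites, "
      f"mean depth {pileup.depth.mean():.2f}x")

gls = compute_gls(pileup)
table = call_snps(gls)
called = table["pass_snp"]
print(f"SNPs at p < 1e-6: {called.sum()}  "
      f"(MAF >= 5%: {int((table.pass_maf05 & called).sum())}, "
      f"MAF >= 10%: {int((table.pass_maf10 & called).sum())})")

err = np.abs(table["alt_freq"] - truth.true_freqs[:4].mean(axis=0))
print(f"median |f_hat - f_true| = {np.nanmedian(err):.4f}")
print("Reading: even at 1.4x, pooling read likelihoods over 60 diploids "
      "recovers allele frequencies to a few percent; the filters "
      "reproduce the study's '-SNP_pval 1e-6' and '-minMaf 0.05/0.1' "
      "site lists.")
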