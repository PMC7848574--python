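"""PC selection scan and inversion-haplotype genotyping.

The chi2(1)-calibrated per-SNP statistic flags the non-recombining
haplotype block; kinship over the block's top SNPs separates the three
regional genotypes, whose frequencies are homogeneous across localities.
"""

import numpy as np

from glpanmix import (SimConfig, simulate_all, compute_gls, call_snps,
                      pca_from_gls, pc_selection_scan, kinship_from_gls,
                      select_region_snps, cluster_three_groups,
                      frequency_homogeneity_test)

span = (400_000, 600_000)
cfg = SimConfig(n_localities=5, n_per_locality=20, n_outgroup=0,
                n_sites=2_000, chrom_length=2_000_000,
                inversion_span=span, seed=11)
_, truth, pileup = simulate_all(cfg)
gls = compute_gls(pileup)
table = call_snps(gls)
mask = (table["pass_maf10"] & table["pass_snp"]).to_numpy()

pca = pca_from_gls(gls, mask)
scan = pc_selection_scan(pca, gls, mask)
pos = scan.sites["pos0"].to_numpy()
inside = (pos >= span[0]) & (pos < span[1])
print(f"median selection statistic: inside block "
      f"{np.median(scan.stat[inside]):.2f}, elsewhere "
      f"{np.median(scan.stat[~inside]):.3f} (neutral expectation ~0.45)")

idx = select_region_snps(scan, "chr1", span, top_fraction=0.5)
snp_pos = scan.sites["pos0"].to_numpy()[idx]
full = np.flatnonzero(np.isin(gls.sites["pos0"].to_numpy(), snp_pos))
site_mask = np.zeros(gls.n_sites, dtype=bool)
site_mask[full] = True
kin = kinship_from_gls(gls, site_mask)
cs = cluster_three_groups(kin, gls, full, "chr1", span, seed=0)

agree = (cs.group[cs.group != "unassigned"]
         == truth.inversion_group[cs.group != "unassigned"]).mean()
print("group counts:", {g: int((cs.group == g).sum())
                        for g in ("hom1", "het", "hom2", "unassigned")})
print(f"haplotype-2 frequency {cs.hap2_frequency()['overall']:.3f} "
      f"(simulated 0.29); agreement with truth {100 * agree:.1f}%")
chi2, df, p = frequency_homogeneity_test(cs, truth.locality_labels)
print(f"frequency homogeneity across localities: chi2 = {chi2:.2f}, "
      f"df = {df}, P = {p:.2f}")
print("Reading: three discrete kinship clusters are the signature of a "
      "segregating inversion; a non-significant homogeneity test says "
      "its frequency does not differ among localities.")
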