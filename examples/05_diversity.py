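"""Windowed nucleotide diversity and Tajima's D with outgroup polarization.

Polarizes alleles against the outgroup read consensus, estimates the
unfolded SFS by EM, and computes theta_pi, Watterson's theta and
Tajima's D in 5-kb windows — showing the diversity loss where the
haplotype swept in the outgroup.
"""

import numpy as np

from glpanmix import (SimConfig, simulate_all, compute_gls,
                      outgroup_consensus, saf_per_site, sfs_em,
                      window_thetas)
from glpanmix.diversity import site_filters

span = (400_000, 600_000)
cfg = SimConfig(n_localities=3, n_per_locality=12, n_outgroup=25,
                n_sites=2_000, chrom_length=1_000_000,
                inversion_span=span, seed=19)
_, truth, pileup = simulate_all(cfg)
gls = compute_gls(pileup)
outg = np.flatnonzero(truth.species_labels == "outgroup")
anc = outgroup_consensus(pileup.subset(outg))
print(f"ancestral allele called at {(anc != 'N').mean() * 100:.1f}% of sites")

for name, idx in (("outgroup", outg),
                  ("one ingroup locality",
                   np.flatnonzero(truth.locality_labels == "L01"))):
    keep = site_filters(pileup.subset(idx))
    sub = gls.subset_individuals(idx).subset_sites(keep)
    saf = saf_per_site(sub, anc[keep])
    sfs = sfs_em(saf.logl)
    wins = window_thetas(saf, sfs, window_bp=5_000,
                         chrom_length=cfg.chrom_length)
    tab = wins.table
    in_reg = ((tab["start"] >= span[0]) & (tab["end"] <= span[1])).to_numpy()
    pi = tab["theta_pi"].to_numpy()
    print(f"{name}: per-SNP theta_pi genome median "
          f"{np.nanmedian(pi[~in_reg]):.3f}, inside swept block "
          f"{np.nanmedian(pi[in_reg]):.3f}, mean Tajima's D "
          f"{np.nanmean(tab['tajima_d']):.2f}")
print("Reading: the outgroup, near-fixed for the founder haplotype, has "
      "lost nearly all diversity inside the block (a sweep signature); "
      "the conspecific sample keeps its diversity there.")
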