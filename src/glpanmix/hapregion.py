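"""Local haplotype analysis of a candidate inversion region.

A non-recombining haplotype block shows up as three discrete clusters of
individuals (the two homozygotes and the heterozygote) in a kinship
matrix computed from the region's most PC-informative SNPs. This module
selects those SNPs, clusters individuals into hom1/het/hom2 along the
kinship leading eigenvector, profiles windowed dosages along the
chromosome, contrasts group-wise Tajima's D, and tests haplotype
frequency homogeneity across sampling localities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .genolik import GLMatrix, estimate_maf
from .popstructure import posterior_expected_dosage
from .scans import SelectionTrack
from .diversity import saf_per_site, sfs_em, window_thetas, WindowDiversity

GROUPS = ("hom1", "het", "hom2")


def select_region_snps(track: SelectionTrack, chrom: str,
                       span: tuple[int, int], *,
                       top_fraction: float = 0.10,
                       min_snps: int = 20) -> np.ndarray:
    """Top selection-statistic SNPs inside a region (indices into track).

    Keeps ceil(top_fraction * m) SNPs, at least ``min_snps``; ties broken
    by position.
    """
    sites = track.sites
    lo, hi = span
    in_region = ((sites["chrom"] == chrom) & (sites["pos0"] >= lo)
                 & (sites["pos0"] < hi)).to_numpy()
    idx = np.flatnonzero(in_region)
    if len(idx) < min_snps:
        raise ValueError(
            f"region {chrom}:{lo}-{hi} has only {len(idx)} scanned SNPs "
            f"(need >= {min_snps})")
    n_keep = max(min_snps, int(np.ceil(top_fraction * len(idx))))
    n_keep = min(n_keep, len(idx))
    stat = track.stat[idx]
    pos = sites["pos0"].to_numpy()[idx]
    order = np.lexsort((pos, -stat))       # stat desc, then position asc
    return np.sort(idx[order[:n_keep]])


@dataclass
class HaplotypeCallSet:
    chrom: str
    span: tuple[int, int]
    snp_indices: np.ndarray
    individuals: list[str]
    group: np.ndarray                 # hom1/het/hom2/unassigned per individual
    mean_dosage: np.ndarray           # regional mean posterior minor dosage
    eigen_projection: np.ndarray

    def counts_by(self, labels: np.ndarray) -> pd.DataFrame:
        """Per-label counts of each haplotype group (assigned only)."""
        df = pd.DataFrame({"label": labels, "group": self.group})
        df = df[df["group"] != "unassigned"]
        return df.groupby(["label", "group"]).size().unstack(fill_value=0)

    def hap2_frequency(self, labels: np.ndarray | None = None) -> pd.Series:
        """Haplotype-2 frequency overall or per label: (2 hom2 + het)/2n."""
        assigned = self.group != "unassigned"
        copies = np.select([self.group == "het", self.group == "hom2"],
                           [1, 2], default=0)
        if labels is None:
            return pd.Series(
                {"overall": copies[assigned].sum() / (2.0 * assigned.sum())})
        df = pd.DataFrame({"label": np.asarray(labels)[assigned],
                           "copies": copies[assigned]})
        grp = df.groupby("label")["copies"]
        return grp.sum() / (2.0 * grp.size())


def cluster_three_groups(kinship: pd.DataFrame, gls: GLMatrix,
                         snp_indices: np.ndarray, chrom: str,
                         span: tuple[int, int], *,
                         sd_cutoff: float = 3.0,
                         min_silhouette: float = 0.2,
                         seed: int = 0) -> HaplotypeCallSet:
    """Assign individuals to hom1/het/hom2 via the kinship eigenvector.

    Individuals are projected on the kinship matrix's leading eigenvector
    and clustered by 1-D k-means (k=3); the middle cluster on the axis is
    the heterozygote group and the smaller extreme cluster is labeled
    hom2 (haplotype 2 being the less common regional haplotype, its
    homozygotes are the rarer class). Individuals more
    than ``sd_cutoff`` within-cluster standard deviations from their
    center are left unassigned, as are all individuals when the three
    clusters are not distinguishable (silhouette < ``min_silhouette``).
    """
    k = kinship.to_numpy(dtype=np.float64)
    filled = np.nan_to_num(k, nan=0.0)
    filled = (filled + filled.T) / 2.0
    vals, vecs = np.linalg.eigh(filled)
    proj = vecs[:, -1]

    mask = np.zeros(gls.n_sites, dtype=bool)
    mask[np.asarray(snp_indices)] = True
    sub = gls.subset_sites(mask)
    f, _ = estimate_maf(sub)
    f = np.nan_to_num(f, nan=0.5)
    dose = posterior_expected_dosage(sub.linear(), f)
    mean_dose = dose.mean(axis=1)

    n = len(proj)
    group = np.full(n, "unassigned", dtype=object)
    if len(np.unique(np.round(proj, 12))) < 3:
        warnings.warn("fewer than 3 distinguishable clusters in region")
        return HaplotypeCallSet(chrom, span, np.asarray(snp_indices),
                                list(kinship.index), group, mean_dose, proj)
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    lab = km.fit_predict(proj[:, None])
    sil = silhouette_score(proj[:, None], lab)
    if sil < min_silhouette:
        warnings.warn(
            f"clusters not distinguishable (silhouette {sil:.3f}); "
            "all individuals unassigned")
        return HaplotypeCallSet(chrom, span, np.asarray(snp_indices),
                                list(kinship.index), group, mean_dose, proj)
    # heterozygotes sit between the homozygote clusters on the kinship
    # axis; of the two extreme clusters, haplotype 2 (by definition the
    # less common regional haplotype) is the smaller one
    axis_order = np.argsort([proj[lab == c].mean() for c in range(3)])
    ends = (axis_order[0], axis_order[2])
    sizes = {c: (lab == c).sum() for c in ends}
    hom2 = min(ends, key=lambda c: (sizes[c], -mean_dose[lab == c].mean()))
    hom1 = ends[0] if ends[1] == hom2 else ends[1]
    relabel = np.empty(3, dtype=int)
    relabel[hom1] = 0
    relabel[axis_order[1]] = 1
    relabel[hom2] = 2
    lab = relabel[lab]
    centers = np.array([proj[lab == c].mean() for c in range(3)])
    sds = np.array([max(proj[lab == c].std(), 1e-12) for c in range(3)])
    dist = np.abs(proj - centers[lab]) / sds[lab]
    ok = dist <= sd_cutoff
    group[ok] = np.array(GROUPS, dtype=object)[lab[ok]]
    return HaplotypeCallSet(chrom, span, np.asarray(snp_indices),
                            list(kinship.index), group, mean_dose, proj)


def windowed_dosage_profiles(gls: GLMatrix, chrom: str, *,
                             window: int = 100, step: int = 10) -> pd.DataFrame:
    """Cohort-centered sliding-window mean dosage per individual.

    For each window of ``window`` consecutive SNPs (step ``step``) on the
    chromosome, the mean posterior expected minor dosage per individual
    minus the cohort mean for that window. Inside a haplotype block the
    three genotype groups separate into three bands; the bands collapse
    where recombination mixes haplotypes.
    """
    on_chrom = (gls.sites["chrom"] == chrom).to_numpy()
    sub = gls.subset_sites(on_chrom)
    f, _ = estimate_maf(sub)
    ok = np.isfinite(f)
    sub, f = sub.subset_sites(ok), f[ok]
    dose = posterior_expected_dosage(sub.linear(), np.nan_to_num(f, nan=0.5))
    pos = sub.sites["pos0"].to_numpy()
    m = dose.shape[1]
    rows = []
    for start in range(0, m - window + 1, step):
        sl = slice(start, start + window)
        wmean = dose[:, sl].mean(axis=1)
        centered = wmean - wmean.mean()
        rows.append((pos[start], pos[start + window - 1] + 1, centered))
    out = pd.DataFrame(
        [(s, e) for s, e, _ in rows], columns=["start", "end"])
    prof = np.array([c for _, _, c in rows])   # (n_windows, n_individuals)
    for i, ind in enumerate(sub.individuals):
        out[ind] = prof[:, i]
    return out


def group_tajimas_d(gls: GLMatrix, ancestral: np.ndarray,
                    callset: HaplotypeCallSet, group: str, *,
                    window_bp: int = 5_000,
                    min_group: int = 4) -> WindowDiversity:
    """Windowed Tajima's D restricted to one haplotype group in the region."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    idx = np.flatnonzero(callset.group == group)
    if len(idx) < min_group:
        raise ValueError(f"group {group} has only {len(idx)} individuals "
                         f"(need >= {min_group})")
    lo, hi = callset.span
    in_region = ((gls.sites["chrom"] == callset.chrom)
                 & (gls.sites["pos0"] >= lo)
                 & (gls.sites["pos0"] < hi)).to_numpy()
    group_gls = gls.subset_individuals(idx)
    # SFS prior from all available sites (the realSFS-style genome-wide
    # spectrum), thetas from the region's windows only
    saf_all = saf_per_site(group_gls, np.asarray(ancestral))
    sfs = sfs_em(saf_all.logl)
    saf_region = saf_per_site(group_gls.subset_sites(in_region),
                              np.asarray(ancestral)[in_region])
    return window_thetas(saf_region, sfs, window_bp=window_bp)


def frequency_homogeneity_test(callset: HaplotypeCallSet,
                               labels: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity of haplotype counts across localities.

    Tests hap2 vs hap1 allele counts over the L localities with assigned
    individuals (df = L - 1); localities with no assigned individual are
    dropped with a warning.
    """
    labels = np.asarray(labels)
    assigned = callset.group != "unassigned"
    copies2 = np.select([callset.group == "het", callset.group == "hom2"],
                        [1, 2], default=0)
    uniq = pd.unique(labels)
    hap2, hap1 = [], []
    for loc in uniq:
        sel = assigned & (labels == loc)
        if sel.sum() == 0:
            warnings.warn(f"locality {loc} has no assigned individuals; dropped")
            continue
        c2 = int(copies2[sel].sum())
        hap2.append(c2)
        hap1.append(int(2 * sel.sum() - c2))
    table = np.array([hap2, hap1])
    if table.shape[1] < 2:
        raise ValueError("need at least two localities with assigned individuals")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    if table.min() == 0 and table.sum(axis=0).min() == 0:
        raise ValueError("degenerate contingency table")
    if np.allclose(chi2, 0.0):
        p = 1.0
    return float(chi2), int(df), float(p)
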