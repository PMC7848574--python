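"""End-to-end orchestration of the panmixia analysis on simulated data.

``run_panmixia_study`` sequences the full flow — simulation, genotype
likelihoods, SNP calling, structure (PCA/admixture), differentiation
contrasts, the PC selection scan, inversion-haplotype genotyping,
windowed diversity and the selection-load model — and emits a
machine-readable JSON report. A single run seed is fanned out
deterministically to per-stage child seeds, so identical configuration
and seed give byte-identical reports.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from . import diversity as dv
from . import genolik as gk
from . import hapregion as hr
from . import loadmodel as lm
from . import popstructure as ps
from . import scans as sc
from .simdata import SimConfig, simulate_all


@dataclass
class RunConfig:
    """Thresholds default to the study's printed values."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_maf05: float = 0.05
    min_maf10: float = 0.10
    snp_pval: float = 1e-6
    roll_window_snps: int = 100
    diversity_window_bp: int = 5_000
    admixture_k: int = 2
    admixture_starts: int = 5
    admixture_tol: float = 1e-4
    region_top_fraction: float = 0.25
    seed: int = 0
    out_dir: str | None = None
    run_diversity: bool = True
    run_hapregion: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "inversion_span" in sim_raw:
            sim_raw["inversion_span"] = tuple(sim_raw["inversion_span"])
        if "introgressed_localities" in sim_raw:
            sim_raw["introgressed_localities"] = tuple(
                sim_raw["introgressed_localities"])
        return cls(sim=SimConfig(**sim_raw), **raw)


def preset(name: str, seed: int = 0) -> RunConfig:
    """Named study scenarios.

    panmictic: the null the study supports (no locality differentiation).
    structured: a positive control with Fst 0.05 among localities.
    inversion-demo: the defaults with the 29%-frequency inversion block
    and the outgroup near-fixed for haplotype 2.
    """
    if name == "panmictic":
        sim = SimConfig(n_per_locality=24, n_outgroup=12, n_sites=4_000,
                        chrom_length=2_000_000,
                        inversion_span=(800_000, 1_000_000), seed=seed)
        return RunConfig(sim=sim, seed=seed, admixture_starts=2,
                         admixture_tol=1e-2, run_diversity=False,
                         run_hapregion=False)
    if name == "structured":
        sim = SimConfig(n_per_locality=24, n_outgroup=12, n_sites=4_000,
                        chrom_length=2_000_000, fst_target=0.05,
                        inversion_span=(800_000, 1_000_000), seed=seed)
        return RunConfig(sim=sim, seed=seed, admixture_starts=2,
                         admixture_tol=1e-2, run_diversity=False,
                         run_hapregion=False)
    if name == "inversion-demo":
        sim = SimConfig(seed=seed)     # study-design defaults
        return RunConfig(sim=sim, seed=seed)
    raise ValueError(f"unknown preset {name!r}")


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31, size=n)]


def _round(x: float, nd: int = 6) -> float | None:
    x = float(x)
    if not np.isfinite(x):
        return None
    return float(np.round(x, nd))


def run_panmixia_study(cfg: RunConfig) -> dict:
    """Execute the full analysis flow and return the report dict."""
    t0 = time.time()
    seeds = _child_seeds(cfg.seed, 4)
    report: dict = {"config": {"seed": cfg.seed,
                               "sim": asdict(cfg.sim),
                               "thresholds": {
                                   "min_maf05": cfg.min_maf05,
                                   "min_maf10": cfg.min_maf10,
                                   "snp_pval": cfg.snp_pval,
                                   "roll_window_snps": cfg.roll_window_snps,
                                   "diversity_window_bp": cfg.diversity_window_bp,
                               }}}

    # --- simulation -------------------------------------------------------
    sim_cfg = SimConfig(**{**asdict(cfg.sim), "seed": seeds[0]})
    try:
        freqs, truth, pileup = simulate_all(sim_cfg)
    except Exception as exc:       # pragma: no cover - defensive
        raise RuntimeError(f"stage simdata failed: {exc}") from exc
    ingroup_idx = np.flatnonzero(truth.species_labels == "ingroup")
    outgroup_idx = np.flatnonzero(truth.species_labels == "outgroup")
    report["simdata"] = {
        "n_individuals": len(truth.individuals),
        "n_ingroup": int(len(ingroup_idx)),
        "n_outgroup": int(len(outgroup_idx)),
        "n_sites": int(len(truth.sites)),
        "mean_depth": _round(pileup.depth.mean(), 4),
    }

    # --- genotype likelihoods and SNP calling -----------------------------
    gls = gk.compute_gls(pileup)
    site_table = gk.call_snps(gls, snp_pval=cfg.snp_pval,
                              maf05=cfg.min_maf05, maf10=cfg.min_maf10)
    maf05 = site_table["pass_maf05"].to_numpy() & site_table["pass_snp"].to_numpy()
    maf10 = site_table["pass_maf10"].to_numpy() & site_table["pass_snp"].to_numpy()
    report["genolik"] = {
        "n_pass_snp": int(site_table["pass_snp"].sum()),
        "n_pass_maf05": int(maf05.sum()),
        "n_pass_maf10": int(maf10.sum()),
    }

    # --- population structure --------------------------------------------
    gls_in = gls.subset_individuals(ingroup_idx)
    site_in = gk.call_snps(gls_in, snp_pval=cfg.snp_pval,
                           maf05=cfg.min_maf05, maf10=cfg.min_maf10)
    maf10_in = site_in["pass_maf10"].to_numpy() & site_in["pass_snp"].to_numpy()
    pca_in = ps.pca_from_gls(gls_in, maf10_in)
    loc_in = truth.locality_labels[ingroup_idx]
    anova_p = []
    for pc in range(min(4, pca_in.scores.shape[1])):
        groups = [pca_in.scores[loc_in == l, pc] for l in np.unique(loc_in)]
        anova_p.append(float(stats.f_oneway(*groups).pvalue))
    # admixture within the focal species: the locality-structure surface
    admix = ps.admixture_em(gls_in, maf10_in, K=cfg.admixture_k,
                            seed=seeds[1], n_starts=cfg.admixture_starts,
                            tol=cfg.admixture_tol)
    q_in = admix.Q[:, 0]
    loc_means = np.array([q_in[loc_in == l].mean() for l in np.unique(loc_in)])
    loc_vars = np.array([q_in[loc_in == l].var() for l in np.unique(loc_in)])
    within = float(loc_vars.mean())
    between = float(loc_means.var())
    q_ratio = between / max(within, 1e-12)
    q_anova_p = float(stats.f_oneway(
        *[q_in[loc_in == l] for l in np.unique(loc_in)]).pvalue)
    report["popstructure"] = {
        "pca_rank_used": int(pca_in.rank_used),
        "pca_var_explained_pc1": _round(pca_in.var_explained[0]),
        "pca_locality_anova_p": [float(f"{p:.6g}") for p in anova_p],
        "admixture_loglik": _round(admix.loglik, 3),
        "admixture_between_within_q_ratio": _round(q_ratio, 4),
        "admixture_locality_anova_p": float(f"{q_anova_p:.6g}"),
    }

    # --- contrasts and selection scan -------------------------------------
    locs = np.unique(loc_in)
    half = len(locs) // 2
    a_idx = np.flatnonzero(np.isin(loc_in, locs[:half]))
    b_idx = np.flatnonzero(np.isin(loc_in, locs[half:]))
    maf05_in = site_in["pass_maf05"].to_numpy() & site_in["pass_snp"].to_numpy()
    contrast = sc.delta_af_contrast(gls_in, a_idx, b_idx, maf05_in,
                                    window=cfg.roll_window_snps,
                                    group_a="localities_1st_half",
                                    group_b="localities_2nd_half")
    f_used = contrast.sites[["f_groupA", "f_groupB"]].mean(axis=1).to_numpy()
    noise = sc.binomial_delta_sd(f_used, len(a_idx), len(b_idx))
    noise_roll = sc.rolling_mean_by_chrom(
        noise, contrast.sites["chrom"].to_numpy(), cfg.roll_window_snps)
    with np.errstate(invalid="ignore"):
        ratio = contrast.rolling_abs / noise_roll
    max_ratio = float(np.nanmax(ratio)) if np.isfinite(ratio).any() else float("nan")
    # permutation calibration: the same contrast with locality labels
    # shuffled gives the pure-noise level of mean squared dAF
    both = np.concatenate([a_idx, b_idx])
    shuffled = np.random.default_rng(seeds[3]).permutation(both)
    perm_a, perm_b = shuffled[: len(a_idx)], shuffled[len(a_idx):]
    contrast_perm = sc.delta_af_contrast(gls_in, perm_a, perm_b, maf05_in,
                                         window=cfg.roll_window_snps)
    msq_obs = float(np.nanmean(contrast.sites["delta_af"] ** 2))
    msq_perm = float(np.nanmean(contrast_perm.sites["delta_af"] ** 2))
    msq_ratio = msq_obs / max(msq_perm, 1e-12)
    scan = sc.pc_selection_scan(pca_in, gls_in, maf10_in)
    report["scans"] = {
        "contrast": {
            "groups": [contrast.group_a, contrast.group_b],
            "n_snps": int(len(contrast.sites)),
            "mean_abs_delta": _round(np.nanmean(np.abs(
                contrast.sites["delta_af"]))),
            "max_rolling_over_binomial_noise": _round(max_ratio, 4),
            "mean_sq_delta_over_permutation": _round(msq_ratio, 4),
        },
        "pc_selection": {
            "n_snps": int(len(scan.sites)),
            "mean_stat": _round(float(np.mean(scan.stat)), 4),
            "n_outliers_p_lt_1e6": int((scan.pvalue < 1e-6).sum()),
        },
    }

    # --- inversion-haplotype region ---------------------------------------
    if cfg.run_hapregion:
        chrom = cfg.sim.chrom_name
        span = cfg.sim.inversion_span
        # haplotype genotyping runs on the conspecific (ingroup) samples
        snp_idx_scan = hr.select_region_snps(
            scan, chrom, span, top_fraction=cfg.region_top_fraction)
        # map scan-track indices back into the full site table
        scan_pos = scan.sites["pos0"].to_numpy()[snp_idx_scan]
        full_idx = np.flatnonzero(
            np.isin(gls_in.sites["pos0"].to_numpy(), scan_pos))
        kin = ps.kinship_from_gls(gls_in, _index_mask(gls_in.n_sites, full_idx))
        callset = hr.cluster_three_groups(kin, gls_in, full_idx, chrom, span,
                                          seed=seeds[2])
        chi2, df, p_hom = hr.frequency_homogeneity_test(callset, loc_in)
        d_hom1 = hr.group_tajimas_d(gls_in, truth.ancestral_allele, callset,
                                    "hom1", window_bp=cfg.diversity_window_bp)
        d_hom2 = hr.group_tajimas_d(gls_in, truth.ancestral_allele, callset,
                                    "hom2", window_bp=cfg.diversity_window_bp)
        freq = callset.hap2_frequency(loc_in)
        report["hapregion"] = {
            "region": f"{chrom}:{span[0] + 1}-{span[1]}",
            "n_region_snps": int(len(full_idx)),
            "group_counts": {g: int((callset.group == g).sum())
                             for g in ("hom1", "het", "hom2", "unassigned")},
            "hap2_freq_overall": _round(float(
                callset.hap2_frequency()["overall"]), 4),
            "hap2_freq_by_locality": {str(k): _round(v, 4)
                                      for k, v in freq.items()},
            "homogeneity_chi2": _round(chi2, 4),
            "homogeneity_df": df,
            "homogeneity_p": _round(p_hom, 4),
            "tajimas_d_hom1_mean": _round(np.nanmean(
                d_hom1.table["tajima_d"]), 4),
            "tajimas_d_hom2_mean": _round(np.nanmean(
                d_hom2.table["tajima_d"]), 4),
        }

    # --- diversity ---------------------------------------------------------
    if cfg.run_diversity and len(outgroup_idx) >= 4:
        anc = dv.outgroup_consensus(pileup.subset(outgroup_idx))
        lo, hi = cfg.sim.inversion_span
        div_rows = {}
        first_loc = truth.locality_labels[ingroup_idx[0]]
        for name, idx in (("outgroup", outgroup_idx),
                          (str(first_loc),
                           np.flatnonzero(truth.locality_labels == first_loc))):
            keep = dv.site_filters(pileup.subset(idx))
            sub = gls.subset_individuals(idx).subset_sites(keep)
            saf = dv.saf_per_site(sub, anc[keep])
            sfs = dv.sfs_em(saf.logl)
            wins = dv.window_thetas(saf, sfs,
                                    window_bp=cfg.diversity_window_bp,
                                    chrom_length=cfg.sim.chrom_length)
            tab = wins.table
            in_region = (tab["start"] >= lo) & (tab["end"] <= hi)
            pi = tab["theta_pi"].to_numpy()
            div_rows[name] = {
                "genome_median_pi": _round(np.nanmedian(pi)),
                "region_median_pi": _round(np.nanmedian(pi[in_region.to_numpy()]))
                if in_region.any() else None,
                "mean_tajima_d": _round(np.nanmean(tab["tajima_d"]), 4),
            }
        report["diversity"] = div_rows

    # --- load model --------------------------------------------------------
    table = lm.load_table(0.5, 0.05, [10, 100])
    report["loadmodel"] = {
        "p0": 0.5,
        "delta_p": 0.05,
        "s": _round(table["s"].iloc[0], 6),
        "per_locus_survival": _round(table["per_locus_survival"].iloc[0], 6),
        "mortality_percent_10_loci": int(table["mortality_percent"].iloc[0]),
        "one_in_ten_to_the_100_loci": int(
            lm.joint_survival(0.5, 0.05, 100).one_in_log10),
    }

    # --- verdict surfaces --------------------------------------------------
    report["panmixia_surfaces"] = {
        "pca_no_locality_differentiation": bool(min(anova_p) > 1e-3),
        "admixture_no_locality_differentiation": bool(q_ratio < 2.0
                                                      and q_anova_p > 1e-3),
        # no window beyond 3x the binomial-noise level, and the mean
        # squared dAF indistinguishable from a label permutation
        "delta_af_no_signal": bool(np.isfinite(max_ratio) and max_ratio < 3.0
                                   and msq_ratio < 1.25),
    }
    _ = time.time() - t0    # wall time deliberately kept out of the report

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
    return report


def _index_mask(n: int, idx: np.ndarray) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
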