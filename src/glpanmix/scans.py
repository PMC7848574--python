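"""Genome scans: group allele-frequency contrasts and a PC1 selection test.

The contrast track is the signed difference of GL-estimated allele
frequencies between two sample groups at every retained SNP, summarized
by a 100-SNP rolling mean of |dAF| per chromosome. The selection scan is
the FastPCA-style statistic: the squared projection of each SNP's
standardized dosages onto the leading principal component, scaled by the
component's eigenvalue so that neutral SNPs follow chi^2(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genolik import GLMatrix, estimate_maf
from .popstructure import PCAResult, posterior_expected_dosage

ROLL_WINDOW = 100


@dataclass
class ContrastTrack:
    sites: pd.DataFrame        # chrom, pos0, f_groupA, f_groupB, delta_af
    rolling_abs: np.ndarray    # rolling mean of |dAF|, NaN where window incomplete
    window: int
    group_a: str
    group_b: str

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        out["rolling_abs_delta"] = self.rolling_abs
        return out


def rolling_mean_by_chrom(values: np.ndarray, chroms: np.ndarray,
                          window: int = ROLL_WINDOW) -> np.ndarray:
    """Rolling mean over consecutive SNPs, restarted at chromosome breaks.

    Defined only where a full window fits (NaN elsewhere).
    """
    s = pd.Series(values)
    return (
        s.groupby(pd.Series(chroms), sort=False)
        .rolling(window, min_periods=window)
        .mean()
        .reset_index(level=0, drop=True)
        .sort_index()
        .to_numpy()
    )


def delta_af_contrast(
    gls: GLMatrix,
    group_a_idx: np.ndarray,
    group_b_idx: np.ndarray,
    site_mask: np.ndarray | None = None,
    *,
    window: int = ROLL_WINDOW,
    group_a: str = "A",
    group_b: str = "B",
) -> ContrastTrack:
    """Signed dAF per SNP plus per-chromosome rolling mean of |dAF|.

    Both group frequencies are EM estimates on the same oriented GL
    matrix, so allele orientation is harmonized by construction.
    """
    work = gls if site_mask is None else gls.subset_sites(np.asarray(site_mask))
    f_a, _ = estimate_maf(work, np.asarray(group_a_idx))
    f_b, _ = estimate_maf(work, np.asarray(group_b_idx))
    delta = f_a - f_b
    sites = work.sites[["chrom", "pos0"]].copy()
    sites["f_groupA"] = f_a
    sites["f_groupB"] = f_b
    sites["delta_af"] = delta
    roll = rolling_mean_by_chrom(np.abs(delta), sites["chrom"].to_numpy(),
                                 window)
    return ContrastTrack(sites, roll, window, group_a, group_b)


def binomial_delta_sd(f: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Binomial sampling sd of dAF between groups of n_a, n_b diploids."""
    f = np.asarray(f, dtype=np.float64)
    return np.sqrt(f * (1.0 - f) * (1.0 / (2 * n_a) + 1.0 / (2 * n_b)))


@dataclass
class SelectionTrack:
    sites: pd.DataFrame     # chrom, pos0, stat, pvalue
    eigenvalue: float

    @property
    def stat(self) -> np.ndarray:
        return self.sites["stat"].to_numpy()

    @property
    def pvalue(self) -> np.ndarray:
        return self.sites["pvalue"].to_numpy()


def pc_selection_scan(
    pca: PCAResult,
    gls: GLMatrix,
    site_mask: np.ndarray | None = None,
    *,
    pc: int = 1,
) -> SelectionTrack:
    """Per-SNP selection statistic along a principal component.

    Standardized posterior expected dosages x_j are projected on the
    unit-norm PC score vector u; D_j = (u^T x_j)^2 / lambda, with lambda
    the component's variance on the scanned SNP set (Rayleigh quotient),
    which calibrates neutral SNPs to chi^2(1). Upper-tail p-values.
    """
    work = gls if site_mask is None else gls.subset_sites(np.asarray(site_mask))
    u = pca.scores[:, pc - 1]
    if np.allclose(u.var(), 0.0):
        raise ValueError(f"PC{pc} is degenerate (zero variance)")
    if len(u) != work.n_individuals:
        raise ValueError("PCA and GL matrix cover different individuals")
    lin = work.linear()
    f, _ = estimate_maf(work)
    ok = np.isfinite(f) & (f > 0) & (f < 1)
    lin, f = lin[:, ok], f[ok]
    dose = posterior_expected_dosage(lin, f)
    x = (dose - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    x = x - x.mean(axis=0)                       # guard vs estimation offset
    proj = u @ x                                 # (m,)
    lam = float(proj @ proj) / x.shape[1]        # Rayleigh quotient of u
    if lam <= 0:
        raise ValueError("degenerate scan: zero variance along the PC")
    d = proj ** 2 / lam
    pval = stats.chi2.sf(d, df=1)
    sites = work.sites.loc[ok, ["chrom", "pos0"]].reset_index(drop=True)
    sites["stat"] = d
    sites["pvalue"] = pval
    return SelectionTrack(sites, lam)


def windowed_track_bed(track: pd.DataFrame, value_col: str,
                       window: int = ROLL_WINDOW) -> pd.DataFrame:
    """BED-style (0-based half-open) frame of full rolling windows."""
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos0"].to_numpy()
        val = grp[value_col].to_numpy()
        for end_i in range(window - 1, len(grp)):
            v = val[end_i]
            if np.isnan(v):
                continue
            rows.append((chrom, pos[end_i - window + 1], pos[end_i] + 1, v))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", value_col])
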