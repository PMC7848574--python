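"""Site-frequency-spectrum diversity estimation from genotype likelihoods.

Follows the standard low-coverage flow: polarize alleles against an
outgroup read consensus, convolve per-individual genotype likelihoods
into per-site sample-allele-frequency (SAF) likelihoods over derived
counts 0..2n, estimate the unfolded SFS by EM across sites, then use the
SFS as an empirical-Bayes prior to compute per-site expectations of
pairwise diversity (theta_pi) and segregating sites (theta_W / Watterson),
aggregated in 5-kb windows together with Tajima's D.

No MAF cutoff is applied at this stage: frequency filtering biases
SFS-based diversity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .genolik import GLMatrix
from .simdata import PileupMatrix

WINDOW_BP = 5_000


# ---------------------------------------------------------------------------
# Polarization

def outgroup_consensus(pileup: PileupMatrix) -> np.ndarray:
    """Per-site ancestral allele as the pooled outgroup majority base.

    Ties and zero-coverage sites give 'N'. Only the two modelled alleles
    compete; error reads ("other") carry no base identity.
    """
    ref_n = pileup.n_major.sum(axis=0)
    alt_n = pileup.n_minor.sum(axis=0)
    ref_b = pileup.sites["ref"].to_numpy()
    alt_b = pileup.sites["alt"].to_numpy()
    anc = np.where(ref_n > alt_n, ref_b, alt_b)
    anc = np.where(ref_n == alt_n, "N", anc)
    return anc


def write_consensus_fasta(anc: np.ndarray, sites: pd.DataFrame,
                          chrom_length: int, path: str | Path) -> None:
    """Emit the consensus as FASTA over simulated coordinates (N elsewhere)."""
    for chrom, grp in sites.groupby("chrom", sort=False):
        seq = np.full(chrom_length, "N", dtype="<U1")
        seq[grp["pos0"].to_numpy()] = anc[grp.index.to_numpy()]
        rec = SeqRecord(Seq("".join(seq)), id=str(chrom), description="")
        with open(path, "a") as fh:
            seqio_write([rec], fh, "fasta")


# ---------------------------------------------------------------------------
# Site filters

def site_filters(pileup: PileupMatrix, *, min_depth: int = 15,
                 max_depth: int = 1000) -> np.ndarray:
    """Retain sites whose total population depth is within [min, max].

    Bounds are inclusive, mirroring depth-outlier removal in the original
    pipeline. Individuals contribute at a site only when they have >= 1
    read (handled downstream by the flat-likelihood convention).
    """
    total = pileup.depth.sum(axis=0)
    return (total >= min_depth) & (total <= max_depth)


# ---------------------------------------------------------------------------
# SAF: sample allele frequency likelihoods

@dataclass
class SAFMatrix:
    """Per-site log-likelihoods over derived allele count d in 0..2n."""

    sites: pd.DataFrame
    logl: np.ndarray        # (m, 2n+1), max 0 per site
    n_diploids: int

    @property
    def n_chrom(self) -> int:
        return 2 * self.n_diploids


def saf_per_site(gls: GLMatrix, ancestral: np.ndarray) -> SAFMatrix:
    """Convolve individual GLs into sample-level derived-count likelihoods.

    Genotype likelihoods are re-oriented to derived-allele dosage using
    the ancestral call (sites where the ancestral base is neither allele,
    or 'N', are skipped), then combined across individuals by dynamic
    programming under independence:

        P(X | d) = sum over genotype configs g with sum(g) = d of
                   prod_i L_i(g_i) C(2, g_i) / C(2n, d),

    the hypergeometric weighting of configurations given d derived
    copies among the 2n chromosomes. An uncovered individual (flat GL)
    therefore contributes no information rather than pulling mass toward
    intermediate frequencies.
    """
    sites = gls.sites
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    anc = np.asarray(ancestral)
    use_ref = anc == ref       # derived = alt, dosage axis unchanged
    use_alt = anc == alt       # derived = ref, flip dosage axis
    keep = use_ref | use_alt
    lin = np.exp(gls.logl[:, keep, :])
    flip = use_alt[keep]
    lin[:, flip, :] = lin[:, flip, ::-1]

    n, m = lin.shape[:2]
    v = np.zeros((m, 2 * n + 1))
    v[:, 0] = 1.0
    width = 0
    for i in range(n):
        new = np.zeros_like(v)
        li = lin[i]
        new[:, : width + 1] += li[:, [0]] * v[:, : width + 1]
        new[:, 1: width + 2] += 2.0 * li[:, [1]] * v[:, : width + 1]
        new[:, 2: width + 3] += li[:, [2]] * v[:, : width + 1]
        width += 2
        peak = new.max(axis=1)
        peak = np.where(peak > 0, peak, 1.0)
        v = new / peak[:, None]
    with np.errstate(divide="ignore"):
        logl = np.log(v)
    # hypergeometric normalization over chromosome arrangements
    d = np.arange(2 * n + 1)
    log_choose = (gammaln(2 * n + 1) - gammaln(d + 1) - gammaln(2 * n - d + 1))
    logl -= log_choose[None, :]
    logl -= logl.max(axis=1, keepdims=True)
    return SAFMatrix(sites.loc[keep].reset_index(drop=True), logl, n)


def fold_saf(saf: SAFMatrix) -> SAFMatrix:
    """Fold derived-count likelihoods onto minor-count bins 0..n."""
    lin = np.exp(saf.logl)
    k = saf.n_chrom
    half = k // 2
    folded = lin[:, : half + 1].copy()
    # bin d merges with k-d; c[:, :half:-1] walks k, k-1, ..., half+1
    folded[:, :half] += lin[:, :half:-1]
    with np.errstate(divide="ignore"):
        logl = np.log(folded)
    logl -= logl.max(axis=1, keepdims=True)
    return SAFMatrix(saf.sites, logl, saf.n_diploids)


# ---------------------------------------------------------------------------
# SFS estimation

@dataclass
class SFS:
    counts: np.ndarray      # expected site counts per frequency bin
    loglik: float

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def sfs_em(saf_logl: np.ndarray, *, tol: float = 1e-6,
           max_iter: int = 500) -> SFS:
    """EM estimate of the site frequency spectrum from SAF likelihoods.

    Maximizes sum_sites log sum_d SFS_d SAF(site, d) over the simplex;
    converges on relative log-likelihood change < tol.
    """
    saf_lin = np.exp(np.asarray(saf_logl))
    m, nb = saf_lin.shape
    if m < 1:
        raise ValueError("need at least one site")
    p = np.full(nb, 1.0 / nb)
    prev = -np.inf
    ll = prev
    for _ in range(max_iter):
        w = saf_lin * p[None, :]
        denom = w.sum(axis=1)
        ll = float(np.log(denom).sum())
        if ll - prev < -1e-6:
            raise AssertionError("SFS EM log-likelihood decreased")
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            break
        prev = ll
        p = (w / denom[:, None]).mean(axis=0)
    return SFS(p * m, ll)


def fold_sfs(sfs: SFS) -> np.ndarray:
    """Fold an unfolded spectrum onto minor-allele-count bins."""
    c = sfs.counts
    k = len(c) - 1
    half = k // 2
    folded = c[: half + 1].copy()
    folded[:half] += c[:half:-1]
    return folded


# ---------------------------------------------------------------------------
# Thetas and Tajima's D

def tajima_constants(n_chrom: int) -> dict[str, float]:
    """Standard variance constants for Tajima's D at n sequences."""
    n = n_chrom
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1 ** 2 + a2)}


def tajimas_d(pi_total: float, s_total: float, n_chrom: int) -> float:
    """Tajima's D from window totals of pairwise diversity and S.

    Returns NaN when S is (effectively) zero, where D is undefined.
    """
    if s_total <= 1e-9:
        return float("nan")
    c = tajima_constants(n_chrom)
    var = c["e1"] * s_total + c["e2"] * s_total * (s_total - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_total - s_total / c["a1"]) / np.sqrt(var)


@dataclass
class WindowDiversity:
    table: pd.DataFrame     # chrom, start, end, n_sites, theta_pi, theta_w, tajima_d
    n_chrom: int


def per_site_expectations(saf: SAFMatrix, sfs: SFS) -> pd.DataFrame:
    """Posterior per-site expected pairwise diversity and segregation.

    Empirical Bayes: the genome-wide SFS is the prior over derived count
    d; pi_site = E[d (2n-d)] / C(2n, 2), seg_site = P(0 < d < 2n).
    """
    k = saf.n_chrom
    prior = sfs.proportions
    w = np.exp(saf.logl) * prior[None, :]
    post = w / w.sum(axis=1, keepdims=True)
    d = np.arange(k + 1)
    pair_w = d * (k - d) / (k * (k - 1) / 2.0)
    pi = post @ pair_w
    seg = post[:, 1:k].sum(axis=1)
    out = saf.sites[["chrom", "pos0"]].copy()
    out["pi"] = pi
    out["seg"] = seg
    return out


def window_thetas(saf: SAFMatrix, sfs: SFS, *, window_bp: int = WINDOW_BP,
                  chrom_length: int | None = None) -> WindowDiversity:
    """Diversity statistics in non-overlapping windows.

    theta_pi and theta_W are per-site (window sums divided by the number
    of usable sites); Tajima's D uses the window totals with the standard
    constants at 2n chromosomes. Windows without usable sites are NaN.
    """
    per_site = per_site_expectations(saf, sfs)
    k = saf.n_chrom
    a1 = tajima_constants(k)["a1"]
    rows = []
    for chrom, grp in per_site.groupby("chrom", sort=False):
        pos = grp["pos0"].to_numpy()
        last = chrom_length if chrom_length is not None else int(pos.max()) + 1
        for start in range(0, last, window_bp):
            end = min(start + window_bp, last)
            sel = (pos >= start) & (pos < end)
            ns = int(sel.sum())
            if ns == 0:
                rows.append((chrom, start, end, 0, np.nan, np.nan, np.nan))
                continue
            pi_sum = float(grp["pi"].to_numpy()[sel].sum())
            s_sum = float(grp["seg"].to_numpy()[sel].sum())
            rows.append((
                chrom, start, end, ns,
                pi_sum / ns, s_sum / a1 / ns,
                tajimas_d(pi_sum, s_sum, k),
            ))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                        "theta_pi", "theta_w", "tajima_d"])
    return WindowDiversity(table, k)


def diversity_pipeline(gls: GLMatrix, ancestral: np.ndarray,
                       pileup: PileupMatrix | None = None,
                       *, window_bp: int = WINDOW_BP,
                       chrom_length: int | None = None) -> WindowDiversity:
    """Convenience flow: filters -> SAF -> SFS -> windowed thetas."""
    work = gls
    if pileup is not None:
        keep = site_filters(pileup)
        work = gls.subset_sites(keep)
        ancestral = np.asarray(ancestral)[keep]
    saf = saf_per_site(work, ancestral)
    sfs = sfs_em(saf.logl)
    return window_thetas(saf, sfs, window_bp=window_bp,
                         chrom_length=chrom_length)
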