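"""Genotype likelihoods, allele-frequency EM and SNP calling.

At ~1.4x coverage individual genotypes cannot be called, so every
downstream estimate works from per-site genotype likelihoods
L(reads | g) over minor-allele dosage g in {0, 1, 2}. Population allele
frequencies are maximum-likelihood estimates obtained by EM under
Hardy–Weinberg, SNPs are called with a likelihood-ratio test against a
monomorphic model, and sites are filtered at a 5% or 10% minor-allele
frequency for the structure and scan stages.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import PileupMatrix

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

EM_TOL = 1e-8
EM_MAX_ITER = 200
EM_START = 0.1


@dataclass
class GLMatrix:
    """Normalized log genotype likelihoods, (n_individuals, m_sites, 3).

    The dosage axis counts copies of the site's minor (alternate) allele.
    Per individual and site the maximum log-likelihood is 0; depth-0
    entries are all equal (no information).
    """

    sites: pd.DataFrame
    individuals: list[str]
    logl: np.ndarray          # (n, m, 3), <= 0
    depth: np.ndarray         # (n, m) read depth

    @property
    def n_individuals(self) -> int:
        return self.logl.shape[0]

    @property
    def n_sites(self) -> int:
        return self.logl.shape[1]

    def linear(self) -> np.ndarray:
        return np.exp(self.logl)

    def subset_individuals(self, idx: np.ndarray) -> "GLMatrix":
        idx = np.atleast_1d(idx)
        return GLMatrix(self.sites, [self.individuals[i] for i in idx],
                        self.logl[idx], self.depth[idx])

    def subset_sites(self, mask: np.ndarray) -> "GLMatrix":
        return GLMatrix(self.sites.loc[mask].reset_index(drop=True),
                        self.individuals, self.logl[:, mask],
                        self.depth[:, mask])


def compute_gls(pileup: PileupMatrix, err: float | None = None) -> GLMatrix:
    """Genotype likelihoods from ref/alt/other read counts.

    Per read, P(base | g) = (1-g/2) P(base | major) + (g/2) P(base | minor)
    with P(true base) = 1-err and each of the three error bases err/3.
    Reads are independent, so the site likelihood is the product over
    reads; returned normalized so max_g log L(g) = 0.
    """
    e = pileup.base_error if err is None else err
    if not 0.0 < e < 0.75:
        raise ValueError(f"error rate must be in (0, 0.75), got {e}")
    for arr in (pileup.n_major, pileup.n_minor, pileup.n_other):
        if (arr < 0).any():
            raise ValueError("negative read counts")
    g = np.array([0.0, 1.0, 2.0])
    p_major = (1.0 - g / 2.0) * (1.0 - e) + (g / 2.0) * (e / 3.0)
    p_minor = (g / 2.0) * (1.0 - e) + (1.0 - g / 2.0) * (e / 3.0)
    p_other = np.full(3, 2.0 * e / 3.0)   # constant in g, cancels on normalize
    logl = (
        pileup.n_major[..., None] * np.log(p_major)
        + pileup.n_minor[..., None] * np.log(p_minor)
        + pileup.n_other[..., None] * np.log(p_other)
    )
    logl -= logl.max(axis=2, keepdims=True)
    return GLMatrix(pileup.sites, list(pileup.individuals), logl,
                    pileup.depth.astype(np.int32))


def hwe_genotype_priors(f: np.ndarray) -> np.ndarray:
    """Stack of HWE genotype probabilities [(1-f)^2, 2f(1-f), f^2]."""
    f = np.asarray(f, dtype=np.float64)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)


def _site_loglik(lin: np.ndarray, covered: np.ndarray,
                 f: np.ndarray) -> np.ndarray:
    """Observed-data log-likelihood per site at frequency f.

    ``lin`` is (n, m, 3) linear likelihoods, ``covered`` an (n, m) mask of
    individuals with reads; uncovered individuals carry no information
    and are excluded so that adding them never changes the estimate.
    """
    pri = hwe_genotype_priors(f)                      # (m, 3)
    per_ind = (lin * pri[None, :, :]).sum(axis=2)     # (n, m)
    with np.errstate(divide="ignore"):
        ll = np.where(covered, np.log(per_ind), 0.0)
    return ll.sum(axis=0)


def estimate_maf(
    gls: GLMatrix,
    individuals: np.ndarray | None = None,
    *,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    f_start: float = EM_START,
    check_monotone: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """EM maximum-likelihood minor-allele frequency per site.

    Iterates posterior expected dosages under HWE(f) and sets f to half
    the mean expected dosage over covered individuals, until |df| < tol
    or ``max_iter``. Returns (f_hat, loglik_at_optimum); sites with no
    covered individual get NaN.
    """
    sub = gls if individuals is None else gls.subset_individuals(individuals)
    lin = sub.linear()
    covered = sub.depth > 0
    n_cov = covered.sum(axis=0)
    m = sub.n_sites
    f = np.full(m, f_start)
    has_data = n_cov > 0
    f[~has_data] = np.nan
    # active-set refinement: converged sites drop out of the update
    act = np.flatnonzero(has_data)
    lin_a, cov_a = lin[:, act], covered[:, act]
    f_a = f[act].copy()
    ll_a = _site_loglik(lin_a, cov_a, f_a)
    last_ll = np.zeros(m)
    last_ll[act] = ll_a
    for _ in range(max_iter):
        pri = hwe_genotype_priors(f_a)
        w = lin_a * pri[None, :, :]
        denom = w.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_dosage = (w[:, :, 1] + 2.0 * w[:, :, 2]) / denom
        e_dosage = np.where(cov_a, e_dosage, 0.0)
        f_new = e_dosage.sum(axis=0) / (2.0 * cov_a.sum(axis=0))
        if check_monotone:
            ll = _site_loglik(lin_a, cov_a, f_new)
            if (ll - last_ll[act] < -1e-8).any():
                raise AssertionError("EM log-likelihood decreased")
            last_ll[act] = ll
        delta = np.abs(f_new - f_a)
        f[act] = f_new
        still = delta >= tol
        if not still.any():
            break
        act = act[still]
        lin_a, cov_a = lin_a[:, still], cov_a[:, still]
        f_a = f_new[still]
    if not check_monotone:
        last_ll = _site_loglik(lin, covered, np.where(has_data, f, EM_START))
        last_ll[~has_data] = 0.0
    return f, last_ll


def call_snps(
    gls: GLMatrix,
    *,
    snp_pval: float = 1e-6,
    maf05: float = 0.05,
    maf10: float = 0.10,
    individuals: np.ndarray | None = None,
) -> pd.DataFrame:
    """SNP calling and MAF filtering into a site table.

    LRT = 2 [log L(f_hat) - log L(f=0)] against chi^2(1); pass_snp at
    p < snp_pval, pass_maf05 / pass_maf10 with inclusive thresholds on
    the folded minor-allele frequency.
    """
    f_hat, ll_hat = estimate_maf(gls, individuals)
    sub = gls if individuals is None else gls.subset_individuals(individuals)
    lin = sub.linear()
    covered = sub.depth > 0
    ll0 = _site_loglik(lin, covered, np.zeros(sub.n_sites))
    lrt = np.maximum(2.0 * (ll_hat - ll0), 0.0)
    pval = stats.chi2.sf(lrt, df=1)
    maf = np.minimum(f_hat, 1.0 - f_hat)
    out = gls.sites.copy()
    out["alt_freq"] = f_hat
    out["maf"] = maf
    out["snp_lrt"] = lrt
    out["snp_pvalue"] = pval
    out["pass_snp"] = (pval < snp_pval) & ~np.isnan(f_hat)
    out["pass_maf05"] = (maf >= maf05) & ~np.isnan(maf)
    out["pass_maf10"] = (maf >= maf10) & ~np.isnan(maf)
    return out


def major_minor_from_reference(base_counts: pd.DataFrame,
                               reference: np.ndarray) -> pd.DataFrame:
    """Orient sites with the reference as major allele.

    ``base_counts`` has columns A, C, G, T of pooled (expected) read
    counts per site. The minor allele is the most frequent non-reference
    base, ties broken lexicographically; sites where the reference base
    was never observed are flagged.
    """
    counts = base_counts[["A", "C", "G", "T"]].to_numpy(dtype=np.float64)
    ref_idx = np.array([_BASE_CODE[b] for b in reference])
    m = len(ref_idx)
    masked = counts.copy()
    masked[np.arange(m), ref_idx] = -np.inf
    # argmax takes the first (lexicographically smallest) on ties
    minor_idx = masked.argmax(axis=1)
    flagged = counts[np.arange(m), ref_idx] == 0
    bases = np.array(["A", "C", "G", "T"])
    return pd.DataFrame(
        {
            "major": bases[ref_idx],
            "minor": bases[minor_idx],
            "ref_missing": flagged,
        }
    )


def pooled_base_counts(pileup: PileupMatrix) -> pd.DataFrame:
    """Expected pooled per-base counts from a ref/alt/other pileup.

    The two unmodelled error bases share the pooled ``n_other`` count
    equally (expected counts under the uniform error model).
    """
    sites = pileup.sites
    m = len(sites)
    counts = np.zeros((m, 4))
    ref_idx = np.array([_BASE_CODE[b] for b in sites["ref"]])
    alt_idx = np.array([_BASE_CODE[b] for b in sites["alt"]])
    counts[np.arange(m), ref_idx] = pileup.n_major.sum(axis=0)
    counts[np.arange(m), alt_idx] = pileup.n_minor.sum(axis=0)
    other = pileup.n_other.sum(axis=0) / 2.0
    for j in range(m):
        for b in range(4):
            if b != ref_idx[j] and b != alt_idx[j]:
                counts[j, b] = other[j]
    return pd.DataFrame(counts, columns=["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Beagle genotype-likelihood text format


def write_beagle(gls: GLMatrix, path: str | Path) -> None:
    """Write normalized linear-scale likelihoods in Beagle GL format.

    Columns: marker (chrom_pos, 1-based), allele1, allele2 (numeric base
    codes A=0 C=1 G=2 T=3), then three likelihood columns per individual.
    """
    sites = gls.sites
    marker = sites["chrom"].astype(str) + "_" + (sites["pos0"] + 1).astype(str)
    lin = gls.linear()
    lin = lin / lin.sum(axis=2, keepdims=True)
    n, m, _ = lin.shape
    cols: dict[str, object] = {
        "marker": marker,
        "allele1": [_BASE_CODE[b] for b in sites["ref"]],
        "allele2": [_BASE_CODE[b] for b in sites["alt"]],
    }
    for i, ind in enumerate(gls.individuals):
        for g in range(3):
            cols[f"{ind}.g{g}"] = lin[i, :, g]
    df = pd.DataFrame(cols)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_beagle(path: str | Path) -> GLMatrix:
    """Read a Beagle GL file back into a :class:`GLMatrix`.

    Depth is not stored in the format; individuals with three equal
    likelihoods at a site are treated as uncovered there.
    """
    df = pd.read_csv(path, sep="\t")
    chrom_pos = df["marker"].str.rsplit("_", n=1, expand=True)
    bases = np.array(["A", "C", "G", "T"])
    sites = pd.DataFrame(
        {
            "chrom": chrom_pos[0],
            "pos0": chrom_pos[1].astype(int) - 1,
            "ref": bases[df["allele1"].to_numpy()],
            "alt": bases[df["allele2"].to_numpy()],
        }
    )
    gl_cols = df.columns[3:]
    individuals = sorted({c.rsplit(".g", 1)[0] for c in gl_cols},
                         key=lambda s: list(gl_cols).index(f"{s}.g0"))
    n, m = len(individuals), len(sites)
    lin = np.empty((n, m, 3))
    for i, ind in enumerate(individuals):
        for g in range(3):
            lin[i, :, g] = df[f"{ind}.g{g}"].to_numpy()
    with np.errstate(divide="ignore"):
        logl = np.log(lin)
    logl -= logl.max(axis=2, keepdims=True)
    flat = np.isclose(logl, 0.0).all(axis=2)
    depth = np.where(flat, 0, 1).astype(np.int32)
    return GLMatrix(sites, individuals, logl, depth)


def callable_fraction(gls: GLMatrix) -> np.ndarray:
    """Per-individual fraction of sites with depth >= 1."""
    return (gls.depth > 0).mean(axis=1)


def exclude_low_coverage(gls: GLMatrix,
                         min_fraction: float = 0.10) -> tuple[GLMatrix, np.ndarray]:
    """Drop individuals whose callable-site fraction is below threshold.

    Mirrors the study's removal of a handful of excessively low-coverage
    individuals before structure analyses. Returns the filtered matrix
    and the indices kept.
    """
    keep = np.flatnonzero(callable_fraction(gls) >= min_fraction)
    return gls.subset_individuals(keep), keep
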