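"""Population structure from genotype likelihoods.

Implements the low-coverage structure toolkit: PCA via iteratively
re-estimated individual allele frequencies (posterior expected dosages
standardized per site, covariance eigendecomposition, rank-e frequency
reconstruction), admixture proportions by EM on the binomial
ancestry-mixture likelihood, and a pairwise kinship matrix from centered
expected dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genolik import GLMatrix, estimate_maf

FREQ_CLAMP = (1e-4, 1 - 1e-4)
ADMIX_CLAMP = (1e-6, 1 - 1e-6)


def posterior_expected_dosage(lin: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """E[g | reads, HWE(freq)] with per-site or per-individual freqs.

    ``lin`` is (n, m, 3) linear likelihoods; ``freq`` broadcasts to (n, m).
    """
    f = np.broadcast_to(np.asarray(freq, dtype=np.float64), lin.shape[:2])
    pri = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)
    w = lin * pri
    return (w[..., 1] + 2.0 * w[..., 2]) / w.sum(axis=2)


@dataclass
class PCAResult:
    covariance: np.ndarray          # (n, n)
    eigenvalues: np.ndarray         # descending
    scores: np.ndarray              # (n, n) unit-norm eigenvector columns
    loadings: np.ndarray            # (k, m) signed per-SNP loadings, PC1..k
    var_explained: np.ndarray
    rank_used: int
    site_mask: np.ndarray           # sites actually used (within input subset)
    individual_freqs: np.ndarray    # final per-individual site freqs (n, m)
    pooled_freq: np.ndarray


def _elbow_rank(eigenvalues: np.ndarray, n_lead: int = 10) -> int:
    """Rank at the largest gap among the leading eigenvalues."""
    lead = eigenvalues[: min(n_lead, len(eigenvalues) - 1)]
    if len(lead) < 2:
        return 1
    gaps = lead[:-1] - lead[1:]
    return int(np.argmax(gaps)) + 1


def pca_from_gls(
    gls: GLMatrix,
    site_mask: np.ndarray | None = None,
    *,
    n_iter: int = 100,
    tol: float = 1e-7,
    rank: int | None = None,
    n_loadings: int = 4,
    pooled_freq: np.ndarray | None = None,
) -> PCAResult:
    """PCA with iterative individual-allele-frequency refinement.

    Iteration 0 uses the pooled frequency as every individual's prior;
    each pass computes posterior expected dosages, standardizes by
    sqrt(2 f (1-f)), forms the individual covariance C = X X^T / M,
    takes the leading ``rank`` eigenvectors (eigen-gap elbow if None) and
    rebuilds per-individual frequencies from the low-rank reconstruction
    (clamped). Stops when C changes by < tol in max norm.
    """
    if gls.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    work = gls if site_mask is None else gls.subset_sites(np.asarray(site_mask))
    if work.n_sites < 2:
        raise ValueError("PCA needs at least two sites")
    lin = work.linear()
    if pooled_freq is None:
        pooled_freq, _ = estimate_maf(work)
    else:
        pooled_freq = np.asarray(pooled_freq, dtype=np.float64)
        if site_mask is not None:
            pooled_freq = pooled_freq[np.asarray(site_mask)]
    usable = np.isfinite(pooled_freq) & (pooled_freq > 0) & (pooled_freq < 1)
    if not usable.all():
        lin = lin[:, usable]
        pooled_freq = pooled_freq[usable]
    f = pooled_freq
    n, m = lin.shape[:2]
    denom = np.sqrt(2.0 * f * (1.0 - f))
    pi = np.broadcast_to(f, (n, m)).copy()
    c_prev = None
    e_used = 1
    for _ in range(max(1, n_iter)):
        dose = posterior_expected_dosage(lin, pi)
        x = (dose - 2.0 * f) / denom
        cov = x @ x.T / m
        if c_prev is not None and np.abs(cov - c_prev).max() < tol:
            c_prev = cov
            break
        c_prev = cov
        vals, vecs = np.linalg.eigh(cov)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        e_used = rank if rank is not None else _elbow_rank(vals)
        u = vecs[:, :e_used]
        x_hat = u @ (u.T @ x)
        pi = np.clip((x_hat * denom + 2.0 * f) / 2.0, *FREQ_CLAMP)
    vals, vecs = np.linalg.eigh(c_prev)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    dose = posterior_expected_dosage(lin, pi)
    x = (dose - 2.0 * f) / denom
    k = min(n_loadings, n)
    loadings = vecs[:, :k].T @ x
    pos = np.clip(vals, 0.0, None)
    var_explained = pos / pos.sum() if pos.sum() > 0 else pos
    full_mask = usable if site_mask is None else _expand_mask(site_mask, usable)
    return PCAResult(
        covariance=c_prev,
        eigenvalues=vals,
        scores=vecs,
        loadings=loadings,
        var_explained=var_explained,
        rank_used=e_used,
        site_mask=full_mask,
        individual_freqs=pi,
        pooled_freq=f,
    )


def _expand_mask(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    outer = np.asarray(outer).copy()
    idx = np.flatnonzero(outer)
    outer[idx[~inner]] = False
    return outer


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray          # (n, K), rows sum to 1
    F: np.ndarray          # (K, m) cluster allele frequencies
    loglik: float
    loglik_trace: np.ndarray


def _admix_loglik(lin: np.ndarray, h: np.ndarray) -> float:
    pri = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=-1)
    return float(np.log((lin * pri).sum(axis=2)).sum())


def admixture_em(
    gls: GLMatrix,
    site_mask: np.ndarray | None = None,
    K: int = 2,
    seed: int = 0,
    *,
    n_starts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 300,
    site_cap: int = 2_000_000,
) -> AdmixtureResult:
    """Admixture proportions by EM on genotype likelihoods.

    Maximizes sum_ij log sum_g GL_ijg P(g | h_ij) with
    h_ij = sum_k Q_ik F_kj and P binomial(2, h). Multi-start EM keeps the
    best likelihood; sites beyond ``site_cap`` are uniformly downsampled.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gls.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    work = gls if site_mask is None else gls.subset_sites(np.asarray(site_mask))
    rng = np.random.default_rng(seed)
    if work.n_sites > site_cap:
        keep = np.sort(rng.choice(work.n_sites, size=site_cap, replace=False))
        mask = np.zeros(work.n_sites, dtype=bool)
        mask[keep] = True
        work = work.subset_sites(mask)
    lin = work.linear()
    n, m = lin.shape[:2]
    pooled, _ = estimate_maf(work)
    pooled = np.clip(np.nan_to_num(pooled, nan=0.5), *ADMIX_CLAMP)

    def loglik(q: np.ndarray, f: np.ndarray) -> float:
        h = np.clip(q @ f, *ADMIX_CLAMP)
        pri = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=-1)
        return float(np.log((lin * pri).sum(axis=2)).sum())

    def em_step(q: np.ndarray, f: np.ndarray):
        h = np.clip(q @ f, *ADMIX_CLAMP)
        pri = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=-1)
        w = lin * pri
        denom = w.sum(axis=2)
        e_alt = (w[..., 1] + 2.0 * w[..., 2]) / denom    # expected minor copies
        e_ref = 2.0 - e_alt
        # attribute allele copies to clusters
        a = q[:, :, None] * f[None, :, :] / h[:, None, :]
        b = q[:, :, None] * (1.0 - f[None, :, :]) / (1.0 - h)[:, None, :]
        alt_k = e_alt[:, None, :] * a                    # (n, K, m)
        ref_k = e_ref[:, None, :] * b
        f_new = np.clip(
            alt_k.sum(axis=0) / (alt_k.sum(axis=0) + ref_k.sum(axis=0)),
            *ADMIX_CLAMP)
        q_new = (alt_k + ref_k).sum(axis=2) / (2.0 * m)
        q_new = q_new / q_new.sum(axis=1, keepdims=True)
        return q_new, f_new

    def project(q: np.ndarray, f: np.ndarray):
        q = np.clip(q, 1e-9, None)
        return q / q.sum(axis=1, keepdims=True), np.clip(f, *ADMIX_CLAMP)

    best: AdmixtureResult | None = None
    for _ in range(max(1, n_starts)):
        q = rng.dirichlet(np.ones(K), size=n)
        f = np.clip(pooled[None, :] + rng.normal(0, 0.05, size=(K, m)),
                    *ADMIX_CLAMP)
        trace = [loglik(q, f)]
        # SQUAREM-accelerated EM: two base steps per cycle plus a
        # quasi-Newton extrapolation, falling back to the plain double
        # step whenever extrapolation does not improve the likelihood
        for _ in range(max_iter):
            q1, f1 = em_step(q, f)
            q2, f2 = em_step(q1, f1)
            rq, rf = q1 - q, f1 - f
            vq, vf = (q2 - q1) - rq, (f2 - f1) - rf
            vnorm = np.sqrt((vq ** 2).sum() + (vf ** 2).sum())
            ll2 = loglik(q2, f2)
            ll_s = -np.inf
            if vnorm > 0:
                alpha = -np.sqrt((rq ** 2).sum() + (rf ** 2).sum()) / vnorm
                alpha = min(alpha, -1.0)
                qs, fs = project(q - 2 * alpha * rq + alpha ** 2 * vq,
                                 f - 2 * alpha * rf + alpha ** 2 * vf)
                # stabilize the extrapolated point with one EM step
                qs, fs = em_step(qs, fs)
                ll_s = loglik(qs, fs)
            if ll_s >= ll2:
                q, f, ll = qs, fs, ll_s
            else:
                q, f, ll = q2, f2, ll2
            if ll - trace[-1] < -1e-6:
                raise AssertionError("admixture EM log-likelihood decreased")
            converged = abs(ll - trace[-1]) < tol
            trace.append(ll)
            if converged:
                break
        res = AdmixtureResult(K, q, f, trace[-1], np.array(trace))
        if best is None or res.loglik > best.loglik:
            best = res
    assert best is not None
    return best


def kinship_from_gls(gls: GLMatrix,
                     site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise kinship as centered-dosage correlation.

    Posterior expected dosages under the pooled-frequency HWE prior are
    centered per site; site pairs where either individual lacks reads are
    dropped pairwise. Individuals with no informative site get NaN rows.
    """
    work = gls if site_mask is None else gls.subset_sites(np.asarray(site_mask))
    if work.n_sites < 1:
        raise ValueError("empty SNP subset")
    lin = work.linear()
    pooled, _ = estimate_maf(work)
    pooled = np.nan_to_num(pooled, nan=0.5)
    dose = posterior_expected_dosage(lin, pooled)
    covered = (work.depth > 0).astype(np.float64)
    n_cov = covered.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_mean = (dose * covered).sum(axis=0) / n_cov
    xc = np.where(covered > 0, dose - site_mean, 0.0)
    num = xc @ xc.T
    sq = (xc ** 2) @ covered.T          # sum of i's squares over shared sites
    with np.errstate(invalid="ignore", divide="ignore"):
        kin = num / np.sqrt(sq * sq.T)
    no_info = (covered.sum(axis=1) == 0) | ((xc ** 2).sum(axis=1) == 0)
    kin[no_info, :] = np.nan
    kin[:, no_info] = np.nan
    return pd.DataFrame(kin, index=work.individuals, columns=work.individuals)
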