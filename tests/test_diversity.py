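"""SFS estimation, windowed diversity and Tajima's D."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from glpanmix.diversity import (outgroup_consensus, site_filters,
                                saf_per_site, fold_saf, sfs_em, fold_sfs,
                                window_thetas, tajimas_d, SFS)
from glpanmix.simdata import PileupMatrix, SimConfig, simulate_all

from conftest import gls_from_dosages, make_sites


def make_pileup(n_major, n_minor, n_other=None, err=0.01, sites=None):
    n_major = np.atleast_2d(np.asarray(n_major))
    if n_other is None:
        n_other = np.zeros_like(n_major)
    if sites is None:
        sites = make_sites(n_major.shape[1])
    return PileupMatrix(sites, [f"i{k}" for k in range(n_major.shape[0])],
                        n_major, np.atleast_2d(np.asarray(n_minor)),
                        np.atleast_2d(np.asarray(n_other)), err)


def brute_force_saf(lin_site, n):
    """Direct enumeration of P(X|d) over all 3^n genotype configurations,
    with hypergeometric configuration weights."""
    out = np.zeros(2 * n + 1)
    for combo in itertools.product(range(3), repeat=n):
        d = sum(combo)
        w = np.prod([comb(2, g) for g in combo])
        out[d] += w * np.prod([lin_site[i, g] for i, g in enumerate(combo)])
    d = np.arange(2 * n + 1)
    return out / comb(2 * n, d)


class TestConsensus:
    def test_fixed_outgroup_calls_that_allele(self):
        pile = make_pileup([[8, 0]], [[0, 8]])
        anc = outgroup_consensus(pile)
        assert anc[0] == "A" and anc[1] == "C"

    def test_read_tie_gives_n(self):
        pile = make_pileup([[4]], [[4]])
        assert outgroup_consensus(pile)[0] == "N"

    def test_zero_coverage_gives_n(self):
        pile = make_pileup([[0]], [[0]])
        assert outgroup_consensus(pile)[0] == "N"

    def test_matches_true_ancestral_with_faithful_outgroup(self):
        """A non-divergent outgroup consensus recovers the ancestral
        allele at virtually all well-covered sites."""
        cfg = SimConfig(n_localities=2, n_per_locality=5, n_outgroup=20,
                        n_sites=2_000, chrom_length=1_000_000,
                        outgroup_fixed_fraction=0.0, divergence_maf_shift=0.1,
                        inversion_span=(400_000, 500_000), inversion_freq=0.0,
                        outgroup_inversion_freq=0.0, seed=51)
        _, truth, pile = simulate_all(cfg)
        outg = np.flatnonzero(truth.species_labels == "outgroup")
        sub = pile.subset(outg)
        anc = outgroup_consensus(sub)
        deep = sub.depth.sum(axis=0) >= 5
        match = anc[deep] == truth.ancestral_allele[deep]
        assert match.mean() >= 0.99


class TestSiteFilters:
    def test_depth_bounds_inclusive(self):
        depths = np.array([[14, 15, 500, 1000, 1001]])
        pile = make_pileup(depths, np.zeros_like(depths))
        keep = site_filters(pile)
        assert list(keep) == [False, True, True, True, False]

    def test_identity_when_all_within_bounds(self):
        depths = np.full((3, 10), 20)
        pile = make_pileup(depths, np.zeros_like(depths))
        assert site_filters(pile).all()


class TestSAF:
    def test_single_certain_het_concentrates_at_one(self):
        gl = gls_from_dosages(np.array([[1]]))
        saf = saf_per_site(gl, np.array(["A"]))
        lin = np.exp(saf.logl[0])
        assert np.argmax(lin) == 1
        assert lin[0] < 1e-10 and lin[2] < 1e-10

    def test_het_plus_hom_derived_concentrates_at_three(self):
        gl = gls_from_dosages(np.array([[1], [2]]))
        saf = saf_per_site(gl, np.array(["A"]))
        assert np.argmax(np.exp(saf.logl[0])) == 3

    def test_ancestral_equal_alt_flips_orientation(self):
        gl = gls_from_dosages(np.array([[2], [2]]))   # alt homozygotes
        saf = saf_per_site(gl, np.array(["C"]))       # alt is ancestral
        assert np.argmax(np.exp(saf.logl[0])) == 0    # zero derived copies

    def test_unknown_ancestral_site_skipped(self):
        gl = gls_from_dosages(np.array([[1, 1]]))
        saf = saf_per_site(gl, np.array(["N", "A"]))
        assert len(saf.sites) == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(61)
        for n in (1, 2, 3):
            for _ in range(8):
                logl = -3 * rng.random((n, 2, 3))
                logl -= logl.max(axis=2, keepdims=True)
                gl = gls_from_dosages(np.zeros((n, 2), dtype=int))
                gl.logl[:] = logl
                saf = saf_per_site(gl, np.array(["A", "A"]))
                for j in range(2):
                    expect = brute_force_saf(np.exp(logl[:, j, :]), n)
                    got = np.exp(saf.logl[j])
                    assert np.allclose(got / got.max(),
                                       expect / expect.max(), atol=1e-10)


class TestSFS:
    def test_certain_genotypes_reduce_to_counting(self):
        rng = np.random.default_rng(62)
        n, m = 6, 400
        d_true = rng.integers(0, 2 * n + 1, size=m)
        dosages = np.zeros((n, m), dtype=int)
        for j, d in enumerate(d_true):
            # distribute d derived copies over individuals
            copies = np.zeros(2 * n, dtype=int)
            copies[:d] = 1
            rng.shuffle(copies)
            dosages[:, j] = copies.reshape(n, 2).sum(axis=1)
        gl = gls_from_dosages(dosages)
        saf = saf_per_site(gl, np.repeat("A", m))
        sfs = sfs_em(saf.logl)
        observed = np.bincount(d_true, minlength=2 * n + 1)
        assert np.allclose(sfs.counts, observed, atol=0.5)

    def test_em_loglik_nondecreasing_and_recovers_neutral_spectrum(self):
        """Deep-coverage draws from the standard neutral 1/d law are
        recovered within 10% per low-frequency bin."""
        rng = np.random.default_rng(63)
        n, m = 20, 50_000
        d_vals = np.arange(1, 2 * n)
        probs = (1.0 / d_vals) / (1.0 / d_vals).sum()
        d_true = rng.choice(d_vals, size=m, p=probs)
        dosages = np.zeros((n, m), dtype=int)
        for j, d in enumerate(d_true):
            copies = np.zeros(2 * n, dtype=int)
            copies[:d] = 1
            rng.shuffle(copies)
            dosages[:, j] = copies.reshape(n, 2).sum(axis=1)
        gl = gls_from_dosages(dosages)
        saf = saf_per_site(gl, np.repeat("A", m))
        sfs = sfs_em(saf.logl)
        expected = m * probs
        for d in range(1, 11):
            assert sfs.counts[d] == pytest.approx(expected[d - 1], rel=0.10)

    def test_folding_consistency(self, small_gls, small_sim):
        """Estimating a folded spectrum from unpolarized likelihoods
        equals folding the unfolded estimate of the same data."""
        _, _, truth, _ = small_sim
        sub = small_gls.subset_individuals(np.arange(8))
        sub = sub.subset_sites(np.arange(sub.n_sites) < 300)
        saf = saf_per_site(sub, truth.ancestral_allele[:300])
        lin = np.exp(saf.logl)
        sym = np.log(lin + lin[:, ::-1])          # ancestral unknown
        sym -= sym.max(axis=1, keepdims=True)
        folded_of_unfolded = fold_sfs(sfs_em(sym, tol=1e-10, max_iter=5000))
        direct_folded = sfs_em(fold_saf(saf).logl, tol=1e-10,
                               max_iter=5000).counts
        assert np.allclose(folded_of_unfolded, direct_folded, atol=0.05)


class TestThetasAndTajima:
    @staticmethod
    def textbook_d(pi, s, n):
        """Independent implementation with the original 1989 constants."""
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1 = c1 / a1
        e2 = c2 / (a1 ** 2 + a2)
        return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))

    def test_matches_textbook_example(self):
        # classic worked example: 5 sequences, 16 segregating sites,
        # mean pairwise difference 3.888...
        pi, s, n = 35.0 / 9.0, 16, 5
        assert tajimas_d(pi, s, n) == pytest.approx(
            self.textbook_d(pi, s, n), abs=1e-9)

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(64)
        for _ in range(25):
            n = int(rng.integers(4, 60))
            s = float(rng.uniform(2, 50))
            pi = float(rng.uniform(0, 20))
            assert tajimas_d(pi, s, n) == pytest.approx(
                self.textbook_d(pi, s, n), abs=1e-9)

    def test_zero_segregating_sites_gives_missing(self):
        assert np.isnan(tajimas_d(0.0, 0.0, 10))

    def test_theta_pi_matches_direct_pairwise_differences(self):
        rng = np.random.default_rng(65)
        n, m = 10, 30
        d_true = rng.integers(0, 2 * n + 1, size=m)
        dosages = np.zeros((n, m), dtype=int)
        for j, d in enumerate(d_true):
            copies = np.zeros(2 * n, dtype=int)
            copies[:d] = 1
            rng.shuffle(copies)
            dosages[:, j] = copies.reshape(n, 2).sum(axis=1)
        gl = gls_from_dosages(dosages, make_sites(m, spacing=10))
        saf = saf_per_site(gl, np.repeat("A", m))
        sfs = sfs_em(saf.logl)
        wins = window_thetas(saf, sfs, window_bp=10_000)
        k = 2 * n
        pi_direct = (d_true * (k - d_true) / (k * (k - 1) / 2)).sum() / m
        assert wins.table["theta_pi"][0] == pytest.approx(pi_direct, abs=1e-6)

    def test_monomorphic_window_has_zero_thetas_and_missing_d(self):
        gl = gls_from_dosages(np.zeros((6, 20), dtype=int),
                              make_sites(20, spacing=10))
        saf = saf_per_site(gl, np.repeat("A", 20))
        prior = np.zeros(13)
        prior[0] = 19.0
        prior[5] = 1.0
        wins = window_thetas(saf, SFS(prior, 0.0), window_bp=1000)
        assert wins.table["theta_pi"][0] == pytest.approx(0.0, abs=1e-6)
        assert wins.table["theta_w"][0] == pytest.approx(0.0, abs=1e-6)
        assert np.isnan(wins.table["tajima_d"][0])

    def test_outgroup_sweep_region_loses_diversity(self, small_sim, small_gls):
        """The near-fixed founder haplotype in the outgroup drains
        regional diversity while the conspecific samples are unaffected."""
        cfg, _, truth, pileup = small_sim
        lo, hi = cfg.inversion_span
        outg = np.flatnonzero(truth.species_labels == "outgroup")
        ing = np.flatnonzero(truth.species_labels == "ingroup")
        anc = truth.ancestral_allele
        results = {}
        for name, idx in (("out", outg), ("in", ing[:10])):
            sub = small_gls.subset_individuals(idx)
            saf = saf_per_site(sub, anc)
            sfs = sfs_em(saf.logl)
            wins = window_thetas(saf, sfs, window_bp=5_000,
                                 chrom_length=cfg.chrom_length)
            tab = wins.table
            in_reg = ((tab["start"] >= lo) & (tab["end"] <= hi)).to_numpy()
            pi = tab["theta_pi"].to_numpy()
            results[name] = (np.nanmedian(pi[in_reg]),
                             np.nanmedian(pi[~in_reg]))
        assert results["out"][0] < 0.2 * results["out"][1]
        assert results["in"][0] > 0.5 * results["in"][1]
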