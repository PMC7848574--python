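"""Genotype-likelihood model, allele-frequency EM and SNP calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glpanmix.genolik import (GLMatrix, compute_gls, estimate_maf, call_snps,
                              major_minor_from_reference, pooled_base_counts,
                              write_beagle, read_beagle, hwe_genotype_priors,
                              exclude_low_coverage)
from glpanmix.simdata import PileupMatrix

from conftest import make_sites, gls_from_dosages


def make_pileup(n_major, n_minor, n_other, err=0.01):
    n_major = np.atleast_2d(n_major)
    sites = make_sites(n_major.shape[1])
    return PileupMatrix(sites, [f"i{k}" for k in range(n_major.shape[0])],
                        np.asarray(n_major), np.atleast_2d(n_minor),
                        np.atleast_2d(n_other), err)


def grid_search_maf(lin, covered, grid=None):
    """Independent 1-D likelihood maximization over a frequency grid."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 1001)
    pri = hwe_genotype_priors(grid)                       # (G, 3)
    per_ind = np.einsum("nis,gs->nig", lin, pri)          # (n, 1?, G) per site
    best_f = np.empty(lin.shape[1])
    for j in range(lin.shape[1]):
        ll = np.where(covered[:, j, None], np.log(per_ind[:, j, :]), 0.0).sum(axis=0)
        best_f[j] = grid[np.argmax(ll)]
    return best_f


class TestComputeGls:
    def test_two_major_reads_match_hand_formula(self):
        pile = make_pileup([[2]], [[0]], [[0]], err=0.01)
        gl = compute_gls(pile)
        lin = np.exp(gl.logl[0, 0])
        ratios = lin / lin[0]
        expected = np.array([0.98010, 0.24668, 1.111e-5]) / 0.98010
        assert np.allclose(ratios, expected, rtol=1e-3)

    def test_depth_zero_gives_flat_likelihood(self):
        pile = make_pileup([[0]], [[0]], [[0]])
        gl = compute_gls(pile)
        assert np.allclose(gl.logl[0, 0], 0.0)

    def test_het_read_pair_favours_heterozygote(self):
        for err in np.linspace(0.001, 0.4, 25):
            pile = make_pileup([[1]], [[1]], [[0]], err=err)
            gl = compute_gls(pile)
            assert np.argmax(gl.logl[0, 0]) == 1

    def test_normalization_max_zero(self, small_gls):
        assert np.allclose(small_gls.logl.max(axis=2), 0.0)
        assert (small_gls.logl <= 0).all()

    def test_negative_counts_rejected(self):
        pile = make_pileup([[-1]], [[0]], [[0]])
        with pytest.raises(ValueError, match="negative"):
            compute_gls(pile)

    @given(st.floats(0.001, 0.5), st.integers(0, 6), st.integers(0, 6))
    @settings(max_examples=30, deadline=None)
    def test_constant_shift_invariance(self, err, a, b):
        """Adding a constant to all three log-likelihoods never changes
        the frequency estimate (normalization invariance)."""
        pile = make_pileup([[a, a]], [[b, b]], [[0, 0]], err=err)
        gl = compute_gls(pile)
        shifted = GLMatrix(gl.sites, gl.individuals, gl.logl - 7.0, gl.depth)
        f1, _ = estimate_maf(gl)
        f2, _ = estimate_maf(shifted)
        assert np.allclose(f1, f2, atol=1e-12, equal_nan=True)


class TestEstimateMaf:
    def test_certain_genotypes_count_alleles(self):
        gl = gls_from_dosages(np.array([[0], [0], [1], [1], [2]]))
        f, _ = estimate_maf(gl)
        assert f[0] == pytest.approx(0.4, abs=1e-6)

    def test_all_reference_gives_zero(self):
        gl = gls_from_dosages(np.zeros((6, 3), dtype=int))
        f, _ = estimate_maf(gl)
        assert np.allclose(f, 0.0, atol=1e-6)

    def test_all_missing_flagged_not_zero(self):
        pile = make_pileup([[0], [0]], [[0], [0]], [[0], [0]])
        f, _ = estimate_maf(compute_gls(pile))
        assert np.isnan(f[0])

    def test_matches_grid_search_oracle_on_small_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = rng.integers(2, 11)
            m = rng.integers(1, 4)
            depth = rng.integers(0, 4, size=(n, m))
            g_true = rng.integers(0, 3, size=(n, m))
            p_min = g_true / 2 * 0.99 + (1 - g_true / 2) * 0.01 / 3
            n_minor = rng.binomial(depth, p_min)
            pile = make_pileup(depth - n_minor, n_minor,
                               np.zeros_like(depth), err=0.01)
            gl = compute_gls(pile)
            f_em, _ = estimate_maf(gl)
            f_grid = grid_search_maf(np.exp(gl.logl), gl.depth > 0)
            covered = (depth > 0).any(axis=0)
            assert np.allclose(f_em[covered], f_grid[covered], atol=1e-3)

    def test_em_close_to_truth_at_low_coverage(self):
        rng = np.random.default_rng(23)
        n, f_true = 200, 0.3
        g = rng.binomial(2, f_true, size=(n, 1))
        depth = rng.poisson(1.4, size=(n, 1))
        p_min = g / 2 * 0.99 + (1 - g / 2) * 0.01 / 3
        n_minor = rng.binomial(depth, p_min)
        gl = compute_gls(make_pileup(depth - n_minor, n_minor,
                                     np.zeros_like(depth), err=0.01))
        f_em, _ = estimate_maf(gl)
        f_grid = grid_search_maf(np.exp(gl.logl), gl.depth > 0)
        assert f_em[0] == pytest.approx(f_grid[0], abs=0.002)
        assert f_em[0] == pytest.approx(f_true, abs=0.05)

    def test_depth_zero_individuals_do_not_move_estimate(self, small_gls):
        sub = small_gls.subset_sites(np.arange(small_gls.n_sites) < 40)
        f1, _ = estimate_maf(sub)
        empty = GLMatrix(
            sub.sites, sub.individuals + ["empty1", "empty2"],
            np.concatenate([sub.logl, np.zeros((2, sub.n_sites, 3))]),
            np.concatenate([sub.depth, np.zeros((2, sub.n_sites), dtype=np.int32)]),
        )
        f2, _ = estimate_maf(empty)
        assert np.allclose(f1, f2, atol=1e-10, equal_nan=True)


class TestCallSnps:
    def test_monomorphic_site_not_called(self):
        gl = gls_from_dosages(np.zeros((20, 2), dtype=int))
        table = call_snps(gl)
        assert np.allclose(table["snp_lrt"], 0.0, atol=1e-6)
        assert (table["snp_pvalue"] > 0.9).all()
        assert not table["pass_snp"].any()

    def test_maf_thresholds_inclusive(self):
        # 2 het in 20 individuals -> f = 0.05 exactly; 49/500 hets -> 0.049
        d1 = np.zeros((20, 1), dtype=int)
        d1[:2, 0] = 1
        t1 = call_snps(gls_from_dosages(d1))
        assert bool(t1["pass_maf05"][0])
        d2 = np.zeros((500, 1), dtype=int)
        d2[:49, 0] = 1
        t2 = call_snps(gls_from_dosages(d2))
        assert t2["maf"][0] == pytest.approx(0.049, abs=1e-4)
        assert not bool(t2["pass_maf05"][0])

    def test_maf_folded_to_minor_allele(self):
        d = np.full((10, 1), 2, dtype=int)
        d[:3, 0] = 1     # alt frequency 0.85 -> MAF 0.15
        t = call_snps(gls_from_dosages(d))
        assert t["alt_freq"][0] == pytest.approx(0.85, abs=1e-3)
        assert t["maf"][0] == pytest.approx(0.15, abs=1e-3)

    def test_false_positive_rate_on_monomorphic_sites(self):
        """10,000 truly monomorphic sites at 1.4x: chi2(1) tail at 1e-6
        predicts ~0.01 false calls; a standard run yields none."""
        rng = np.random.default_rng(31)
        n, m = 40, 10_000
        depth = rng.poisson(1.4, size=(n, m))
        n_minor = rng.binomial(depth, 0.01 / 3)
        gl = compute_gls(make_pileup(depth - n_minor, n_minor,
                                     np.zeros_like(depth), err=0.01))
        table = call_snps(gl)
        assert int(table["pass_snp"].sum()) == 0


class TestOrientation:
    def test_reference_stays_major_even_when_rare(self):
        counts = pd.DataFrame({"A": [30.0], "C": [70.0],
                               "G": [0.0], "T": [0.0]})
        out = major_minor_from_reference(counts, np.array(["A"]))
        assert out["major"][0] == "A" and out["minor"][0] == "C"

    def test_tie_broken_lexicographically(self):
        counts = pd.DataFrame({"A": [10.0], "C": [5.0],
                               "G": [5.0], "T": [0.0]})
        out = major_minor_from_reference(counts, np.array(["A"]))
        assert out["minor"][0] == "C"

    def test_unobserved_reference_flagged(self):
        counts = pd.DataFrame({"A": [0.0], "C": [9.0],
                               "G": [1.0], "T": [0.0]})
        out = major_minor_from_reference(counts, np.array(["A"]))
        assert bool(out["ref_missing"][0])

    def test_orientation_idempotent(self, small_sim):
        _, _, _, pileup = small_sim
        counts = pooled_base_counts(pileup)
        ref = pileup.sites["ref"].to_numpy()
        once = major_minor_from_reference(counts, ref)
        twice = major_minor_from_reference(counts, once["major"].to_numpy())
        assert once.equals(twice)


class TestBeagleIO:
    def test_round_trip(self, small_gls, tmp_path):
        sub = small_gls.subset_sites(np.arange(small_gls.n_sites) < 25)
        path = tmp_path / "gl.beagle.gz"
        write_beagle(sub, path)
        back = read_beagle(path)
        assert back.individuals == sub.individuals
        assert np.array_equal(back.sites["pos0"], sub.sites["pos0"])
        f1, _ = estimate_maf(sub)
        f2, _ = estimate_maf(back)
        assert np.allclose(f1, f2, atol=1e-4, equal_nan=True)


class TestCoverageFilter:
    def test_low_coverage_individuals_dropped(self):
        rng = np.random.default_rng(5)
        depth = rng.poisson(1.4, size=(6, 200))
        depth[0] = 0
        depth[1, :190] = 0       # 5% callable
        n_minor = rng.binomial(depth, 0.1)
        gl = compute_gls(make_pileup(depth - n_minor, n_minor,
                                     np.zeros_like(depth)))
        kept_gl, kept = exclude_low_coverage(gl, min_fraction=0.10)
        assert 0 not in kept and 1 not in kept
        assert kept_gl.n_individuals == 4
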