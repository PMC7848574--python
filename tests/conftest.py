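import numpy as np
import pandas as pd
import pytest

from glpanmix.genolik import GLMatrix
from glpanmix.simdata import SimConfig, simulate_all

CERTAIN_LOG = -60.0


def make_sites(m: int, chrom: str = "chr1", start: int = 0,
               spacing: int = 100) -> pd.DataFrame:
    pos = start + spacing * np.arange(m)
    return pd.DataFrame({"chrom": chrom, "pos0": pos,
                         "ref": "A", "alt": "C"})


def gls_from_dosages(dosages: np.ndarray,
                     sites: pd.DataFrame | None = None) -> GLMatrix:
    """Fully certain genotype likelihoods from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=int)
    n, m = dosages.shape
    logl = np.full((n, m, 3), CERTAIN_LOG)
    for g in range(3):
        logl[:, :, g][dosages == g] = 0.0
    if sites is None:
        sites = make_sites(m)
    depth = np.full((n, m), 30, dtype=np.int32)
    return GLMatrix(sites, [f"ind{i}" for i in range(n)], logl, depth)


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed-species dataset with an inversion block."""
    cfg = SimConfig(n_localities=4, n_per_locality=10, n_outgroup=8,
                    n_sites=800, chrom_length=1_000_000,
                    inversion_span=(400_000, 600_000), seed=3)
    freqs, truth, pileup = simulate_all(cfg)
    return cfg, freqs, truth, pileup


@pytest.fixture(scope="session")
def small_gls(small_sim):
    from glpanmix.genolik import compute_gls
    _, _, _, pileup = small_sim
    return compute_gls(pileup)


@pytest.fixture(scope="session")
def inv_sim():
    """Ingroup-heavy dataset where the inversion block is well sampled."""
    cfg = SimConfig(n_localities=5, n_per_locality=20, n_outgroup=15,
                    n_sites=1_500, chrom_length=1_000_000,
                    inversion_span=(400_000, 600_000), seed=13)
    freqs, truth, pileup = simulate_all(cfg)
    return cfg, freqs, truth, pileup


@pytest.fixture(scope="session")
def inv_gls(inv_sim):
    from glpanmix.genolik import compute_gls
    _, _, _, pileup = inv_sim
    return compute_gls(pileup)


@pytest.fixture(scope="session")
def deep_sim():
    """Same design at saturating coverage: genotypes effectively certain."""
    cfg = SimConfig(n_localities=4, n_per_locality=10, n_outgroup=8,
                    n_sites=600, chrom_length=1_000_000, mean_depth=25.0,
                    inversion_span=(400_000, 600_000), seed=9)
    freqs, truth, pileup = simulate_all(cfg)
    return cfg, freqs, truth, pileup


@pytest.fixture(scope="session")
def deep_gls(deep_sim):
    from glpanmix.genolik import compute_gls
    _, _, _, pileup = deep_sim
    return compute_gls(pileup)
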