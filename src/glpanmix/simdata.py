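"""Synthetic low-coverage population-genomic data.

Generates the study design this package's inference assumes: ten
conspecific sampling localities with zero (panmictic null) to low
(Balding–Nichols) differentiation, a deeply diverged outgroup species
carrying genome-wide fixed differences, a non-recombining inversion-like
haplotype block segregating in all localities and near-fixed in the
outgroup, optional low-rate introgression of outgroup segments, and
per-site Poisson read depth with a uniform base-error model.

Everything is driven by a single integer seed; identical seed and
configuration give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults mirror the study design: 10 localities of 40 diploids plus a
    49-individual outgroup sample, median ~1.4x coverage, a ~200-kb
    inversion block at 29% frequency in the ingroup and 98% in the
    outgroup.
    """

    n_localities: int = 10
    n_per_locality: int = 40
    n_outgroup: int = 49
    n_sites: int = 20_000
    chrom_length: int = 5_000_000
    chrom_name: str = "chr1"
    fst_target: float = 0.0
    divergence_maf_shift: float = 0.2
    outgroup_fixed_fraction: float = 0.15
    inversion_span: tuple[int, int] = (2_000_000, 2_200_000)
    inversion_freq: float = 0.29
    outgroup_inversion_freq: float = 0.98
    hap2_mutation_rate: float = 0.002
    introgression_fraction: float = 0.0
    introgressed_localities: tuple[int, ...] = (0, 1)
    introgression_segment_bp: int = 100_000
    mean_depth: float = 1.4
    base_error: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_target",):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in (
            "inversion_freq",
            "outgroup_inversion_freq",
            "introgression_fraction",
            "outgroup_fixed_fraction",
            "hap2_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.base_error < 0.75:
            raise ValueError("base_error must be in [0, 0.75)")
        lo, hi = self.inversion_span
        if not (0 <= lo < hi <= self.chrom_length):
            raise ValueError("inversion_span must lie within [0, chrom_length)")
        if min(self.n_localities, self.n_per_locality, self.n_sites) < 1:
            raise ValueError("counts must be positive")
        if self.n_outgroup < 0:
            raise ValueError("n_outgroup must be >= 0")

    @property
    def n_ingroup(self) -> int:
        return self.n_localities * self.n_per_locality

    @property
    def n_individuals(self) -> int:
        return self.n_ingroup + self.n_outgroup

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "inversion_span" in raw:
            raw["inversion_span"] = tuple(raw["inversion_span"])
        if "introgressed_localities" in raw:
            raw["introgressed_localities"] = tuple(raw["introgressed_localities"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["inversion_span"] = list(self.inversion_span)
        d["introgressed_localities"] = list(self.introgressed_localities)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class FrequencyTable:
    """Per-locality true alternate(derived)-allele frequencies.

    ``sites`` has columns chrom, pos0, ref, alt; ``ref`` is the ancestral
    allele. ``ingroup`` is (n_localities, n_sites), ``outgroup`` (n_sites,).
    """

    sites: pd.DataFrame
    ancestral_freq: np.ndarray
    ingroup: np.ndarray
    outgroup: np.ndarray


@dataclass
class SimTruth:
    """Ground truth emitted alongside the reads."""

    sites: pd.DataFrame
    individuals: list[str]
    genotypes: np.ndarray            # (n, m) alt-allele dosage in {0,1,2}
    locality_labels: np.ndarray      # per individual, e.g. "L03" or "OUT"
    species_labels: np.ndarray       # "ingroup" / "outgroup"
    inversion_genotype: np.ndarray   # per individual: copies of haplotype 2
    true_freqs: np.ndarray           # (n_localities + 1, m) incl. outgroup row
    ancestral_allele: np.ndarray     # per site, equals sites.ref

    @property
    def inversion_group(self) -> np.ndarray:
        """String labels hom1/het/hom2 from haplotype-2 copy number."""
        return np.array(["hom1", "het", "hom2"])[self.inversion_genotype]


@dataclass
class PileupMatrix:
    """Per-individual, per-site read counts against the ref/alt alleles.

    n_major counts reads matching the reference (ancestral) base, n_minor
    the alternate base, n_other everything else (sequencing error).
    """

    sites: pd.DataFrame
    individuals: list[str]
    n_major: np.ndarray
    n_minor: np.ndarray
    n_other: np.ndarray
    base_error: float

    @property
    def depth(self) -> np.ndarray:
        return self.n_major + self.n_minor + self.n_other

    def subset(self, ind_idx: np.ndarray) -> "PileupMatrix":
        return PileupMatrix(
            self.sites,
            [self.individuals[i] for i in np.atleast_1d(ind_idx)],
            self.n_major[ind_idx],
            self.n_minor[ind_idx],
            self.n_other[ind_idx],
            self.base_error,
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_frequencies(cfg: SimConfig) -> FrequencyTable:
    """Draw per-locality true allele frequencies.

    Ancestral (derived-allele) frequencies are uniform on [0.05, 0.95];
    locality frequencies follow a Balding–Nichols Beta around the
    ancestral frequency with parameter ``fst_target`` (exactly equal
    under panmixia, fst_target = 0). The outgroup mostly retains the
    ancestral allele — its derived-allele frequency is half-normal with
    scale ``divergence_maf_shift`` (so an outgroup read consensus can
    polarize alleles) — except at an ``outgroup_fixed_fraction`` of
    sites where it is fixed for the allele opposite the ingroup major
    (the genome-wide fixed interspecies differences).
    """
    rng = _child_rngs(cfg.seed, 3)[0]
    m = cfg.n_sites
    pos0 = np.sort(rng.choice(cfg.chrom_length, size=m, replace=False))
    ref_idx = rng.integers(0, 4, size=m)
    # alt drawn uniformly among the three non-reference bases
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    sites = pd.DataFrame(
        {
            "chrom": cfg.chrom_name,
            "pos0": pos0,
            "ref": BASES[ref_idx],
            "alt": BASES[alt_idx],
        }
    )

    p_anc = rng.uniform(0.05, 0.95, size=m)
    F = cfg.fst_target
    if F == 0.0:
        ingroup = np.tile(p_anc, (cfg.n_localities, 1))
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        ingroup = rng.beta(a, b, size=(cfg.n_localities, m))

    fixed = rng.random(m) < cfg.outgroup_fixed_fraction
    drift = np.abs(rng.normal(0.0, cfg.divergence_maf_shift, size=m))
    outgroup = np.clip(drift, 0.0, 1.0)
    # fixed difference: outgroup fixed for the opposite of the ingroup major
    outgroup[fixed] = np.where(p_anc[fixed] < 0.5, 1.0, 0.0)
    return FrequencyTable(sites, p_anc, ingroup, outgroup)


def _inversion_mask(cfg: SimConfig, sites: pd.DataFrame) -> np.ndarray:
    lo, hi = cfg.inversion_span
    return (
        (sites["chrom"].to_numpy() == cfg.chrom_name)
        & (sites["pos0"].to_numpy() >= lo)
        & (sites["pos0"].to_numpy() < hi)
    )


def simulate_genotypes(freqs: FrequencyTable, cfg: SimConfig) -> SimTruth:
    """Draw true genotypes under the configured demography.

    Outside the inversion span genotypes are Hardy–Weinberg draws from
    each locality's true frequency. Inside the span each chromosome copy
    is either a haplotype-1 draw (ancestral diversity) or the single
    haplotype-2 founder allele plus sparse new mutations, so haplotype-2
    homozygotes carry depressed within-group diversity. Designated
    localities may carry introgressed outgroup segments on one copy.
    """
    rng = _child_rngs(cfg.seed, 3)[1]
    m = cfg.n_sites
    sites = freqs.sites
    inv = _inversion_mask(cfg, sites)
    if not inv.any():
        raise ValueError("inversion_span contains no simulated sites")

    n_in, n_out = cfg.n_ingroup, cfg.n_outgroup
    n = n_in + n_out
    locality = np.concatenate(
        [
            np.repeat(
                [f"L{i + 1:02d}" for i in range(cfg.n_localities)],
                cfg.n_per_locality,
            ),
            np.repeat("OUT", n_out),
        ]
    )
    species = np.where(locality == "OUT", "outgroup", "ingroup")
    individuals = [f"{loc}_{i:03d}" for i, loc in enumerate(locality)]

    # per-individual frequency row (locality for ingroup, outgroup row last)
    loc_index = np.concatenate(
        [np.repeat(np.arange(cfg.n_localities), cfg.n_per_locality),
         np.repeat(cfg.n_localities, n_out)]
    )
    all_freqs = np.vstack([freqs.ingroup, freqs.outgroup[None, :]])
    p_ind = all_freqs[loc_index]                      # (n, m)

    # two chromosome copies so segments/haplotypes can be manipulated
    copy_a = (rng.random((n, m)) < p_ind).astype(np.int8)
    copy_b = (rng.random((n, m)) < p_ind).astype(np.int8)

    # inversion haplotypes
    q = np.where(species == "outgroup", cfg.outgroup_inversion_freq,
                 cfg.inversion_freq)
    hap_a = rng.random(n) < q
    hap_b = rng.random(n) < q
    inv_geno = (hap_a.astype(np.int8) + hap_b.astype(np.int8))

    founder = (rng.random(inv.sum()) < freqs.ancestral_freq[inv]).astype(np.int8)

    def hap2_block(n_rows: int) -> np.ndarray:
        block = np.tile(founder, (n_rows, 1))
        muts = rng.random(block.shape) < cfg.hap2_mutation_rate
        return np.where(muts, 1 - block, block).astype(np.int8)

    copy_a[:, inv] = np.where(hap_a[:, None], hap2_block(n), copy_a[:, inv])
    copy_b[:, inv] = np.where(hap_b[:, None], hap2_block(n), copy_b[:, inv])

    # introgression: outgroup segments on one copy in designated localities
    if cfg.introgression_fraction > 0 and n_out > 0:
        target_locs = {f"L{i + 1:02d}" for i in cfg.introgressed_localities}
        pos = sites["pos0"].to_numpy()
        seg = cfg.introgression_segment_bp
        n_seg = max(1, round(2 * cfg.introgression_fraction
                             * cfg.chrom_length / seg))
        for i in np.flatnonzero(np.isin(locality, list(target_locs))):
            starts = rng.integers(0, cfg.chrom_length - seg, size=n_seg)
            in_seg = np.zeros(m, dtype=bool)
            for s in starts:
                in_seg |= (pos >= s) & (pos < s + seg)
            in_seg &= ~inv
            repl = (rng.random(in_seg.sum()) < freqs.outgroup[in_seg])
            copy_b[i, in_seg] = repl.astype(np.int8)

    genotypes = copy_a + copy_b

    # effective per-group frequencies (haplotype mixture inside the span)
    true_freqs = all_freqs.copy()
    q_groups = np.append(
        np.repeat(cfg.inversion_freq, cfg.n_localities),
        cfg.outgroup_inversion_freq,
    )
    true_freqs[:, inv] = (
        (1.0 - q_groups[:, None]) * all_freqs[:, inv]
        + q_groups[:, None] * founder[None, :]
    )

    return SimTruth(
        sites=sites,
        individuals=individuals,
        genotypes=genotypes,
        locality_labels=locality,
        species_labels=species,
        inversion_genotype=inv_geno,
        true_freqs=true_freqs,
        ancestral_allele=sites["ref"].to_numpy(),
    )


def simulate_pileups(truth: SimTruth, cfg: SimConfig) -> PileupMatrix:
    """Simulate read pileups over the true genotypes.

    Depth is Poisson(mean_depth) per individual and site; a read reports
    the reference base with probability (1-g/2)(1-e) + (g/2)(e/3), the
    alternate with the mirror expression, and one of the two remaining
    bases with total probability 2e/3.
    """
    rng = _child_rngs(cfg.seed, 3)[2]
    g = truth.genotypes.astype(np.float64)
    e = cfg.base_error
    p_major = (1.0 - g / 2.0) * (1.0 - e) + (g / 2.0) * (e / 3.0)
    p_minor = (g / 2.0) * (1.0 - e) + (1.0 - g / 2.0) * (e / 3.0)
    # remaining mass 2e/3 is error reads to the two unmodelled bases
    depth = rng.poisson(cfg.mean_depth, size=g.shape)
    n_major = rng.binomial(depth, p_major)
    rest = depth - n_major
    with np.errstate(invalid="ignore", divide="ignore"):
        p_min_given_rest = np.where(p_major < 1.0,
                                    p_minor / (1.0 - p_major), 0.0)
    n_minor = rng.binomial(rest, p_min_given_rest)
    n_other = rest - n_minor
    return PileupMatrix(
        sites=truth.sites,
        individuals=list(truth.individuals),
        n_major=n_major.astype(np.int32),
        n_minor=n_minor.astype(np.int32),
        n_other=n_other.astype(np.int32),
        base_error=e,
    )


def simulate_all(cfg: SimConfig) -> tuple[FrequencyTable, SimTruth, PileupMatrix]:
    """Frequencies, truth and pileups in one deterministic call."""
    freqs = simulate_frequencies(cfg)
    truth = simulate_genotypes(freqs, cfg)
    pileup = simulate_pileups(truth, cfg)
    return freqs, truth, pileup


def write_truth(truth: SimTruth, prefix: str | Path) -> None:
    """Write ground-truth TSVs (gzip); positions 1-based in files."""
    prefix = Path(prefix)
    sites = truth.sites.copy()
    sites["pos"] = sites["pos0"] + 1
    geno = pd.DataFrame(truth.genotypes.T, columns=truth.individuals)
    pd.concat([sites[["chrom", "pos", "ref", "alt"]], geno], axis=1).to_csv(
        f"{prefix}.genotypes.tsv.gz", sep="\t", index=False)
    pd.DataFrame(
        {
            "individual": truth.individuals,
            "locality": truth.locality_labels,
            "species": truth.species_labels,
            "inversion_genotype": truth.inversion_genotype,
        }
    ).to_csv(f"{prefix}.labels.tsv.gz", sep="\t", index=False)
    freq_cols = {f"freq_{i}": truth.true_freqs[i]
                 for i in range(truth.true_freqs.shape[0])}
    pd.concat(
        [sites[["chrom", "pos", "ref", "alt"]], pd.DataFrame(freq_cols)], axis=1
    ).to_csv(f"{prefix}.freqs.tsv.gz", sep="\t", index=False)


def write_pileup(pileup: PileupMatrix, path: str | Path) -> None:
    """Long-format pileup TSV: chrom, pos, individual_id, counts."""
    n, m = pileup.n_major.shape
    sites = pileup.sites
    df = pd.DataFrame(
        {
            "chrom": np.tile(sites["chrom"].to_numpy(), n),
            "pos": np.tile(sites["pos0"].to_numpy() + 1, n),
            "individual_id": np.repeat(pileup.individuals, m),
            "n_major": pileup.n_major.ravel(),
            "n_minor": pileup.n_minor.ravel(),
            "n_other": pileup.n_other.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path, sites: pd.DataFrame,
                base_error: float) -> PileupMatrix:
    """Inverse of :func:`write_pileup` given the site table."""
    df = pd.read_csv(path, sep="\t")
    individuals = list(pd.unique(df["individual_id"]))
    m = len(sites)
    n = len(individuals)
    shape = (n, m)
    return PileupMatrix(
        sites=sites,
        individuals=individuals,
        n_major=df["n_major"].to_numpy().reshape(shape),
        n_minor=df["n_minor"].to_numpy().reshape(shape),
        n_other=df["n_other"].to_numpy().reshape(shape),
        base_error=base_error,
    )
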