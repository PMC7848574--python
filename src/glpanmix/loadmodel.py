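"""Multilocus viability-selection load model.

Quantifies the demographic cost of within-generation selection: if
viability selection at L independent codominant loci shifts each locus's
allele frequency by delta_p in a single generation, what fraction of the
cohort must die?

Per locus, genotype fitnesses are 1 : 1-s/2 : 1-s (codominant, the
favoured homozygote fittest). The deterministic recursion

    p' = (p - p q s / 2) / (1 - q s),  q = 1 - p

is solved for s in closed form; survival relative to the fittest genotype
is the mean fitness w-bar = 1 - q s, and independent loci multiply, so a
cohort's joint survival is w-bar^L and the required mortality 1 - w-bar^L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def one_generation(p: float, s: float) -> float:
    """Allele frequency after one generation of codominant selection."""
    q = 1.0 - p
    return (p - p * q * s / 2.0) / (1.0 - q * s)


def mean_fitness(p: float, s: float) -> float:
    """Mean fitness w-bar = p^2 + 2pq(1-s/2) + q^2(1-s) = 1 - qs."""
    return 1.0 - (1.0 - p) * s


def solve_selection_coefficient(p0: float, delta_p: float) -> float:
    """Selection coefficient giving a one-generation shift of delta_p.

    Closed form: s = delta_p / (q (p' - p/2)) with p' = p0 + delta_p.
    The recursion caps at p' = 1 - q/2 when s = 1 (lethal homozygote);
    larger shifts are infeasible under this fitness scheme.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if delta_p == 0.0:
        return 0.0
    if delta_p < 0.0:
        raise ValueError("delta_p must be non-negative")
    q = 1.0 - p0
    target = p0 + delta_p
    if target >= 1.0:
        raise ValueError("infeasible shift: p0 + delta_p must be < 1")
    s = delta_p / (q * (target - p0 / 2.0))
    if s > 1.0:
        raise ValueError(
            f"shift {delta_p} from {p0} needs s = {s:.4f} > 1 "
            f"(max one-generation shift is {1 - q / 2 - p0:.4f})")
    return s


def survival_fraction(s: float, p0: float) -> float:
    """Per-locus cohort survival relative to the fittest genotype."""
    return mean_fitness(p0, s)


@dataclass
class LoadScenario:
    p0: float
    delta_p: float
    n_loci: int
    s: float
    per_locus_survival: float
    joint_survival: float
    mortality: float

    @property
    def mortality_percent(self) -> int:
        """Mortality to the nearest integer percent."""
        return int(round(100.0 * self.mortality))

    @property
    def one_in_log10(self) -> int:
        """Reciprocal survival rounded to the nearest power of ten."""
        return int(round(np.log10(1.0 / self.joint_survival)))


def joint_survival(p0: float, delta_p: float, n_loci: int) -> LoadScenario:
    """Joint survival and mortality for independent loci.

    Survival multiplies across loci; n_loci = 0 gives survival 1.
    """
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    s = solve_selection_coefficient(p0, delta_p)
    w = survival_fraction(s, p0)
    joint = w ** n_loci
    return LoadScenario(p0, delta_p, n_loci, s, w, joint, 1.0 - joint)


def load_table(p0: float, delta_p: float,
               loci: list[int] | tuple[int, ...]) -> pd.DataFrame:
    """TSV-ready table of the load scenario across locus counts."""
    rows = []
    for L in loci:
        sc = joint_survival(p0, delta_p, L)
        rows.append({
            "n_loci": L,
            "p0": sc.p0,
            "delta_p": sc.delta_p,
            "s": sc.s,
            "per_locus_survival": sc.per_locus_survival,
            "joint_survival": sc.joint_survival,
            "mortality": sc.mortality,
            "mortality_percent": sc.mortality_percent,
        })
    return pd.DataFrame(rows)


def wright_fisher_cohort(p0: float, s: float, n: int,
                         rng: np.random.Generator) -> tuple[float, float]:
    """Simulate one generation of viability selection in a finite cohort.

    Draws n HWE genotypes at frequency p0, applies survival proportional
    to fitness (1, 1-s/2, 1-s), and returns (realized p', realized
    survival fraction). Serves as the stochastic cross-check of the
    deterministic recursion.
    """
    geno = rng.binomial(2, p0, size=n)             # copies of the favoured allele
    fitness = np.array([1.0 - s, 1.0 - s / 2.0, 1.0])[geno]
    survive = rng.random(n) < fitness
    if survive.sum() == 0:
        return float("nan"), 0.0
    p_after = geno[survive].mean() / 2.0
    return float(p_after), float(survive.mean())
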