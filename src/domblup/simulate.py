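"""Synthetic populations with known additive + dominance architecture.

The generator emulates the statistical structure of a genotyped dairy-cow
evaluation: a core set of genotyped animals with own phenotypes (group C),
ungenotyped offspring whose genotypes are only probabilistically known from
a genotyped sire and dam (group SD), and sire-MGS daughter groups whose
phenotype is the mean of N ungenotyped daughters (group SMGS).

Phenotypes follow the generative counterpart of the additive + dominance
model:

    y = intercept + Z a + W d + e

with per-SNP additive effects a_i ~ N(0, sigma2_a / sum 2 p q) and
dominance effects d_i drawn either on the dominance-value scale
(W = H, variance sigma2_d / sum 2pq(1 - 2pq)) or on the deviation scale
(W = M, variance sigma2_d / sum (2pq)^2).  The phenotypic variance is 1 by
convention, so sigma2_a = h2_additive, sigma2_d = h2_dominance and
sigma2_e = 1 - h2_additive - h2_dominance; trait-scale output is an affine
rescaling away and irrelevant to every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import (
    AlleleFrequencies,
    GenotypeMatrix,
    compute_codings,
)

__all__ = [
    "SimConfig",
    "TruePopulation",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_descendant_groups",
    "simulate_population",
]


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic population.

    Defaults mirror a Holstein-like milk-yield architecture: additive
    heritability 0.27 and dominance heritability 0.05 on a unit phenotypic
    variance, with SMGS groups retained only at >= 20 daughters.
    """

    n_animals: int = 2000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_additive: float = 0.27
    h2_dominance: float = 0.05
    intercept: float = 0.0
    n_sd_offspring: int = 500
    n_smgs_groups: int = 200
    daughters_per_group: tuple[int, int] = (20, 60)
    min_group_size: int = 20
    dominance_scale: str = "value"  # "value" (H) or "deviation" (M)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5] with lo <= hi")
        if self.n_snps < 1 or self.n_animals < 2:
            raise ValueError("need n_snps >= 1 and n_animals >= 2")
        if self.h2_additive < 0 or self.h2_dominance < 0:
            raise ValueError("heritabilities must be nonnegative")
        # equality gives a noiseless (sigma2_e = 0) configuration
        if self.h2_additive + self.h2_dominance > 1.0:
            raise ValueError("h2_additive + h2_dominance must not exceed 1")
        if self.dominance_scale not in ("value", "deviation"):
            raise ValueError("dominance_scale must be 'value' or 'deviation'")
        if self.n_smgs_groups > 0 and self.daughters_per_group[1] < 1:
            raise ValueError("daughters_per_group max must be >= 1")


@dataclass
class TruePopulation:
    """A simulated genotyped population plus its generative ground truth."""

    genotypes: GenotypeMatrix
    allele_freqs: AlleleFrequencies  # the true (drawn) frequencies
    true_additive_effects: np.ndarray | None = None
    true_dominance_effects: np.ndarray | None = None
    true_bv: np.ndarray | None = None
    true_dominance_values: np.ndarray | None = None
    phenotypes: np.ndarray | None = None
    realized_variances: tuple[float, float, float] | None = None
    sd_records: pd.DataFrame | None = None
    smgs_records: pd.DataFrame | None = None
    sd_true_codes: np.ndarray | None = field(default=None, repr=False)

    def phenotype_frame(self) -> pd.DataFrame:
        """Phenotype table over all groups (C, SD, SMGS)."""
        frames = [
            pd.DataFrame(
                {
                    "id": self.genotypes.ids,
                    "group": "C",
                    "phenotype": self.phenotypes,
                    "n_daughters": 1,
                    "sire": "0",
                    "dam": "0",
                    "mgs": "0",
                }
            )
        ]
        if self.sd_records is not None and len(self.sd_records):
            frames.append(self.sd_records)
        if self.smgs_records is not None and len(self.smgs_records):
            frames.append(self.smgs_records[~self.smgs_records["excluded"]].drop(columns="excluded"))
        return pd.concat(frames, ignore_index=True)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent substream per stage so later stages don't perturb earlier ones
    return np.random.default_rng([config.seed, stage])


def simulate_genotypes(config: SimConfig) -> TruePopulation:
    """Draw per-SNP frequencies uniformly on maf_range, then HWE genotypes."""
    rng = _rng(config, 0)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    codes = rng.binomial(2, p, size=(config.n_animals, config.n_snps))
    ids = [f"C{i:06d}" for i in range(config.n_animals)]
    return TruePopulation(
        genotypes=GenotypeMatrix(ids=ids, codes=codes),
        allele_freqs=AlleleFrequencies(p),
    )


def simulate_phenotypes(pop: TruePopulation, config: SimConfig) -> TruePopulation:
    """Draw SNP effects and residuals; complete the population in place."""
    rng = _rng(config, 1)
    freqs = pop.allele_freqs
    coding = compute_codings(pop.genotypes, freqs)
    if coding.s_a <= 0:
        raise ValueError("all SNPs are monomorphic; cannot scale effects")

    sigma2_a = config.h2_additive
    sigma2_d = config.h2_dominance
    sigma2_e = 1.0 - sigma2_a - sigma2_d

    a = rng.normal(0.0, np.sqrt(sigma2_a / coding.s_a), size=coding.k)
    if config.dominance_scale == "value":
        W, s_w = coding.H, coding.s_h
    else:
        W, s_w = coding.M, coding.s_m
    if sigma2_d > 0:
        d = rng.normal(0.0, np.sqrt(sigma2_d / s_w), size=coding.k)
    else:
        d = np.zeros(coding.k)

    bv = coding.Z @ a
    dv = W @ d
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=coding.n) if sigma2_e > 0 else np.zeros(coding.n)

    pop.true_additive_effects = a
    pop.true_dominance_effects = d
    pop.true_bv = bv
    pop.true_dominance_values = dv
    pop.phenotypes = config.intercept + bv + dv + e
    pop.realized_variances = (
        float(np.var(bv, ddof=1)),
        float(np.var(dv, ddof=1)) if sigma2_d > 0 else 0.0,
        float(np.var(e, ddof=1)) if sigma2_e > 0 else 0.0,
    )
    return pop


def _transmit(rng: np.random.Generator, parent_codes: np.ndarray) -> np.ndarray:
    """One gamete per locus: allele B transmitted with probability code/2."""
    return rng.binomial(1, parent_codes / 2.0)


def simulate_descendant_groups(
    pop: TruePopulation, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate SD offspring and SMGS daughter groups from genotyped parents.

    SD offspring receive a true genotype by per-SNP Mendelian transmission
    (kept as a truth sidecar; the analyst sees only the parent ids) and an
    own phenotype.  Each SMGS group draws N daughters whose dam transmits
    an MGS allele with probability 1/2 and a population allele otherwise;
    the group phenotype is the daughter mean and N is recorded.  Groups with
    N below ``min_group_size`` are flagged for exclusion.
    """
    if pop.phenotypes is None:
        raise ValueError("population phenotypes must be simulated first")
    if config.n_smgs_groups > 0 and config.daughters_per_group[1] < 1:
        raise ValueError("daughters_per_group max must be >= 1")
    rng = _rng(config, 2)
    codes = pop.genotypes.codes
    ids = pop.genotypes.ids
    p = pop.allele_freqs.p
    a, d = pop.true_additive_effects, pop.true_dominance_effects
    sigma2_e = 1.0 - config.h2_additive - config.h2_dominance
    freqs = pop.allele_freqs

    def genetic_value(child_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gm = GenotypeMatrix(
            ids=[str(i) for i in range(child_codes.shape[0])], codes=child_codes
        )
        cs = compute_codings(gm, freqs)
        W = cs.H if config.dominance_scale == "value" else cs.M
        return cs.Z @ a, W @ d

    # --- sire-dam offspring -------------------------------------------------
    n_sd = config.n_sd_offspring
    sd_rows, sd_codes = [], None
    if n_sd > 0:
        sires = rng.integers(0, pop.genotypes.n, size=n_sd)
        dams = rng.integers(0, pop.genotypes.n, size=n_sd)
        sd_codes = _transmit(rng, codes[sires]) + _transmit(rng, codes[dams])
        bv, dv = genetic_value(sd_codes)
        e = rng.normal(0.0, np.sqrt(sigma2_e), size=n_sd) if sigma2_e > 0 else 0.0
        y = config.intercept + bv + dv + e
        sd_rows = pd.DataFrame(
            {
                "id": [f"SD{i:06d}" for i in range(n_sd)],
                "group": "SD",
                "phenotype": y,
                "n_daughters": 1,
                "sire": [ids[s] for s in sires],
                "dam": [ids[dm] for dm in dams],
                "mgs": "0",
            }
        )
    else:
        sd_rows = pd.DataFrame(
            columns=["id", "group", "phenotype", "n_daughters", "sire", "dam", "mgs"]
        )

    # --- sire-MGS daughter groups -------------------------------------------
    smgs_rows = []
    for g in range(config.n_smgs_groups):
        sire = int(rng.integers(0, pop.genotypes.n))
        mgs = int(rng.integers(0, pop.genotypes.n))
        lo, hi = config.daughters_per_group
        n_daughters = int(rng.integers(lo, hi + 1))
        sire_gam = _transmit(rng, np.tile(codes[sire], (n_daughters, 1)))
        from_mgs = rng.binomial(1, 0.5, size=(n_daughters, codes.shape[1]))
        mgs_gam = _transmit(rng, np.tile(codes[mgs], (n_daughters, 1)))
        popn_gam = rng.binomial(1, p, size=(n_daughters, codes.shape[1]))
        dam_gam = np.where(from_mgs == 1, mgs_gam, popn_gam)
        child = sire_gam + dam_gam
        bv, dv = genetic_value(child)
        e = (
            rng.normal(0.0, np.sqrt(sigma2_e), size=n_daughters)
            if sigma2_e > 0
            else np.zeros(n_daughters)
        )
        y = config.intercept + bv + dv + e
        smgs_rows.append(
            {
                "id": f"G{g:06d}",
                "group": "SMGS",
                "phenotype": float(np.mean(y)),
                "n_daughters": n_daughters,
                "sire": ids[sire],
                "dam": "0",
                "mgs": ids[mgs],
                "excluded": n_daughters < config.min_group_size,
            }
        )
    smgs = pd.DataFrame(
        smgs_rows,
        columns=["id", "group", "phenotype", "n_daughters", "sire", "dam", "mgs", "excluded"],
    )

    pop.sd_records = sd_rows
    pop.smgs_records = smgs
    pop.sd_true_codes = sd_codes
    return sd_rows, smgs


def simulate_population(config: SimConfig) -> TruePopulation:
    """Run all three stages: genotypes, phenotypes, descendant groups."""
    pop = simulate_genotypes(config)
    simulate_phenotypes(pop, config)
    if config.n_sd_offspring > 0 or config.n_smgs_groups > 0:
        simulate_descendant_groups(pop, config)
    return pop
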