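"""Synthetic genotype-phenotype cohorts with the structure the analysis assumes.

The generator emulates a genotyping-by-sequencing panel in an aquaculture
cohort: biallelic SNPs with a uniform MAF spectrum on [0.05, 0.5], strong
local (adjacent-marker) linkage disequilibrium, ~12% missingness injected
completely at random, a two-level sex fixed effect, and a sparse additive
QTL architecture.  Phenotypes follow

    y_i = mu + sex_k + sum_j X'_ij g_j + e_i

with QTL effects on the standardized-genotype scale and the residual variance
set so the genetic fraction of (TBV + residual) variance hits the target h².
True breeding values (TBV) are computed from pre-missingness genotypes, so
data-quality effects never leak into the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .genotype_data import GenotypeMatrix, PhenotypeTable, standardize

__all__ = [
    "SimulationConfig", "SimulatedCohort", "PRESETS", "preset",
    "simulate_genotypes", "simulate_phenotypes", "simulate_cohort",
    "true_accuracy", "write_cohort",
]


@dataclass
class SimulationConfig:
    """Cohort-generating parameters; presets carry the croaker-like values."""

    n: int = 500                 # individuals
    p: int = 2000                # markers
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 30
    h2: float = 0.6
    mu: float = 0.0              # overall mean, trait units
    sex_effect: float = 0.0      # level-2 (female) minus level-1 (male), trait units
    phenotype_sd: float = 1.0    # target phenotypic SD net of the sex effect
    effect_dist: str = "double-exponential"   # or "normal"
    missing_rate: float = 0.12
    ld: float = 0.0              # adjacent-marker allele-copy probability in [0, 1)
    null_residual_var: float = 1.0  # residual variance when h2 == 0
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ConfigurationError(f"h2={self.h2} outside [0, 1)")
        if self.n_qtl > self.p:
            raise ConfigurationError("n_qtl exceeds marker count")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not (0 <= self.ld < 1):
            raise ConfigurationError(f"ld={self.ld} outside [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate outside [0, 1)")
        if self.effect_dist not in ("double-exponential", "normal"):
            raise ConfigurationError(f"unknown effect_dist {self.effect_dist!r}")


# Croaker-like presets.  n, h² and split sizes mirror the study cohorts
# (growth traits n=500 with h²≈0.6; muscle n-3HUFA n=176 with h²≈0.44);
# intercepts, sex effects and phenotypic SDs come from its summary table.
# The marker panel is scaled to p=2000 with adjacent-marker LD 0.985 so the
# panel's redundancy (effective segments ≈ 1.5% of markers) matches the
# ~30k-SNP panel the study fitted, where effective locus counts were ~400.
PRESETS: dict[str, SimulationConfig] = {
    "bw": SimulationConfig(n=500, p=2000, n_qtl=30, h2=0.60, mu=202.22,
                           sex_effect=45.19, phenotype_sd=88.0, missing_rate=0.12,
                           ld=0.985, trait="body_weight"),
    "bl": SimulationConfig(n=500, p=2000, n_qtl=30, h2=0.59, mu=227.19,
                           sex_effect=7.66, phenotype_sd=27.0, missing_rate=0.12,
                           ld=0.985, trait="body_length"),
    "hufa": SimulationConfig(n=176, p=2000, n_qtl=10, h2=0.44, mu=23.50,
                             sex_effect=0.89, phenotype_sd=4.6, missing_rate=0.12,
                             ld=0.985, trait="n3hufa"),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """A copy of a named preset, optionally with fields overridden."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix       # with injected missingness
    phenotypes: PhenotypeTable
    true_codes: np.ndarray          # pre-missingness genotypes
    true_freqs: np.ndarray
    qtl_ids: list[str]
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray         # standardized scale
    tbv: np.ndarray
    realized_h2: float
    config: SimulationConfig


def simulate_genotypes(cfg: SimulationConfig):
    """Draw a genotype matrix; returns (GenotypeMatrix, true allele frequencies).

    Marker frequencies are uniform over the MAF range; genotypes are in HWE.
    First-order LD: each haplotype copies the previous marker's allele with
    probability ``cfg.ld``, else draws fresh at that marker's frequency.
    Missingness is injected completely at random.  The returned matrix keeps
    the true codes under the mask; the analysis pipeline must treat masked
    entries as unobserved.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.p)
    hap = np.empty((cfg.n, 2, cfg.p), dtype=np.int8)
    hap[:, :, 0] = rng.random((cfg.n, 2)) < freqs[0]
    for j in range(1, cfg.p):
        fresh = rng.random((cfg.n, 2)) < freqs[j]
        copy = rng.random((cfg.n, 2)) < cfg.ld
        hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
    codes = hap.sum(axis=1).astype(float)
    missing = rng.random((cfg.n, cfg.p)) < cfg.missing_rate
    width = len(str(cfg.p))
    markers = pd.DataFrame({
        "marker_id": [f"snp{j:0{width}d}" for j in range(cfg.p)],
        "chrom": "1",
        "pos": np.arange(1, cfg.p + 1) * 1000,
    })
    sample_ids = [f"fish{i:04d}" for i in range(cfg.n)]
    return GenotypeMatrix(sample_ids, markers, codes, missing), freqs


def simulate_phenotypes(g: GenotypeMatrix, true_freqs: np.ndarray,
                        cfg: SimulationConfig) -> SimulatedCohort:
    """Assemble phenotypes over simulated genotypes.

    QTL positions are sampled without replacement; effects are drawn from the
    configured distribution on the standardized scale and rescaled so the
    TBV variance equals h2 * phenotype_sd²; residuals make up the rest.
    Sexes alternate male/female so both levels are balanced at any n.
    TBV uses the pre-missingness codes carried by the simulated matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n, p = g.n_samples, g.n_markers
    if cfg.h2 > 0 and cfg.n_qtl == 0:
        raise ConfigurationError("h2 > 0 requires at least one QTL")

    sex = np.tile([1, 2], (n + 1) // 2)[:n]
    var_pheno = cfg.phenotype_sd**2

    if cfg.h2 > 0:
        qtl_idx = np.sort(rng.choice(p, size=cfg.n_qtl, replace=False))
        if cfg.effect_dist == "double-exponential":
            eff = rng.laplace(0.0, 1.0, size=cfg.n_qtl)
        else:
            eff = rng.normal(0.0, 1.0, size=cfg.n_qtl)
        x_std = standardize(g.codes[:, qtl_idx], freqs=true_freqs[qtl_idx])
        tbv = x_std @ eff
        scale = np.sqrt(cfg.h2 * var_pheno / tbv.var())
        eff, tbv = eff * scale, tbv * scale
        sigma_e2 = (1 - cfg.h2) / cfg.h2 * tbv.var()
    else:
        qtl_idx = np.array([], dtype=int)
        eff = np.array([])
        tbv = np.zeros(n)
        sigma_e2 = cfg.null_residual_var

    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    y = cfg.mu + np.where(sex == 2, cfg.sex_effect, 0.0) + tbv + e
    realized_h2 = float(tbv.var() / (tbv.var() + e.var())) if cfg.h2 > 0 else 0.0

    phen = PhenotypeTable(list(g.sample_ids), y, sex, trait=cfg.trait)
    return SimulatedCohort(
        genotypes=g,
        phenotypes=phen,
        true_codes=g.codes.copy(),
        true_freqs=np.asarray(true_freqs),
        qtl_ids=list(g.markers["marker_id"].iloc[qtl_idx]),
        qtl_indices=qtl_idx,
        qtl_effects=eff,
        tbv=tbv,
        realized_h2=realized_h2,
        config=cfg,
    )


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Genotypes + phenotypes in one call, fully determined by cfg.seed."""
    g, freqs = simulate_genotypes(cfg)
    return simulate_phenotypes(g, freqs, cfg)


def true_accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation r(ĝ, g) between predicted and true breeding values."""
    gebv, tbv = np.asarray(gebv, float), np.asarray(tbv, float)
    if gebv.shape != tbv.shape:
        raise ConfigurationError("gebv and tbv lengths differ")
    if gebv.std() == 0 or tbv.std() == 0:
        raise ConfigurationError("true_accuracy undefined: zero variance input")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def write_cohort(cohort: SimulatedCohort, prefix: str) -> None:
    """Write genotypes (matrix-text + sidecar), phenotypes and truth TSVs."""
    from .genotype_data import write_genotypes

    write_genotypes(cohort.genotypes, f"{prefix}.genotypes.tsv",
                    sidecar=f"{prefix}.markers.tsv")
    cohort.phenotypes.to_frame().to_csv(f"{prefix}.phenotypes.tsv", sep="\t", index=False)
    truth = pd.DataFrame({"sample_id": cohort.genotypes.sample_ids, "tbv": cohort.tbv})
    truth.to_csv(f"{prefix}.tbv.tsv", sep="\t", index=False)
    qtl = pd.DataFrame({"marker_id": cohort.qtl_ids, "effect": cohort.qtl_effects})
    qtl.to_csv(f"{prefix}.qtl.tsv", sep="\t", index=False)
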