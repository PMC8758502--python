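"""Synthetic cohorts with biobank-like statistical structure.

Real blood-cell-trait cohorts are access-controlled, so the pipeline is
exercised on generated data that reproduces the features the analysis relies
on: LD-block-structured genotypes across a MAF spectrum that includes
low-frequency variants, a polygenic trait architecture with optional
pairwise-product (interaction) terms, sex main effects, genetic-score-by-sex
interaction, sex-specific age trends, and a second cohort drawn from the same
effect model with its own genotype and noise sampling (the external-validation
role).

LD is produced by a block-equicorrelated latent-Gaussian threshold model: per
block, each haplotype's latent value is ``sqrt(r) * u + sqrt(1-r) * e`` with a
shared per-haplotype block factor ``u``, thresholded at the MAF quantile to an
allele.  Variants in different blocks are exactly independent; within a block
the latent correlation is ``within_block_r`` (the realized allelic/dosage
correlation is attenuated below the latent value by the thresholding, more so
at low MAF — see the methods note).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

__all__ = [
    "LDBlockSpec",
    "TraitArchitecture",
    "SimulatedCohort",
    "make_variant_panel",
    "simulate_genotypes",
    "random_architecture",
    "simulate_phenotype",
    "simulate_cohort",
    "make_external_cohort",
    "make_partitions",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclasses.dataclass
class LDBlockSpec:
    """Layout of the synthetic variant panel.

    ``within_block_r`` is the latent-Gaussian correlation shared by variants
    of a block; ``low_maf_fraction`` of variants draw their MAF from the low
    end of ``maf_range`` (below 0.05), emulating the low-MAF tail where
    univariate effect estimates are noisy.  ``ambiguous_fraction`` plants
    strand-ambiguous (A/T, G/C) allele pairs for exercising allele-matching;
    the default panel has none so scoring-side exclusions do not confound
    method comparisons.  INFO scores are drawn uniform on [0.4, 1] and
    ``missing_rate`` is applied uniformly at random to genotype calls.
    """

    n_blocks: int = 20
    block_size: int = 100
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.005, 0.5)
    low_maf_fraction: float = 0.2
    ambiguous_fraction: float = 0.0
    missing_rate: float = 0.0
    chrom: str = "1"
    block_gap_bp: int = 6_000_000
    variant_spacing_bp: int = 1_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclasses.dataclass
class TraitArchitecture:
    """Generative truth for one trait.

    ``additive_betas`` are per-dosage effects of the causal variants;
    ``interaction_pairs`` are (id, id, gamma) terms on centred dosage
    products; ``pgs_sex_interaction`` multiplies the standardized additive
    genetic value by sex, the generative twin of a PGSxSex regression term;
    ``age_slope_by_sex`` gives (female, male) slopes per year on centred age.
    ``target_h2`` is var(additive genetic) / var(phenotype | sex, age fixed).
    """

    causal_ids: list[str]
    additive_betas: np.ndarray
    interaction_pairs: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    sex_beta: float = 0.0
    pgs_sex_interaction: float = 0.0
    age_slope_by_sex: tuple[float, float] = (0.0, 0.0)
    target_h2: float = 0.3

    def __post_init__(self) -> None:
        self.additive_betas = np.asarray(self.additive_betas, dtype=float)
        if len(self.causal_ids) != len(self.additive_betas):
            raise ValueError("causal_ids and additive_betas lengths differ")
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in [0, 1)")


@dataclasses.dataclass
class SimulatedCohort:
    """One cohort: genotypes, phenotype, covariates and the stored truth."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    sex: np.ndarray          # 0 = female, 1 = male
    age: np.ndarray          # years
    pcs: np.ndarray          # n_samples x 10
    truth: TraitArchitecture
    genetic_value: np.ndarray  # realized additive genetic value per sample

    @property
    def n_samples(self) -> int:
        return len(self.phenotype)

    def covariate_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sex": self.sex, "age": self.age})
        for k in range(self.pcs.shape[1]):
            df[f"pc{k + 1}"] = self.pcs[:, k]
        return df

    def subset(self, index: np.ndarray) -> "SimulatedCohort":
        index = np.asarray(index)
        return SimulatedCohort(
            genotypes=self.genotypes.subset_samples(index),
            phenotype=self.phenotype[index],
            sex=self.sex[index],
            age=self.age[index],
            pcs=self.pcs[index],
            truth=self.truth,
            genetic_value=self.genetic_value[index],
        )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_variant_panel(spec: LDBlockSpec, seed: int) -> pd.DataFrame:
    """Draw the variant metadata panel (ids, positions, alleles, MAF, INFO).

    Blocks are laid consecutively on one chromosome with a gap larger than
    5 Mb, so each LD block is also a conditional-analysis block under the
    default partition rule.
    """
    rng = _rng(seed)
    m = spec.n_blocks * spec.block_size
    lo, hi = spec.maf_range
    low_cut = min(0.05, hi)
    if lo < low_cut and spec.low_maf_fraction > 0:
        is_low = rng.random(m) < spec.low_maf_fraction
        maf = np.where(
            is_low,
            rng.uniform(lo, low_cut, m),
            rng.uniform(low_cut, hi, m),
        )
    else:
        maf = rng.uniform(lo, hi, m)
    a1 = rng.choice(_BASES, size=m)
    a2 = np.empty(m, dtype="<U1")
    make_ambiguous = rng.random(m) < spec.ambiguous_fraction
    for j in range(m):
        if make_ambiguous[j]:
            a2[j] = _COMPLEMENT[a1[j]]
        else:
            choices = [b for b in _BASES if b != a1[j] and b != _COMPLEMENT[a1[j]]]
            a2[j] = choices[rng.integers(len(choices))]
    block = np.repeat(np.arange(spec.n_blocks), spec.block_size)
    within = np.tile(np.arange(spec.block_size), spec.n_blocks)
    pos = 1 + block * spec.block_gap_bp + within * spec.variant_spacing_bp
    return pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(m)],
            "chrom": spec.chrom,
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "maf": maf,
            "info": rng.uniform(0.4, 1.0, m),
            "missing_rate": spec.missing_rate,
            "block": block,
        }
    )


def simulate_genotypes(
    spec: LDBlockSpec,
    n_samples: int,
    seed: int,
    panel: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Draw additive dosages under the block-equicorrelated threshold model.

    With ``panel`` given (e.g. the training cohort's panel), only genotypes
    are redrawn — the variant identities, MAFs and block structure are
    shared, which is how the external cohort stays on the same panel.
    """
    if n_samples < 2:
        raise ValueError(f"need n_samples >= 2, got {n_samples}")
    rng = _rng(seed)
    if panel is None:
        panel = make_variant_panel(spec, seed=rng.integers(2**31))
    m = len(panel)
    maf = panel["maf"].to_numpy()
    block = panel["block"].to_numpy()
    r = spec.within_block_r
    thresh = stats.norm.ppf(maf)  # latent below threshold -> minor (A1) allele
    dosages = np.zeros((n_samples, m))
    for hap in range(2):
        u = rng.standard_normal((n_samples, spec.n_blocks))
        e = rng.standard_normal((n_samples, m))
        z = np.sqrt(r) * u[:, block] + np.sqrt(1.0 - r) * e
        dosages += (z < thresh[None, :]).astype(float)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(dosages, panel.copy(), [f"s{i}" for i in range(n_samples)])


def random_architecture(
    panel: pd.DataFrame,
    n_causal: int,
    seed: int,
    low_maf_causal_fraction: float = 0.2,
    target_h2: float = 0.3,
    n_interactions: int = 0,
    interaction_gamma: float = 0.5,
    sex_beta: float = 0.0,
    pgs_sex_interaction: float = 0.0,
    age_slope_by_sex: tuple[float, float] = (0.0, 0.0),
) -> TraitArchitecture:
    """Draw a causal architecture: which variants act, and how strongly.

    A stated fraction of causal variants is drawn from the low-MAF pool
    (MAF < 0.05) so that method comparisons see the noisy-estimate regime.
    Additive betas are drawn standard normal per causal variant, then
    rescaled so the additive genetic value has approximately unit variance
    (sum of beta^2 * 2f(1-f) = 1 under independence).  Heritability fixes
    the noise scale relative to the genetic signal either way; the
    normalization just keeps trait units interpretable, so sex and
    interaction coefficients of order 0.1-1 are visible effects.
    """
    rng = _rng(seed)
    maf = panel["maf"].to_numpy()
    low_pool = np.flatnonzero(maf < 0.05)
    high_pool = np.flatnonzero(maf >= 0.05)
    n_low = min(int(round(low_maf_causal_fraction * n_causal)), len(low_pool))
    n_high = min(n_causal - n_low, len(high_pool))
    chosen = np.concatenate([
        rng.choice(low_pool, size=n_low, replace=False),
        rng.choice(high_pool, size=n_high, replace=False),
    ])
    chosen.sort()
    ids = panel["id"].to_numpy()[chosen].tolist()
    betas = rng.standard_normal(len(chosen))
    f = maf[chosen]
    scale = np.sqrt(np.sum(betas**2 * 2.0 * f * (1.0 - f)))
    if scale > 0:
        betas = betas / scale
    pairs: list[tuple[str, str, float]] = []
    if n_interactions > 0:
        for _ in range(n_interactions):
            i, j = rng.choice(len(ids), size=2, replace=False)
            pairs.append((ids[int(i)], ids[int(j)], interaction_gamma))
    return TraitArchitecture(
        causal_ids=ids,
        additive_betas=betas,
        interaction_pairs=pairs,
        sex_beta=sex_beta,
        pgs_sex_interaction=pgs_sex_interaction,
        age_slope_by_sex=age_slope_by_sex,
        target_h2=target_h2,
    )


def simulate_phenotype(
    g: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int,
    age_range: tuple[float, float] = (40.0, 70.0),
    noise_var: float | None = None,
) -> SimulatedCohort:
    """Realize phenotypes over a genotype draw.

    phenotype = additive genetic value + centred-product interaction terms
    + sex, age and genetic-score-by-sex terms + Gaussian noise, with the
    noise variance chosen so that var(additive) / var(additive +
    interaction + noise) equals the architecture's target heritability
    (``noise_var`` overrides that calibration when given, e.g. to force a
    noiseless deterministic limit).
    """
    rng = _rng(seed)
    ids = list(g.variants["id"])
    col = {v: j for j, v in enumerate(ids)}
    missing_causal = [v for v in arch.causal_ids if v not in col]
    if missing_causal:
        raise ValueError(f"causal variants absent from genotypes: {missing_causal[:5]}")
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("genotypes contain missing calls; mean-impute first")
    n = d.shape[0]

    causal_cols = [col[v] for v in arch.causal_ids]
    g_add = d[:, causal_cols] @ arch.additive_betas

    g_int = np.zeros(n)
    for v1, v2, gamma in arch.interaction_pairs:
        x1 = d[:, col[v1]] - d[:, col[v1]].mean()
        x2 = d[:, col[v2]] - d[:, col[v2]].mean()
        g_int += gamma * x1 * x2

    var_add = float(np.var(g_add))
    var_int = float(np.var(g_int))
    if noise_var is None:
        h2 = arch.target_h2
        if h2 == 0.0:
            if var_add > 0:
                raise ValueError("target_h2 = 0 with nonzero additive effects")
            noise_var = 1.0
        else:
            noise_var = var_add * (1.0 - h2) / h2 - var_int
            if noise_var < 0:
                raise ValueError(
                    "interaction variance exceeds the budget left by target_h2"
                )

    sex = rng.integers(0, 2, n).astype(float)  # male = 1
    age = rng.uniform(*age_range, n)
    age_c = age - age.mean()
    pcs = rng.standard_normal((n, 10))

    g_std = np.std(g_add)
    g_scaled = (g_add - g_add.mean()) / g_std if g_std > 0 else np.zeros(n)
    y = (
        g_add
        + g_int
        + arch.sex_beta * sex
        + arch.pgs_sex_interaction * g_scaled * sex
        + np.where(sex == 1, arch.age_slope_by_sex[1], arch.age_slope_by_sex[0]) * age_c
        + rng.normal(0.0, np.sqrt(noise_var), n)
    )
    return SimulatedCohort(
        genotypes=g,
        phenotype=y,
        sex=sex,
        age=age,
        pcs=pcs,
        truth=arch,
        genetic_value=g_add,
    )


def simulate_cohort(
    spec: LDBlockSpec,
    arch: TraitArchitecture,
    n_samples: int,
    seed: int,
    panel: pd.DataFrame | None = None,
    **phenotype_kwargs,
) -> SimulatedCohort:
    """Genotypes plus phenotype in one call (seeds derived deterministically)."""
    rng = _rng(seed)
    g = simulate_genotypes(spec, n_samples, seed=int(rng.integers(2**31)), panel=panel)
    return simulate_phenotype(g, arch, seed=int(rng.integers(2**31)), **phenotype_kwargs)


def make_external_cohort(
    arch: TraitArchitecture,
    spec: LDBlockSpec,
    n: int,
    seed: int,
    panel: pd.DataFrame,
    age_range: tuple[float, float] = (40.0, 70.0),
) -> SimulatedCohort:
    """A second cohort under the same truth: fresh genotype and noise draws.

    ``panel`` must be the training cohort's variant panel so both cohorts
    share variant identities; ``age_range`` allows a covariate-distribution
    shift (the external cohort may span different ages), which is a modelling
    knob of this generator, not a claim about any particular study pair.
    """
    if n < 2:
        raise ValueError(f"external cohort needs n >= 2, got {n}")
    return simulate_cohort(spec, arch, n, seed, panel=panel, age_range=age_range)


def make_partitions(
    n_samples: int, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random equal split into k portions; fold i trains on the other k-1.

    Test sets are pairwise disjoint, cover every sample exactly once, and
    differ in size by at most 1.
    """
    if k > n_samples:
        raise ValueError(f"cannot make {k} partitions from {n_samples} samples")
    rng = _rng(seed)
    perm = rng.permutation(n_samples)
    test_sets = np.array_split(perm, k)
    folds = []
    for i in range(k):
        test = np.sort(test_sets[i])
        train = np.sort(np.concatenate([test_sets[j] for j in range(k) if j != i]))
        folds.append((train, test))
    return folds
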