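"""Disease PGS derivation and the cross-trait genetic-correlation scan.

A disease score is built from external-style summary statistics by filtering
to variants that (in order) overlap a high-confidence reference panel,
survive LD thinning at r² < 0.9, have imputation INFO > 0.4 and MAF > 1%,
and are not strand-ambiguous (A/T and G/C SNPs excluded); published
log-odds/betas are used verbatim as weights.  Scoring substitutes the
expected dosage (2 x effect-allele frequency) for missing genotype calls and
standardizes the final scores to mean 0, SD 1.

The correlation scan residualizes every trait and disease score on the first
10 principal components, then tests all trait-by-disease Pearson
correlations against a Bonferroni threshold derived from the realized number
of tests.  Correlations are between scores across samples (not an LD-score
genetic correlation): shared causal architecture induces score-score
correlation, which ``plant_shared_architecture`` provides the synthetic twin
for.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, match_alleles
from .simcohort import TraitArchitecture
from . import assoc
from .pgs_methods import PGSModel

logger = logging.getLogger("polyscore.crosstrait")

__all__ = [
    "DiseaseScoringSpec",
    "CorrelationScanResult",
    "derive_disease_model",
    "score_with_frequency_substitution",
    "pc_adjust",
    "correlation_scan",
    "plant_shared_architecture",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclasses.dataclass
class DiseaseScoringSpec:
    """Summary statistics plus the reference panel and filter thresholds.

    ``sumstats`` needs columns id, chrom, pos, effect_allele, other_allele,
    beta, info.  ``reference`` supplies the overlap panel, the genotypes LD
    thinning runs on, and the MAFs the common-variant filter uses.
    """

    sumstats: pd.DataFrame
    reference: GenotypeMatrix
    ld_r2: float = 0.9
    info_min: float = 0.4
    maf_min: float = 0.01


@dataclasses.dataclass
class CorrelationScanResult:
    trait: str
    disease: str
    r: float
    p: float
    significant: bool


def derive_disease_model(spec: DiseaseScoringSpec) -> PGSModel:
    """Filter summary statistics to scoring variants; weights copied verbatim.

    Filters apply in order — overlap with the reference panel, LD thinning
    at r² < ``ld_r2``, INFO > ``info_min``, MAF > ``maf_min`` (strict, as
    printed), strand-ambiguity exclusion — and the per-filter attrition is
    recorded in the model provenance.
    """
    ss = spec.sumstats.reset_index(drop=True)
    attrition = [f"input={len(ss)}"]

    ref_ids = set(spec.reference.variants["id"])
    keep = ss["id"].isin(ref_ids)
    attrition.append(f"overlap: removed {int((~keep).sum())}")
    ss = ss[keep]

    thinned = assoc.ld_thin(spec.reference, r2=spec.ld_r2,
                            candidate_ids=ss["id"].tolist())
    keep = ss["id"].isin(set(thinned.ids))
    attrition.append(f"ld_thin r2<{spec.ld_r2}: removed {int((~keep).sum())}")
    ss = ss[keep]

    keep = ss["info"].to_numpy(dtype=float) > spec.info_min
    attrition.append(f"info>{spec.info_min}: removed {int((~keep).sum())}")
    ss = ss[keep]

    ref_maf = spec.reference.variants.set_index("id")["maf"]
    maf = ref_maf.reindex(ss["id"]).to_numpy(dtype=float)
    keep = maf > spec.maf_min
    attrition.append(f"maf>{spec.maf_min}: removed {int((~keep).sum())}")
    ss = ss[keep]

    ambiguous = np.array([
        _COMPLEMENT.get(ea) == oa
        for ea, oa in zip(ss["effect_allele"], ss["other_allele"])
    ])
    attrition.append(f"ambiguous: removed {int(ambiguous.sum())}")
    ss = ss[~ambiguous]

    attrition.append(f"output={len(ss)}")
    if len(ss) == 0:
        raise ValueError(f"no variants survive filtering ({'; '.join(attrition)})")
    return PGSModel(
        ids=ss["id"].astype(str).tolist(),
        effect_alleles=ss["effect_allele"].tolist(),
        other_alleles=ss["other_allele"].tolist(),
        chroms=ss["chrom"].astype(str).tolist(),
        positions=ss["pos"].astype(int).tolist(),
        weights=ss["beta"].to_numpy(dtype=float),
        method="disease",
        provenance="; ".join(attrition),
    )


def score_with_frequency_substitution(
    model: PGSModel,
    g: GenotypeMatrix,
    eaf: Mapping[str, float] | pd.Series,
) -> np.ndarray:
    """Weighted dosage sum with expected-dosage substitution, then z-scored.

    A missing genotype contributes ``2 * eaf * weight`` — the expected
    effect-allele dosage under Hardy-Weinberg at the stated effect-allele
    frequency.  Final scores are standardized to mean 0, SD 1 across
    samples.
    """
    match = match_alleles(model.to_scoring_frame(), g)
    if len(match.genotype_index) == 0:
        raise ValueError("no model variants matched the genotype panel")
    matched_ids = [g.variants["id"].iat[j] for j in match.genotype_index]
    missing_eaf = [v for v in matched_ids if v not in eaf]
    if missing_eaf:
        raise KeyError(f"no effect-allele frequency for: {missing_eaf[:10]}")
    d = match.effective_dosages(g)
    fill = np.array([2.0 * float(eaf[v]) for v in matched_ids])
    nan_mask = np.isnan(d)
    d[nan_mask] = np.broadcast_to(fill, d.shape)[nan_mask]
    raw = d @ match.weight
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero score variance; cannot standardize")
    return (raw - raw.mean()) / sd


def pc_adjust(scores: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """Residualize scores on an intercept plus the principal components."""
    scores = np.asarray(scores, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    X = np.column_stack([np.ones(len(scores)), pcs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient principal-component matrix")
    beta, _, _, _ = np.linalg.lstsq(X, scores, rcond=None)
    return scores - X @ beta


def correlation_scan(
    trait_scores: Mapping[str, np.ndarray],
    disease_scores: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    sample_ids: Sequence | None = None,
) -> list[CorrelationScanResult]:
    """All trait-by-disease Pearson correlations with Bonferroni control.

    Scores must be PC-adjusted and in identical sample order; the
    significance threshold is ``alpha / (n_traits * n_diseases)``, derived
    from the realized number of tests.  P-values use the t reference for a
    correlation coefficient.
    """
    lengths = {len(v) for v in trait_scores.values()} | {
        len(v) for v in disease_scores.values()
    }
    if len(lengths) != 1:
        raise ValueError("score vectors differ in length (sample-order mismatch?)")
    n = lengths.pop()
    if sample_ids is not None and len(sample_ids) != n:
        raise ValueError("sample_ids length does not match score vectors")
    n_tests = len(trait_scores) * len(disease_scores)
    threshold = alpha / n_tests
    out: list[CorrelationScanResult] = []
    for t_name, t in trait_scores.items():
        for d_name, d in disease_scores.items():
            r = float(np.corrcoef(t, d)[0, 1])
            df = n - 2
            denom = max(1.0 - r * r, np.finfo(float).tiny)
            with np.errstate(over="ignore"):
                tstat = r * np.sqrt(df / denom)
            p = float(np.clip(2.0 * stats.t.sf(abs(tstat), df),
                              np.nextafter(0, 1), 1.0))
            out.append(CorrelationScanResult(
                trait=t_name, disease=d_name, r=r, p=p,
                significant=bool(p < threshold),
            ))
    return out


def plant_shared_architecture(
    arch_trait: TraitArchitecture,
    overlap_fraction: float,
    seed: int,
    panel: pd.DataFrame,
    effect_correlation: float = 1.0,
) -> TraitArchitecture:
    """A disease architecture sharing a stated fraction of causal variants.

    The shared causal variants keep effects correlated with the trait's
    (``effect_correlation`` = 1 copies them exactly); the remainder are
    fresh draws from the panel with independent effects.  Raising the
    overlap raises the expected correlation between the two traits' scores.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_causal = len(arch_trait.causal_ids)
    n_shared = int(round(overlap_fraction * n_causal))
    shared_idx = rng.choice(n_causal, size=n_shared, replace=False)
    shared_ids = [arch_trait.causal_ids[i] for i in shared_idx]
    rho = effect_correlation
    shared_betas = (
        rho * arch_trait.additive_betas[shared_idx]
        + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal(n_shared)
    )
    pool = [v for v in panel["id"] if v not in set(arch_trait.causal_ids)]
    n_new = n_causal - n_shared
    if n_new > len(pool):
        raise ValueError("panel too small for the requested non-shared causal count")
    new_ids = list(rng.choice(pool, size=n_new, replace=False))
    new_betas = rng.standard_normal(n_new)
    return TraitArchitecture(
        causal_ids=shared_ids + new_ids,
        additive_betas=np.concatenate([shared_betas, new_betas]),
        target_h2=arch_trait.target_h2,
    )
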