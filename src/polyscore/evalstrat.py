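"""Evaluation protocol, quantile stratification and the PGS-by-sex test.

The benchmark follows the 5-partition protocol: the training cohort is split
into five equal portions; each fold trains on four portions (80%) and is
tested on the held-out portion, plus an external validation on the whole
second cohort.  Performance is the Pearson correlation between predicted
score and (covariate-adjusted) trait, with the mean over the five folds as
the headline number and per-fold values kept for dispersion.

Stratification ranks samples into score quantiles (quintiles by default, or
top/bottom percentiles) and fits, per sex-by-quantile group, a penalized
cubic regression spline of trait on age with the penalty weight chosen by
generalized cross-validation — a GAM smooth with pointwise 95% bands.

The sex-interaction model is ``y = b0 + b1*PGS + b2*Sex + b3*PGS*Sex`` with
the PGS standardized to unit variance and ``y`` adjusted for age and the
first 10 principal components but NOT for sex (sex enters the model itself).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix
from .simcohort import SimulatedCohort, make_partitions
from . import assoc
from . import pgs_methods as pm

logger = logging.getLogger("polyscore.eval")

__all__ = [
    "EvalResult",
    "SexInteractionResult",
    "TrajectoryFit",
    "pearson_r",
    "run_benchmark",
    "summarize_benchmark",
    "quantile_stratify",
    "select_extremes",
    "fit_trajectories",
    "sex_interaction_test",
]

#: Covariates regressed out of the trait before association and evaluation.
DEFAULT_COVARIATES = ("sex", "age") + tuple(f"pc{i}" for i in range(1, 11))
#: Covariates for the sex-interaction model's adjusted trait (sex excluded).
SEX_TEST_COVARIATES = ("age",) + tuple(f"pc{i}" for i in range(1, 11))


@dataclasses.dataclass
class EvalResult:
    method: str
    variant_set: str
    fold: int  # 1-based
    internal_r: float
    external_r: float
    n_train: int
    n_test: int
    error: str | None = None


@dataclasses.dataclass
class SexInteractionResult:
    beta_pgs: float
    beta_sex: float
    beta_interaction: float
    se_pgs: float
    se_sex: float
    se_interaction: float
    p_pgs: float
    p_sex: float
    p_interaction: float
    pgs_standardized: bool = True


@dataclasses.dataclass
class TrajectoryFit:
    sex: int
    quantile: int
    ages: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int
    penalty: float


def pearson_r(pred: np.ndarray, obs: np.ndarray) -> float:
    """Sample Pearson correlation; errors on constant input."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(pred) < 3:
        raise ValueError("need equal-length vectors of at least 3")
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(pred, obs)[0, 1])


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

MethodSpec = str | Callable


def _fit_builtin(
    name: str,
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    sumstats: pd.DataFrame,
    vset: assoc.VariantSet,
    seed: int,
    configs: Mapping,
):
    if name == "pt":
        return pm.fit_pt(sumstats, vset)
    if name == "en":
        return pm.fit_en(g_train, y_train, configs.get("en"), seed=seed, variant_set=vset)
    if name == "br":
        return pm.fit_br(g_train, y_train, configs.get("br"), seed=seed, variant_set=vset)
    if name == "mlp":
        return pm.fit_mlp(g_train, y_train, configs.get("mlp"), seed=seed, variant_set=vset)
    if name == "mixture":
        cfg = configs.get("mixture") or pm.MixtureConfig()
        R, sd_x = pm.ld_reference(g_train, vset.ids, subsample=cfg.ld_ref_subsample,
                                  seed=seed)
        ss = sumstats.set_index("id").loc[vset.ids].reset_index()
        g_set = g_train.subset_variants(vset.ids)
        return pm.fit_mixture_gibbs(
            ss, R, cfg, n_gwas=g_train.n_samples, seed=seed,
            sd_x=sd_x, sd_y=float(np.std(y_train)),
            validation=(g_set, y_train),
        )
    raise ValueError(f"unknown method {name!r}")


def _predict(model, g: GenotypeMatrix) -> np.ndarray:
    if isinstance(model, pm.PGSModel):
        return pm.predict_scores(model, g)
    return model.predict(g)


def run_benchmark(
    cohort: SimulatedCohort,
    external: SimulatedCohort,
    methods: Sequence[str] | Mapping[str, Callable],
    variant_sets: Mapping[str, assoc.VariantSet],
    seed: int = 0,
    k: int = 5,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    configs: Mapping | None = None,
) -> list[EvalResult]:
    """Train every (method, variant set) on each of the 5 folds and score it.

    A method is a builtin name (``pt``, ``en``, ``br``, ``mixture``,
    ``mlp``) or a custom callable ``f(g_train, y_train, sumstats, vset,
    seed) -> model``; models are scored with Pearson r against the adjusted
    trait on the held-out fold and on the full external cohort.  Fit
    failures are recorded per cell and the benchmark continues.
    """
    configs = configs or {}
    if isinstance(methods, Mapping):
        method_items = list(methods.items())
    else:
        method_items = [(name, None) for name in methods]

    y_adj = assoc.adjust_phenotype(cohort, covariates)
    y_ext = assoc.adjust_phenotype(external, covariates)
    g_ext = external.genotypes
    folds = make_partitions(cohort.n_samples, k=k, seed=seed)
    results: list[EvalResult] = []
    for fold_i, (train, test) in enumerate(folds, start=1):
        g_train = cohort.genotypes.subset_samples(train)
        g_test = cohort.genotypes.subset_samples(test)
        y_train, y_test = y_adj[train], y_adj[test]
        sumstats = assoc.run_gwas(g_train, y_train)
        for name, custom in method_items:
            for set_name, vset in variant_sets.items():
                try:
                    if custom is not None:
                        model = custom(g_train, y_train, sumstats, vset, seed)
                    else:
                        model = _fit_builtin(name, g_train, y_train, sumstats,
                                             vset, seed, configs)
                    r_int = pearson_r(_predict(model, g_test), y_test)
                    r_ext = pearson_r(_predict(model, g_ext), y_ext)
                    results.append(EvalResult(name, set_name, fold_i, r_int, r_ext,
                                              len(train), len(test)))
                except Exception as exc:  # recorded, benchmark continues
                    logger.warning("fit failed: %s/%s fold %d: %s",
                                   name, set_name, fold_i, exc)
                    results.append(EvalResult(name, set_name, fold_i,
                                              np.nan, np.nan,
                                              len(train), len(test), error=str(exc)))
    return results


def summarize_benchmark(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Mean internal/external r over folds per (method, variant set)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    return (
        df.groupby(["method", "variant_set"])[["internal_r", "external_r"]]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def quantile_stratify(
    scores: np.ndarray, q: int, sample_ids: Sequence | None = None
) -> np.ndarray:
    """Rank samples into q near-equal groups (0 = lowest scores).

    Group sizes differ by at most one.  Ties in score break
    deterministically by sample id (or by index when ids are absent).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if q < 2:
        raise ValueError("need q >= 2")
    if n < q:
        raise ValueError(f"cannot form {q} groups from {n} samples")
    if sample_ids is None:
        sample_ids = np.arange(n)
    order = sorted(range(n), key=lambda i: (scores[i], str(sample_ids[i])))
    if len(np.unique(scores)) < n:
        logger.info("score ties broken by sample id")
    sizes = np.full(q, n // q)
    sizes[: n % q] += 1
    assignment = np.empty(n, dtype=int)
    start = 0
    for grp, size in enumerate(sizes):
        for i in order[start : start + size]:
            assignment[i] = grp
        start += size
    return assignment


def select_extremes(scores: np.ndarray, percent: float,
                    sample_ids: Sequence | None = None):
    """Indices of the bottom and top ``percent``% of scores (at least 1 each)."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if sample_ids is None:
        sample_ids = np.arange(n)
    k = max(1, int(round(n * percent / 100.0)))
    order = sorted(range(n), key=lambda i: (scores[i], str(sample_ids[i])))
    return np.asarray(order[:k]), np.asarray(order[-k:])


# ---------------------------------------------------------------------------
# Age trajectories (GAM smooths)
# ---------------------------------------------------------------------------

def _gam_smooth(age: np.ndarray, trait: np.ndarray, n_grid: int = 100,
                df: int = 8):
    """Penalized cubic B-spline of trait on age, penalty chosen by GCV.

    Returns (grid, fitted, se, penalty).  The grid spans only the observed
    age range.
    """
    from statsmodels.gam.api import GLMGam, BSplines

    age = np.asarray(age, dtype=float)
    trait = np.asarray(trait, dtype=float)
    df = min(df, max(4, len(age) // 10))
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    bs = BSplines(age[:, None], df=[df], degree=[3])
    n = len(age)
    grid = np.linspace(age.min(), age.max(), n_grid)
    design = np.column_stack([np.ones(n_grid), bs.transform(grid[:, None])])
    try:
        gam = GLMGam(trait, exog=np.ones((n, 1)), smoother=bs, alpha=[1.0])
        gam.scale = None  # required before penalty-weight selection in this API
        try:
            alpha = gam.select_penweight(criterion="gcv")[0]
        except Exception:
            alpha = [1.0]
        res = GLMGam(trait, exog=np.ones((n, 1)), smoother=bs, alpha=alpha).fit()
        params, cov = res.params, res.cov_params()
        penalty = float(np.atleast_1d(alpha)[0])
    except PerfectSeparationError:
        # noiseless trait: the penalized IRLS refuses a perfect fit, but the
        # unpenalized basis regression reproduces it exactly with zero bands
        X = np.column_stack([np.ones(n), bs.transform(age[:, None])])
        params = np.linalg.lstsq(X, trait, rcond=None)[0]
        resid = trait - X @ params
        dof = max(n - X.shape[1], 1)
        cov = (resid @ resid / dof) * np.linalg.pinv(X.T @ X)
        penalty = 0.0
    fitted = design @ params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", design, cov, design), 0.0))
    return grid, fitted, se, penalty


def fit_trajectories(
    cohort: SimulatedCohort,
    assignment: np.ndarray,
    trait: np.ndarray | None = None,
    min_n: int = 30,
) -> list[TrajectoryFit]:
    """Per (sex, quantile) group, a GAM smooth of trait on age with 95% bands.

    Groups below ``min_n`` samples are skipped with a warning.  Bands are
    pointwise (fitted +- 1.96 se), defined only within each group's observed
    age range.
    """
    if trait is None:
        trait = cohort.phenotype
    trait = np.asarray(trait, dtype=float)
    out: list[TrajectoryFit] = []
    for sex in (0, 1):
        for grp in np.unique(assignment):
            mask = (cohort.sex == sex) & (assignment == grp)
            n = int(mask.sum())
            if n < min_n:
                logger.warning("group sex=%d quantile=%d has n=%d < %d; skipped",
                               sex, grp, n, min_n)
                continue
            grid, fitted, se, alpha = _gam_smooth(cohort.age[mask], trait[mask])
            out.append(TrajectoryFit(
                sex=sex, quantile=int(grp), ages=grid, fitted=fitted,
                lower=fitted - 1.96 * se, upper=fitted + 1.96 * se,
                n=n, penalty=alpha,
            ))
    return out


# ---------------------------------------------------------------------------
# PGS-by-sex interaction
# ---------------------------------------------------------------------------

def sex_interaction_test(
    cohort: SimulatedCohort,
    scores: np.ndarray,
    adjusted_y: np.ndarray | None = None,
) -> SexInteractionResult:
    """Fit y = b0 + b1*PGS + b2*Sex + b3*PGS*Sex with the PGS standardized.

    ``y`` is the trait adjusted for age and the first 10 PCs — NOT for sex,
    which enters the model itself.  Two-sided t p-values per coefficient;
    the Bonferroni family threshold belongs to the caller (it depends on how
    many traits the run tests).
    """
    sex = np.asarray(cohort.sex, dtype=float)
    if len(np.unique(sex)) < 2:
        raise ValueError("single-sex cohort: interaction model unidentifiable")
    if adjusted_y is None:
        adjusted_y = assoc.adjust_phenotype(cohort, SEX_TEST_COVARIATES)
    scores = np.asarray(scores, dtype=float)
    if np.std(scores) == 0:
        raise ValueError("constant scores cannot be standardized")
    z = (scores - scores.mean()) / scores.std()
    n = len(z)
    X = np.column_stack([np.ones(n), z, sex, z * sex])
    beta, se, p, rank = assoc._ols_t(X, np.asarray(adjusted_y, dtype=float))
    if rank < 4:
        raise ValueError("rank-deficient interaction design")
    return SexInteractionResult(
        beta_pgs=float(beta[1]), beta_sex=float(beta[2]),
        beta_interaction=float(beta[3]),
        se_pgs=float(se[1]), se_sex=float(se[2]), se_interaction=float(se[3]),
        p_pgs=float(p[1]), p_sex=float(p[2]), p_interaction=float(p[3]),
    )
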