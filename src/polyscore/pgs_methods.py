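"""The five polygenic scoring estimators.

Every estimator emits (or mirrors) the same exchange object, :class:`PGSModel`
— an ordered set of (variant, effect allele, per-dosage weight) — so a score
is always the weighted sum of effect-allele dosages,

    PGS_i = sum_j beta_j * x_ij.

Estimators:

* **P+T** — weights copied verbatim from the univariate GWAS betas of a
  pruned/thresholded variant set; no refitting.
* **Elastic net (EN)** — joint weights minimizing
  ``sum_i (y_i - PGS_i)^2 + s*mix*sum|b_j| + s*(1-mix)/2*sum b_j^2``
  with the L1/L2 mixing fraction fixed at 0.5 and the overall strength ``s``
  tuned on a held-out 10% validation split.  Coordinate descent is delegated
  to scikit-learn (the exact scale mapping is ``alpha = s/(2n)``,
  ``l1_ratio = mix`` on the standardized design); the KKT optimality check
  against the objective above is implemented independently here.
* **Bayesian ridge (BR)** — Gaussian likelihood with precision ``alpha`` and
  spherical Gaussian weight prior with precision ``lambda``, both under
  Gamma hyperpriors; fitted by evidence maximization alternating the
  closed-form posterior mean (a ridge solve with shrinkage ``lambda/alpha``)
  with MacKay-style precision updates; the Gamma-hyperparameter grid is
  scored on the validation split.
* **Gaussian-mixture posterior (LDpred-style)** — spike-and-slab prior
  ``beta_j ~ N(0, h2/(M p))`` with probability ``p``, else 0; the posterior
  over standardized effects given marginal GWAS effects and an LD matrix is
  sampled by Gibbs, and the posterior-mean weights are used; (h2, p) chosen
  on a validation cohort.
* **MLP** — a small feed-forward network (weighted linear sums followed by an
  activation at each neuron) trained by full-batch gradient descent on
  squared loss; deliberately minimal and numpy-only.  Its fitted function is
  generally nonlinear, hence not expressible as a PGSModel; it exposes the
  same ``predict`` interface instead.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from .io_formats import GenotypeMatrix, match_alleles
from .assoc import VariantSet

logger = logging.getLogger("polyscore.pgs")

__all__ = [
    "PGSModel",
    "ENConfig",
    "BRConfig",
    "MixtureConfig",
    "MLPConfig",
    "MLPPredictor",
    "predict_scores",
    "fit_pt",
    "fit_en",
    "fit_br",
    "fit_mixture_gibbs",
    "fit_mlp",
    "en_objective",
    "en_kkt_residual",
    "ld_reference",
]


# ---------------------------------------------------------------------------
# The exchange format
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PGSModel:
    """Ordered (variant, effect allele, weight) set — the scoring exchange format."""

    ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    chroms: list[str]
    positions: list[int]
    weights: np.ndarray
    method: str = ""
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("PGSModel ids must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PGSModel weights must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def to_scoring_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsID": self.ids,
                "chr_name": self.chroms,
                "chr_position": self.positions,
                "effect_allele": self.effect_alleles,
                "other_allele": self.other_alleles,
                "effect_weight": self.weights,
            }
        )

    @classmethod
    def from_scoring_frame(cls, df: pd.DataFrame, method: str = "") -> "PGSModel":
        return cls(
            ids=df["rsID"].astype(str).tolist(),
            effect_alleles=df["effect_allele"].tolist(),
            other_alleles=df["other_allele"].tolist(),
            chroms=df["chr_name"].astype(str).tolist(),
            positions=df["chr_position"].astype(int).tolist(),
            weights=df["effect_weight"].to_numpy(dtype=float),
            method=method,
        )


def _model_from_panel(
    g: GenotypeMatrix, ids: Sequence[str], weights: np.ndarray, method: str,
    hyperparameters: dict | None = None, provenance: str = "",
) -> PGSModel:
    v = g.variants.set_index("id")
    rows = v.loc[list(ids)]
    return PGSModel(
        ids=list(ids),
        effect_alleles=rows["a1"].tolist(),
        other_alleles=rows["a2"].tolist(),
        chroms=rows["chrom"].astype(str).tolist(),
        positions=rows["pos"].astype(int).tolist(),
        weights=np.asarray(weights, dtype=float),
        method=method,
        hyperparameters=hyperparameters or {},
        provenance=provenance,
    )


def predict_scores(model: PGSModel, g: GenotypeMatrix) -> np.ndarray:
    """Weighted sum of effect-allele dosages over the matched variants.

    The model is aligned to the panel by allele matching (swaps handled by
    counting the complementary dosage; strand-ambiguous variants excluded).
    Genotypes must already carry the active missing-call policy (training
    flows mean-impute; disease scoring substitutes expected dosage — see
    ``crosstrait.score_with_frequency_substitution``).
    """
    match = match_alleles(model.to_scoring_frame(), g)
    if len(match.genotype_index) == 0:
        raise ValueError("no model variants matched the genotype panel")
    d = match.effective_dosages(g)
    if np.isnan(d).any():
        raise ValueError("missing dosages; impute (or substitute) before scoring")
    return d @ match.weight


# ---------------------------------------------------------------------------
# P+T
# ---------------------------------------------------------------------------

def fit_pt(sumstats: pd.DataFrame, variant_set: VariantSet) -> PGSModel:
    """Pruning-and-thresholding: univariate GWAS betas, copied verbatim."""
    if len(variant_set) == 0:
        raise ValueError("empty variant set")
    ss = sumstats.set_index("id")
    missing = [v for v in variant_set.ids if v not in ss.index]
    if missing:
        raise KeyError(f"variants absent from summary statistics: {missing[:10]}")
    rows = ss.loc[variant_set.ids]
    return PGSModel(
        ids=list(variant_set.ids),
        effect_alleles=rows["effect_allele"].tolist(),
        other_alleles=rows["other_allele"].tolist(),
        chroms=rows["chrom"].astype(str).tolist(),
        positions=rows["pos"].astype(int).tolist(),
        weights=rows["beta"].to_numpy(dtype=float),
        method="pt",
        provenance=f"set={variant_set.name}",
    )


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ENConfig:
    """Elastic-net settings: fixed mixing, validation-tuned overall strength."""

    mixing: float = 0.5
    strength_path: np.ndarray | None = None  # descending; default from data
    n_path: int = 16
    path_decades: float = 3.5
    validation_fraction: float = 0.10
    tol: float = 1e-4  # sklearn's relative dual-gap criterion
    max_iter: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")
        if self.strength_path is not None:
            sp = np.asarray(self.strength_path, dtype=float)
            # zero is allowed (the penalty-free limit) but only as the last entry
            if np.any(sp < 0) or np.any(np.diff(sp) >= 0):
                raise ValueError("strength_path must be non-negative, strictly decreasing")
            self.strength_path = sp


def _standardize(d: np.ndarray):
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (d - mu) / sd_safe, mu, sd_safe


def en_objective(X: np.ndarray, y: np.ndarray, b: np.ndarray,
                 strength: float, mixing: float = 0.5) -> float:
    """The penalized squared loss the elastic net minimizes."""
    r = y - X @ b
    return float(
        r @ r
        + strength * mixing * np.abs(b).sum()
        + strength * (1.0 - mixing) / 2.0 * (b @ b)
    )


def en_kkt_residual(X: np.ndarray, y: np.ndarray, b: np.ndarray,
                    strength: float, mixing: float = 0.5) -> float:
    """Max violation of the subgradient optimality conditions at ``b``.

    For active coordinates the smooth gradient must cancel the L1 term
    exactly; for zero coordinates it must lie inside the subgradient
    interval.  A true minimizer has residual 0.
    """
    grad = -2.0 * X.T @ (y - X @ b) + strength * (1.0 - mixing) * b
    lam = strength * mixing
    active = b != 0
    viol_active = np.abs(grad[active] + lam * np.sign(b[active]))
    viol_zero = np.maximum(np.abs(grad[~active]) - lam, 0.0)
    parts = np.concatenate([viol_active, viol_zero])
    return float(parts.max()) if parts.size else 0.0


def _validation_split(n: int, fraction: float, rng: np.random.Generator):
    n_val = max(1, int(round(fraction * n)))
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def fit_en(
    g: GenotypeMatrix,
    y: np.ndarray,
    cfg: ENConfig | None = None,
    seed: int = 0,
    variant_set: VariantSet | None = None,
) -> PGSModel:
    """Elastic net on the standardized design, strength tuned on 10% held out.

    The path is fit with warm starts on the 90% split, the strength with the
    best validation Pearson r is chosen, and the model is refit on the full
    training data at that strength.  Output weights are back-transformed to
    per-dosage scale.
    """
    cfg = cfg or ENConfig()
    if variant_set is not None:
        g = g.subset_variants(variant_set.ids)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(g.dosages)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n, m = g.dosages.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    Xs, mu, sd = _standardize(g.dosages)
    yc = y - y.mean()
    rng = np.random.default_rng(seed)
    tr, va = _validation_split(n, cfg.validation_fraction, rng)

    if cfg.strength_path is not None:
        path = cfg.strength_path
    else:
        mix = max(cfg.mixing, 1e-3)
        s_max = 2.0 * np.abs(Xs[tr].T @ yc[tr]).max() / mix
        path = s_max * np.logspace(0.0, -cfg.path_decades, cfg.n_path)

    def _gram(X):
        # coordinate descent over the Gram matrix is cheaper whenever n > m
        if X.shape[0] > X.shape[1]:
            return np.ascontiguousarray(X.T @ X)
        return False

    def _solve(X, yv, s, net=None):
        """Minimize the penalized loss at one strength (s = 0: plain OLS)."""
        if s == 0.0:
            return np.linalg.lstsq(X, yv, rcond=None)[0], net
        nn = X.shape[0]
        if net is None:
            net = ElasticNet(alpha=s / (2.0 * nn), l1_ratio=cfg.mixing,
                             fit_intercept=False, tol=cfg.tol,
                             max_iter=cfg.max_iter, warm_start=True,
                             precompute=_gram(X))
        else:
            net.set_params(alpha=s / (2.0 * nn))
        net.fit(X, yv)
        if net.n_iter_ >= cfg.max_iter:
            logger.warning("elastic net hit max_iter=%d at strength %g",
                           cfg.max_iter, s)
        return net.coef_.copy(), net

    best_s, best_r = path[0], -np.inf
    net = None
    for s in path:
        coef, net = _solve(Xs[tr], yc[tr], s, net)
        r_val = _safe_r(Xs[va] @ coef, yc[va])
        if r_val > best_r:
            best_r, best_s = r_val, s

    w_std, _ = _solve(Xs, yc, best_s)
    w_dosage = w_std / sd
    return _model_from_panel(
        g, list(g.variants["id"]), w_dosage, method="en",
        hyperparameters={"strength": float(best_s), "mixing": cfg.mixing,
                         "validation_r": float(best_r)},
    )


# ---------------------------------------------------------------------------
# Bayesian ridge
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BRConfig:
    """Evidence-maximization settings and the Gamma-hyperparameter grid.

    ``grid`` holds candidate values for each of the four Gamma parameters
    (noise shape/rate, prior shape/rate); values are mapped through a
    positivity floor because Gamma parameters must be strictly positive.
    The floored, deduplicated product grid is scored on the validation
    split.
    """

    gamma_noise: tuple[float, float] = (1e-6, 1e-6)
    gamma_prior: tuple[float, float] = (1e-6, 1e-6)
    grid: Sequence[float] = (-1e10, -1e5, -10.0, 0.0, 10.0, 1e5, 1e10)
    positivity_floor: float = 1e-6
    validation_fraction: float = 0.10
    max_iter: int = 300
    tol: float = 1e-8


def _br_solve(svd, yc_t, alpha: float, lam: float):
    """Posterior-mean ridge solve from a precomputed thin SVD."""
    U, s, Vt = svd
    shrink = s / (s**2 + lam / alpha)
    return Vt.T @ (shrink * yc_t)


def _br_em(Xs, yc, a0, b0, l1, l2, max_iter, tol, fixed=None):
    """MacKay evidence-maximization loop; returns (coef, alpha, lambda)."""
    n, m = Xs.shape
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    yc_t = U.T @ yc
    if fixed is not None:
        alpha, lam = fixed
        return _br_solve((U, s, Vt), yc_t, alpha, lam), alpha, lam
    var_y = np.var(yc)
    alpha = 1.0 / var_y if var_y > 0 else 1.0
    lam = 1.0
    coef = _br_solve((U, s, Vt), yc_t, alpha, lam)
    for _ in range(max_iter):
        coef_old = coef
        # effective number of well-determined weights
        gamma = float(np.sum(alpha * s**2 / (lam + alpha * s**2)))
        rss = float(np.sum((yc - Xs @ coef) ** 2))
        lam = (gamma + 2.0 * l1) / (float(coef @ coef) + 2.0 * l2)
        alpha = (n - gamma + 2.0 * a0) / (rss + 2.0 * b0)
        coef = _br_solve((U, s, Vt), yc_t, alpha, lam)
        if np.max(np.abs(coef - coef_old)) < tol:
            break
    return coef, alpha, lam


def fit_br(
    g: GenotypeMatrix,
    y: np.ndarray,
    cfg: BRConfig | None = None,
    seed: int = 0,
    variant_set: VariantSet | None = None,
    fixed_precisions: tuple[float, float] | None = None,
) -> PGSModel:
    """Bayesian ridge with a validation-scored Gamma-hyperparameter grid.

    ``fixed_precisions = (alpha, lambda)`` freezes the noise and weight
    precisions, in which case the fit is the closed-form ridge solution
    ``(X'X + (lambda/alpha) I)^{-1} X'y`` on the standardized design.
    """
    cfg = cfg or BRConfig()
    if variant_set is not None:
        g = g.subset_variants(variant_set.ids)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(g.dosages)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n, m = g.dosages.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    Xs, mu, sd = _standardize(g.dosages)
    yc = y - y.mean()

    if fixed_precisions is not None:
        coef, alpha, lam = _br_em(Xs, yc, 0, 0, 0, 0, cfg.max_iter, cfg.tol,
                                  fixed=fixed_precisions)
        hp = {"alpha": float(alpha), "lambda": float(lam), "fixed": True}
        return _model_from_panel(g, list(g.variants["id"]), coef / sd, "br", hp)

    floor = cfg.positivity_floor
    values = sorted({max(float(v), floor) for v in cfg.grid})
    rng = np.random.default_rng(seed)
    tr, va = _validation_split(n, cfg.validation_fraction, rng)
    Xtr, ytr = Xs[tr], yc[tr]
    Xva, yva = Xs[va], yc[va]
    best = None
    for a0 in values:
        for b0 in values:
            for l1 in values:
                for l2 in values:
                    coef, alpha, lam = _br_em(
                        Xtr, ytr, a0, b0, l1, l2, cfg.max_iter, cfg.tol
                    )
                    r_val = _safe_r(Xva @ coef, yva)
                    if best is None or r_val > best[0]:
                        best = (r_val, (a0, b0, l1, l2))
    r_best, (a0, b0, l1, l2) = best
    coef, alpha, lam = _br_em(Xs, yc, a0, b0, l1, l2, cfg.max_iter, cfg.tol)
    hp = {"gamma_noise": (a0, b0), "gamma_prior": (l1, l2),
          "alpha": float(alpha), "lambda": float(lam),
          "validation_r": float(r_best)}
    return _model_from_panel(g, list(g.variants["id"]), coef / sd, "br", hp)


# ---------------------------------------------------------------------------
# Gaussian-mixture posterior via Gibbs sampling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MixtureConfig:
    """Spike-and-slab prior grid and Gibbs chain settings.

    The slab variance is ``h2 / (M p)`` per included variant.  The LD
    reference matrix is computed from at most ``ld_ref_subsample`` training
    samples and shrunk toward the identity by ``ld_shrink`` for chain
    stability.
    """

    h2_grid: Sequence[float] = (0.01, 0.03, 0.1, 0.3)
    p_grid: Sequence[float] = (1e-4, 1e-3, 1e-2, 0.1, 0.3, 1.0)
    n_iter: int = 500
    n_burnin: int = 100
    ld_ref_subsample: int = 10_000
    ld_shrink: float = 0.01

    def __post_init__(self) -> None:
        if len(self.h2_grid) == 0 or len(self.p_grid) == 0:
            raise ValueError("grids must be non-empty")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")

    def with_h2_anchor(self, h2_hat: float) -> "MixtureConfig":
        """Extend the h2 grid with {0.7, 1.0, 1.4} x an external estimate."""
        extra = [f * h2_hat for f in (0.7, 1.0, 1.4)]
        return dataclasses.replace(
            self, h2_grid=tuple(sorted(set(list(self.h2_grid) + extra)))
        )


def ld_reference(
    g: GenotypeMatrix, ids: Sequence[str], subsample: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Variant-variant correlation matrix (and dosage SDs) from a subsample."""
    sub = g.subset_variants(ids)
    n = sub.n_samples
    if n > subsample:
        rng = np.random.default_rng(seed)
        take = rng.choice(n, size=subsample, replace=False)
        d = sub.dosages[take]
    else:
        d = sub.dosages
    sd = d.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance variant in LD reference")
    R = np.corrcoef(d, rowvar=False)
    if R.ndim == 0:  # single variant
        R = np.array([[1.0]])
    return R, sd


def _gibbs_chain(bhat, R, n_gwas, h2, p, n_iter, n_burnin, rng):
    """One Gibbs chain over inclusion + effect; returns posterior-mean betas.

    Works on the standardized scale where the marginal effect of variant j
    is its correlation with the phenotype and its sampling variance is
    1/N.  Returns None if the chain state goes non-finite.
    """
    M = len(bhat)
    sigma2 = h2 / (M * p)
    N = float(n_gwas)
    var0 = 1.0 / N
    var1 = sigma2 + var0
    log_prior_odds = np.log(p) - np.log1p(-p) if p < 1.0 else np.inf
    v_post = 1.0 / (N + 1.0 / sigma2)
    sd_post = np.sqrt(v_post)

    beta = np.zeros(M)
    resid = bhat.copy()  # bhat - R @ beta
    acc = np.zeros(M)
    n_keep = 0
    for sweep in range(n_iter):
        for j in range(M):
            bt = resid[j] + beta[j]  # residualized marginal effect (R_jj = 1)
            if p >= 1.0:
                include = True
            else:
                log_lr = (
                    -0.5 * np.log(var1 / var0)
                    - 0.5 * bt * bt * (1.0 / var1 - 1.0 / var0)
                )
                logit = log_prior_odds + log_lr
                include = rng.random() < 1.0 / (1.0 + np.exp(-logit))
            new = (v_post * N * bt + sd_post * rng.standard_normal()) if include else 0.0
            if new != beta[j]:
                resid -= R[:, j] * (new - beta[j])
                beta[j] = new
        if not np.all(np.isfinite(beta)):
            return None
        if sweep >= n_burnin:
            acc += beta
            n_keep += 1
    return acc / n_keep


def fit_mixture_gibbs(
    sumstats: pd.DataFrame,
    ld_matrix: np.ndarray,
    cfg: MixtureConfig | None = None,
    n_gwas: int | None = None,
    seed: int = 0,
    sd_x: np.ndarray | None = None,
    sd_y: float = 1.0,
    validation: tuple[GenotypeMatrix, np.ndarray] | None = None,
    panel: GenotypeMatrix | None = None,
) -> PGSModel:
    """Posterior-mean effects under the Gaussian-mixture prior, per grid point.

    ``sumstats`` rows must align with ``ld_matrix`` order.  Marginal effects
    are converted to the standardized scale via the t statistic
    (r = t / sqrt(df + t^2)), sampled by Gibbs, and the posterior-mean
    weights back-transformed to dosage scale with ``sd_y / sd_x``.  The
    (h2, p) grid point with the best validation Pearson r wins; a chain
    that diverges (non-finite state) is dropped with a log entry.
    """
    cfg = cfg or MixtureConfig()
    M = len(sumstats)
    if ld_matrix.shape != (M, M):
        raise ValueError("LD matrix does not match summary-statistics length")
    eigmin = float(np.linalg.eigvalsh(ld_matrix).min())
    if eigmin < -1e-8:
        raise ValueError(f"LD matrix not positive semidefinite (min eig {eigmin:.3g})")
    R = (1.0 - cfg.ld_shrink) * ld_matrix + cfg.ld_shrink * np.eye(M)
    if n_gwas is None:
        n_gwas = int(np.median(sumstats["n"]))
    beta = sumstats["beta"].to_numpy(dtype=float)
    se = sumstats["se"].to_numpy(dtype=float)
    t = beta / se
    df = n_gwas - 2
    bhat_std = t / np.sqrt(df + t * t)

    if sd_x is None:
        eaf = sumstats["eaf"].to_numpy(dtype=float)
        sd_x = np.sqrt(np.maximum(2.0 * eaf * (1.0 - eaf), 1e-12))

    grid = [(h2, p) for h2 in cfg.h2_grid for p in cfg.p_grid]
    rng = np.random.default_rng(seed)
    results = []
    for h2, p in grid:
        post = _gibbs_chain(
            bhat_std, R, n_gwas, h2, p, cfg.n_iter, cfg.n_burnin,
            np.random.default_rng(rng.integers(2**31)),
        )
        if post is None:
            logger.warning("divergent chain at h2=%g p=%g; skipped", h2, p)
            continue
        results.append((h2, p, post))
    if not results:
        raise RuntimeError("every Gibbs chain diverged")

    ids = sumstats["id"].astype(str).tolist()

    def _to_model(h2, p, post):
        w = post * sd_y / sd_x
        return PGSModel(
            ids=ids,
            effect_alleles=sumstats["effect_allele"].tolist(),
            other_alleles=sumstats["other_allele"].tolist(),
            chroms=sumstats["chrom"].astype(str).tolist(),
            positions=sumstats["pos"].astype(int).tolist(),
            weights=w,
            method="mixture",
            hyperparameters={"h2": h2, "p": p, "n_gwas": n_gwas},
        )

    if len(results) == 1 or validation is None:
        h2, p, post = results[0]
        return _to_model(h2, p, post)
    g_val, y_val = validation
    best = None
    for h2, p, post in results:
        model = _to_model(h2, p, post)
        r = _safe_r(predict_scores(model, g_val), np.asarray(y_val, dtype=float))
        if best is None or r > best[0]:
            best = (r, model)
    best[1].hyperparameters["validation_r"] = float(best[0])
    return best[1]


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MLPConfig:
    hidden_sizes: Sequence[int] = (8,)
    activation: str = "relu"  # relu | tanh | identity
    epochs: int = 2_000
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must each be >= 1")
        if self.activation not in ("relu", "tanh", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


_ACT = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


class MLPPredictor:
    """A fitted feed-forward network with a ``predict(GenotypeMatrix)`` interface.

    Unlike the linear estimators this is generally not expressible as a
    PGSModel (the fitted map need not be a weighted dosage sum), so it only
    mirrors the prediction interface.
    """

    def __init__(self, weights, biases, activation, mu, sd, y_mean, variant_ids):
        self.weights = weights
        self.biases = biases
        self.activation = activation
        self.mu, self.sd, self.y_mean = mu, sd, y_mean
        self.variant_ids = list(variant_ids)
        self.method = "mlp"

    def _forward(self, X):
        act, _ = _ACT[self.activation]
        a = X
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = act(z) if k < len(self.weights) - 1 else z
        return a[:, 0]

    def predict(self, g: GenotypeMatrix) -> np.ndarray:
        sub = g.subset_variants(self.variant_ids)
        if np.isnan(sub.dosages).any():
            raise ValueError("missing dosages; impute before prediction")
        X = (sub.dosages - self.mu) / self.sd
        return self._forward(X) + self.y_mean


def fit_mlp(
    g: GenotypeMatrix,
    y: np.ndarray,
    cfg: MLPConfig | None = None,
    seed: int | None = None,
    variant_set: VariantSet | None = None,
) -> MLPPredictor:
    """Train a small MLP by full-batch Adam on squared loss.

    Intended for conditional-analysis-scale variant sets; the run is
    deterministic under the seed.  An empty ``hidden_sizes`` collapses the
    network to a linear model.  Non-finite loss aborts with an error.
    """
    cfg = cfg or MLPConfig()
    if seed is None:
        seed = cfg.seed
    if variant_set is not None:
        g = g.subset_variants(variant_set.ids)
    y = np.asarray(y, dtype=float)
    Xs, mu, sd = _standardize(g.dosages)
    y_mean = y.mean()
    yc = y - y_mean
    n, m = Xs.shape
    sizes = [m] + list(cfg.hidden_sizes) + [1]
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[k]), size=(sizes[k], sizes[k + 1]))
        for k in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[k + 1]) for k in range(len(sizes) - 1)]
    act, dact = _ACT[cfg.activation]

    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mB = [np.zeros_like(b) for b in biases]
    vB = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate
    L = len(weights)

    for epoch in range(1, cfg.epochs + 1):
        # forward pass, caching pre-activations
        a_list, z_list = [Xs], []
        a = Xs
        for k in range(L):
            z = a @ weights[k] + biases[k]
            z_list.append(z)
            a = act(z) if k < L - 1 else z
            a_list.append(a)
        pred = a[:, 0]
        loss = np.mean((pred - yc) ** 2)
        if not np.isfinite(loss):
            raise RuntimeError(f"MLP training diverged at epoch {epoch} (loss NaN)")
        # backward
        delta = (2.0 / n) * (pred - yc)[:, None]
        grads_W, grads_b = [None] * L, [None] * L
        for k in range(L - 1, -1, -1):
            grads_W[k] = a_list[k].T @ delta
            grads_b[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ weights[k].T) * dact(z_list[k - 1])
        for k in range(L):
            mW[k] = b1 * mW[k] + (1 - b1) * grads_W[k]
            vW[k] = b2 * vW[k] + (1 - b2) * grads_W[k] ** 2
            mB[k] = b1 * mB[k] + (1 - b1) * grads_b[k]
            vB[k] = b2 * vB[k] + (1 - b2) * grads_b[k] ** 2
            mhW = mW[k] / (1 - b1**epoch)
            vhW = vW[k] / (1 - b2**epoch)
            mhB = mB[k] / (1 - b1**epoch)
            vhB = vB[k] / (1 - b2**epoch)
            weights[k] -= lr * mhW / (np.sqrt(vhW) + eps)
            biases[k] -= lr * mhB / (np.sqrt(vhB) + eps)

    return MLPPredictor(weights, biases, cfg.activation, mu, sd, y_mean,
                        list(g.variants["id"]))
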