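"""Estimator correctness: closed forms, optimality conditions, samplers."""

import numpy as np
import pandas as pd
import pytest

from polyscore import (
    ENConfig,
    MixtureConfig,
    MLPConfig,
    VariantSet,
    fit_br,
    fit_en,
    fit_mixture_gibbs,
    fit_mlp,
    fit_pt,
    predict_scores,
    read_scoring_file,
    run_gwas,
    write_scoring_file,
)
from polyscore.pgs_methods import (
    PGSModel,
    _br_em,
    _standardize,
    en_kkt_residual,
    en_objective,
)

from conftest import genotypes_from_array, make_panel_frame


def _toy_model(weights, m=None, alleles=("A", "G")):
    m = m or len(weights)
    return PGSModel(
        ids=[f"v{j}" for j in range(m)],
        effect_alleles=[alleles[0]] * m,
        other_alleles=[alleles[1]] * m,
        chroms=["1"] * m,
        positions=list(range(1, m + 1)),
        weights=np.asarray(weights, dtype=float),
        method="test",
    )


def _sumstats_for(bhat_std, n, se=0.01):
    """Summary statistics whose standardized marginal effects equal bhat_std."""
    bhat_std = np.asarray(bhat_std, dtype=float)
    df = n - 2
    t = bhat_std * np.sqrt(df / (1.0 - bhat_std**2))
    m = len(bhat_std)
    return pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": "1",
        "pos": np.arange(1, m + 1), "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": t * se, "se": se, "p": 0.5, "n": n,
    })


# ---------------------------------------------------------------------------
# predict_scores
# ---------------------------------------------------------------------------

def test_predict_zero_weights_zero_scores():
    g = genotypes_from_array(np.random.default_rng(0).integers(0, 3, (10, 4)))
    assert np.all(predict_scores(_toy_model([0, 0, 0, 0]), g) == 0.0)


def test_predict_single_snp_weight_two():
    g = genotypes_from_array(np.array([[0.0], [1.0], [2.0]]))
    np.testing.assert_array_equal(predict_scores(_toy_model([2.0]), g),
                                  [0.0, 2.0, 4.0])


def test_predict_matches_double_loop_oracle():
    rng = np.random.default_rng(1)
    X = rng.uniform(0, 2, size=(100, 300))
    g = genotypes_from_array(X)
    w = rng.standard_normal(300)
    scores = predict_scores(_toy_model(w), g)
    oracle = np.zeros(100)
    for i in range(100):
        for j in range(300):
            oracle[i] += w[j] * X[i, j]
    np.testing.assert_allclose(scores, oracle, atol=1e-10)


def test_predict_applies_allele_swap():
    g = genotypes_from_array(np.array([[0.0], [2.0]]), alleles=("A", "G"))
    model = _toy_model([1.0], alleles=("G", "A"))  # effect allele is panel A2
    np.testing.assert_array_equal(predict_scores(model, g), [2.0, 0.0])


def test_predict_no_matches_raises():
    g = genotypes_from_array(np.zeros((3, 1)), alleles=("A", "T"))  # ambiguous
    with pytest.raises(ValueError, match="matched"):
        predict_scores(_toy_model([1.0], alleles=("A", "T")), g)


# ---------------------------------------------------------------------------
# P+T
# ---------------------------------------------------------------------------

def test_pt_copies_univariate_betas_exactly(small_cohort):
    y = small_cohort.phenotype - small_cohort.phenotype.mean()
    ss = run_gwas(small_cohort.genotypes, y)
    ids = ss.nsmallest(10, "p")["id"].tolist()
    model = fit_pt(ss, VariantSet("top", ids))
    lookup = ss.set_index("id")["beta"]
    assert np.array_equal(model.weights, lookup.loc[ids].to_numpy())


def test_pt_empty_set_and_missing_variant_rejected(small_cohort):
    y = small_cohort.phenotype - small_cohort.phenotype.mean()
    ss = run_gwas(small_cohort.genotypes, y)
    with pytest.raises(ValueError):
        fit_pt(ss, VariantSet("empty", []))
    with pytest.raises(KeyError, match="nosuch"):
        fit_pt(ss, VariantSet("bad", ["nosuch"]))


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

def test_en_huge_strength_gives_zero_model():
    rng = np.random.default_rng(2)
    g = genotypes_from_array(rng.integers(0, 3, (100, 10)).astype(float))
    y = rng.standard_normal(100)
    cfg = ENConfig(strength_path=np.array([1e9]))
    model = fit_en(g, y, cfg, seed=0)
    assert np.all(model.weights == 0.0)


def test_en_zero_strength_recovers_ols():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((80, 6)) + 1.0
    g = genotypes_from_array(np.clip(X, 0, 2))
    y = rng.standard_normal(80)
    model = fit_en(g, y, ENConfig(strength_path=np.array([0.0])), seed=0)
    Xc = g.dosages - g.dosages.mean(axis=0)
    ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    np.testing.assert_allclose(model.weights, ols, atol=1e-8)


def test_en_zero_strength_orthonormal_design_matches_univariate_slopes():
    rng = np.random.default_rng(4)
    raw = rng.standard_normal((60, 5))
    Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    g = genotypes_from_array(Q - Q.min())  # shift into dosage range
    y = rng.standard_normal(60)
    model = fit_en(g, y, ENConfig(strength_path=np.array([0.0])), seed=0)
    Xc = g.dosages - g.dosages.mean(axis=0)
    yc = y - y.mean()
    univariate = np.array([(Xc[:, j] @ yc) / (Xc[:, j] @ Xc[:, j])
                           for j in range(5)])
    np.testing.assert_allclose(model.weights, univariate, atol=1e-8)


def test_en_kkt_conditions_hold_at_solution():
    rng = np.random.default_rng(5)
    g = genotypes_from_array(rng.integers(0, 3, (100, 10)).astype(float))
    y = (g.dosages[:, 0] - g.dosages[:, 2]) + 0.5 * rng.standard_normal(100)
    s = 20.0
    cfg = ENConfig(strength_path=np.array([s]), tol=1e-14)
    model = fit_en(g, y, cfg, seed=0)
    Xs, _, sd = _standardize(g.dosages)
    b_std = model.weights * sd
    assert en_kkt_residual(Xs, y - y.mean(), b_std, s, 0.5) < 1e-6


def test_en_solution_beats_perturbations_and_matches_ista_oracle():
    rng = np.random.default_rng(6)
    g = genotypes_from_array(rng.integers(0, 3, (100, 10)).astype(float))
    y = g.dosages[:, 1] + rng.standard_normal(100)
    s = 30.0
    model = fit_en(g, y, ENConfig(strength_path=np.array([s]), tol=1e-14), seed=0)
    Xs, _, sd = _standardize(g.dosages)
    yc = y - y.mean()
    b = model.weights * sd
    obj = en_objective(Xs, yc, b, s, 0.5)

    # 10,000 random perturbations never improve the objective
    scales = np.repeat([1e-3, 1e-2, 1e-1, 1.0], 2500)
    deltas = rng.standard_normal((10_000, 10)) * scales[:, None]
    pert = b[None, :] + deltas
    r = yc[:, None] - Xs @ pert.T
    objs = (np.einsum("ij,ij->j", r, r)
            + s * 0.5 * np.abs(pert).sum(axis=1)
            + s * 0.25 * np.einsum("ij,ij->i", pert, pert))
    assert np.all(objs >= obj - 1e-9)

    # independent proximal-gradient (ISTA) oracle on the same objective
    L = 2.0 * np.linalg.eigvalsh(Xs.T @ Xs).max() + s * 0.5
    eta = 1.0 / L
    bo = np.zeros(10)
    for _ in range(200_000):
        grad = -2.0 * Xs.T @ (yc - Xs @ bo) + s * 0.5 * bo
        z = bo - eta * grad
        bo_new = np.sign(z) * np.maximum(np.abs(z) - eta * s * 0.5, 0.0)
        if np.max(np.abs(bo_new - bo)) < 1e-14:
            bo = bo_new
            break
        bo = bo_new
    assert abs(en_objective(Xs, yc, bo, s, 0.5) - obj) < 1e-6
    np.testing.assert_allclose(b, bo, atol=1e-6)


def test_en_nonfinite_inputs_rejected(small_cohort):
    y = small_cohort.phenotype.copy()
    y[0] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        fit_en(small_cohort.genotypes, y, seed=0)


# ---------------------------------------------------------------------------
# Bayesian ridge
# ---------------------------------------------------------------------------

def _br_instance(seed=7, n=200, m=20):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    g = genotypes_from_array(X)
    y = 0.4 * X[:, 0] - 0.3 * X[:, 3] + rng.standard_normal(n)
    return g, y


def test_br_huge_lambda_shrinks_to_zero():
    g, y = _br_instance()
    model = fit_br(g, y, fixed_precisions=(1.0, 1e12))
    assert np.max(np.abs(model.weights)) < 1e-6


def test_br_fixed_precisions_equal_ridge_closed_form():
    g, y = _br_instance()
    alpha, lam = 2.0, 5.0
    model = fit_br(g, y, fixed_precisions=(alpha, lam))
    Xs, _, sd = _standardize(g.dosages)
    yc = y - y.mean()
    ridge = np.linalg.solve(Xs.T @ Xs + (lam / alpha) * np.eye(Xs.shape[1]),
                            Xs.T @ yc)
    np.testing.assert_allclose(model.weights, ridge / sd, atol=1e-8)


def test_br_evidence_loop_agrees_with_sklearn():
    """The MacKay update loop reproduces sklearn's BayesianRidge fit."""
    from sklearn.linear_model import BayesianRidge

    g, y = _br_instance(seed=8)
    Xs, _, _ = _standardize(g.dosages)
    yc = y - y.mean()
    coef, alpha, lam = _br_em(Xs, yc, 1e-6, 1e-6, 1e-6, 1e-6, 500, 1e-12)
    ref = BayesianRidge(alpha_1=1e-6, alpha_2=1e-6, lambda_1=1e-6,
                        lambda_2=1e-6, fit_intercept=False, tol=1e-12,
                        max_iter=1000).fit(Xs, yc)
    np.testing.assert_allclose(coef, ref.coef_, atol=1e-8)
    assert abs(alpha - ref.alpha_) < 1e-6 * ref.alpha_
    assert abs(lam - ref.lambda_) < 1e-6 * ref.lambda_


def test_br_grid_selection_is_consistent():
    """The validation-selected grid point is near-best on a fresh test set."""
    rng = np.random.default_rng(9)
    n, m = 200, 20
    Xtr = rng.integers(0, 3, size=(n, m)).astype(float)
    Xte = rng.integers(0, 3, size=(400, m)).astype(float)
    beta = np.zeros(m)
    beta[:5] = rng.normal(0, 0.4, 5)
    ytr = Xtr @ beta + rng.standard_normal(n)
    yte = Xte @ beta + rng.standard_normal(400)
    g = genotypes_from_array(Xtr)
    from polyscore import BRConfig

    cfg = BRConfig(grid=(0.0, 10.0, 1e5))
    model = fit_br(g, ytr, cfg, seed=1)
    chosen_r = np.corrcoef(predict_scores(model, genotypes_from_array(Xte)),
                           yte)[0, 1]
    # exhaustive loop over the same floored grid
    Xs, _, sd = _standardize(Xtr)
    yc = ytr - ytr.mean()
    values = sorted({max(v, 1e-6) for v in cfg.grid})
    rs = []
    Xte_s = (Xte - Xtr.mean(axis=0)) / np.where(Xtr.std(axis=0) == 0, 1,
                                                 Xtr.std(axis=0))
    for a0 in values:
        for b0 in values:
            for l1 in values:
                for l2 in values:
                    coef, _, _ = _br_em(Xs, yc, a0, b0, l1, l2, 300, 1e-8)
                    rs.append(np.corrcoef(Xte_s @ coef, yte)[0, 1])
    assert chosen_r >= max(rs) - 0.02


# ---------------------------------------------------------------------------
# Gaussian-mixture Gibbs sampler
# ---------------------------------------------------------------------------

def test_mixture_p1_identity_ld_matches_conjugate_shrinkage():
    M, N, h2 = 20, 5000, 0.2
    rng = np.random.default_rng(10)
    bhat = rng.normal(0, 0.02, M)
    ss = _sumstats_for(bhat, N)
    cfg = MixtureConfig(h2_grid=(h2,), p_grid=(1.0,), n_iter=2000,
                        n_burnin=400, ld_shrink=0.0)
    chains = [
        fit_mixture_gibbs(ss, np.eye(M), cfg, n_gwas=N, seed=s,
                          sd_x=np.ones(M), sd_y=1.0).weights
        for s in (1, 2, 3)
    ]
    mean = np.mean(chains, axis=0)
    expected = bhat / (1.0 + M / (N * h2))
    # iid draws: MC SE from the closed-form posterior sd
    mc_se = np.sqrt(1.0 / (N + M * (1.0 / h2))) / np.sqrt(3 * 1600)
    assert np.all(np.abs(mean - expected) < 3.5 * mc_se)


def test_mixture_vanishing_h2_gives_zero_weights():
    M, N = 10, 2000
    rng = np.random.default_rng(11)
    ss = _sumstats_for(rng.normal(0, 0.05, M), N)
    cfg = MixtureConfig(h2_grid=(1e-6,), p_grid=(1.0,), n_iter=400,
                        n_burnin=100, ld_shrink=0.0)
    m = fit_mixture_gibbs(ss, np.eye(M), cfg, n_gwas=N, seed=0,
                          sd_x=np.ones(M), sd_y=1.0)
    assert np.max(np.abs(m.weights)) < 1e-3


def test_mixture_rejects_mismatched_ld():
    ss = _sumstats_for([0.01, 0.02], 1000)
    with pytest.raises(ValueError, match="LD matrix"):
        fit_mixture_gibbs(ss, np.eye(3), n_gwas=1000)


def test_mixture_grid_requires_more_iters_than_burnin():
    with pytest.raises(ValueError):
        MixtureConfig(n_iter=100, n_burnin=100)


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

def test_mlp_no_hidden_layers_collapses_to_ols():
    rng = np.random.default_rng(12)
    X = rng.integers(0, 3, size=(300, 4)).astype(float)
    y = X @ np.array([0.5, -0.3, 0.2, 0.0]) + 0.3 * rng.standard_normal(300)
    g = genotypes_from_array(X)
    mlp = fit_mlp(g, y, MLPConfig(hidden_sizes=(), epochs=3000,
                                  learning_rate=0.02), seed=0)
    pred = mlp.predict(g)
    Xc = np.column_stack([np.ones(300), X])
    ols_pred = Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    assert np.max(np.abs(pred - ols_pred)) < 0.02 * np.std(y)


def test_mlp_identity_activation_is_linear_map():
    rng = np.random.default_rng(13)
    X = rng.integers(0, 3, size=(300, 3)).astype(float)
    y = X @ np.array([0.4, -0.2, 0.1]) + 0.2 * rng.standard_normal(300)
    g = genotypes_from_array(X)
    mlp = fit_mlp(g, y, MLPConfig(hidden_sizes=(8,), activation="identity",
                                  epochs=3000, learning_rate=0.02), seed=0)
    pred = mlp.predict(g)
    Xc = np.column_stack([np.ones(300), X])
    ols_pred = Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    assert np.max(np.abs(pred - ols_pred)) < 0.03 * np.std(y)


def test_mlp_detects_planted_product_interaction():
    """MLP beats the linear fit on an interaction trait in >= 8/10 replicates."""
    wins = 0
    for rep in range(10):
        rng = np.random.default_rng(100 + rep)
        n = 5000
        X = rng.integers(0, 3, size=(n, 3)).astype(float)
        prod = (X[:, 0] - X[:, 0].mean()) * (X[:, 1] - X[:, 1].mean())
        y = prod + 0.5 * rng.standard_normal(n)
        tr, te = np.arange(0, 4000), np.arange(4000, n)
        g = genotypes_from_array(X)
        gtr, gte = g.subset_samples(tr), g.subset_samples(te)
        mlp = fit_mlp(gtr, y[tr], MLPConfig(hidden_sizes=(16,), epochs=800,
                                            learning_rate=0.02), seed=rep)
        r_mlp = np.corrcoef(mlp.predict(gte), y[te])[0, 1]
        Xc = np.column_stack([np.ones(4000), X[tr]])
        beta = np.linalg.lstsq(Xc, y[tr], rcond=None)[0]
        lin_pred = np.column_stack([np.ones(1000), X[te]]) @ beta
        r_lin = (np.corrcoef(lin_pred, y[te])[0, 1]
                 if np.std(lin_pred) > 0 else 0.0)
        wins += int(r_mlp > r_lin)
    assert wins >= 8


def test_mlp_determinism_and_bad_activation():
    rng = np.random.default_rng(14)
    X = rng.integers(0, 3, size=(50, 2)).astype(float)
    y = rng.standard_normal(50)
    g = genotypes_from_array(X)
    a = fit_mlp(g, y, MLPConfig(epochs=50), seed=3).predict(g)
    b = fit_mlp(g, y, MLPConfig(epochs=50), seed=3).predict(g)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        MLPConfig(activation="sigmoidal")


# ---------------------------------------------------------------------------
# scoring-file round trip of fitted models
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["pt", "en", "br"])
def test_fitted_models_round_trip_scoring_file(tmp_path, small_cohort, method):
    c = small_cohort
    y = c.phenotype - c.phenotype.mean()
    ss = run_gwas(c.genotypes, y)
    ids = ss.nsmallest(8, "p")["id"].tolist()
    vset = VariantSet("top", ids)
    if method == "pt":
        model = fit_pt(ss, vset)
    elif method == "en":
        model = fit_en(c.genotypes, y, seed=0, variant_set=vset)
    else:
        model = fit_br(c.genotypes, y, seed=0, variant_set=vset)
    write_scoring_file(model.to_scoring_frame(), tmp_path / "m.tsv")
    back = PGSModel.from_scoring_frame(read_scoring_file(tmp_path / "m.tsv"))
    assert back.ids == model.ids
    np.testing.assert_array_equal(back.weights, model.weights)
    scores_a = predict_scores(model, c.genotypes)
    scores_b = predict_scores(back, c.genotypes)
    np.testing.assert_array_equal(scores_a, scores_b)
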