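"""REML criterion, AI-REML fitting, BLUP solutions and predictions."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

import nagblup as ng
from nagblup.varcomp import (
    ModelSpec,
    RandomTerm,
    blup_predict,
    neg2_restricted_loglik,
    reml_fit,
    solve_at_theta,
)

from conftest import hwe_matrix


def _oracle_m2ll(y, X, gammas, theta):
    """Independent dense evaluation via explicit inverses and slogdet."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for th, gam in zip(theta[:-1], gammas):
        V = V + th * gam
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + y @ P @ y)


# ---------------------------------------------------------------------------
# the restricted-likelihood criterion


def test_criterion_matches_independent_oracle(rng):
    n = 6
    y = rng.normal(size=n)
    K = np.eye(n)
    spec = ModelSpec(y=y, terms=[RandomTerm("g", covariance=K)])
    theta = np.array([1.3, 0.7])
    assert neg2_restricted_loglik(spec, theta) == pytest.approx(
        _oracle_m2ll(y, np.ones((n, 1)), [K], theta), abs=1e-10
    )


def test_criterion_location_scale_identity(rng):
    """Scaling y by c shifts -2logL by (N - rank(X)) log c^2 at theta*c^2."""
    n = 12
    y = rng.normal(size=n)
    A = rng.normal(size=(n, n))
    K = A @ A.T / n
    spec = ModelSpec(y=y, terms=[RandomTerm("g", covariance=K)])
    theta = np.array([0.8, 1.1])
    c = 3.7
    spec_scaled = ModelSpec(y=c * y, terms=[RandomTerm("g", covariance=K)])
    lhs = neg2_restricted_loglik(spec_scaled, c**2 * theta)
    rhs = neg2_restricted_loglik(spec, theta) + (n - 1) * np.log(c**2)
    assert lhs == pytest.approx(rhs, abs=1e-8)


def test_residual_only_minimizer_is_unbiased_sample_variance(rng):
    y = rng.normal(size=40)
    spec = ModelSpec(y=y, terms=[])
    res = minimize_scalar(
        lambda s: neg2_restricted_loglik(spec, [np.exp(s)]),
        bounds=(-8, 8), method="bounded",
    )
    assert np.exp(res.x) == pytest.approx(np.var(y, ddof=1), rel=1e-5)


def test_criterion_rejects_nonpositive_theta(rng):
    spec = ModelSpec(y=rng.normal(size=5), terms=[])
    with pytest.raises(ValueError):
        neg2_restricted_loglik(spec, [0.0])


# ---------------------------------------------------------------------------
# AI-REML fitting


def test_reml_recovers_grouped_variance_components(rng):
    """Grouped iid random effect, truth (2, 1): estimates within 3 SE."""
    n_groups, per = 500, 4
    n = n_groups * per
    Z = np.zeros((n, n_groups))
    Z[np.arange(n), np.repeat(np.arange(n_groups), per)] = 1.0
    u = rng.normal(0.0, np.sqrt(2.0), n_groups)
    y = Z @ u + rng.normal(0.0, 1.0, n)
    fit = reml_fit(ModelSpec(y=y, terms=[RandomTerm("group", incidence=Z)]))
    assert fit.converged
    for est, se, truth in zip(fit.theta, fit.se, (2.0, 1.0)):
        assert abs(est - truth) < 3 * se


def test_constant_response_pins_everything():
    fit = reml_fit(ModelSpec(y=np.full(15, 3.0),
                             terms=[RandomTerm("g", covariance=np.eye(15))]))
    assert fit.converged
    assert fit.pinned.all()
    assert np.isfinite(fit.minus2logl)
    assert np.allclose(fit.blups["g"], 0.0)


def test_em_fallback_steps_never_increase_criterion(small_pipeline):
    for fit in small_pipeline["fits"].values():
        values = [rec["minus2logl"] for rec in fit.trace]
        steps = [rec["step"] for rec in fit.trace]
        for i in range(1, len(values)):
            if steps[i - 1] == "EM":
                assert values[i] <= values[i - 1] + 1e-8


def test_aireml_agrees_with_derivative_free_optimum(rng):
    """Nelder-Mead on the criterion lands on the AI-REML optimum (N small)."""
    g, _ = hwe_matrix(rng, 150, 300, 0.1, 0.9)
    K = ng.build_relationship_matrices(g)["additive"].K
    L = np.linalg.cholesky(K + 1e-8 * np.eye(150))
    y = L @ rng.normal(size=150) * np.sqrt(2.0) + rng.normal(0, 1.0, 150)
    spec = ModelSpec(y=y, terms=[RandomTerm("additive", covariance=K)])
    fit = reml_fit(spec)
    assert fit.converged
    res = minimize(
        lambda lt: neg2_restricted_loglik(spec, np.exp(lt)),
        np.log(fit.theta) + 0.3,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    np.testing.assert_allclose(np.exp(res.x), fit.theta, rtol=1e-4)
    assert fit.minus2logl == pytest.approx(res.fun, abs=1e-6)


def test_heritability_invariant_to_response_scaling(rng):
    g, _ = hwe_matrix(rng, 120, 200)
    K = ng.build_relationship_matrices(g)["additive"].K
    L = np.linalg.cholesky(K + 1e-8 * np.eye(120))
    y = L @ rng.normal(size=120) + rng.normal(0, 1, 120)
    fit1 = reml_fit(ModelSpec(y=y, terms=[RandomTerm("additive", covariance=K)]))
    fit2 = reml_fit(ModelSpec(y=10 * y, terms=[RandomTerm("additive", covariance=K)]))
    h1 = ng.variance_proportions(fit1).h2_narrow
    h2 = ng.variance_proportions(fit2).h2_narrow
    assert h1 == pytest.approx(h2, rel=1e-4)


def test_model_family_nesting_monotonicity(small_pipeline):
    fits = small_pipeline["fits"]
    # convergence is declared at 1e-8 relative change, so nested -2logL values
    # can differ by optimisation slop of that order
    tol = 1e-6 * abs(fits["MA"].minus2logl)
    assert fits["MAED"].minus2logl <= fits["MAD"].minus2logl + tol
    assert fits["MAD"].minus2logl <= fits["MA"].minus2logl + tol
    assert fits["MAED"].minus2logl <= fits["MAE"].minus2logl + tol
    assert fits["MAE"].minus2logl <= fits["MA"].minus2logl + tol


def test_null_nonadditive_components_shrink_to_bound(rng):
    """Zero true dominance/epistasis: MAED pins or nearly pins the extras."""
    cfg = ng.SimulationConfig(n_ref=400, n_test=1, m=600, seed=42,
                              var_epistatic=0.0, var_dominance=0.0)
    g, meta = ng.simulate_genotypes(cfg)
    truth = ng.simulate_phenotypes(g, meta, cfg)
    mats = ng.build_relationship_matrices(g)
    pheno = truth.table[["individual_id", "phenotype", "litter", "is_reference"]].rename(
        columns={"phenotype": "dgc"})
    fit = ng.fit_model_family(pheno, mats["additive"], mats["epistatic"],
                              mats["dominance"], models=("MAED",))["MAED"]
    vary = np.var(pheno.loc[pheno["is_reference"], "dgc"], ddof=1)
    extras = [fit.variance("epistatic"), fit.variance("dominance")]
    assert min(extras) <= 0.02 * vary


def test_variance_proportions_sum_to_one(small_pipeline):
    for fit in small_pipeline["fits"].values():
        props = ng.variance_proportions(fit).proportions
        assert sum(props.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# prediction


def test_identical_covariance_rows_get_identical_gbv(rng):
    g, _ = hwe_matrix(rng, 25, 60, 0.2, 0.8)
    G = ng.build_relationship_matrices(g)["additive"]
    # append a "test" individual that is an exact genotype copy of i3
    K = np.zeros((26, 26))
    K[:25, :25] = G.K
    K[25, :] = K[3, :][np.r_[np.arange(25), 3]]
    K[:, 25] = K[25, :]
    Kfull = ng.RelationshipMatrix(G.individual_ids + ["copy"], K, "additive", "A")
    y = rng.normal(size=25)
    phenotyped = np.r_[np.ones(25, bool), False]
    spec = ModelSpec(y=y, terms=[RandomTerm("additive", covariance=G.K)])
    fit = solve_at_theta(spec, [1.5, 1.0])
    pred = blup_predict(fit, {"additive": Kfull}, phenotyped)
    assert pred.gbv[25] == pytest.approx(pred.gbv[3], abs=1e-10)


def test_zero_genetic_variance_gives_zero_gbv(rng):
    g, _ = hwe_matrix(rng, 20, 50)
    G = ng.build_relationship_matrices(g)["additive"]
    y = rng.normal(size=15)
    mask = np.r_[np.ones(15, bool), np.zeros(5, bool)]
    spec = ModelSpec(y=y, terms=[RandomTerm("additive",
                                            covariance=G.K[:15, :15])])
    fit = solve_at_theta(spec, [1.0, 1.0])
    fit.theta = np.array([0.0, 1.0])  # no genetic signal
    pred = blup_predict(fit, {"additive": G}, mask)
    # py was computed at the solved theta; the projection is scaled by 0
    assert np.allclose(pred.gbv, 0.0)


def test_prediction_routes_agree_mme_vs_projection(rng):
    """Covariance projection of reference solutions equals the MME route."""
    cfg = ng.SimulationConfig(n_ref=40, n_test=15, m=100, n_founders=40, seed=9)
    g, meta = ng.simulate_genotypes(cfg)
    truth = ng.simulate_phenotypes(g, meta, cfg)
    G = ng.build_relationship_matrices(g)["additive"]
    ref = meta["is_reference"].to_numpy()
    y = truth.table.loc[ref, "phenotype"].to_numpy()
    spec = ModelSpec(y=y, terms=[RandomTerm("additive",
                                            covariance=G.submatrix(ref).K)])
    fit = solve_at_theta(spec, [2000.0, 2500.0])
    pred = blup_predict(fit, {"additive": G}, ref)
    u_ref = fit.blups["additive"]
    Krr = G.submatrix(ref).K
    proj = G.K[~ref][:, np.flatnonzero(ref)] @ np.linalg.lstsq(
        Krr, u_ref, rcond=None)[0]
    np.testing.assert_allclose(pred.gbv[~ref], proj, atol=1e-6)


def test_gblup_equals_snpblup(rng):
    """Additive GBLUP equals ridge regression on markers at matched shrinkage."""
    n, m = 200, 500
    g, _ = hwe_matrix(rng, n, m, 0.1, 0.9)
    f = ng.allele_frequencies(g)
    cod = ng.build_additive_coding(g, f)
    G = ng.build_G(cod)
    y = rng.normal(size=n)
    var_a, var_e = 2.0, 1.0
    spec = ModelSpec(y=y, terms=[RandomTerm("additive", covariance=G.K)])
    a_gblup = solve_at_theta(spec, [var_a, var_e]).blups["additive"]
    # SNP-BLUP mixed-model equations with lambda = var_e / (var_a / scale)
    M = cod.M
    lam = var_e / (var_a / cod.scale)
    X = np.ones((n, 1))
    lhs = np.block([[X.T @ X, X.T @ M], [M.T @ X, M.T @ M + lam * np.eye(m)]])
    rhs = np.concatenate([X.T @ y, M.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    a_snp = M @ sol[1:]
    assert np.max(np.abs(a_gblup - a_snp)) < 1e-6


def test_gtv_is_sum_of_genetic_components(small_pipeline):
    for pred in small_pipeline["predictions"].values():
        total = np.sum(list(pred.components.values()), axis=0)
        np.testing.assert_allclose(pred.gtv, total)


def test_predict_requires_matching_dimensions(rng):
    g, _ = hwe_matrix(rng, 10, 30)
    G = ng.build_relationship_matrices(g)["additive"]
    spec = ModelSpec(y=rng.normal(size=8),
                     terms=[RandomTerm("additive", covariance=G.K[:8, :8])])
    fit = solve_at_theta(spec, [1.0, 1.0])
    with pytest.raises(ValueError):
        blup_predict(fit, {"additive": G}, np.ones(10, bool))  # 10 != 8 records
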