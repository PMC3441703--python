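"""Linear mixed models over relationship matrices: AI-REML and BLUP.

The model is y = Xb + Σ_j Z_j u_j + e with u_j ~ N(0, K_j σ²_j) and
e ~ N(0, I σ²_e), where each K_j is a (genomic) relationship matrix or the
identity for grouped environmental effects such as litter.  Variance
components are estimated by restricted maximum likelihood using
average-information (AI) updates with step halving and an EM-REML fallback,
the scheme used by the DMU/ASReml family of programs.  BLUP solutions come
from the fitted covariance structure: u_hat_j = σ²_j K_j Z_j' P y.

The named model family for a corrected-phenotype analysis with litter groups:

* MA   — additive (G) + litter + residual
* MAE  — MA plus additive-by-additive epistasis (G#G)
* MAD  — MA plus dominance (D)
* MAED — all three genetic components + litter + residual

All four are fitted on the same records with the same conventions, so their
-2 log restricted likelihoods are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .relationship import RelationshipMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "REMLFit",
    "PredictionSet",
    "neg2_restricted_loglik",
    "reml_fit",
    "solve_at_theta",
    "blup_solutions",
    "blup_predict",
    "fit_model_family",
    "predict_model_family",
    "MODEL_TERMS",
]

logger = logging.getLogger(__name__)

# lower bound for variance components, relative to var(y)
LOWER_BOUND_FACTOR = 1e-6

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "MA": ("additive", "litter"),
    "MAE": ("additive", "epistatic", "litter"),
    "MAD": ("additive", "dominance", "litter"),
    "MAED": ("additive", "epistatic", "dominance", "litter"),
}

GENETIC_LABELS = ("additive", "epistatic", "dominance")


@dataclass
class RandomTerm:
    """One random effect: label, covariance K (None = identity) and incidence
    Z (None = one record per level, in record order)."""

    label: str
    covariance: np.ndarray | None = None
    incidence: np.ndarray | None = None
    start: float | None = None

    def n_levels(self, n_records: int) -> int:
        if self.covariance is not None:
            return self.covariance.shape[0]
        if self.incidence is not None:
            return self.incidence.shape[1]
        return n_records

    def contribution(self, n_records: int) -> np.ndarray:
        """Z K Z', the N x N covariance contribution per unit variance."""
        K = self.covariance
        Z = self.incidence
        if K is not None and K.shape[0] != K.shape[1]:
            raise ValueError(f"term {self.label!r}: covariance not square")
        if Z is None:
            if K is None:
                return np.eye(n_records)
            if K.shape[0] != n_records:
                raise ValueError(
                    f"term {self.label!r}: covariance is {K.shape[0]}x{K.shape[0]} "
                    f"but there are {n_records} records and no incidence matrix"
                )
            return np.asarray(K, dtype=float)
        if Z.shape[0] != n_records:
            raise ValueError(f"term {self.label!r}: incidence rows != records")
        if K is None:
            return Z @ Z.T
        return Z @ K @ Z.T


@dataclass
class ModelSpec:
    """Response, fixed design (default: intercept only) and random terms."""

    y: np.ndarray
    terms: list[RandomTerm]
    X: np.ndarray | None = None
    residual_start: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("X rows != length of y")
        if np.linalg.matrix_rank(self.X) >= n:
            raise ValueError("need more records than fixed-effect rank for REML")
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("random-term labels must be unique")

    @property
    def n_records(self) -> int:
        return self.y.size

    def labels(self) -> list[str]:
        return [t.label for t in self.terms] + ["residual"]


@dataclass
class REMLFit:
    """REML estimates, their asymptotic SEs, BLUP solutions and the trace."""

    labels: list[str]  # random-term labels, 'residual' last
    theta: np.ndarray
    se: np.ndarray
    minus2logl: float
    converged: bool
    pinned: np.ndarray
    n_iterations: int
    trace: list[dict]
    beta: np.ndarray
    blups: dict[str, np.ndarray]
    model: str | None = None
    spec: ModelSpec | None = field(default=None, repr=False)
    py: np.ndarray | None = field(default=None, repr=False)  # P y at the optimum

    @property
    def variances(self) -> dict[str, float]:
        return dict(zip(self.labels, self.theta))

    def variance(self, label: str) -> float:
        return self.variances[label]

    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.labels, self.se))


@dataclass
class PredictionSet:
    """Per-individual BLUP of each genetic component, GBV and GTV.

    GBV is the additive-component BLUP (the genomic breeding value); GTV is
    the sum of all genetic components in the model (litter and residual are
    excluded).
    """

    individual_ids: list[str]
    components: dict[str, np.ndarray]
    gbv: np.ndarray
    gtv: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {label: vals for label, vals in self.components.items()}
        data["GBV"] = self.gbv
        data["GTV"] = self.gtv
        return pd.DataFrame(data, index=self.individual_ids)


# ---------------------------------------------------------------------------
# restricted likelihood


def _gammas(spec: ModelSpec) -> list[np.ndarray]:
    n = spec.n_records
    out = [t.contribution(n) for t in spec.terms]
    out.append(np.eye(n))  # residual
    return out


def _reml_pieces(
    y: np.ndarray, X: np.ndarray, gammas: Sequence[np.ndarray], theta: np.ndarray
) -> dict:
    """Dense evaluation of the REML criterion and the projection matrix P."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for th, gam in zip(theta[:-1], gammas[:-1]):
        V = V + th * gam
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"V is singular at theta={theta}") from exc
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtViX = X.T @ VinvX
    try:
        cho_x = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X'V^-1X is singular") from exc
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    beta = linalg.cho_solve(cho_x, VinvX.T @ y, check_finite=False)
    P = Vinv - VinvX @ linalg.cho_solve(cho_x, VinvX.T, check_finite=False)
    Py = P @ y
    m2ll = float(logdet_v + logdet_x + y @ Py)
    return {"m2ll": m2ll, "P": P, "Py": Py, "beta": beta}


def _m2ll_only(y: np.ndarray, X: np.ndarray, gammas, theta: np.ndarray) -> float:
    """Criterion value without forming P (used inside step halving)."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for th, gam in zip(theta[:-1], gammas[:-1]):
        V = V + th * gam
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    ViX = linalg.cho_solve(cho, X, check_finite=False)
    Viy = linalg.cho_solve(cho, y, check_finite=False)
    XtViX = X.T @ ViX
    cho_x = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    XtViy = X.T @ Viy
    ypy = y @ Viy - XtViy @ linalg.cho_solve(cho_x, XtViy, check_finite=False)
    return float(logdet_v + logdet_x + ypy)


def neg2_restricted_loglik(spec: ModelSpec, theta: np.ndarray | Sequence[float]) -> float:
    """-2 log restricted likelihood (up to a constant):
    log|V| + log|X'V^-1 X| + y'Py, with P the REML projection matrix.

    ``theta`` lists one variance per random term, residual last.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size != len(spec.terms) + 1:
        raise ValueError("theta must hold one variance per random term plus residual")
    if (theta <= 0).any():
        raise ValueError("variances must be strictly positive")
    return _m2ll_only(spec.y, spec.X, _gammas(spec), theta)


# ---------------------------------------------------------------------------
# AI-REML


def _start_values(spec: ModelSpec, vary: float) -> np.ndarray:
    k = len(spec.terms)
    theta = np.empty(k + 1)
    for j, term in enumerate(spec.terms):
        theta[j] = term.start if term.start is not None else 0.5 * vary / max(k, 1)
    theta[-1] = spec.residual_start if spec.residual_start is not None else 0.5 * vary
    return theta


def reml_fit(spec: ModelSpec, max_iter: int = 200, tol: float = 1e-8) -> REMLFit:
    """Fit variance components by AI-REML.

    Average-information updates with step halving; when a proposed step
    leaves the feasible region or increases the criterion after 10 halvings,
    one EM-REML step is taken instead (EM never increases -2logL).
    Components hitting the lower bound (1e-6 x var(y)) with an outward
    gradient are pinned there and excluded from the AI matrix, including for
    standard errors.
    """
    y, X = spec.y, spec.X
    n = spec.n_records
    gammas = _gammas(spec)
    labels = spec.labels()
    k = len(labels)  # includes residual
    q_levels = np.array([t.n_levels(n) for t in spec.terms] + [n], dtype=float)
    vary = float(np.var(y, ddof=1))

    if vary <= 0:
        # degenerate: no variation in the response; everything at the bound
        eps = 1e-12
        theta = np.full(k, eps)
        pieces = _reml_pieces(y, X, gammas, theta)
        fit = REMLFit(
            labels=labels,
            theta=theta,
            se=np.zeros(k),
            minus2logl=pieces["m2ll"],
            converged=True,
            pinned=np.ones(k, dtype=bool),
            n_iterations=0,
            trace=[],
            beta=pieces["beta"],
            blups={t.label: np.zeros(t.n_levels(n)) for t in spec.terms},
            spec=spec,
            py=pieces["Py"],
        )
        return fit

    lower = LOWER_BOUND_FACTOR * vary
    theta = np.maximum(_start_values(spec, vary), lower)
    pinned = np.zeros(k, dtype=bool)
    trace: list[dict] = []
    converged = False
    pieces = _reml_pieces(y, X, gammas, theta)
    it = 0

    for it in range(1, max_iter + 1):
        m2ll, P, Py = pieces["m2ll"], pieces["P"], pieces["Py"]

        # gradient pieces: tr(P Gamma_j) and y'P Gamma_j P y
        tr_pg = np.array([np.sum(P * gam) for gam in gammas])  # P, Gamma symmetric
        f_vecs = [gam @ Py for gam in gammas]
        ypgpy = np.array([Py @ f for f in f_vecs])
        grad_logl = -0.5 * (tr_pg - ypgpy)  # gradient of log L_R

        # pin components stuck at the bound with an outward gradient
        at_bound = theta <= lower * (1 + 1e-9)
        pinned = at_bound & (grad_logl < 0)
        free = ~pinned
        if not free.any():
            converged = True
            break

        idx = np.flatnonzero(free)
        pf = [P @ f_vecs[i] for i in idx]
        ai = 0.5 * np.array([[f_vecs[i] @ pf[jj] for jj in range(len(idx))] for i in idx])
        # symmetrise tiny asymmetries
        ai = (ai + ai.T) / 2.0

        step_kind = "AI"
        theta_new = None
        m2_new = None
        try:
            delta = np.linalg.solve(ai, grad_logl[idx])
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = delta.copy()
            for halving in range(11):
                cand = theta.copy()
                # clamp components the step pushes out of the feasible region
                cand[idx] = np.maximum(theta[idx] + step, lower)
                try:
                    cand_m2 = _m2ll_only(y, X, gammas, cand)
                except np.linalg.LinAlgError:
                    cand_m2 = np.inf
                if cand_m2 <= m2ll + 1e-10:
                    theta_new = cand
                    m2_new = cand_m2
                    step_kind = "AI" if halving == 0 else f"AI-halved-{halving}"
                    break
                step = step / 2.0
        if theta_new is None:
            # EM-REML fallback: theta_j <- theta_j + theta_j^2/q_j (y'PGPy - tr(PG))
            cand = theta.copy()
            cand[idx] = theta[idx] + (theta[idx] ** 2 / q_levels[idx]) * (
                ypgpy[idx] - tr_pg[idx]
            )
            cand[idx] = np.maximum(cand[idx], lower)
            theta_new = cand
            m2_new = _m2ll_only(y, X, gammas, theta_new)
            step_kind = "EM"

        trace.append(
            {
                "iteration": it,
                "theta": theta.copy(),
                "minus2logl": m2ll,
                "step": step_kind,
            }
        )

        rel_ll = abs(m2_new - m2ll) / max(1.0, abs(m2ll))
        rel_theta = np.max(np.abs(theta_new - theta) / np.maximum(theta, lower))
        theta = theta_new
        pieces = _reml_pieces(y, X, gammas, theta)
        if rel_ll < tol and rel_theta < 1e-6:
            converged = True
            break

    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)

    # final gradient/AI at the optimum for SEs
    m2ll, P, Py, beta = pieces["m2ll"], pieces["P"], pieces["Py"], pieces["beta"]
    tr_pg = np.array([np.sum(P * gam) for gam in gammas])
    f_vecs = [gam @ Py for gam in gammas]
    grad_logl = -0.5 * (tr_pg - np.array([Py @ f for f in f_vecs]))
    pinned = (theta <= lower * (1 + 1e-9)) & (grad_logl < 0)
    se = np.zeros(k)
    idx = np.flatnonzero(~pinned)
    if idx.size:
        pf = [P @ f_vecs[i] for i in idx]
        ai = 0.5 * np.array([[f_vecs[i] @ pf[jj] for jj in range(len(idx))] for i in idx])
        ai = (ai + ai.T) / 2.0
        try:
            cov = np.linalg.inv(ai)
            se[idx] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            logger.warning("AI matrix singular at the optimum; SEs set to 0")

    blups = blup_solutions(spec, theta, Py)
    trace.append({"iteration": it + 1, "theta": theta.copy(), "minus2logl": m2ll, "step": "final"})
    return REMLFit(
        labels=labels,
        theta=theta,
        se=se,
        minus2logl=m2ll,
        converged=converged,
        pinned=pinned,
        n_iterations=it,
        trace=trace,
        beta=beta,
        blups=blups,
        spec=spec,
        py=Py,
    )


def solve_at_theta(spec: ModelSpec, theta: np.ndarray | Sequence[float]) -> REMLFit:
    """Mixed-model solutions at fixed, known variances (no REML iteration).

    Useful for re-deriving BLUP/predictions from stored variance estimates.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size != len(spec.terms) + 1:
        raise ValueError("theta must hold one variance per random term plus residual")
    gammas = _gammas(spec)
    pieces = _reml_pieces(spec.y, spec.X, gammas, theta)
    return REMLFit(
        labels=spec.labels(),
        theta=theta,
        se=np.zeros(theta.size),
        minus2logl=pieces["m2ll"],
        converged=True,
        pinned=np.zeros(theta.size, dtype=bool),
        n_iterations=0,
        trace=[],
        beta=pieces["beta"],
        blups=blup_solutions(spec, theta, pieces["Py"]),
        spec=spec,
        py=pieces["Py"],
    )


def blup_solutions(
    spec: ModelSpec, theta: np.ndarray, py: np.ndarray
) -> dict[str, np.ndarray]:
    """BLUP of each random term at fixed variances: u_j = σ²_j K_j Z_j' P y."""
    out: dict[str, np.ndarray] = {}
    for term, th in zip(spec.terms, theta[:-1]):
        ztpy = py if term.incidence is None else term.incidence.T @ py
        u = ztpy if term.covariance is None else term.covariance @ ztpy
        out[term.label] = th * u
    return out


# ---------------------------------------------------------------------------
# prediction for unphenotyped individuals


def blup_predict(
    fit: REMLFit,
    matrices: Mapping[str, RelationshipMatrix],
    phenotyped: np.ndarray,
) -> PredictionSet:
    """BLUP of the genetic components for every individual in ``matrices``.

    ``matrices`` maps genetic-term labels (as used in the fit) to
    relationship matrices over reference-plus-test individuals; ``phenotyped``
    is a boolean mask over those individuals whose True entries correspond,
    in order, to the records the fit was made on.  Test individuals carry no
    records, so their solutions are the covariance projection
    u_test = σ²_j K_j[test, ref] P y — identical to solving the mixed-model
    equations with the test records absent.
    """
    if fit.py is None:
        raise ValueError("fit carries no projection vector; refit with reml_fit")
    phenotyped = np.asarray(phenotyped, dtype=bool)
    ids = None
    for label, K in matrices.items():
        if label not in fit.labels:
            raise ValueError(f"matrix {label!r} does not match any fitted term")
        if ids is None:
            ids = K.individual_ids
        elif K.individual_ids != ids:
            raise ValueError("relationship matrices cover different individuals")
    if ids is None:
        raise ValueError("no genetic matrices supplied")
    if phenotyped.size != len(ids):
        raise ValueError("phenotyped mask length != number of individuals")
    if int(phenotyped.sum()) != fit.py.size:
        raise ValueError("phenotyped count does not match the fitted records")

    ref = np.flatnonzero(phenotyped)
    variances = fit.variances
    components: dict[str, np.ndarray] = {}
    for label, K in matrices.items():
        components[label] = variances[label] * (K.K[:, ref] @ fit.py)
    gbv = components.get("additive", np.zeros(len(ids)))
    gtv = np.sum([components[lab] for lab in components], axis=0)
    return PredictionSet(list(ids), components, gbv, gtv)


# ---------------------------------------------------------------------------
# the named model family


def _litter_incidence(litters: Sequence) -> np.ndarray:
    codes, uniques = pd.factorize(np.asarray(litters))
    Z = np.zeros((len(codes), len(uniques)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def fit_model_family(
    pheno: pd.DataFrame,
    G: RelationshipMatrix,
    Gaa: RelationshipMatrix | None = None,
    D: RelationshipMatrix | None = None,
    *,
    response: str = "dgc",
    litter: str = "litter",
    reference: str = "is_reference",
    models: Sequence[str] = ("MA", "MAE", "MAD", "MAED"),
    max_iter: int = 200,
    tol: float = 1e-8,
) -> dict[str, REMLFit]:
    """Fit MA / MAE / MAD / MAED on the reference records of ``pheno``.

    ``pheno`` needs columns ``individual_id``, the response, the litter code
    and a boolean reference flag; relationship matrices are over
    reference-plus-test individuals and are subset to the reference block for
    fitting.  Fits share records and conventions so -2logL values are
    comparable across models.
    """
    pheno = pheno.set_index(pheno["individual_id"].astype(str))
    ids = G.individual_ids
    missing = [i for i in ids if i not in pheno.index]
    if missing:
        raise ValueError(f"{len(missing)} matrix individuals missing from phenotypes, e.g. {missing[0]!r}")
    pheno = pheno.loc[ids]
    ref_mask = pheno[reference].to_numpy(dtype=bool)
    y = pheno.loc[ref_mask, response].to_numpy(dtype=float)
    litters = pheno.loc[ref_mask, litter].to_numpy()
    Zl = _litter_incidence(litters)

    available: dict[str, RelationshipMatrix] = {"additive": G}
    if Gaa is not None:
        available["epistatic"] = Gaa
    if D is not None:
        available["dominance"] = D
    ref_blocks = {lab: K.submatrix(ref_mask) for lab, K in available.items()}

    fits: dict[str, REMLFit] = {}
    for model in models:
        if model not in MODEL_TERMS:
            raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_TERMS)}")
        terms: list[RandomTerm] = []
        for label in MODEL_TERMS[model]:
            if label == "litter":
                terms.append(RandomTerm("litter", covariance=None, incidence=Zl))
            else:
                if label not in ref_blocks:
                    raise ValueError(f"model {model} needs a {label!r} relationship matrix")
                terms.append(RandomTerm(label, covariance=ref_blocks[label].K))
        spec = ModelSpec(y=y, terms=terms)
        fit = reml_fit(spec, max_iter=max_iter, tol=tol)
        fit.model = model
        fits[model] = fit
        logger.info(
            "%s: -2logL=%.3f, theta=%s, converged=%s",
            model, fit.minus2logl, np.array2string(fit.theta, precision=3), fit.converged,
        )
    return fits


def predict_model_family(
    fits: Mapping[str, REMLFit],
    G: RelationshipMatrix,
    Gaa: RelationshipMatrix | None,
    D: RelationshipMatrix | None,
    pheno: pd.DataFrame,
    *,
    reference: str = "is_reference",
) -> dict[str, PredictionSet]:
    """Genetic-value predictions for all individuals, for each fitted model."""
    pheno = pheno.set_index(pheno["individual_id"].astype(str)).loc[G.individual_ids]
    ref_mask = pheno[reference].to_numpy(dtype=bool)
    available = {"additive": G, "epistatic": Gaa, "dominance": D}
    out: dict[str, PredictionSet] = {}
    for model, fit in fits.items():
        matrices = {
            lab: available[lab]
            for lab in fit.labels
            if lab in GENETIC_LABELS and available.get(lab) is not None
        }
        out[model] = blup_predict(fit, matrices, ref_mask)
    return out
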