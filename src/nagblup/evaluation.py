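"""Model comparison and predictive-ability statistics.

Covers the validation toolkit for the model family: variance proportions and
heritabilities, likelihood-ratio tests between nested variance-component
models, reliability of genomic breeding values, regression-based
unbiasedness, and the Hotelling-Williams t-test for comparing two dependent
correlations that share a variable (the test phenotype).

Conventions: correlations are Pearson throughout; the LRT uses a plain
central chi-square with df equal to the number of added variance components
(a 50:50 boundary mixture is available behind a flag); the heritability used
for reliability defaults to the narrow-sense estimate from the full MAED
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .varcomp import GENETIC_LABELS, PredictionSet, REMLFit

__all__ = [
    "VarianceProportions",
    "RegressionResult",
    "ValidationReport",
    "proportions_from_components",
    "variance_proportions",
    "likelihood_ratio_test",
    "reliability",
    "regression_unbiasedness",
    "hotelling_williams_test",
    "validate_predictions",
]


@dataclass
class VarianceProportions:
    """Each component's share of phenotypic variance (sum of all components)."""

    proportions: dict[str, float]
    h2_narrow: float
    H2_broad: float

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError("proportions must sum to 1")


@dataclass
class RegressionResult:
    """OLS slope of observed on predicted, its SE, and |b-1|/SE."""

    b: float
    se: float

    @property
    def deviation_from_one(self) -> float:
        return abs(self.b - 1.0) / self.se


@dataclass
class ValidationReport:
    accuracy: pd.DataFrame  # per model: correlations, reliability, regressions
    lrt: pd.DataFrame  # alternative models vs the additive-only baseline
    hotelling: pd.DataFrame  # pairwise comparison of cor(GBV, y_test)
    h2_used: float


def proportions_from_components(components: Mapping[str, float]) -> VarianceProportions:
    """Variance proportions from named variance components.

    Phenotypic variance is defined as the sum of all components in the model.
    Narrow-sense heritability is the additive share; broad-sense adds the
    epistatic and dominance shares when present.
    """
    total = float(sum(components.values()))
    if total <= 0:
        raise ValueError("total variance must be positive")
    props = {label: float(v) / total for label, v in components.items()}
    h2 = props.get("additive", 0.0)
    H2 = sum(props.get(lab, 0.0) for lab in GENETIC_LABELS)
    return VarianceProportions(props, h2, H2)


def variance_proportions(fit: REMLFit) -> VarianceProportions:
    """Variance proportions of a converged REML fit."""
    if not fit.converged:
        raise ValueError("fit did not converge; proportions would be unreliable")
    return proportions_from_components(fit.variances)


def likelihood_ratio_test(
    minus2logl_null: float,
    minus2logl_alt: float,
    df: int,
    *,
    boundary_mixture: bool = False,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Chi-square LRT between nested variance-component models.

    chi2 = -2logL(null) - (-2logL(alt)), floored at zero; P is the upper tail
    of a central chi-square with ``df`` = number of added variance
    components.  With ``boundary_mixture=True`` the 50:50 mixture of
    chi-square(df-1) and chi-square(df) is used instead, which accounts for
    the tested variances lying on the boundary of the parameter space.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    chi2 = minus2logl_null - minus2logl_alt
    if chi2 < -tol * max(1.0, abs(minus2logl_null)):
        raise ValueError(
            f"-2logL increased by {-chi2:.6g} under the larger model; "
            "models are not nested or a fit did not converge"
        )
    chi2 = max(chi2, 0.0)
    if boundary_mixture:
        lower = 0.5 * (stats.chi2.sf(chi2, df - 1) if df > 1 else float(chi2 == 0.0))
        p = lower + 0.5 * stats.chi2.sf(chi2, df)
    else:
        p = float(stats.chi2.sf(chi2, df))
    return float(chi2), float(p)


def reliability(r: float, h2: float) -> float:
    """Reliability of predicted breeding values: cor(GBV, phenotype)^2 / h2.

    ``h2`` is the narrow-sense heritability of the (corrected) phenotype;
    dividing the squared correlation by it converts accuracy against the
    phenotype into accuracy against the unobserved true breeding value.
    """
    if not 0 < h2 <= 1:
        raise ValueError("heritability must lie in (0, 1]")
    return float(r**2 / h2)


def regression_unbiasedness(
    y_test: np.ndarray, predictions: np.ndarray
) -> RegressionResult:
    """OLS slope of observed phenotype on prediction, with its SE.

    A slope of one indicates unbiased predictions; the inflation/shrinkage of
    predictions shows up as slopes above/below one.
    """
    y_test = np.asarray(y_test, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if y_test.size != predictions.size:
        raise ValueError("length mismatch")
    if y_test.size < 3:
        raise ValueError("need at least 3 test records")
    if np.var(predictions) <= 0:
        raise ValueError("predictions have zero variance")
    res = stats.linregress(predictions, y_test)
    return RegressionResult(float(res.slope), float(res.stderr))


def hotelling_williams_test(
    r13: float, r23: float, r12: float, n: int
) -> tuple[float, float, int]:
    """Williams' t-test for two dependent correlations sharing variable 3.

    Tests H0: rho13 = rho23 given the correlation r12 between the two
    predictors, using Williams' statistic

        t = (r13 - r23) * sqrt( (n-1)(1+r12) /
              ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r12)^3 ) ),

    with |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 and
    rbar = (r13 + r23)/2, referred to a t distribution with n-3 df.
    """
    for r in (r13, r23, r12):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    det_r = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det_r < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")
    det_r = max(det_r, 0.0)
    rbar = (r13 + r23) / 2.0
    denom = 2.0 * ((n - 1) / (n - 3)) * det_r + rbar**2 * (1 - r12) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation configuration")
    t = (r13 - r23) * np.sqrt((n - 1) * (1 + r12) / denom)
    df = n - 3
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p, df


def validate_predictions(
    fits: Mapping[str, REMLFit],
    predictions: Mapping[str, PredictionSet],
    pheno: pd.DataFrame,
    *,
    response: str = "dgc",
    reference: str = "is_reference",
    baseline: str = "MA",
    h2: float | None = None,
) -> ValidationReport:
    """Assemble the full validation report over the test individuals.

    For each model: cor(GTV, y), cor(GBV, y), reliability of GBV, and the
    regression slopes of y on GTV and on GBV with their SEs.  Adds an LRT
    table of every model against the baseline and pairwise Hotelling-Williams
    tests on cor(GBV, y).
    """
    pheno = pheno.set_index(pheno["individual_id"].astype(str))
    test_mask = ~pheno[reference].to_numpy(dtype=bool)
    test_ids = list(pheno.index[test_mask])
    if len(test_ids) < 4:
        raise ValueError("need at least 4 test individuals")
    y_test = pheno.loc[test_ids, response].to_numpy(dtype=float)

    if h2 is None:
        source = fits.get("MAED") or fits[list(fits)[-1]]
        h2 = variance_proportions(source).h2_narrow

    rows = []
    gbv_by_model: dict[str, np.ndarray] = {}
    for model, pred in predictions.items():
        frame = pred.to_frame().loc[test_ids]
        gtv = frame["GTV"].to_numpy()
        gbv = frame["GBV"].to_numpy()
        gbv_by_model[model] = gbv
        cor_gtv = float(np.corrcoef(gtv, y_test)[0, 1])
        cor_gbv = float(np.corrcoef(gbv, y_test)[0, 1])
        reg_gtv = regression_unbiasedness(y_test, gtv)
        reg_gbv = regression_unbiasedness(y_test, gbv)
        rows.append(
            {
                "model": model,
                "cor_gtv": cor_gtv,
                "cor_gbv": cor_gbv,
                "reliability": reliability(cor_gbv, h2),
                "b_gtv": reg_gtv.b,
                "se_b_gtv": reg_gtv.se,
                "b_gbv": reg_gbv.b,
                "se_b_gbv": reg_gbv.se,
            }
        )
    accuracy = pd.DataFrame(rows).set_index("model")

    lrt_rows = []
    if baseline in fits:
        base = fits[baseline]
        n_base = len(base.labels)
        for model, fit in fits.items():
            if model == baseline:
                lrt_rows.append(
                    {"model": model, "minus2logl": base.minus2logl, "chi2": np.nan,
                     "df": 0, "p": np.nan}
                )
                continue
            df = len(fit.labels) - n_base
            if df < 1:
                continue
            chi2, p = likelihood_ratio_test(base.minus2logl, fit.minus2logl, df)
            lrt_rows.append(
                {"model": model, "minus2logl": fit.minus2logl, "chi2": chi2, "df": df, "p": p}
            )
    lrt = pd.DataFrame(lrt_rows).set_index("model") if lrt_rows else pd.DataFrame()

    hw_rows = []
    models = list(predictions)
    n_test = len(test_ids)
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            m1, m2 = models[i], models[j]
            r13 = float(np.corrcoef(gbv_by_model[m1], y_test)[0, 1])
            r23 = float(np.corrcoef(gbv_by_model[m2], y_test)[0, 1])
            r12 = float(np.corrcoef(gbv_by_model[m1], gbv_by_model[m2])[0, 1])
            r12 = min(r12, 1 - 1e-12)  # near-identical predictions
            t, p, df = hotelling_williams_test(r13, r23, r12, n_test)
            hw_rows.append({"model_1": m1, "model_2": m2, "t": t, "p": p, "df": df})
    hotelling = pd.DataFrame(hw_rows)

    return ValidationReport(accuracy=accuracy, lrt=lrt, hotelling=hotelling, h2_used=float(h2))
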