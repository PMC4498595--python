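"""Drivers analysis: BIC-approximate Bayesian model averaging for GLMs.

Given a response (annual PU counts, or a PU's selection counts) and a set of
standardized water-availability predictors, every predictor subset is fitted
as a GLM (Gaussian or Poisson, intercept always included) and weighted by

    weight_m  proportional to  exp(-BIC_m / 2),
    BIC_m = -2 loglik_m + k_m ln(n),

the standard unit-information approximation to the posterior model
probability.  Averaging the submodels yields per-predictor posterior
inclusion probabilities, model-averaged coefficients (unconditional and
conditional on inclusion) with total-variance standard deviations, and an
Efron pseudo-R^2 from the averaged predictions.

Predictors are screened for collinearity first by iteratively dropping the
largest variance inflation factor at or above a threshold (default 5).
Model fitting is delegated to statsmodels (OLS for Gaussian, IRLS for
Poisson); the enumeration, weighting and averaging layer lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import ValidationError

__all__ = [
    "DesignMatrix",
    "ModelPosterior",
    "scale_predictors",
    "vif_screen",
    "glm_fit",
    "bma_average",
    "efron_r2",
]


@dataclass(frozen=True)
class DesignMatrix:
    """Response, named predictor columns, and the error family."""

    y: np.ndarray
    X: pd.DataFrame
    family: str = "gaussian"
    standardized: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if self.family not in ("gaussian", "poisson"):
            raise ValidationError(f"family must be gaussian or poisson, got {self.family!r}")
        if len(y) != len(self.X):
            raise ValidationError("response and predictors have different lengths")
        if np.isnan(y).any() or self.X.isna().to_numpy().any():
            raise ValidationError("design matrix must not contain missing values")
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, names) -> "DesignMatrix":
        return replace(self, X=self.X[list(names)])


def scale_predictors(dm: DesignMatrix, log_columns=()) -> DesignMatrix:
    """Center each predictor to mean 0 and scale to sample sd 1 (n-1).

    Columns named in ``log_columns`` (e.g. total flow) are log-transformed
    first.  The response is untouched.  A zero-variance column is an error —
    it cannot be standardized and carries no information.
    """
    X = dm.X.copy().astype(float)
    for col in log_columns:
        if col in X.columns:
            if (X[col] <= 0).any():
                raise ValidationError(f"column {col!r} must be positive for log transform")
            X[col] = np.log(X[col])
    for col in X.columns:
        sd = X[col].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValidationError(f"predictor {col!r} has zero variance; cannot standardize")
        X[col] = (X[col] - X[col].mean()) / sd
    return replace(dm, X=X, standardized=True)


def vif_screen(dm: DesignMatrix, threshold: float = 5.0):
    """Iterative variance-inflation-factor screen.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing predictor j on the
    remaining predictors (with intercept).  While any VIF is at or above the
    threshold, the largest is dropped (highest column index on ties) and the
    VIFs recomputed.  Perfectly collinear columns surface as infinite VIF.

    Returns ``(retained names, trace)`` where the trace is one DataFrame row
    of VIFs per elimination round.
    """
    cols = list(dm.X.columns)
    if len(cols) < 2:
        raise ValidationError("VIF screen needs at least 2 predictors")
    trace_rows = []
    while True:
        vifs = {}
        for j, col in enumerate(cols):
            others = [c for c in cols if c != col]
            if not others:
                vifs[col] = 1.0
                continue
            exog = sm.add_constant(dm.X[others].to_numpy())
            r2 = sm.OLS(dm.X[col].to_numpy(), exog).fit().rsquared
            vifs[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        trace_rows.append(dict(vifs))
        worst = max(vifs.values())
        if worst < threshold or len(cols) == 1:
            break
        # drop the largest VIF; on ties, the highest column index
        candidates = [c for c in cols if vifs[c] == worst]
        drop = candidates[-1]
        cols.remove(drop)
    trace = pd.DataFrame(trace_rows)
    return cols, trace


def glm_fit(dm: DesignMatrix):
    """Maximum-likelihood GLM fit with an intercept always included.

    Gaussian: ordinary least squares with the variance profiled out of the
    likelihood.  Poisson: log link via iteratively reweighted least squares.
    Returns ``(coefficients as a Series indexed const + predictors,
    log-likelihood, fit result)``.
    """
    if dm.n <= len(dm.predictors) + 1:
        raise ValidationError("need more observations than estimated coefficients")
    exog = sm.add_constant(dm.X.to_numpy(), has_constant="add")
    names = ["const"] + dm.predictors
    if dm.family == "gaussian":
        fit = sm.OLS(dm.y, exog).fit()
    else:
        fit = sm.GLM(dm.y, exog, family=sm.families.Poisson()).fit(tol=1e-10, maxiter=200)
        if not fit.converged:
            raise ValidationError(
                f"Poisson IRLS failed to converge for predictors {dm.predictors}"
            )
    coefs = pd.Series(fit.params, index=names)
    return coefs, float(fit.llf), fit


def _predict(fit_exog, coefs: np.ndarray, family: str) -> np.ndarray:
    eta = fit_exog @ coefs
    return np.exp(eta) if family == "poisson" else eta


@dataclass(frozen=True)
class ModelPosterior:
    """Enumerated submodels with BIC weights and model-averaged summaries."""

    models: pd.DataFrame          # predictors, k, loglik, bic, weight
    summary: pd.DataFrame         # term, pp, beta_mean, beta_sd, beta_cond
    pseudo_r2: float
    family: str
    n: int

    def pp(self) -> pd.Series:
        return self.summary.set_index("term")["pp"]

    def beta(self) -> pd.Series:
        return self.summary.set_index("term")["beta_mean"]


def bma_average(dm: DesignMatrix, occam_odds: float | None = 20.0) -> ModelPosterior:
    """Enumerate all predictor subsets and average them by BIC weight.

    ``k_m`` counts every estimated parameter (intercept, slopes, and the
    Gaussian error variance).  With ``occam_odds`` set, models whose
    posterior odds against the best model exceed the cutoff are discarded
    before renormalizing (Occam's window).  Inclusion probabilities sum the
    weights of the models containing each term; averaged coefficients treat
    a term as 0 where excluded (the unconditional estimate; the
    inclusion-conditional value is also reported), and their sd comes from
    the law of total variance across models.
    """
    k = len(dm.predictors)
    if k > 20:
        raise ValidationError("full enumeration supports at most 20 predictors")
    exog_full = sm.add_constant(dm.X.to_numpy(), has_constant="add")
    terms = ["const"] + dm.predictors

    rows = []
    fits = []
    for size in range(k + 1):
        for subset in combinations(dm.predictors, size):
            sub = dm.subset(subset)
            coefs, llf, fit = glm_fit(sub)
            n_par = len(coefs) + (1 if dm.family == "gaussian" else 0)
            bic = -2.0 * llf + n_par * np.log(dm.n)
            rows.append({"predictors": subset, "k": n_par, "loglik": llf, "bic": bic})
            fits.append((subset, coefs, fit))
    models = pd.DataFrame(rows)
    rel = np.exp(-0.5 * (models["bic"] - models["bic"].min()))
    keep = np.ones(len(models), dtype=bool)
    if occam_odds is not None:
        keep = (rel.max() / rel) <= occam_odds
    weight = np.where(keep, rel, 0.0)
    weight = weight / weight.sum()
    models["weight"] = weight

    # model-averaged coefficients over the retained models
    beta = np.zeros((len(models), len(terms)))
    var = np.zeros_like(beta)
    preds = np.zeros(dm.n)
    term_index = {t: i for i, t in enumerate(terms)}
    for m, (subset, coefs, fit) in enumerate(fits):
        if weight[m] == 0:
            continue
        cols = [0] + [1 + dm.predictors.index(p) for p in subset]
        full = np.zeros(len(terms))
        for name, value in coefs.items():
            full[term_index[name if name == "const" else name]] = value
        beta[m] = full
        se = np.zeros(len(terms))
        for local, name in enumerate(["const"] + list(subset)):
            se[term_index[name]] = fit.bse[local]
        var[m] = se**2
        preds += weight[m] * _predict(exog_full[:, cols], np.asarray(coefs), dm.family)

    w = weight[:, None]
    beta_mean = (w * beta).sum(axis=0)
    second_moment = (w * (var + beta**2)).sum(axis=0)
    beta_sd = np.sqrt(np.maximum(0.0, second_moment - beta_mean**2))
    pp = np.array(
        [
            1.0 if t == "const" else float(
                models.loc[[t in s for s in models["predictors"]], "weight"].sum()
            )
            for t in terms
        ]
    )
    pp = np.clip(pp, 0.0, 1.0)  # guard the summation against 1 + eps
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_cond = np.where(pp > 0, beta_mean / np.where(pp > 0, pp, 1), 0.0)

    summary = pd.DataFrame(
        {"term": terms, "pp": pp, "beta_mean": beta_mean, "beta_sd": beta_sd,
         "beta_cond": beta_cond}
    )
    return ModelPosterior(
        models=models, summary=summary,
        pseudo_r2=efron_r2(dm.y, preds), family=dm.family, n=dm.n,
    )


def efron_r2(y, fitted) -> float:
    """Efron's pseudo R^2: squared Pearson correlation of observed and fitted.

    A constant fitted vector has no association to measure; it returns 0
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if y.shape != fitted.shape:
        raise ValidationError("y and fitted must have equal lengths")
    if len(y) < 2:
        raise ValidationError("need at least 2 observations")
    if np.std(fitted) == 0 or np.std(y) == 0:
        warnings.warn("constant vector: pseudo R^2 undefined, returning 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(y, fitted)[0, 1] ** 2)
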