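"""Difference-in-differences GLMs for hospital-utilisation outcomes.

Four outcomes are modelled on the log scale:

* ED presentation rate and inpatient admission rate — Poisson log-linear
  models on monthly counts with a ``log(beds/1000)`` exposure offset;
* ED and inpatient length of stay — gamma GLMs with log link on episode
  records, adjusting for age group, gender, triage category, diagnosis
  group, and day/time of attendance.

Each model carries indicators ``x1`` (intervention hospital), ``x2`` (post
period) and ``x3 = x1 * x2`` (the realized intervention cell); ``exp(beta3)``
is the intervention rate/LOS ratio.  With two hospitals and two periods the
intervention indicator is identical to the hospital-by-period interaction,
which is the only estimable encoding.

Estimators follow the scikit-learn protocol (``fit``, ``predict``,
``get_params``); the fitted statsmodels results object is kept on the
estimator for inspection.  Adjusted cell means use marginal standardization
over the pooled observed covariate distribution, and interval estimates for
means and differences come from parametric simulation of the coefficient
vector (multivariate normal on the estimated covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from sklearn.base import BaseEstimator

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "RateEffectModel",
    "LosEffectModel",
    "InterventionContrast",
    "ResidualDiagnostics",
    "ConvergenceError",
    "fit_rate_model",
    "fit_los_model",
    "adjusted_means",
    "intervention_contrast",
    "residual_diagnostics",
]

DEFAULT_CONFOUNDERS = (
    "age_group",
    "gender",
    "triage",
    "diagnosis_group",
    "attendance_day",
    "attendance_time",
)

CELLS = [
    ("control", "pre"),
    ("control", "post"),
    ("intervention", "pre"),
    ("intervention", "post"),
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace per iteration."""

    def __init__(self, message, trace):
        super().__init__(f"{message}; deviance trace: {trace}")
        self.trace = trace


def _design_indicators(data: pd.DataFrame) -> pd.DataFrame:
    frame = data.copy()
    frame["x1"] = (frame["hospital"] == "intervention").astype(int)
    frame["x2"] = (frame["year"] == "post").astype(int)
    frame["x3"] = frame["x1"] * frame["x2"]
    return frame


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a 95% interval."""

    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class InterventionContrast:
    """With/without-intervention adjusted means and their difference.

    All three quantities refer to the intervention-hospital post-period
    cell: ``without`` forces the intervention indicator to 0, ``with_`` to 1.
    The p-value is the Wald p-value of the intervention coefficient.
    """

    without: Estimate
    with_: Estimate
    difference: Estimate
    p_value: float


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Standardized deviance residual diagnostics for a fitted model."""

    fitted: np.ndarray
    residuals: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    deviance_ratio: float
    pearson_ratio: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fitted": self.fitted, "residual": self.residuals})


class _BaseDiDModel(BaseEstimator):
    """Shared fitting machinery for the DiD GLMs."""

    covariates: tuple = ()

    def _formula(self, outcome: str) -> str:
        terms = ["x1", "x2", "x3"] + [f"C({c})" for c in self.covariates]
        return f"{outcome} ~ " + " + ".join(terms)

    def _fit_glm(self, frame: pd.DataFrame, outcome: str, family, offset=None, scale=None):
        model = smf.glm(self._formula(outcome), data=frame, family=family, offset=offset)
        result = model.fit(maxiter=200, scale=scale)
        if not result.converged:
            raise ConvergenceError(
                "GLM did not converge", result.fit_history.get("deviance")
            )
        self.frame_ = frame
        self.result_ = result
        self.coefficients_ = result.params
        self.cov_ = result.cov_params()
        conf = result.conf_int()
        self.ratios_ = pd.DataFrame(
            {
                "coef": result.params,
                "ratio": np.exp(result.params),
                "ci_low": np.exp(conf[0]),
                "ci_high": np.exp(conf[1]),
                "p_value": result.pvalues,
            }
        )
        self.n_obs_ = int(result.nobs)
        df = result.df_resid
        self.deviance_ratio_ = float(result.deviance / df) if df > 0 else np.nan
        self.pearson_ratio_ = float(result.pearson_chi2 / df) if df > 0 else np.nan
        self.scale_ = float(result.scale)
        return self

    # -- prediction helpers ------------------------------------------------------

    def _design_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        design_info = self.result_.model.data.design_info
        (mat,) = patsy.build_design_matrices([design_info], frame)
        return np.asarray(mat)

    def _split_columns(self):
        names = list(self.result_.model.data.design_info.column_names)
        cell = [n for n in ("Intercept", "x1", "x2", "x3") if n in names]
        cov = [n for n in names if n not in cell]
        return names, cell, cov

    def _cell_eta(self, x1: int, x2: int, x3: int, beta) -> np.ndarray:
        """Linear-predictor contribution of the design-cell terms.

        ``beta`` may be a 1-d coefficient vector or an (n_draws, p) matrix.
        """
        names, _, _ = self._split_columns()
        single = np.asarray(beta).ndim == 1
        beta = np.atleast_2d(np.asarray(beta))
        values = {"Intercept": 1.0, "x1": x1, "x2": x2, "x3": x3}
        eta = np.zeros(beta.shape[0])
        for term, val in values.items():
            if term in names:
                eta += val * beta[:, names.index(term)]
        return float(eta[0]) if single else eta

    def _standardization_factor(self, beta, chunk: int = 500) -> np.ndarray:
        """Mean over pooled covariate rows of exp(covariate part of eta).

        Marginal standardization: every observed covariate combination is
        carried to the target cell and predictions are averaged on the
        response scale.  Factorises out of the cell terms because the model
        is log-linear.
        """
        names, _, cov = self._split_columns()
        single = np.asarray(beta).ndim == 1
        beta = np.atleast_2d(np.asarray(beta))
        if not cov:
            return 1.0 if single else np.ones(beta.shape[0])
        X = self._design_matrix(self.frame_)[:, [names.index(c) for c in cov]]
        B = beta[:, [names.index(c) for c in cov]]
        out = np.empty(B.shape[0])
        for start in range(0, B.shape[0], chunk):
            block = B[start : start + chunk]
            out[start : start + chunk] = np.exp(X @ block.T).mean(axis=0)
        return float(out[0]) if single else out

    def _cell_mean(self, x1, x2, x3, beta) -> np.ndarray:
        return np.exp(self._cell_eta(x1, x2, x3, beta)) * self._standardization_factor(beta)

    def _coef_draws(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        beta = self.coefficients_.to_numpy()
        cov = np.asarray(self.cov_)
        return rng.multivariate_normal(beta, cov, size=n_draws)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted mean response (rate per 1,000 beds/month, or LOS hours)."""
        frame = _design_indicators(data)
        X = self._design_matrix(frame)
        return np.exp(X @ self.coefficients_.to_numpy())


class RateEffectModel(_BaseDiDModel):
    """Poisson log-linear DiD model for monthly event rates.

    Parameters
    ----------
    outcome : ``"presentations"`` or ``"admissions"``.
    n_draws : simulation draws used for interval estimates.
    random_state : seed of the simulation RNG.

    Fitted attributes (trailing underscore) include ``coefficients_``,
    ``cov_``, ``ratios_`` (exponentiated coefficients with 95% CIs and
    p-values), ``deviance_ratio_`` and ``pearson_ratio_``.
    """

    def __init__(self, outcome: str = "presentations", n_draws: int = 10_000, random_state: int = 0):
        self.outcome = outcome
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        if self.outcome not in ("presentations", "admissions"):
            raise ValueError("outcome must be 'presentations' or 'admissions'")
        frame = _design_indicators(data)
        if np.any(frame["exposure_beds"] <= 0):
            raise ValueError("exposures must be strictly positive")
        for h, yr in CELLS:
            if not ((frame["hospital"] == h) & (frame["year"] == yr)).any():
                raise ValueError(f"design cell ({h}, {yr}) has no observations")
        offset = np.log(frame["exposure_beds"].to_numpy() / 1000.0)
        return self._fit_glm(
            frame, f"n_{self.outcome}", sm.families.Poisson(), offset=offset
        )


class LosEffectModel(_BaseDiDModel):
    """Gamma log-link DiD model for length of stay, adjusting for confounders.

    ``outcome`` is ``"ed"`` or ``"inpatient"``; the latter uses admitted
    episodes only.  Dispersion is estimated by the Pearson method.
    """

    def __init__(
        self,
        outcome: str = "ed",
        covariates: tuple = DEFAULT_CONFOUNDERS,
        n_draws: int = 10_000,
        random_state: int = 0,
    ):
        self.outcome = outcome
        self.covariates = covariates
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        if self.outcome not in ("ed", "inpatient"):
            raise ValueError("outcome must be 'ed' or 'inpatient'")
        column = f"{self.outcome}_los_hours"
        frame = _design_indicators(data)
        if self.outcome == "inpatient":
            frame = frame[frame["admitted"].astype(bool)].reset_index(drop=True)
        frame = frame[frame[column].notna()].reset_index(drop=True)
        if len(frame) == 0:
            raise ValueError("no usable LOS observations")
        if np.any(frame[column] <= 0):
            raise ValueError("length-of-stay values must be strictly positive")
        family = sm.families.Gamma(link=sm.families.links.Log())
        # Pearson dispersion is 0/0 when the outcome is constant; fall back
        # to unit scale for that degenerate (noise-free) case
        scale = "X2" if frame[column].nunique() > 1 else 1.0
        return self._fit_glm(frame, column, family, scale=scale)


def fit_rate_model(counts: pd.DataFrame, outcome: str = "presentations", **kwargs) -> RateEffectModel:
    """Fit the Poisson rate model on a monthly-count extract."""
    return RateEffectModel(outcome=outcome, **kwargs).fit(counts)


def fit_los_model(episodes: pd.DataFrame, outcome: str = "ed", **kwargs) -> LosEffectModel:
    """Fit the gamma LOS model on an episode extract."""
    return LosEffectModel(outcome=outcome, **kwargs).fit(episodes)


def _check_fitted(model):
    if not hasattr(model, "result_"):
        raise ValueError("model is not fitted")


def _cell_indicators(hospital: str, year: str):
    x1 = int(hospital == "intervention")
    x2 = int(year == "post")
    return x1, x2, x1 * x2


def adjusted_means(
    model,
    cells=CELLS,
    n_draws: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Marginally standardized mean response per design cell, with 95% CIs.

    The intervention indicator takes its realized value (1 only in the
    intervention-hospital post-period cell).  Intervals are percentile
    intervals over parametric simulation draws of the coefficients.
    """
    _check_fitted(model)
    if rng is None:
        rng = np.random.default_rng(model.random_state)
    draws = model._coef_draws(n_draws or model.n_draws, rng)
    factor = model._standardization_factor(draws)
    factor_hat = model._standardization_factor(model.coefficients_.to_numpy())
    rows = []
    observed = set(zip(model.frame_["hospital"], model.frame_["year"]))
    for hospital, year in cells:
        if (hospital, year) not in observed:
            raise ValueError(f"design cell ({hospital}, {year}) not present in data")
        x1, x2, x3 = _cell_indicators(hospital, year)
        mean = float(
            np.exp(model._cell_eta(x1, x2, x3, model.coefficients_.to_numpy()))
            * factor_hat
        )
        sim = np.exp(model._cell_eta(x1, x2, x3, draws)) * factor
        lo, hi = np.percentile(sim, [2.5, 97.5])
        rows.append(
            {"hospital": hospital, "year": year, "mean": mean, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows).set_index(["hospital", "year"])


def intervention_contrast(
    model,
    n_draws: int | None = None,
    rng: np.random.Generator | None = None,
) -> InterventionContrast:
    """With/without-intervention estimates for the treated cell.

    Both estimates refer to the intervention hospital in the post period;
    "without" forces the intervention indicator to 0 (the counterfactual),
    "with" to 1.  The difference and its 95% CI come from the same
    parametric simulation draws, so ``difference = with - without`` holds
    exactly for the point estimates.
    """
    _check_fitted(model)
    if "x3" not in model.coefficients_.index:
        raise ValueError("model does not include the intervention indicator")
    if rng is None:
        rng = np.random.default_rng(model.random_state)
    draws = model._coef_draws(n_draws or model.n_draws, rng)
    factor = model._standardization_factor(draws)
    factor_hat = model._standardization_factor(model.coefficients_.to_numpy())
    beta_hat = model.coefficients_.to_numpy()

    def _pair(beta, fac):
        without = np.exp(model._cell_eta(1, 1, 0, beta)) * fac
        with_ = np.exp(model._cell_eta(1, 1, 1, beta)) * fac
        return without, with_

    w0_hat, w1_hat = _pair(beta_hat, factor_hat)
    w0, w1 = _pair(draws, factor)
    diff = w1 - w0

    def _est(point, sim):
        lo, hi = np.percentile(sim, [2.5, 97.5])
        return Estimate(float(point), float(lo), float(hi))

    return InterventionContrast(
        without=_est(w0_hat, w0),
        with_=_est(w1_hat, w1),
        difference=_est(w1_hat - w0_hat, diff),
        p_value=float(model.result_.pvalues["x3"]),
    )


def residual_diagnostics(model, bins: int = 30) -> ResidualDiagnostics:
    """Standardized deviance residuals vs fitted values, plus summary ratios.

    Quantile pairs use rank-averaged plotting positions ``(r - 0.5)/n``
    against the standard normal, with ties broken by averaging ranks.
    """
    _check_fitted(model)
    result = model.result_
    scale = model.scale_ if model.scale_ > 0 else 1.0
    resid = np.asarray(result.resid_deviance) / np.sqrt(scale)
    fitted = np.asarray(result.fittedvalues)
    counts, edges = np.histogram(resid, bins=bins)
    ranks = stats.rankdata(resid, method="average")
    theoretical = stats.norm.ppf((ranks - 0.5) / len(resid))
    order = np.argsort(resid, kind="stable")
    return ResidualDiagnostics(
        fitted=fitted,
        residuals=resid,
        hist_counts=counts,
        hist_edges=edges,
        qq_theoretical=theoretical[order],
        qq_sample=resid[order],
        deviance_ratio=model.deviance_ratio_,
        pearson_ratio=model.pearson_ratio_,
    )
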