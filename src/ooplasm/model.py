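"""Quartile recoding, optimal ranges, logistic outcome models and ROC/AUC.

Each continuous imaging parameter is recoded into quartiles Q1-Q4 computed
over all inseminated oocytes.  For an outcome, the two quartiles with the
highest outcome rate define that parameter's "optimal range"; membership of
the optimal range is a binary predictor.  One binary logistic regression per
outcome on these indicators yields odds ratios with Wald 95% CIs, an ROC
AUC, and 0.5-threshold confusion metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import ConfusionMetrics, confusion_metrics

QUARTILE_NAMES = ("Q1", "Q2", "Q3", "Q4")


class ModelError(ValueError):
    """Raised for degenerate model inputs."""


class SeparationError(ModelError):
    """Raised when the outcome is (quasi-)completely separated by a predictor."""


class ConvergenceError(ModelError):
    """Raised when the likelihood maximization fails to converge."""


# ----------------------------------------------------------- quartiles

@dataclass(frozen=True)
class QuartileScheme:
    """Sample-quartile cut points and the Q1-Q4 label of every oocyte.

    Cut points use the linear-interpolation sample-quantile definition
    (configurable through ``assign_quartiles``); labels come from half-open
    bins (-inf, q25], (q25, q50], (q50, q75], (q75, inf), so a value lying
    exactly on a cut point goes to the lower quartile.
    """

    cuts: tuple[float, float, float]
    labels: np.ndarray = field(repr=False)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=5)[1:5]


def quartile_of(values, cuts) -> np.ndarray:
    """Q1-Q4 integer label (1..4) for values given (q25, q50, q75) cut points."""
    v = np.asarray(values, dtype=float)
    q25, q50, q75 = cuts
    return (1 + (v > q25).astype(int) + (v > q50).astype(int)
            + (v > q75).astype(int))


def assign_quartiles(values, method: str = "linear") -> QuartileScheme:
    """Recode continuous values into quartile labels Q1-Q4.

    Raises
    ------
    ModelError
        Fewer than 4 finite values, or all values identical (degenerate
        quartiles).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4 or not np.all(np.isfinite(v)):
        raise ModelError("need >= 4 finite values for quartiles")
    if np.ptp(v) == 0:
        raise ModelError("all values identical; quartiles degenerate")
    cuts = tuple(float(c) for c in np.quantile(v, [0.25, 0.5, 0.75], method=method))
    return QuartileScheme(cuts=cuts, labels=quartile_of(v, cuts))


# -------------------------------------------------------- optimal range

@dataclass(frozen=True)
class OptimalRange:
    """The two quartiles of a feature with the highest outcome rate.

    ``bounds`` are the continuous limits of the selected quartile bins; for a
    non-contiguous selection (flagged) membership is still evaluated through
    the quartile labels, which ``contains`` reproduces exactly on the
    training cohort.
    """

    feature: str
    outcome: str
    cuts: tuple[float, float, float]
    quartile_rates: tuple[float, float, float, float]
    selected: tuple[int, int]  # 1-based quartile indices, ascending
    contiguous: bool

    @property
    def bounds(self) -> tuple[float, float]:
        """(low, high) continuous bounds of the selected bins (union hull)."""
        edges = (-np.inf, *self.cuts, np.inf)
        lo = min(edges[q - 1] for q in self.selected)
        hi = max(edges[q] for q in self.selected)
        return (float(lo), float(hi))

    def contains(self, values):
        """Boolean in-optimal-range indicator for scalar or array input."""
        labels = quartile_of(values, self.cuts)
        result = np.isin(labels, self.selected)
        return bool(result) if np.isscalar(values) else result


def optimal_range(scheme: QuartileScheme, outcomes, feature: str = "",
                  outcome_name: str = "") -> OptimalRange:
    """Select the two quartiles with the highest outcome rate.

    ``outcomes`` is a binary vector aligned with the scheme's labels; NaN
    marks oocytes ineligible for this outcome (e.g. not transferred) and is
    excluded from the rates.  Rate ties prefer a contiguous (adjacent) pair,
    then the pair with the lower quartile indices.

    Raises
    ------
    ModelError
        If any quartile has no eligible oocyte.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.size != scheme.labels.size:
        raise ModelError("outcomes length differs from quartile labels")
    eligible = ~np.isnan(y)
    rates = []
    for q in range(1, 5):
        sel = (scheme.labels == q) & eligible
        if not sel.any():
            raise ModelError(f"quartile Q{q} has no eligible oocyte for '{outcome_name}'")
        rates.append(100.0 * float(np.mean(y[sel])))
    # best pair by total rate; ties prefer contiguous, then lower indices
    best = max(
        ((i, j) for i in range(1, 5) for j in range(i + 1, 5)),
        key=lambda p: (round(rates[p[0] - 1] + rates[p[1] - 1], 9),
                       p[1] - p[0] == 1, -(p[0] * 10 + p[1])),
    )
    return OptimalRange(feature=feature, outcome=outcome_name, cuts=scheme.cuts,
                        quartile_rates=tuple(rates), selected=best,
                        contiguous=(best[1] - best[0] == 1))


def quartile_rate_table(features_df: pd.DataFrame, outcomes_df: pd.DataFrame,
                        feature_cols, outcome_cols) -> pd.DataFrame:
    """Feature x quartile outcome-rate table with optimal-range flags.

    One row per (feature, quartile): the quartile bin bounds, the outcome
    rate (%) per outcome, and whether that quartile belongs to the optimal
    range for each outcome.
    """
    rows = []
    for feat in feature_cols:
        scheme = assign_quartiles(features_df[feat].to_numpy())
        edges = (-np.inf, *scheme.cuts, np.inf)
        ranges = {out: optimal_range(scheme, outcomes_df[out].to_numpy(),
                                     feature=feat, outcome_name=out)
                  for out in outcome_cols}
        for q in range(1, 5):
            row = {"feature": feat, "quartile": QUARTILE_NAMES[q - 1],
                   "low": edges[q - 1], "high": edges[q],
                   "n": int(np.sum(scheme.labels == q))}
            for out in outcome_cols:
                row[f"{out}_rate"] = ranges[out].quartile_rates[q - 1]
                row[f"{out}_optimal"] = q in ranges[out].selected
            rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ logistic

@dataclass(frozen=True)
class LogisticModel:
    """Fitted binary logistic regression on optimal-range indicators.

    Coefficients are maximum-likelihood (Newton/IRLS); standard errors come
    from the inverse observed information, so OR = exp(coef) and the 95% CI
    is exp(coef +/- 1.96 SE).
    """

    outcome: str
    predictors: tuple[str, ...]
    intercept: float
    coefs: np.ndarray = field(repr=False)
    ses: np.ndarray = field(repr=False)
    report: pd.DataFrame = field(repr=False, compare=False)

    def predict(self, indicators) -> np.ndarray:
        x = np.asarray(indicators, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != len(self.predictors):
            raise ModelError("indicator matrix width differs from predictor count")
        eta = self.intercept + x @ self.coefs
        return 1.0 / (1.0 + np.exp(-eta))

    def odds_ratios(self) -> pd.DataFrame:
        return self.report


_SEPARATION_COEF = 15.0  # |log-odds| beyond this is numerically a separated fit


def fit_logistic(indicators, outcome, predictor_names=None,
                 outcome_name: str = "", maxiter: int = 100,
                 tol: float = 1e-8) -> LogisticModel:
    """Maximum-likelihood binary logistic regression with Wald inference.

    ``indicators`` is an (n, k) binary matrix (or DataFrame) of in-optimal-
    range predictors; an intercept is always included.  Convergence is by
    Newton iteration to a parameter-change tolerance of ``tol`` within
    ``maxiter`` iterations.

    Raises
    ------
    ModelError
        Constant predictor column or too few rows.
    SeparationError
        Complete or quasi-complete separation (divergent coefficients).
    ConvergenceError
        Newton iteration fails to converge.
    """
    if isinstance(indicators, pd.DataFrame):
        names = tuple(indicators.columns) if predictor_names is None else tuple(predictor_names)
        x = indicators.to_numpy(dtype=float)
    else:
        x = np.asarray(indicators, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = (tuple(predictor_names) if predictor_names is not None
                 else tuple(f"x{i + 1}" for i in range(x.shape[1])))
    y = np.asarray(outcome, dtype=float)
    if y.size != x.shape[0]:
        raise ModelError("outcome length differs from indicator rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelError("outcome must be binary 0/1")
    if x.shape[0] <= x.shape[1] + 1:
        raise ModelError("need n > number of predictors + 1")
    for j, name in enumerate(names):
        if np.ptp(x[:, j]) == 0:
            raise ModelError(f"predictor '{name}' is constant")

    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(method="newton", maxiter=maxiter,
                                          tol=tol, disp=0, warn_convergence=False)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise SeparationError(f"separated fit for '{outcome_name}': {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix for '{outcome_name}'") from exc
    params = np.asarray(res.params, dtype=float)
    if np.any(np.abs(params) > _SEPARATION_COEF):
        raise SeparationError(f"divergent coefficients for '{outcome_name}' "
                              "(quasi-complete separation)")
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit for '{outcome_name}' did not converge")
    ses = np.asarray(res.bse, dtype=float)

    coefs, coef_ses = params[1:], ses[1:]
    z = sps.norm.ppf(0.975)
    report = pd.DataFrame({
        "predictor": names,
        "coef": coefs,
        "se": coef_ses,
        "or": np.exp(coefs),
        "ci_low": np.exp(coefs - z * coef_ses),
        "ci_high": np.exp(coefs + z * coef_ses),
    })
    return LogisticModel(outcome=outcome_name, predictors=names,
                         intercept=float(params[0]), coefs=coefs,
                         ses=coef_ses, report=report)


# ------------------------------------------------------------- ROC/AUC

@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci: tuple[float, float]


def roc_auc(scores, outcome) -> RocResult:
    """AUC via the Mann-Whitney identity (ties count one half).

    The standard error is Hanley-McNeil; the 95% CI is clipped to [0, 1].

    Raises
    ------
    ModelError
        If only one outcome class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s.size != y.size:
        raise ModelError("scores and outcome lengths differ")
    pos, neg = s[y == 1], s[y == 0]
    n1, n2 = pos.size, neg.size
    if n1 == 0 or n2 == 0:
        raise ModelError("both outcome classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return RocResult(auc=float(auc), se=se, ci=(float(ci[0]), float(ci[1])))


def classify(model: LogisticModel, indicators, outcome,
             threshold: float = 0.5) -> tuple[np.ndarray, ConfusionMetrics]:
    """Threshold predicted probabilities and score against the outcomes."""
    probs = model.predict(indicators)
    preds = probs >= threshold
    return preds, confusion_metrics(preds, np.asarray(outcome, dtype=float) == 1)


# ----------------------------------------------------- outcome pipeline

@dataclass(frozen=True)
class OutcomeModel:
    """Everything fitted for one outcome: ranges, logistic model, AUC, metrics."""

    outcome: str
    ranges: dict
    model: LogisticModel
    auc: RocResult
    metrics: ConfusionMetrics

    def report(self) -> pd.DataFrame:
        rep = self.model.report.copy()
        rep.insert(0, "outcome", self.outcome)
        return rep


def fit_outcome_model(features_df: pd.DataFrame, outcomes: pd.Series | np.ndarray,
                      feature_cols, outcome_name: str = "") -> OutcomeModel:
    """Quartile -> optimal range -> logistic -> ROC pipeline for one outcome.

    Quartiles and optimal ranges are computed on the full feature table
    (all inseminated oocytes); the logistic model is fitted on the rows where
    the outcome is defined (non-NaN).
    """
    y = np.asarray(outcomes, dtype=float)
    ranges = {}
    indicators = pd.DataFrame(index=features_df.index)
    for feat in feature_cols:
        scheme = assign_quartiles(features_df[feat].to_numpy())
        rng = optimal_range(scheme, y, feature=feat, outcome_name=outcome_name)
        ranges[feat] = rng
        indicators[f"{feat}_in_range"] = rng.contains(features_df[feat].to_numpy()).astype(int)
    fit_rows = ~np.isnan(y)
    model = fit_logistic(indicators.loc[fit_rows], y[fit_rows],
                         outcome_name=outcome_name)
    probs = model.predict(indicators.loc[fit_rows])
    auc = roc_auc(probs, y[fit_rows])
    _, metrics = classify(model, indicators.loc[fit_rows], y[fit_rows])
    return OutcomeModel(outcome=outcome_name, ranges=ranges, model=model,
                        auc=auc, metrics=metrics)
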