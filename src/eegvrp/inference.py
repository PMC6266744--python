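"""Statistical layer: logistic risk classification with a likelihood-ratio
test and leave-one-out cross-validation, and nested linear-model
comparison for developmental-score prediction.

Two scikit-learn-style estimators carry the machinery:

* :class:`VRPLogisticScreen` — single-feature maximum-likelihood logistic
  regression of at-risk status on VRP, with the likelihood-ratio test
  against the intercept-only model, the per-unit odds ratio, and
  complete-separation handling.
* :class:`NestedLinearComparison` — ordinary-least-squares fits of a null
  and a nested full model (default: score ~ age + at_risk vs + vrp), with
  adjusted R^2, BIC (counting the residual-variance parameter, the R
  convention) and the partial-F / ANOVA test on the added predictors.

Module-level functions (:func:`fit_logistic_lrt`, :func:`loocv_confusion`,
:func:`fit_linear`, :func:`compare_nested`, :func:`same_visit_table`,
:func:`predict_future_visit`) are thin wrappers over these.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LogisticFitResult",
    "ConfusionSummary",
    "LinearFitResult",
    "ModelComparison",
    "VRPLogisticScreen",
    "NestedLinearComparison",
    "fit_logistic_lrt",
    "loocv_confusion",
    "fit_linear",
    "compare_nested",
    "same_visit_table",
    "predict_future_visit",
    "TABLE_OUTCOMES",
]

#: The twelve developmental outcomes modelled per visit.
TABLE_OUTCOMES = (
    "bayley_raw_fine_motor",
    "bayley_raw_gross_motor",
    "bayley_raw_receptive_lang",
    "bayley_raw_expressive_lang",
    "bayley_raw_cognitive",
    "bayley_total_raw",
    "composite_cognitive",
    "percentile_cognitive",
    "composite_language",
    "percentile_language",
    "composite_motor",
    "percentile_motor",
)

#: Bound on |slope| * SD(feature) used when the classes are completely
#: separated and the unpenalized MLE diverges.
_SEPARATION_SLOPE_BOUND = 20.0


# --------------------------------------------------------------------------
# result containers


@dataclass
class LogisticFitResult:
    intercept: float
    slope: float
    llf_full: float
    llf_null: float
    lrt_chi2: float
    df: int
    p_value: float
    odds_ratio: float
    n: int
    odds_ratio_per_sd: float = float("nan")
    feature_sd: float = float("nan")
    feature_scale: str = "native"
    degenerate: bool = False
    separation: bool = False


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


@dataclass
class LinearFitResult:
    """OLS fit summary with R-convention BIC (k counts intercept, slopes
    and the Gaussian residual-variance parameter)."""

    outcome: str
    predictors: tuple
    params: np.ndarray
    n: int
    rss: float
    r2: float
    adj_r2: float
    llf: float
    bic: float
    bse: np.ndarray = None
    outcome_values: np.ndarray = field(repr=False, default=None)

    @property
    def n_slopes(self) -> int:
        return len(self.predictors)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """t-based (1-alpha) confidence intervals, rows = (const, *slopes)."""
        dof = self.n - self.n_slopes - 1
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        return np.column_stack(
            [self.params - tcrit * self.bse, self.params + tcrit * self.bse]
        )


@dataclass
class ModelComparison:
    outcome: str
    null_fit: LinearFitResult
    full_fit: LinearFitResult
    partial_f: float
    df_num: int
    df_den: int
    anova_p: float

    @property
    def delta_adj_r2(self) -> float:
        return self.full_fit.adj_r2 - self.null_fit.adj_r2


# --------------------------------------------------------------------------
# logistic layer


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = y.size - n1
    return float(n1 * math.log(p) + n0 * math.log(1 - p))


def _bernoulli_llf(x: np.ndarray, y: np.ndarray, b0: float, b1: float) -> float:
    eta = b0 + b1 * x
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """True iff some threshold on x perfectly splits the classes."""
    if y.min() == y.max():
        return True
    x0, x1 = x[y == 0], x[y == 1]
    return bool(x0.max() < x1.min() or x1.max() < x0.min())


def _bounded_logit_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """ML logistic fit with |slope_std| bounded, on the standardized scale.

    Used when complete separation makes the unpenalized MLE diverge; the
    bound keeps estimates finite-at-tolerance.
    """
    mu, sd = x.mean(), x.std()
    sd = sd if sd > 0 else 1.0
    z = (x - mu) / sd

    def nll(theta):
        return -_bernoulli_llf(z, y, theta[0], theta[1])

    res = optimize.minimize(
        nll,
        x0=np.array([0.0, 0.0]),
        method="L-BFGS-B",
        bounds=[(-50, 50), (-_SEPARATION_SLOPE_BOUND, _SEPARATION_SLOPE_BOUND)],
    )
    b0s, b1s = res.x
    b1 = b1s / sd
    b0 = b0s - b1s * mu / sd
    return float(b0), float(b1), float(-res.fun)


def _fit_binary_logit(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, bool, bool]:
    """Returns (intercept, slope, llf, degenerate, separation)."""
    if np.ptp(x) == 0:
        p = y.mean()
        b0 = math.log(p / (1 - p)) if 0 < p < 1 else 0.0
        return b0, 0.0, _null_llf(y), True, False
    if _is_separated(x, y):
        b0, b1, llf = _bounded_logit_fit(x, y)
        return b0, b1, llf, False, True
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0)
            if np.all(np.isfinite(res.params)) and np.abs(res.params[1]) * x.std() < _SEPARATION_SLOPE_BOUND * 2:
                return float(res.params[0]), float(res.params[1]), float(res.llf), False, False
        except Exception:
            pass
    b0, b1, llf = _bounded_logit_fit(x, y)
    return b0, b1, llf, False, True


class VRPLogisticScreen(BaseEstimator, ClassifierMixin):
    """Single-feature logistic classifier with a likelihood-ratio test.

    Parameters
    ----------
    threshold : float
        Decision threshold on the predicted probability of class 1.

    Attributes (after ``fit``)
    --------------------------
    intercept_, coef_ : ML logistic parameters (native feature scale).
    lrt_chi2_, lrt_df_, lrt_p_ : likelihood-ratio test of the feature
        against the intercept-only model (df = 1 added parameter).
    odds_ratio_ : exp(slope), the multiplicative odds change per unit of
        the feature on its native scale.
    separation_ : True when the classes were completely separable and a
        bounded-slope fit was substituted (a warning is emitted).
    degenerate_ : True when the feature was constant (odds ratio
        reported as 1).
    """

    def __init__(self, threshold: float = 0.5) -> None:
        self.threshold = threshold

    def fit(self, X, y) -> "VRPLogisticScreen":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if x.size != y.size:
            raise ValueError("X and y length mismatch")
        if x.size < 4:
            raise ValueError("need at least 4 observations")
        if not np.all(np.isfinite(x)):
            raise ValueError("feature contains non-finite values")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"need exactly 2 classes, got {self.classes_.tolist()}"
            )
        yb = (y == self.classes_[1]).astype(float)
        b0, b1, llf, degenerate, separation = _fit_binary_logit(x, yb)
        if separation:
            warnings.warn(
                "complete separation detected; slope bounded at "
                f"|b*SD| <= {_SEPARATION_SLOPE_BOUND}",
                UserWarning,
                stacklevel=2,
            )
        llf_null = _null_llf(yb)
        chi2 = max(2.0 * (llf - llf_null), 0.0)
        self.intercept_ = b0
        self.coef_ = np.array([[b1]])
        self.llf_ = llf
        self.llf_null_ = llf_null
        self.lrt_chi2_ = chi2
        self.lrt_df_ = 1
        self.lrt_p_ = float(stats.chi2.sf(chi2, 1)) if not degenerate else 1.0
        with np.errstate(over="ignore"):
            # the native-unit OR can overflow to inf when the feature's
            # units are tiny (e.g. VRP ~ 0.05); the per-SD OR stays finite
            self.odds_ratio_ = 1.0 if degenerate else float(np.exp(b1))
            self.feature_sd_ = float(np.std(x, ddof=1))
            self.odds_ratio_per_sd_ = (
                1.0 if degenerate else float(np.exp(b1 * self.feature_sd_))
            )
        self.degenerate_ = degenerate
        self.separation_ = separation
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        eta = self.intercept_ + self.coef_[0, 0] * x
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > self.threshold).astype(int)]

    def result(self, feature_scale: str = "native") -> LogisticFitResult:
        return LogisticFitResult(
            intercept=self.intercept_,
            slope=float(self.coef_[0, 0]),
            llf_full=self.llf_,
            llf_null=self.llf_null_,
            lrt_chi2=self.lrt_chi2_,
            df=self.lrt_df_,
            p_value=self.lrt_p_,
            odds_ratio=self.odds_ratio_,
            n=int(self.n_obs_) if hasattr(self, "n_obs_") else -1,
            odds_ratio_per_sd=self.odds_ratio_per_sd_,
            feature_sd=self.feature_sd_,
            feature_scale=feature_scale,
            degenerate=self.degenerate_,
            separation=self.separation_,
        )


def fit_logistic_lrt(
    feature: Sequence[float], labels: Sequence[int]
) -> LogisticFitResult:
    """ML logistic fit of binary labels on one feature, with the LRT
    against the intercept-only model and the per-unit odds ratio."""
    est = VRPLogisticScreen().fit(np.asarray(feature), np.asarray(labels))
    res = est.result()
    res.n = len(np.asarray(feature).reshape(-1))
    return res


def loocv_confusion(
    feature: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> ConfusionSummary:
    """Leave-one-out cross-validated confusion matrix for the logistic
    screen.

    Each observation is predicted from a model fit on the other n-1; a
    training fold with a single class predicts that class's training
    frequency (i.e. the majority class at the default threshold).
    """
    x = np.asarray(feature, dtype=float).reshape(-1)
    y = np.asarray(labels)
    if x.size < 3:
        raise ValueError("LOOCV needs at least 3 observations")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    yb = (y == classes[1]).astype(float)
    tp = tn = fp = fn = 0
    idx = np.arange(x.size)
    for i in idx:
        tr = idx != i
        xt, yt = x[tr], yb[tr]
        if yt.min() == yt.max():
            p1 = float(yt.mean())
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b0, b1, _, _, _ = _fit_binary_logit(xt, yt)
            p1 = 1.0 / (1.0 + math.exp(-(b0 + b1 * x[i])))
        pred = 1 if p1 > threshold else 0
        if pred == 1 and yb[i] == 1:
            tp += 1
        elif pred == 0 and yb[i] == 0:
            tn += 1
        elif pred == 1 and yb[i] == 0:
            fp += 1
        else:
            fn += 1
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn)


# --------------------------------------------------------------------------
# linear layer


def fit_linear(
    outcome: Sequence[float],
    predictors: pd.DataFrame,
    outcome_name: str = "outcome",
) -> LinearFitResult:
    """OLS with intercept; adjusted R^2, Gaussian log-likelihood and BIC.

    BIC = k ln n - 2 llf with k = (#slopes + intercept + residual
    variance), matching R's ``BIC()`` for ``lm`` fits.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(predictors, pd.DataFrame):
        names = tuple(predictors.columns)
        Xp = predictors.to_numpy(dtype=float)
    else:
        Xp = np.asarray(predictors, dtype=float)
        if Xp.ndim == 1:
            Xp = Xp[:, None]
        names = tuple(f"x{i}" for i in range(Xp.shape[1]))
    n, p = Xp.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} predictors plus intercept")
    X = np.column_stack([np.ones(n), Xp])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1))
            == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    r2 = float(res.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    llf = float(res.llf)  # Gaussian MLE variance (rss/n)
    k = p + 2
    bic = k * math.log(n) - 2.0 * llf
    return LinearFitResult(
        outcome=outcome_name,
        predictors=names,
        params=np.asarray(res.params),
        n=n,
        rss=rss,
        r2=r2,
        adj_r2=float(adj),
        llf=llf,
        bic=float(bic),
        bse=np.asarray(res.bse),
        outcome_values=y,
    )


def compare_nested(
    null_fit: LinearFitResult, full_fit: LinearFitResult
) -> ModelComparison:
    """Partial F-test (nested ANOVA) between two OLS fits on the same data.

    F = ((RSS0 - RSS1)/q) / (RSS1/(n - p1 - 1)) with q added predictors;
    identical models give F = 0, p = 1.
    """
    if null_fit.n != full_fit.n:
        raise ValueError("fits use different numbers of observations")
    if null_fit.outcome_values is not None and full_fit.outcome_values is not None:
        if not np.allclose(null_fit.outcome_values, full_fit.outcome_values):
            raise ValueError("fits model different outcome vectors")
    if not set(null_fit.predictors) <= set(full_fit.predictors):
        raise ValueError(
            f"models are not nested: {null_fit.predictors} is not a subset "
            f"of {full_fit.predictors}"
        )
    n = full_fit.n
    q = full_fit.n_slopes - null_fit.n_slopes
    df_den = n - full_fit.n_slopes - 1
    if q == 0:
        f, p = 0.0, 1.0
    else:
        f = ((null_fit.rss - full_fit.rss) / q) / (full_fit.rss / df_den)
        f = max(f, 0.0)
        p = float(stats.f.sf(f, q, df_den))
    return ModelComparison(
        outcome=full_fit.outcome,
        null_fit=null_fit,
        full_fit=full_fit,
        partial_f=float(f),
        df_num=q,
        df_den=df_den,
        anova_p=p,
    )


class NestedLinearComparison(BaseEstimator):
    """Null-vs-full nested OLS comparison as an estimator.

    Parameters
    ----------
    null_predictors : sequence of str
        Columns of the null (baseline) model.
    added_predictors : sequence of str
        Columns added in the full model.

    ``fit(X, y)`` takes a DataFrame containing all predictor columns and
    the outcome vector; fitted attributes expose both
    :class:`LinearFitResult` objects and the :class:`ModelComparison`.
    """

    def __init__(
        self,
        null_predictors: Sequence[str] = ("age_days_adjusted", "at_risk"),
        added_predictors: Sequence[str] = ("vrp",),
    ) -> None:
        self.null_predictors = null_predictors
        self.added_predictors = added_predictors

    def fit(self, X: pd.DataFrame, y, outcome_name: str = "outcome"):
        null_cols = list(self.null_predictors)
        full_cols = null_cols + list(self.added_predictors)
        self.null_fit_ = fit_linear(y, X[null_cols], outcome_name=outcome_name)
        self.full_fit_ = fit_linear(y, X[full_cols], outcome_name=outcome_name)
        self.comparison_ = compare_nested(self.null_fit_, self.full_fit_)
        return self


def same_visit_table(
    cohort: pd.DataFrame,
    vrp_col: str = "vrp",
    outcomes: Sequence[str] = TABLE_OUTCOMES,
    visit: int = 1,
    null_includes_risk: bool = True,
) -> pd.DataFrame:
    """Null-vs-full model comparison for every developmental outcome.

    Null model: score ~ age + at_risk (or age only when
    ``null_includes_risk=False``); full model adds the VRP feature.
    Returns one row per outcome with adjusted R^2 and BIC for both models,
    the partial-F ANOVA p-value, and a Holm-adjusted column for
    transparency (no correction is applied to the primary p-values).
    """
    df = cohort[cohort["visit"] == visit].dropna(subset=[vrp_col])
    null_cols = ["age_days_adjusted"] + (["at_risk"] if null_includes_risk else [])
    rows = []
    for outcome in outcomes:
        est = NestedLinearComparison(
            null_predictors=null_cols, added_predictors=[vrp_col]
        ).fit(df, df[outcome].to_numpy(), outcome_name=outcome)
        cmp_ = est.comparison_
        rows.append(
            {
                "outcome": outcome,
                "adj_r2_null": cmp_.null_fit.adj_r2,
                "adj_r2_full": cmp_.full_fit.adj_r2,
                "bic_null": cmp_.null_fit.bic,
                "bic_full": cmp_.full_fit.bic,
                "partial_f": cmp_.partial_f,
                "anova_p": cmp_.anova_p,
            }
        )
    out = pd.DataFrame(rows)
    out["anova_p_holm"] = multipletests(out["anova_p"], method="holm")[1]
    return out


def predict_future_visit(
    cohort: pd.DataFrame,
    vrp_col: str = "vrp",
    outcome: str = "bayley_raw_fine_motor",
    baseline_visit: int = 1,
    future_visit: int = 3,
) -> ModelComparison:
    """Visit-1 predictors (age, at-risk, VRP) against the visit-3 outcome.

    Compares the 2-regressor model (age, at_risk) with the 3-regressor
    model (+ VRP), both fit on subjects observed at both visits.
    """
    v1 = cohort[cohort["visit"] == baseline_visit].set_index("subject_id")
    v3 = cohort[cohort["visit"] == future_visit].set_index("subject_id")
    linked = v1.join(v3[[outcome]], rsuffix="_future", how="inner").dropna(
        subset=[vrp_col, f"{outcome}_future"]
    )
    if len(linked) < 3:
        raise ValueError(
            f"only {len(linked)} subjects have both visit-{baseline_visit} "
            f"predictors and a visit-{future_visit} outcome; need >= 3"
        )
    est = NestedLinearComparison(
        null_predictors=["age_days_adjusted", "at_risk"],
        added_predictors=[vrp_col],
    ).fit(
        linked,
        linked[f"{outcome}_future"].to_numpy(),
        outcome_name=f"{outcome}@visit{future_visit}",
    )
    return est.comparison_
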