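"""Survival estimation, test routing, progression regression, missingness audit.

Survival uses the Kaplan-Meier product-limit estimator with Greenwood
confidence bands and one-degree-of-freedom log-rank comparisons (lifelines).
Group differences are routed by distributional checks: Shapiro-Wilk
normality on both samples, then Levene's test (median-centred) for equal
variances, choosing a pooled t, Welch t, or Mann-Whitney U accordingly.
Score progression is an ordinary least-squares fit of per-visit scores on
years since diagnosis plus covariates, with VIF multicollinearity and
residual-normality diagnostics and an optional cluster-robust (by patient)
covariance; slope differences between sources are Wald tests on a
source-by-time interaction in a pooled model.  The missingness audit
cross-validates a logistic classifier predicting score presence and reports
the mean AUC.  No multiple-testing correction is applied; p-values are
reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats as sps

ROUTE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    median: float | None             # None = not reached within follow-up
    median_ci: tuple[float | None, float | None]
    horizon: float                   # largest observed time

    @property
    def median_label(self) -> str:
        return (f"{self.median:g}" if self.median is not None
                else f"not reached (> {self.horizon:g})")


def km_fit(times: Sequence[float], observed: Sequence[bool] | None = None
           ) -> KMCurve:
    """Product-limit survival estimate with Greenwood 95% band.

    ``observed`` defaults to all-events.  The median is the smallest time
    with S(t) <= 0.5; when the curve never reaches 0.5 the median is None
    and the follow-up horizon is reported alongside.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("no records")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    obs = (np.ones_like(times, dtype=bool) if observed is None
           else np.asarray(list(observed), dtype=bool))
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=obs)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    med = kmf.median_survival_time_
    med_ci_frame = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(med_ci_frame.iloc[0, 0]), float(med_ci_frame.iloc[0, 1]))
    grid = surv.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    return KMCurve(
        times=grid,
        survival=surv.to_numpy(dtype=float),
        ci_low=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_high=ci.iloc[:, 1].to_numpy(dtype=float),
        n_at_risk=at_risk,
        median=None if np.isinf(med) else float(med),
        median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
        horizon=float(times.max()),
    )


def logrank_test(times_a, observed_a, times_b, observed_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank chi-square statistic and p-value."""
    r = _ll_logrank(times_a, times_b, event_observed_A=observed_a,
                    event_observed_B=observed_b)
    return float(r.test_statistic), float(r.p_value)


# ---------------------------------------------------------------------------
# group-difference routing

@dataclass
class TestRecord:
    route: str                       # pooled_t | welch_t | mann_whitney
    shapiro_p: tuple[float, float]
    levene_p: float | None
    statistic: float
    p_value: float


def group_difference_test(x, y, alpha: float = ROUTE_ALPHA) -> TestRecord:
    """Normality/variance-routed two-sample comparison.

    Both samples Shapiro-Wilk normal (p >= alpha): Levene's test
    (median-centred) picks pooled t (p >= alpha) or Welch t (p < alpha).
    Otherwise Mann-Whitney U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sw_x = float(sps.shapiro(x).pvalue)
    sw_y = float(sps.shapiro(y).pvalue)
    if sw_x >= alpha and sw_y >= alpha:
        lev = float(sps.levene(x, y, center="median").pvalue)
        equal_var = lev >= alpha
        t = sps.ttest_ind(x, y, equal_var=equal_var)
        return TestRecord(route="pooled_t" if equal_var else "welch_t",
                          shapiro_p=(sw_x, sw_y), levene_p=lev,
                          statistic=float(t.statistic), p_value=float(t.pvalue))
    u = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestRecord(route="mann_whitney", shapiro_p=(sw_x, sw_y),
                      levene_p=None, statistic=float(u.statistic),
                      p_value=float(u.pvalue))


# ---------------------------------------------------------------------------
# per-year score summaries

def stratified_score_summary(df: pd.DataFrame, horizon_years: int = 10,
                             value_col: str = "value", time_col: str = "t"
                             ) -> pd.DataFrame:
    """Mean/median and 95% CI of scores per whole-year bin since diagnosis.

    Bin k covers [k, k+1) years.  Empty bins are omitted; the CI is
    reported only when n >= 2 (t-interval on the mean).
    """
    d = df[(df[time_col] >= 0) & (df[time_col] < horizon_years)].copy()
    d["year_bin"] = np.floor(d[time_col]).astype(int)
    rows = []
    for k, g in d.groupby("year_bin"):
        v = g[value_col].to_numpy(dtype=float)
        n = len(v)
        mean = float(np.mean(v))
        if n >= 2:
            sem = float(np.std(v, ddof=1) / np.sqrt(n))
            tcrit = float(sps.t.ppf(0.975, n - 1))
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            lo = hi = np.nan
        rows.append({"year_bin": int(k), "n": n, "mean": mean,
                     "median": float(np.median(v)), "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# progression regression

@dataclass
class ProgressionFit:
    scale: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    intercept_at_dx: float           # expected score at diagnosis, covariates
                                     # at their sample means
    slope_per_year: float
    nobs: int
    vif: dict[str, float] = field(default_factory=dict)
    vif_flag: bool = False
    resid_normality_p: float = float("nan")
    qq: tuple[np.ndarray, np.ndarray] | None = None
    model: object = None

    def summary_dict(self) -> dict:
        return {"scale": self.scale, "coefficients": self.coefficients,
                "std_errors": self.std_errors,
                "intercept_at_dx": self.intercept_at_dx,
                "slope_per_year": self.slope_per_year, "nobs": self.nobs,
                "vif": self.vif, "vif_flag": self.vif_flag,
                "resid_normality_p": self.resid_normality_p}


class RankDeficiencyError(ValueError):
    def __init__(self, collinear: list[str]):
        self.collinear = collinear
        super().__init__("design matrix is rank deficient; collinear "
                         f"covariates: {collinear}")


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        corr = X.corr().abs()
        cols = list(corr.columns)
        collinear: list[str] = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if corr.iloc[i, j] > 1 - 1e-10:
                    collinear += [cols[i], cols[j]]
        raise RankDeficiencyError(sorted(set(collinear)) or cols)


def fit_progression_model(table: pd.DataFrame, score_type: str,
                          covariates: Sequence[str] = ("age_at_dx", "sex"),
                          time_col: str = "t", value_col: str = "value",
                          cluster_col: str | None = None) -> ProgressionFit:
    """Covariate-adjusted OLS of per-visit scores on years since diagnosis.

    Continuous covariates (and the 0/1 sex indicator) are centred at their
    sample means, so the intercept is the expected score at diagnosis for an
    average cohort member.  VIFs are computed per predictor and the fit is
    flagged when any reaches 10.  ``cluster_col`` switches to cluster-robust
    standard errors (visits are repeated within patients).
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    d = table.dropna(subset=[value_col, time_col, *covariates])
    X = pd.DataFrame({"years_since_dx": d[time_col].to_numpy(dtype=float)})
    for c in covariates:
        col = d[c]
        if col.dtype == object:
            col = (col == "M").astype(float)
        col = col.astype(float)
        X[c] = col.to_numpy() - float(col.mean())
    _check_rank(X)
    Xc = sm.add_constant(X, prepend=True)
    model = sm.OLS(d[value_col].to_numpy(dtype=float), Xc)
    if cluster_col:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": d[cluster_col]})
    else:
        res = model.fit()

    vif = {}
    if X.shape[1] > 1:
        arr = Xc.to_numpy(dtype=float)
        for j, name in enumerate(X.columns):
            vif[name] = float(variance_inflation_factor(arr, j + 1))
    resid = res.resid
    sw_p = float(sps.shapiro(resid if len(resid) <= 4500
                             else np.random.default_rng(0).choice(
                                 resid, 4500, replace=False)).pvalue)
    osm, osr = sps.probplot(resid, fit=False)
    names = list(Xc.columns)
    params = np.asarray(res.params, dtype=float)
    ci = np.asarray(res.conf_int(), dtype=float)
    return ProgressionFit(
        scale=score_type,
        coefficients=dict(zip(names, map(float, params))),
        std_errors=dict(zip(names, map(float, np.asarray(res.bse)))),
        conf_int={n: (float(ci[i, 0]), float(ci[i, 1]))
                  for i, n in enumerate(names)},
        intercept_at_dx=float(params[0]),
        slope_per_year=float(params[names.index("years_since_dx")]),
        nobs=int(res.nobs),
        vif=vif, vif_flag=any(v >= 10 for v in vif.values()),
        resid_normality_p=sw_p, qq=(np.asarray(osm), np.asarray(osr)),
        model=res)


@dataclass
class SlopeComparison:
    slope_a: float
    slope_b: float
    difference: float                # slope_b - slope_a (interaction coef)
    std_error: float
    p_value: float
    separate_fit_difference: float


def compare_progression_slopes(table: pd.DataFrame, source_col: str = "source",
                               covariates: Sequence[str] = ("age_at_dx", "sex"),
                               time_col: str = "t", value_col: str = "value"
                               ) -> SlopeComparison:
    """Wald test on a source-by-time interaction in a pooled model.

    The pooled OLS adds a source indicator and its product with time; the
    interaction coefficient is the between-source slope difference.  The
    delta of two separately fitted slopes is reported alongside.
    """
    import statsmodels.api as sm

    sources = sorted(table[source_col].unique())
    if len(sources) != 2:
        raise ValueError("exactly two sources required")
    a, b = sources
    d = table.dropna(subset=[value_col, time_col, *covariates]).copy()
    ind = (d[source_col] == b).astype(float)
    X = pd.DataFrame({
        "years_since_dx": d[time_col].to_numpy(dtype=float),
        "source_b": ind.to_numpy(),
        "source_b_x_time": ind.to_numpy() * d[time_col].to_numpy(dtype=float),
    })
    for c in covariates:
        col = d[c]
        if col.dtype == object:
            col = (col == "M").astype(float)
        col = col.astype(float)
        X[c] = col.to_numpy() - float(col.mean())
    _check_rank(X)
    res = sm.OLS(d[value_col].to_numpy(dtype=float),
                 sm.add_constant(X, prepend=True)).fit()
    names = ["const"] + list(X.columns)
    k = names.index("source_b_x_time")
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    fit_a = fit_progression_model(d[d[source_col] == a], "a", covariates,
                                  time_col, value_col)
    fit_b = fit_progression_model(d[d[source_col] == b], "b", covariates,
                                  time_col, value_col)
    slope_a = float(params[names.index("years_since_dx")])
    return SlopeComparison(
        slope_a=slope_a,
        slope_b=slope_a + float(params[k]),
        difference=float(params[k]),
        std_error=float(bse[k]),
        p_value=float(pvals[k]),
        separate_fit_difference=fit_b.slope_per_year - fit_a.slope_per_year)


# ---------------------------------------------------------------------------
# missingness audit

def missingness_audit(features: pd.DataFrame, has_score: Sequence[int],
                      n_splits: int = 5, seed: int = 0) -> dict:
    """Cross-validated AUC of a score-presence classifier.

    Logistic regression on standardized features, stratified k-fold; the
    mean out-of-fold AUC quantifies how predictable score recording is from
    patient covariates (an AUC near 0.5 supports treating scores as missing
    without imputation).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = features.to_numpy(dtype=float)
    y = np.asarray(list(has_score), dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("score presence is constant; AUC undefined")
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=1000))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
    return {"auc": float(np.mean(aucs)), "auc_folds": [float(a) for a in aucs],
            "n": int(len(y)), "n_splits": n_splits}
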