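"""Lagged climate-window predictors and driver attribution.

Monthly climate (mean temperature T, total precipitation Pr, rain-day count
RD) is aggregated into window predictors named ``VAR_n_lag``: the variable
over ``n`` consecutive months ending ``lag`` months before the target month
(lag 0 includes the target month itself; e.g. for an October event, Pr_2_0
sums October + September and Pr_2_2 sums August + July).  Responses
(phenology events or monthly EVI) are attributed to windows via Pearson
screening followed by forward-backward stepwise multiple linear regression
with a VIF collinearity guard, and, for monthly EVI, additionally via a
random-forest regression on the full predictor set.
"""
from __future__ import annotations

import calendar as _calendar
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

VARIABLES = ("T", "Pr", "RD")
_VAR_COLUMN = {"T": "t_mean", "Pr": "p_total", "RD": "rain_days"}
_CUM_DAYS = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def doy_to_month(doy: float) -> tuple[int, int]:
    """(year offset, month) containing a 1-based DOY; DOY > 365 wraps forward."""
    offset = 0
    while doy > 365:
        doy -= 365
        offset += 1
    month = int(np.searchsorted(_CUM_DAYS, doy, side="left"))
    return offset, max(1, min(12, month))


# ---------------------------------------------------------------------------
# Monthly aggregation
# ---------------------------------------------------------------------------


def aggregate_monthly(daily: pd.DataFrame, rain_day_min: float = 1.0,
                      max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Monthly mean temperature, precipitation total, and rain-day count.

    ``daily`` columns: date, tavg_c, prcp_mm.  A month missing more than
    ``max_missing_fraction`` of its days is kept but flagged missing (NaN).
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df["prcp_mm"].dropna() < 0).any():
        raise ValueError("precipitation must be >= 0")
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    rows = []
    for (year, month), grp in df.groupby(["year", "month"], sort=True):
        n_days = _calendar.monthrange(int(year), int(month))[1]
        t = grp["tavg_c"].dropna()
        p = grp["prcp_mm"].dropna()
        present = min(len(t), len(p))
        if present < (1.0 - max_missing_fraction) * n_days:
            logger.warning("month %d-%02d flagged missing (%d/%d days)",
                           year, month, present, n_days)
            rows.append({"year": int(year), "month": int(month), "t_mean": math.nan,
                         "p_total": math.nan, "rain_days": math.nan})
            continue
        rows.append({
            "year": int(year), "month": int(month),
            "t_mean": float(t.mean()),
            "p_total": float(p.sum()),
            "rain_days": int((p >= rain_day_min).sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Window predictors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """One aggregated climate variable over an (n months, lag) window."""

    variable: str
    n_months: int
    lag_months: int

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"variable must be one of {VARIABLES}")
        if self.n_months < 1 or self.lag_months < 0:
            raise ValueError("n_months >= 1 and lag_months >= 0 required")

    @property
    def name(self) -> str:
        return f"{self.variable}_{self.n_months}_{self.lag_months}"

    @classmethod
    def from_name(cls, name: str) -> "WindowSpec":
        var, n, lag = name.split("_")
        return cls(var, int(n), int(lag))


def enumerate_windows(max_n_lag0: int = 6, max_n_lagged: int = 5,
                      max_lag: int = 5) -> list[WindowSpec]:
    """All window specs in deterministic (variable, lag, n) order.

    Defaults reproduce the study design: per variable, 1-6 month concurrent
    windows plus 1-5 month windows at 1-5 month lags (31 each, 93 total).
    """
    specs = []
    for var in VARIABLES:
        for lag in range(0, max_lag + 1):
            n_max = max_n_lag0 if lag == 0 else max_n_lagged
            for n in range(1, n_max + 1):
                specs.append(WindowSpec(var, n, lag))
    return specs


def _shift_month(year: int, month: int, delta: int) -> tuple[int, int]:
    m = (month - 1) + delta
    return year + m // 12, m % 12 + 1


def _monthly_lookup(monthly: pd.DataFrame) -> dict[str, dict[tuple[int, int], float]]:
    out: dict[str, dict[tuple[int, int], float]] = {}
    keys = list(zip(monthly["year"].astype(int), monthly["month"].astype(int)))
    for var, col in _VAR_COLUMN.items():
        out[var] = dict(zip(keys, monthly[col].astype(float)))
    return out


def _window_value(lookup, spec: WindowSpec, event_year: int, event_month: int) -> float:
    table = lookup[spec.variable]
    total = 0.0
    for j in range(spec.n_months):
        y, m = _shift_month(event_year, event_month, -(spec.lag_months + j))
        v = table.get((y, m), math.nan)
        if math.isnan(v):
            return math.nan
        total += v
    return total / spec.n_months if spec.variable == "T" else total


def window_value(monthly: pd.DataFrame, spec: WindowSpec,
                 event_year: int, event_month: int) -> float:
    """Aggregate ``spec`` for an event in (event_year, event_month).

    The window ends ``lag`` months before the event month and spans
    ``n_months`` backwards; T averages, Pr and RD sum.  Any missing month
    makes the value missing (NaN).
    """
    return _window_value(_monthly_lookup(monthly), spec, event_year, event_month)


def predictor_matrix(monthly: pd.DataFrame, specs: list[WindowSpec],
                     anchors: list[tuple[int, int]],
                     index=None) -> pd.DataFrame:
    """Window predictors evaluated at each (year, month) anchor; one column per spec."""
    lookup = _monthly_lookup(monthly)
    data = {
        spec.name: [_window_value(lookup, spec, y, m) for y, m in anchors]
        for spec in specs
    }
    return pd.DataFrame(data, index=index if index is not None else range(len(anchors)))


def mean_event_month(doys: pd.Series) -> tuple[int, int]:
    """(year offset, month) of the long-term mean DOY of an event."""
    return doy_to_month(float(np.nanmean(doys.astype(float))))


# ---------------------------------------------------------------------------
# Pearson screening
# ---------------------------------------------------------------------------


def pearson_screen(response: pd.Series, predictors: pd.DataFrame,
                   min_pairs: int = 5) -> pd.DataFrame:
    """Pearson r and two-sided p per predictor, ranked by |r| descending.

    Ties break by predictor (spec) order; zero-variance or data-poor
    predictors are skipped with a log entry.
    """
    rows = []
    for col in predictors.columns:
        x = predictors[col].astype(float)
        ok = x.notna() & response.notna()
        if ok.sum() < min_pairs:
            logger.info("screen: %s skipped (%d complete pairs)", col, int(ok.sum()))
            continue
        xv, yv = x[ok].to_numpy(), response[ok].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            logger.info("screen: %s skipped (zero variance)", col)
            continue
        r, p = stats.pearsonr(xv, yv)
        rows.append({"name": col, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows, columns=["name", "r", "p"])
    if len(out):
        out = out.reindex(out["r"].abs().sort_values(ascending=False, kind="stable").index)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stepwise multiple linear regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    response: str
    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    model_p: float
    dropped_collinear: list[str] = field(default_factory=list)
    rmse: float = math.nan
    predictions: pd.Series | None = None


class StepwiseLinearRegression(RegressorMixin, BaseEstimator):
    """Forward-backward stepwise OLS with a VIF collinearity guard.

    Predictors enter at p < ``p_enter`` and leave at p > ``p_remove``; before
    each entry, candidates with variance inflation factor above ``vif_limit``
    against the current model are dropped from the pool.  Follows the sklearn
    estimator contract: ``fit(X, y)`` with a DataFrame (or array) ``X``,
    fitted attributes ``selected_``, ``coef_``, ``intercept_``, ``r2_``.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 vif_limit: float = 10.0, max_steps: int = 50):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.vif_limit = vif_limit
        self.max_steps = max_steps

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def _vif(self, Xf: pd.DataFrame, candidate: str, selected: list[str]) -> float:
        if not selected:
            return 1.0
        res = sm.OLS(Xf[candidate], sm.add_constant(Xf[selected], has_constant="add")).fit()
        r2 = min(res.rsquared, 1.0 - 1e-12)
        return 1.0 / (1.0 - r2)

    def fit(self, X, y):
        Xf = self._as_frame(X)
        yv = pd.Series(np.asarray(y, dtype=float), index=Xf.index)
        ok = yv.notna() & Xf.notna().all(axis=1)
        Xf, yv = Xf[ok], yv[ok]
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)

        selected: list[str] = []
        dropped: list[str] = []
        pool = list(Xf.columns) if float(np.std(yv)) > 1e-12 else []
        for _ in range(self.max_steps):
            # collinearity guard before each entry attempt
            keep = []
            for c in pool:
                if self._vif(Xf, c, selected) > self.vif_limit:
                    dropped.append(c)
                    logger.info("stepwise: %s dropped (VIF > %g)", c, self.vif_limit)
                else:
                    keep.append(c)
            pool = keep
            # forward step: best entrant by p-value
            best, best_p = None, math.inf
            for c in pool:
                res = sm.OLS(yv, sm.add_constant(Xf[selected + [c]], has_constant="add")).fit()
                p = float(res.pvalues[c])
                if p < best_p:
                    best, best_p = c, p
            if best is None or best_p >= self.p_enter:
                break
            selected.append(best)
            pool.remove(best)
            # backward step: prune entrants that lost significance
            while len(selected) > 1:
                res = sm.OLS(yv, sm.add_constant(Xf[selected], has_constant="add")).fit()
                pvals = res.pvalues.drop("const")
                worst = pvals.idxmax()
                if float(pvals[worst]) <= self.p_remove:
                    break
                selected.remove(worst)
                pool.append(worst)
                logger.info("stepwise: %s removed (p > %g)", worst, self.p_remove)

        self.selected_ = selected
        self.dropped_collinear_ = dropped
        if selected:
            res = sm.OLS(yv, sm.add_constant(Xf[selected], has_constant="add")).fit()
            self.results_ = res
            self.intercept_ = float(res.params["const"])
            self.coef_ = res.params.drop("const").to_dict()
            self.r2_ = float(res.rsquared)
            self.model_p_ = float(res.f_pvalue)
        else:
            self.results_ = None
            self.intercept_ = float(yv.mean())
            self.coef_ = {}
            self.r2_ = 0.0
            self.model_p_ = math.nan
        return self

    def predict(self, X):
        Xf = self._as_frame(X)
        pred = np.full(len(Xf), self.intercept_, dtype=float)
        for name, c in self.coef_.items():
            pred += c * Xf[name].to_numpy()
        return pred


def _balanced_candidates(screened: pd.DataFrame, top_k: int,
                         min_per_variable: int) -> list[str]:
    """Top-k screened names, guaranteeing each climate variable its own best windows.

    Windows of one variable are strongly inter-correlated, so a single strong
    driver floods a plain top-k list with near-duplicates of itself and the
    other variables never reach the regression stage; reserving each
    variable's highest-|r| windows keeps the candidate set diverse, in line
    with screening each climatic parameter separately.
    """
    names = list(screened["name"])
    chosen: list[str] = []
    for var in VARIABLES:
        chosen.extend([n for n in names if n.split("_")[0] == var][:min_per_variable])
    for n in names:
        if len(chosen) >= top_k:
            break
        if n not in chosen:
            chosen.append(n)
    # preserve overall screen order
    return sorted(chosen[:top_k], key=names.index)


def stepwise_mlr(response: pd.Series, predictors: pd.DataFrame,
                 response_name: str = "response", top_k: int = 10,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 vif_limit: float = 10.0, min_per_variable: int = 3) -> StepwiseResult:
    """Screen predictors by |Pearson r|, then stepwise-fit the top ``top_k``.

    The candidate list is balanced across the three climate variables (see
    :func:`_balanced_candidates`); set ``min_per_variable=0`` for a plain
    overall top-k.
    """
    screened = pearson_screen(response, predictors)
    candidates = _balanced_candidates(screened, top_k, min_per_variable)
    if not candidates:
        return StepwiseResult(response_name, [], {}, float(np.nanmean(response)),
                              0.0, math.nan)
    est = StepwiseLinearRegression(p_enter=p_enter, p_remove=p_remove, vif_limit=vif_limit)
    est.fit(predictors[candidates], response)
    ok = response.notna() & predictors[candidates].notna().all(axis=1)
    preds = pd.Series(est.predict(predictors.loc[ok, candidates]), index=response.index[ok])
    rmse = float(np.sqrt(np.mean((preds - response[ok]) ** 2)))
    return StepwiseResult(
        response=response_name, selected=est.selected_, coefficients=est.coef_,
        intercept=est.intercept_, r2=est.r2_, model_p=est.model_p_,
        dropped_collinear=est.dropped_collinear_, rmse=rmse, predictions=preds,
    )


# ---------------------------------------------------------------------------
# Interannual trends
# ---------------------------------------------------------------------------


@dataclass
class TrendResult:
    name: str
    slope: float
    intercept: float
    p: float
    n_years: int


def trend_fit(values: pd.Series, name: str = "series") -> TrendResult:
    """OLS of a yearly quantity on calendar year (slope in units/year)."""
    v = values.astype(float).dropna()
    if len(v) < 3:
        raise ValueError("trend fit needs >= 3 non-missing years")
    years = v.index.to_numpy(dtype=float)
    y = v.to_numpy()
    if np.allclose(y, y[0]):
        return TrendResult(name, 0.0, float(y[0]), 1.0, len(v))
    res = stats.linregress(years, y)
    return TrendResult(name, float(res.slope), float(res.intercept),
                       float(res.pvalue), len(v))


# ---------------------------------------------------------------------------
# Monthly EVI models: best-pair MLR and random forest
# ---------------------------------------------------------------------------


def monthly_anchors(monthly_evi: pd.DataFrame) -> list[tuple[int, int]]:
    return [(int(r.year), int(r.month)) for r in monthly_evi.itertuples()]


def mlr_evi_model(monthly_evi: pd.DataFrame, monthly_climate: pd.DataFrame,
                  n_predictors: int = 2, top_k: int = 10,
                  specs: list[WindowSpec] | None = None) -> StepwiseResult:
    """Best ``n_predictors``-subset linear model of monthly EVI on window predictors.

    Candidates are the ``top_k`` windows by single-regression |r|; the pair
    (by default) with the highest adjusted R-squared wins.  Returns the fitted
    coefficients, R-squared, RMSE and per-month predictions.
    """
    specs = specs or enumerate_windows()
    anchors = monthly_anchors(monthly_evi)
    X = predictor_matrix(monthly_climate, specs, anchors, index=monthly_evi.index)
    y = monthly_evi["evi"].astype(float)
    ok = y.notna() & X.notna().all(axis=1)
    Xc, yc = X[ok], y[ok]
    screened = pearson_screen(yc, Xc)
    candidates = _balanced_candidates(screened, top_k, min_per_variable=3)
    if not candidates:
        return StepwiseResult("monthly_evi", [], {}, float(yc.mean()), 0.0, math.nan)
    from itertools import combinations

    best, best_adj = None, -math.inf
    for combo in combinations(candidates, min(n_predictors, len(candidates))):
        res = sm.OLS(yc, sm.add_constant(Xc[list(combo)], has_constant="add")).fit()
        if res.rsquared_adj > best_adj:
            best, best_adj = combo, res.rsquared_adj
    res = sm.OLS(yc, sm.add_constant(Xc[list(best)], has_constant="add")).fit()
    preds = pd.Series(res.fittedvalues, index=yc.index)
    rmse = float(np.sqrt(np.mean((preds - yc) ** 2)))
    return StepwiseResult(
        response="monthly_evi", selected=list(best),
        coefficients=res.params.drop("const").to_dict(),
        intercept=float(res.params["const"]), r2=float(res.rsquared),
        model_p=float(res.f_pvalue), rmse=rmse, predictions=preds,
    )


@dataclass
class RFResult:
    fractions: tuple[float, float, float]
    seed: int
    r2_test: float
    rmse_test: float
    importances: list[tuple[str, float]]
    best_params: dict
    split_sizes: tuple[int, int, int]
    r2_all: float = math.nan
    rmse_all: float = math.nan
    oob_mode: bool = False
    predictions_all: pd.Series | None = None


def split_sizes(n: int, fractions=(0.64, 0.16, 0.20)) -> tuple[int, int, int]:
    """Floor rounding on train and validation; the remainder goes to test."""
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    return n_train, n_val, n - n_train - n_val


def rf_evi_model(monthly_evi: pd.DataFrame, monthly_climate: pd.DataFrame,
                 seed: int, specs: list[WindowSpec] | None = None,
                 n_trees_grid=(250, 500), leaf_grid=(1, 3, 5),
                 fractions=(0.64, 0.16, 0.20), top_importances: int = 10,
                 evaluate_all: bool = True) -> RFResult:
    """Random-forest regression of monthly EVI on the full window-predictor set.

    Months are split 64/16/20 into train/validation/test; the validation set
    picks (trees, min leaf) over a small grid, the test set reports R2 and
    RMSE, and permutation importances on the test months rank the windows.
    With fewer than 50 usable months the split is refused and an out-of-bag
    evaluation is run instead.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    specs = specs or enumerate_windows()
    anchors = monthly_anchors(monthly_evi)
    X = predictor_matrix(monthly_climate, specs, anchors, index=monthly_evi.index)
    y = monthly_evi["evi"].astype(float)
    ok = y.notna() & X.notna().all(axis=1)
    Xc, yc = X[ok], y[ok]
    n = len(yc)
    rng = np.random.default_rng(seed)

    if n < 50:
        logger.warning("only %d months: refusing the 64/16/20 split, using OOB mode", n)
        model = RandomForestRegressor(n_estimators=max(n_trees_grid), oob_score=True,
                                      random_state=seed, n_jobs=1)
        model.fit(Xc, yc)
        imp = permutation_importance(model, Xc, yc, n_repeats=5, random_state=seed, n_jobs=1)
        order = np.argsort(imp.importances_mean)[::-1][:top_importances]
        ranked = [(Xc.columns[i], float(imp.importances_mean[i])) for i in order]
        preds = pd.Series(model.predict(Xc), index=yc.index)
        rmse_all = float(np.sqrt(np.mean((preds - yc) ** 2)))
        return RFResult(fractions, seed, float(model.oob_score_), math.nan, ranked,
                        {"n_estimators": max(n_trees_grid)}, (n, 0, 0),
                        r2_all=float(model.score(Xc, yc)), rmse_all=rmse_all,
                        oob_mode=True, predictions_all=preds)

    n_train, n_val, n_test = split_sizes(n, fractions)
    perm = rng.permutation(n)
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test = perm[n_train + n_val :]
    Xa, ya = Xc.to_numpy(), yc.to_numpy()

    best_params, best_score = None, -math.inf
    for n_trees in n_trees_grid:
        for leaf in leaf_grid:
            model = RandomForestRegressor(n_estimators=n_trees, min_samples_leaf=leaf,
                                          random_state=seed, n_jobs=1)
            model.fit(Xa[idx_train], ya[idx_train])
            score = model.score(Xa[idx_val], ya[idx_val])
            if score > best_score:
                best_params, best_score = {"n_estimators": n_trees,
                                           "min_samples_leaf": leaf}, score
    model = RandomForestRegressor(**best_params, random_state=seed, n_jobs=1)
    fit_idx = np.concatenate([idx_train, idx_val])
    model.fit(Xa[fit_idx], ya[fit_idx])
    pred_test = model.predict(Xa[idx_test])
    r2_test = float(model.score(Xa[idx_test], ya[idx_test]))
    rmse_test = float(np.sqrt(np.mean((pred_test - ya[idx_test]) ** 2)))
    imp = permutation_importance(model, Xa[idx_test], ya[idx_test], n_repeats=5,
                                 random_state=seed, n_jobs=1)
    order = np.argsort(imp.importances_mean)[::-1][:top_importances]
    ranked = [(str(Xc.columns[i]), float(imp.importances_mean[i])) for i in order]

    result = RFResult(tuple(fractions), seed, r2_test, rmse_test, ranked, best_params,
                      (n_train, n_val, n_test))
    if evaluate_all:
        preds = pd.Series(model.predict(Xa), index=yc.index)
        result.r2_all = float(model.score(Xa, ya))
        result.rmse_all = float(np.sqrt(np.mean((preds - yc) ** 2)))
        result.predictions_all = preds
    return result


def compare_models(mlr: StepwiseResult, rf: RFResult) -> dict:
    """Side-by-side MLR vs RF skill and predictor overlap."""
    rf_top = [name for name, _ in rf.importances]
    overlap = [name for name in mlr.selected if name in rf_top]
    return {
        "mlr_r2": mlr.r2,
        "mlr_rmse": mlr.rmse,
        "mlr_selected": list(mlr.selected),
        "rf_r2_test": rf.r2_test,
        "rf_rmse_test": rf.rmse_test,
        "rf_r2_all": rf.r2_all,
        "rf_rmse_all": rf.rmse_all,
        "rf_top_importances": rf_top,
        "overlap": overlap,
        "overlap_count": len(overlap),
    }


def neighbour_windows(name: str, specs: list[WindowSpec] | None = None) -> set[str]:
    """Window names one month-shift away from ``name`` (same variable).

    Two windows are neighbours when their start month and end month each
    differ by at most one; such windows share most of their months and are
    near-collinear, so selection may land on either.
    """
    specs = specs or enumerate_windows()
    s = WindowSpec.from_name(name)
    end0, start0 = s.lag_months, s.lag_months + s.n_months - 1
    out = set()
    for t in specs:
        if t.variable != s.variable:
            continue
        end1, start1 = t.lag_months, t.lag_months + t.n_months - 1
        if abs(end1 - end0) <= 1 and abs(start1 - start0) <= 1:
            out.add(t.name)
    return out
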