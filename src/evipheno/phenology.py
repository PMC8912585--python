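"""Phenology metric extraction from smoothed EVI series.

Thirteen per-year metrics describe the growth cycle of a drought
semi-deciduous shrub: spring drop onset/end/duration (SDO, SDE, SDD) and
autumn revival onset/end/duration (ARO, ARE, ARD) from first-derivative
rules; dry-period onset/end/duration (DPO, DPE, DPD) from an EVI threshold
(default 0.3); and the annual maximum/minimum EVI with their dates.

DOY values above 365 denote dates in the following calendar year (370 is
Jan 5); autumn events are attributed to the year of the spring drop so that
durations stay positive and years stay comparable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import NOMINAL_YEAR_DAYS, EviSeries

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "sdo", "sde", "sdd", "aro", "are", "ard",
    "dpo", "dpe", "dpd", "max_evi", "max_date", "min_evi", "min_date",
]


@dataclass
class DetectionParams:
    """Event-detection tunables.

    dry_threshold
        EVI level separating the dry period (default 0.3, the midpoint
        between the long-term extremes; see :func:`compute_threshold`).
    deriv_epsilon_fraction
        "Near zero" band for the first derivative, as a fraction of the
        within-window maximum absolute derivative.
    min_run
        Composites a derivative excursion must be sustained to count.
    spring_search_window / autumn_search_window
        DOY ranges searched for the falling / rising transition; autumn
        values above 365 wrap into the next calendar year.
    min_search_end_doy
        End of the search range for the annual minimum (and DPE), expressed
        as a DOY possibly beyond 365 ("the following spring").
    """

    dry_threshold: float = 0.3
    deriv_epsilon_fraction: float = 0.19
    min_run: int = 2
    spring_search_window: tuple[int, int] = (1, 240)
    autumn_search_window: tuple[int, int] = (210, 400)
    min_search_end_doy: int = 365 + 120

    def __post_init__(self) -> None:
        if not 0 < self.dry_threshold < 1:
            raise ValueError("dry_threshold must be in (0, 1)")
        if not 0 < self.deriv_epsilon_fraction < 1:
            raise ValueError("deriv_epsilon_fraction must be in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        for lo, hi in (self.spring_search_window, self.autumn_search_window):
            if hi <= lo:
                raise ValueError("search windows must be non-empty")


def first_derivative(series: EviSeries) -> np.ndarray:
    """dEVI per composite step: central differences inside, one-sided at the ends."""
    if len(series) < 3:
        raise ValueError("derivative needs at least 3 points")
    return np.gradient(series.evi)


def _runs(mask: np.ndarray):
    """(start, length) of each run of True in ``mask``."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2] - idx[::2]))


def detect_transition(series: EviSeries, deriv: np.ndarray, params: DetectionParams,
                      direction: str, window: tuple[int, int], year: int):
    """Onset/end DOY of a falling (spring drop) or rising (autumn revival) transition.

    The transition is the sustained run (>= ``min_run`` composites) of signed
    derivative beyond the near-zero band (epsilon = fraction of the
    within-window max |derivative|) that contains the window's peak
    derivative; the end is the first subsequent run of >= ``min_run``
    composites back inside the band.  The reported onset/end DOYs are the
    band-crossing times, linearly interpolated between the bracketing
    composites and rounded to integer days.  Missing events are returned as
    NaN (not raised).
    """
    if direction not in ("falling", "rising"):
        raise ValueError("direction must be 'falling' or 'rising'")
    axis = series.day_axis()
    base = (year - series.start_year) * NOMINAL_YEAR_DAYS
    lo, hi = window
    sel = np.flatnonzero((axis >= base + lo) & (axis <= base + hi))
    if sel.size < params.min_run + 1:
        return (math.nan, math.nan)
    d = deriv[sel]
    eps = params.deriv_epsilon_fraction * np.max(np.abs(d))
    if eps <= 0:
        logger.info("%s year %d: flat %s window, no transition", series.site_id, year, direction)
        return (math.nan, math.nan)
    sign = -1.0 if direction == "falling" else 1.0
    beyond = sign * d > eps
    # the transition is the sustained excursion containing the window's peak
    # derivative; isolated noise wiggles before it are not the onset
    peak = int(np.argmax(sign * d))
    runs = [(s, ln) for s, ln in _runs(beyond) if ln >= params.min_run]
    if not runs:
        logger.info("%s year %d: no %s onset found", series.site_id, year, direction)
        return (math.nan, math.nan)
    containing = [(s, ln) for s, ln in runs if s <= peak < s + ln]
    onset_pos, run_len = containing[0] if containing else max(runs, key=lambda r: r[1])
    t = axis[sel].astype(float)
    sd = sign * d
    if onset_pos == 0 or sd[onset_pos - 1] > eps:
        onset = float(t[0] - base)  # run starts at the window edge
    else:
        onset = float(round(_cross_doy(t[onset_pos - 1], sd[onset_pos - 1],
                                       t[onset_pos], sd[onset_pos], eps) - base))
    inside = np.abs(d) < eps
    inside[: onset_pos + run_len] = False
    end_pos = next((s for s, ln in _runs(inside) if ln >= params.min_run), None)
    if end_pos is None:
        logger.info("%s year %d: %s onset without end", series.site_id, year, direction)
        return (onset, math.nan)
    if sd[end_pos - 1] > eps:  # crossing bracketed by the last beyond-band composite
        end = float(round(_cross_doy(t[end_pos - 1], sd[end_pos - 1],
                                     t[end_pos], sd[end_pos], eps) - base))
    else:
        end = float(t[end_pos] - base)
    return (onset, end)


def _cross_doy(t0: float, v0: float, t1: float, v1: float, thr: float) -> float:
    """Linearly interpolated crossing time of ``thr`` between two composites."""
    return t0 + (v0 - thr) / (v0 - v1) * (t1 - t0)


def _extrema_indices(series: EviSeries, year: int, params: DetectionParams):
    axis = series.day_axis()
    base = (year - series.start_year) * NOMINAL_YEAR_DAYS
    in_year = np.flatnonzero((axis >= base + 1) & (axis <= base + NOMINAL_YEAR_DAYS))
    if in_year.size < 40:
        raise ValueError(f"year {year} not completely covered by the series")
    max_idx = in_year[int(np.argmax(series.evi[in_year]))]  # argmax: earliest tie wins
    after = np.flatnonzero(
        (np.arange(len(series)) > max_idx) & (axis <= base + params.min_search_end_doy)
    )
    if after.size == 0:
        raise ValueError(f"no composites after the year-{year} maximum")
    min_idx = after[int(np.argmin(series.evi[after]))]
    return base, max_idx, min_idx


def extrema_metrics(series: EviSeries, year: int,
                    params: DetectionParams | None = None):
    """Annual max EVI (calendar year) and the minimum between it and next spring."""
    params = params or DetectionParams()
    base, max_idx, min_idx = _extrema_indices(series, year, params)
    axis = series.day_axis()
    return (
        float(series.evi[max_idx]), float(axis[max_idx] - base),
        float(series.evi[min_idx]), float(axis[min_idx] - base),
    )


def detect_dry_period(series: EviSeries, params: DetectionParams, year: int):
    """Threshold crossings delimiting the dry period.

    DPO: first downward crossing of ``dry_threshold`` after the annual
    maximum; DPE: first upward crossing after the subsequent minimum.
    Crossings are linearly interpolated between bracketing composites and
    rounded to the nearest integer DOY; DPE may exceed 365.
    """
    thr = params.dry_threshold
    base, max_idx, _ = _extrema_indices(series, year, params)
    axis = series.day_axis().astype(float)
    y = series.evi

    def _down_cross_after(start_idx):
        for i in range(start_idx, len(y) - 1):
            if axis[i] > base + NOMINAL_YEAR_DAYS:
                return None
            if y[i] >= thr > y[i + 1]:
                return i
        return None

    cross = _down_cross_after(max_idx)
    if cross is None and axis[max_idx] > base + 182:
        # smoothing overshoot can put the calendar-year maximum after the
        # trough; the dry period follows the pre-summer (spring) maximum
        first_half = np.flatnonzero((axis >= base + 1) & (axis <= base + 182))
        if first_half.size:
            max_idx = first_half[int(np.argmax(y[first_half]))]
            cross = _down_cross_after(max_idx)
    if cross is None:
        logger.info("%s year %d: EVI never drops below %.3g (wet year)",
                    series.site_id, year, thr)
        return (math.nan, math.nan)
    dpo = float(round(_cross_doy(axis[cross], y[cross],
                                 axis[cross + 1], y[cross + 1], thr) - base))

    stop = base + params.min_search_end_doy
    after = np.flatnonzero((np.arange(len(y)) > cross) & (axis <= stop))
    min_idx = after[int(np.argmin(y[after]))]
    dpe = math.nan
    for i in range(min_idx, len(y) - 1):
        if axis[i] > stop:
            break
        if y[i] < thr <= y[i + 1]:
            dpe = float(round(_cross_doy(axis[i], y[i], axis[i + 1], y[i + 1], thr) - base))
            break
    if math.isnan(dpe):
        logger.info("%s year %d: dry period end not found", series.site_id, year)
    return (dpo, dpe)


def compute_threshold(series: EviSeries) -> float:
    """Midpoint of the all-years absolute max and min EVI (threshold alternative)."""
    if len(series) == 0:
        raise ValueError("empty series")
    return float((np.max(series.evi) + np.min(series.evi)) / 2.0)


def extract_all_metrics(series: EviSeries,
                        params: DetectionParams | None = None) -> pd.DataFrame:
    """One row of the 13 phenology metrics per covered year.

    Metrics that cannot be detected (flat windows, wet years, truncated final
    autumn) are NaN.  Duration identities (sdd = sde - sdo, etc.) hold exactly
    whenever both ends are present.
    """
    params = params or DetectionParams()
    deriv = first_derivative(series)
    rows = []
    for year in series.years:
        year = int(year)
        row: dict[str, float] = {"site": series.site_id, "year": year}
        sdo, sde = detect_transition(series, deriv, params, "falling",
                                     params.spring_search_window, year)
        aro, are = detect_transition(series, deriv, params, "rising",
                                     params.autumn_search_window, year)
        row.update(sdo=sdo, sde=sde, sdd=sde - sdo, aro=aro, are=are, ard=are - aro)
        try:
            max_evi, max_date, min_evi, min_date = extrema_metrics(series, year, params)
            dpo, dpe = detect_dry_period(series, params, year)
        except ValueError:
            max_evi = max_date = min_evi = min_date = dpo = dpe = math.nan
        row.update(dpo=dpo, dpe=dpe, dpd=dpe - dpo,
                   max_evi=max_evi, max_date=max_date, min_evi=min_evi, min_date=min_date)
        rows.append(row)
    return pd.DataFrame(rows, columns=["site", "year", *METRIC_COLUMNS])


# ---------------------------------------------------------------------------
# Site comparison
# ---------------------------------------------------------------------------


def compare_sites(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                  metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-metric site means, SDs, difference of means (a - b) and paired t-test p.

    Pairing is by year; years with a missing value in either site are dropped
    pairwise per metric.  Fewer than 3 complete pairs leaves p missing; a
    zero-variance nonzero difference is flagged by p = 0, identical series by
    p = 1.
    """
    metrics = metrics or [c for c in METRIC_COLUMNS if c in metrics_a.columns]
    a = metrics_a.set_index("year")
    b = metrics_b.set_index("year")
    common = a.index.intersection(b.index)
    rows = []
    for m in metrics:
        va = a.loc[common, m].astype(float)
        vb = b.loc[common, m].astype(float)
        ok = va.notna() & vb.notna()
        va, vb = va[ok], vb[ok]
        n = len(va)
        mean_a, mean_b = va.mean(), vb.mean()
        diff = mean_a - mean_b
        if n < 3:
            p = math.nan
        else:
            d = va.to_numpy() - vb.to_numpy()
            if np.allclose(d, 0.0, atol=1e-12):
                p = 1.0
            elif np.isclose(d.std(ddof=1), 0.0):
                p = 0.0  # constant nonzero difference: limit case
            else:
                p = float(stats.ttest_rel(va, vb).pvalue)
        rows.append({
            "metric": m, "mean_a": mean_a, "sd_a": va.std(ddof=1),
            "mean_b": mean_b, "sd_b": vb.std(ddof=1),
            "difference": diff, "p": p, "n_pairs": n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sklearn-style facade
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class PhenologyExtractor(BaseEstimator):
    """Estimator-style wrapper around :func:`extract_all_metrics`.

    ``transform`` maps a smoothed :class:`EviSeries` to the per-year metrics
    table; parameters follow :class:`DetectionParams` and are exposed through
    ``get_params``/``set_params`` for grid searches over detection settings.
    """

    def __init__(self, dry_threshold: float = 0.3, deriv_epsilon_fraction: float = 0.19,
                 min_run: int = 2, spring_search_window: tuple[int, int] = (1, 240),
                 autumn_search_window: tuple[int, int] = (210, 400),
                 min_search_end_doy: int = 365 + 120):
        self.dry_threshold = dry_threshold
        self.deriv_epsilon_fraction = deriv_epsilon_fraction
        self.min_run = min_run
        self.spring_search_window = spring_search_window
        self.autumn_search_window = autumn_search_window
        self.min_search_end_doy = min_search_end_doy

    def _params(self) -> DetectionParams:
        return DetectionParams(
            dry_threshold=self.dry_threshold,
            deriv_epsilon_fraction=self.deriv_epsilon_fraction,
            min_run=self.min_run,
            spring_search_window=tuple(self.spring_search_window),
            autumn_search_window=tuple(self.autumn_search_window),
            min_search_end_doy=self.min_search_end_doy,
        )

    def fit(self, X: EviSeries, y=None):
        self.params_ = self._params()
        return self

    def transform(self, X: EviSeries) -> pd.DataFrame:
        return extract_all_metrics(X, self._params())

    def fit_transform(self, X: EviSeries, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
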