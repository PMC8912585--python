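"""EVI computation, BISE noise correction, harmonic smoothing, aggregation.

The Enhanced Vegetation Index is computed from surface reflectance as

    EVI = 2.5 * (R_nir - R_red) / (R_nir + 6 * R_red - 7.5 * R_blue + 1)

Cloud contamination biases composite EVI *low*; cleaning therefore proceeds
in two stages: a forward-scan slope test (BISE) that rejects sudden drops
followed by a quick recovery, and a Fourier-harmonic reconstruction with an
optional upper-envelope bias that pulls the fit toward the high points.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import (
    COMPOSITES_PER_YEAR,
    FLAG_BISE,
    FLAG_SMOOTHED,
    SITE_MEAN_PIXEL,
    EviSeries,
    gap_fill,
)

logger = logging.getLogger(__name__)


@dataclass
class ReflectanceSample:
    """Blue/red/NIR surface reflectance for one composite start date."""

    date: pd.Timestamp
    r_blue: float
    r_red: float
    r_nir: float


@dataclass
class EviPoint:
    date: pd.Timestamp
    evi: float
    flag: str = "observed"


@dataclass
class SmoothingParams:
    """Tunables for cleaning and smoothing.

    n_harmonics
        Per-year harmonic count retained in the Fourier reconstruction.
    envelope_iterations
        Upper-envelope reweighting passes (points above the fit get double
        weight); compensates the negative bias of cloud-affected composites.
    bise_slide_composites
        BISE sliding window (composites) searched for a recovery.
    bise_recovery_fraction
        Fraction of a drop that must be recovered within the window for the
        low point to be called noise.
    bise_min_drop_fraction
        Minimum relative drop (fraction of the last accepted value) before a
        point is examined at all; gentler declines are accepted as phenology.
    """

    n_harmonics: int = 5
    envelope_iterations: int = 2
    bise_slide_composites: int = 5
    bise_recovery_fraction: float = 0.2
    bise_min_drop_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_harmonics < 0 or self.envelope_iterations < 0:
            raise ValueError("n_harmonics and envelope_iterations must be >= 0")
        if self.bise_slide_composites < 1:
            raise ValueError("bise_slide_composites must be >= 1")
        if not 0 < self.bise_recovery_fraction <= 1:
            raise ValueError("bise_recovery_fraction must be in (0, 1]")
        if not 0 <= self.bise_min_drop_fraction < 1:
            raise ValueError("bise_min_drop_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# EVI from reflectance
# ---------------------------------------------------------------------------

_DEN_EPS = 1e-9


def evi_from_reflectance(r_blue, r_red, r_nir):
    """Vectorised EVI; raises on near-zero denominator or out-of-range input."""
    r_blue, r_red, r_nir = (np.asarray(x, dtype=float) for x in (r_blue, r_red, r_nir))
    for name, arr in (("r_blue", r_blue), ("r_red", r_red), ("r_nir", r_nir)):
        if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} must be finite and within [0, 1]")
    den = r_nir + 6.0 * r_red - 7.5 * r_blue + 1.0
    if np.any(np.abs(den) < _DEN_EPS):
        raise ValueError("EVI denominator within 1e-9 of zero")
    return 2.5 * (r_nir - r_red) / den


def compute_evi(sample: ReflectanceSample) -> EviPoint:
    """EVI for a single reflectance sample."""
    try:
        value = float(evi_from_reflectance(sample.r_blue, sample.r_red, sample.r_nir))
    except ValueError as exc:
        raise ValueError(f"invalid reflectance sample at {sample.date}: {exc}") from exc
    return EviPoint(date=sample.date, evi=value, flag="observed")


def read_reflectance_csv(path, fill_gaps: bool = True) -> dict[tuple[str, str], EviSeries]:
    """Read a reflectance CSV (site,pixel,date,r_blue,r_red,r_nir) into EVI series."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"site", "pixel", "date", "r_blue", "r_red", "r_nir"}
    if not required.issubset(df.columns):
        raise ValueError(f"reflectance CSV needs columns {sorted(required)}")
    df = df.assign(evi=evi_from_reflectance(df["r_blue"], df["r_red"], df["r_nir"]))
    out: dict[tuple[str, str], EviSeries] = {}
    for (site, pixel), grp in df.groupby(["site", "pixel"], sort=True):
        site, pixel = str(site), str(pixel)
        if fill_gaps:
            out[(site, pixel)] = gap_fill(site, pixel, grp["date"], grp["evi"].to_numpy())
        else:
            out[(site, pixel)] = EviSeries(
                site, pixel, pd.DatetimeIndex(grp["date"]), grp["evi"].to_numpy()
            )
    return out


# ---------------------------------------------------------------------------
# BISE correction
# ---------------------------------------------------------------------------


def _bise_rejects(y: np.ndarray, slide: int, recovery_fraction: float,
                  min_drop_fraction: float) -> np.ndarray:
    """Boolean mask of rejected points under the forward-scan slope test."""
    n = len(y)
    rejected = np.zeros(n, dtype=bool)
    last = y[0]  # the first point is always accepted
    for i in range(1, n):
        drop = last - y[i]
        rel = drop / max(abs(last), 1e-6)
        if rel > min_drop_fraction:
            hi = min(i + slide, n - 1)
            window = y[i + 1 : hi + 1]
            if window.size and np.max(window) >= y[i] + recovery_fraction * drop:
                rejected[i] = True
                continue  # `last` stays at the pre-drop level
        last = y[i]
    return rejected


def bise_correct(series: EviSeries, params: SmoothingParams | None = None) -> EviSeries:
    """Best Index Slope Extraction noise correction.

    A point that drops sharply relative to the last accepted point and whose
    drop is recovered (by at least ``bise_recovery_fraction`` of its depth)
    within the sliding window is a cloud artefact: it is replaced by linear
    interpolation between accepted neighbours and flagged ``bise-replaced``.
    """
    params = params or SmoothingParams()
    if len(series) < params.bise_slide_composites + 2:
        raise ValueError(
            f"series too short for BISE: need >= {params.bise_slide_composites + 2} points"
        )
    rejected = _bise_rejects(
        series.evi,
        params.bise_slide_composites,
        params.bise_recovery_fraction,
        params.bise_min_drop_fraction,
    )
    if rejected.all():
        raise ValueError("BISE rejected every point")
    values = series.evi.copy()
    flags = series.flags.copy()
    if rejected.any():
        accepted_idx = np.flatnonzero(~rejected)
        bad_idx = np.flatnonzero(rejected)
        values[bad_idx] = np.interp(bad_idx, accepted_idx, values[accepted_idx])
        flags[bad_idx] = FLAG_BISE
        logger.info("%s/%s: BISE replaced %d composites",
                    series.site_id, series.pixel_id, len(bad_idx))
    return series.with_values(values, flags)


# ---------------------------------------------------------------------------
# Fourier-harmonic smoothing
# ---------------------------------------------------------------------------


def _harmonic_design(n: int, k_max: int) -> np.ndarray:
    t = np.arange(n)
    cols = [np.ones(n)]
    for k in range(1, k_max + 1):
        arg = 2.0 * np.pi * k * t / n
        cols.append(np.cos(arg))
        cols.append(np.sin(arg))
    return np.column_stack(cols)


def fft_smooth(series: EviSeries, params: SmoothingParams | None = None) -> EviSeries:
    """Harmonic (Fourier) smoothing with optional upper-envelope adjustment.

    The full multi-year series is decomposed; DC plus all harmonics at
    ``<= n_harmonics`` cycles/year are retained.  Each envelope iteration then
    doubles the weight of input points lying above the current fit and refits,
    biasing the reconstruction toward the upper envelope of the data.
    """
    params = params or SmoothingParams()
    n = len(series)
    if n % COMPOSITES_PER_YEAR != 0:
        raise ValueError(
            "fft_smooth needs whole years on the full composite calendar; gap-fill first"
        )
    n_years = n // COMPOSITES_PER_YEAR
    k_max = min(params.n_harmonics * n_years, n // 2)
    y = series.evi

    if params.envelope_iterations == 0:
        spec = np.fft.rfft(y)
        spec[k_max + 1 :] = 0.0
        fit = np.fft.irfft(spec, n)
    else:
        design = _harmonic_design(n, k_max)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fit = design @ coef
        for _ in range(params.envelope_iterations):
            w = np.where(y > fit, 2.0, 1.0)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
            fit = design @ coef
    flags = np.full(n, FLAG_SMOOTHED, dtype=object)
    return series.with_values(fit, flags)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def average_pixels(series_list: list[EviSeries]) -> EviSeries:
    """Per-date arithmetic mean over pixels of one site (pixel_id 'site-mean')."""
    if not series_list:
        raise ValueError("no series to average")
    first = series_list[0]
    for s in series_list[1:]:
        if s.site_id != first.site_id:
            raise ValueError(f"site mismatch: {s.site_id!r} vs {first.site_id!r}")
        if len(s.dates) != len(first.dates) or not (s.dates == first.dates).all():
            offending = first.dates.symmetric_difference(s.dates)
            raise ValueError(f"date grids differ at {list(offending[:5])}")
    values = np.mean([s.evi for s in series_list], axis=0)
    stacked = np.vstack([s.flags for s in series_list])
    flags = np.where((stacked == stacked[0]).all(axis=0), stacked[0], "observed")
    return first.with_values(values, flags.astype(object), pixel_id=SITE_MEAN_PIXEL)


def monthly_mean_evi(series: EviSeries) -> pd.DataFrame:
    """Per-calendar-month mean EVI (composite assigned to its start month)."""
    df = pd.DataFrame(
        {"year": series.dates.year, "month": series.dates.month, "evi": series.evi}
    )
    out = df.groupby(["year", "month"], as_index=False)["evi"].mean()
    if out.empty:
        raise ValueError("no monthly records produced")
    return out


def annual_profile(series: EviSeries) -> pd.DataFrame:
    """Cross-year mean and sample SD per 8-day composite (46 rows)."""
    if series.n_years < 2:
        raise ValueError("annual profile needs >= 2 complete years (SD undefined)")
    composite = (series.doy - 1) // 8 + 1
    df = pd.DataFrame({"composite": composite, "evi": series.evi})
    out = df.groupby("composite")["evi"].agg(mean_evi="mean", sd_evi=lambda v: v.std(ddof=1))
    return out.reset_index()


# ---------------------------------------------------------------------------
# sklearn-style transformer facades
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class BiseCorrector(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying BISE row-wise to (n_series, n_composites) arrays."""

    def __init__(self, bise_slide_composites: int = 5, bise_recovery_fraction: float = 0.2,
                 bise_min_drop_fraction: float = 0.2):
        self.bise_slide_composites = bise_slide_composites
        self.bise_recovery_fraction = bise_recovery_fraction
        self.bise_min_drop_fraction = bise_min_drop_fraction

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for i, row in enumerate(X):
            rejected = _bise_rejects(row, self.bise_slide_composites,
                                     self.bise_recovery_fraction, self.bise_min_drop_fraction)
            vals = row.copy()
            if rejected.any():
                ok = np.flatnonzero(~rejected)
                bad = np.flatnonzero(rejected)
                vals[bad] = np.interp(bad, ok, row[ok])
            out[i] = vals
        return out


class HarmonicSmoother(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: row-wise harmonic truncation + envelope passes."""

    def __init__(self, n_harmonics: int = 5, envelope_iterations: int = 2):
        self.n_harmonics = n_harmonics
        self.envelope_iterations = envelope_iterations

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = SmoothingParams(n_harmonics=self.n_harmonics,
                                 envelope_iterations=self.envelope_iterations)
        out = np.empty_like(X)
        from .series import composite_dates

        n_years = X.shape[1] // COMPOSITES_PER_YEAR
        dates = composite_dates(2000, n_years)
        for i, row in enumerate(X):
            s = EviSeries("_", "_", dates, row)
            out[i] = fft_smooth(s, params).evi
        return out
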