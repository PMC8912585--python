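"""Dated 8-day composite vegetation-index series.

The whole pipeline operates on :class:`EviSeries`: one site/pixel worth of
Enhanced Vegetation Index values on the standard 8-day compositing calendar
(46 composites per year, start days-of-year 1, 9, ..., 361; the final
composite absorbs day 365/366).  Dates are composite *start* dates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPOSITES_PER_YEAR = 46
COMPOSITE_DOYS = tuple(range(1, 362, 8))
#: nominal year length used for the continuous day axis; day-of-year values
#: above 365 denote a wrap into the following calendar year (370 = Jan 5).
NOMINAL_YEAR_DAYS = 365

FLAG_OBSERVED = "observed"
FLAG_GAPFILLED = "gap-filled"
FLAG_BISE = "bise-replaced"
FLAG_SMOOTHED = "smoothed"

SITE_MEAN_PIXEL = "site-mean"


def composite_dates(start_year: int, n_years: int) -> pd.DatetimeIndex:
    """Composite start dates for ``n_years`` whole years from ``start_year``."""
    dates = []
    for year in range(start_year, start_year + n_years):
        base = pd.Timestamp(year=year, month=1, day=1)
        dates.extend(base + pd.Timedelta(days=8 * i) for i in range(COMPOSITES_PER_YEAR))
    return pd.DatetimeIndex(dates)


@dataclass
class EviSeries:
    """EVI values for one site/pixel on the full composite calendar.

    Invariants (enforced by :meth:`validate`): strictly increasing dates, each
    date on the composite calendar, exactly 46 composites per covered year.
    """

    site_id: str
    pixel_id: str
    dates: pd.DatetimeIndex
    evi: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.evi = np.asarray(self.evi, dtype=float)
        if self.flags is None:
            self.flags = np.full(len(self.evi), FLAG_OBSERVED, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not (len(self.dates) == len(self.evi) == len(self.flags)):
            raise ValueError("dates, evi and flags must have equal length")
        if len(self.dates) == 0:
            raise ValueError("empty series")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing without duplicates")
        doys = self.doy
        bad = set(np.unique(doys)) - set(COMPOSITE_DOYS)
        if bad:
            raise ValueError(f"dates off the 8-day composite calendar (DOYs {sorted(bad)})")
        counts = pd.Series(1, index=self.dates).groupby(self.dates.year).sum()
        incomplete = counts[counts != COMPOSITES_PER_YEAR]
        if len(incomplete):
            raise ValueError(
                "every covered year needs exactly "
                f"{COMPOSITES_PER_YEAR} composites; got {incomplete.to_dict()}"
            )
        if not np.all(np.isfinite(self.evi)):
            raise ValueError("EVI values must be finite (gap-fill missing composites first)")
        out = (self.evi < -0.2) | (self.evi > 1.0)
        if out.any():
            # not clamped by design: out-of-range values survive to detection
            logger.warning(
                "%s/%s: %d EVI values outside [-0.2, 1]", self.site_id, self.pixel_id, out.sum()
            )

    # -- derived views ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.evi)

    @property
    def doy(self) -> np.ndarray:
        """1-based day of year of each composite start (always 1, 9, ..., 361)."""
        return self.dates.dayofyear.to_numpy()

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)

    @property
    def start_year(self) -> int:
        return int(self.dates[0].year)

    @property
    def n_years(self) -> int:
        return len(self) // COMPOSITES_PER_YEAR

    def day_axis(self) -> np.ndarray:
        """Continuous nominal-day axis: (year - first_year) * 365 + DOY."""
        return (self.dates.year.to_numpy() - self.start_year) * NOMINAL_YEAR_DAYS + self.doy

    def with_values(self, evi: np.ndarray, flags: np.ndarray | None = None,
                    pixel_id: str | None = None) -> "EviSeries":
        return EviSeries(
            site_id=self.site_id,
            pixel_id=self.pixel_id if pixel_id is None else pixel_id,
            dates=self.dates,
            evi=np.asarray(evi, dtype=float).copy(),
            flags=self.flags.copy() if flags is None else np.asarray(flags, dtype=object),
        )

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_id,
                "pixel": self.pixel_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "evi": self.evi,
                "flag": self.flags,
            }
        )


def gap_fill(site_id: str, pixel_id: str, dates, evi) -> EviSeries:
    """Build a calendar-complete series from possibly-incomplete observations.

    Missing composites are linearly interpolated on the continuous day axis and
    flagged ``gap-filled`` (edges are held at the nearest observed value).
    """
    dates = pd.DatetimeIndex(dates)
    order = np.argsort(dates.values)
    dates, evi = dates[order], np.asarray(evi, dtype=float)[order]
    keep = np.isfinite(evi)
    dates, evi = dates[keep], evi[keep]
    if len(dates) == 0:
        raise ValueError("no finite observations to build a series from")
    y0, y1 = int(dates[0].year), int(dates[-1].year)
    full = composite_dates(y0, y1 - y0 + 1)
    axis_full = (full.year.to_numpy() - y0) * NOMINAL_YEAR_DAYS + full.dayofyear.to_numpy()
    axis_obs = (dates.year.to_numpy() - y0) * NOMINAL_YEAR_DAYS + dates.dayofyear.to_numpy()
    values = np.interp(axis_full, axis_obs, evi)
    flags = np.where(np.isin(full.values, dates.values), FLAG_OBSERVED, FLAG_GAPFILLED)
    n_filled = int((flags == FLAG_GAPFILLED).sum())
    if n_filled:
        logger.info("%s/%s: gap-filled %d missing composites", site_id, pixel_id, n_filled)
    return EviSeries(site_id, pixel_id, full, values, flags.astype(object))


def read_index_csv(path, fill_gaps: bool = True) -> dict[tuple[str, str], EviSeries]:
    """Read an index CSV (columns site,pixel,date,evi) into per-pixel series."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"site", "pixel", "date", "evi"}
    if not required.issubset(df.columns):
        raise ValueError(f"index CSV needs columns {sorted(required)}")
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


def write_series_csv(path, series_list) -> None:
    """Write series to the cleaned/smoothed CSV dialect (site,pixel,date,evi,flag)."""
    if isinstance(series_list, EviSeries):
        series_list = [series_list]
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(path, index=False)
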