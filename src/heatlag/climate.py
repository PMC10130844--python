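"""Citywide daily exposure series built from weather-station records.

The exposure of interest is the daily minimum temperature (Tmin, °F), a
proxy for nighttime heat.  Multiple stations are combined into a single
citywide series by unweighted per-day averaging; relative humidity is
derived from mean temperature and dew point with the Magnus
approximation.  All temperatures are handled in °F; °F→°C conversion is
centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StationSeries",
    "CityTemperatureSeries",
    "GapError",
    "average_stations",
    "relative_humidity",
    "dew_point_from_rh",
    "exposure_percentile",
    "f_to_c",
    "c_to_f",
    "QUANTILE_RULE",
]

#: Quantile convention used by :func:`exposure_percentile` (recorded in
#: run manifests because percentile-based quantities depend on it).
QUANTILE_RULE = "linear interpolation between order statistics (type 7)"

# Magnus saturation-vapour-pressure coefficients (Alduchov & Eskridge).
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # °C


class GapError(ValueError):
    """A required exposure day is missing from the citywide series."""


def f_to_c(t_f):
    """Convert °F to °C."""
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def c_to_f(t_c):
    """Convert °C to °F."""
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


@dataclass
class StationSeries:
    """Daily records from one weather station.

    ``frame`` is indexed by normalized daily timestamps and carries the
    columns ``tmin_f``, ``tmean_f``, ``tdew_f``; any cell may be NaN
    (missing for that day).
    """

    station_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.index = pd.DatetimeIndex(self.frame.index).normalize()
        if self.frame.index.has_duplicates:
            raise ValueError(f"station {self.station_id}: duplicate dates")
        both = self.frame[["tmean_f", "tdew_f"]].dropna()
        if (both["tdew_f"] > both["tmean_f"] + 1e-9).any():
            bad = both.index[both["tdew_f"] > both["tmean_f"] + 1e-9][0]
            raise ValueError(
                f"station {self.station_id}: dew point exceeds mean "
                f"temperature on {bad.date()}"
            )

    @staticmethod
    def read_csv(path) -> list["StationSeries"]:
        """Read a station CSV (``station_id,date,tmin_f,tmean_f,tdew_f``)."""
        df = pd.read_csv(path, parse_dates=["date"])
        out = []
        for sid, grp in df.groupby("station_id", sort=True):
            frame = grp.set_index("date")[["tmin_f", "tmean_f", "tdew_f"]]
            out.append(StationSeries(str(sid), frame))
        return out


@dataclass
class CityTemperatureSeries:
    """Calendar-indexed citywide daily exposure.

    ``frame`` is indexed by contiguous daily timestamps with columns
    ``tmin_f``, ``tmean_f``, ``rh_pct``.  By default Tmin must be present
    for every day inside the coverage range; with ``allow_gaps=True``
    missing days are retained as declared NaN gaps (downstream stratum
    construction drops and counts anything touching them).  RH may be NaN
    (it is only needed by the humidity-adjusted sensitivity model).
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.index = pd.DatetimeIndex(self.frame.index).normalize()
        self.frame = self.frame.sort_index()
        full = pd.date_range(self.frame.index[0], self.frame.index[-1], freq="D")
        if len(full) != len(self.frame):
            if not self.allow_gaps:
                missing = full.difference(self.frame.index)[0]
                raise GapError(f"coverage gap: no record for {missing.date()}")
            self.frame = self.frame.reindex(full)
        if not self.allow_gaps and self.frame["tmin_f"].isna().any():
            bad = self.frame.index[self.frame["tmin_f"].isna()][0]
            raise GapError(f"coverage gap: Tmin missing on {bad.date()}")
        rh = self.frame["rh_pct"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError("relative humidity outside [0, 100]")

    @property
    def gap_dates(self) -> pd.DatetimeIndex:
        """Declared gap days (NaN Tmin) inside the coverage range."""
        return self.frame.index[self.frame["tmin_f"].isna()]

    @property
    def start(self) -> pd.Timestamp:
        return self.frame.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.frame.index[-1]

    def covers(self, date) -> bool:
        d = pd.Timestamp(date).normalize()
        return self.start <= d <= self.end

    def tmin(self, dates) -> np.ndarray:
        """Tmin (°F) for one date or an array of dates."""
        idx = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(dates))).normalize()
        out = self.frame["tmin_f"].reindex(idx)
        if out.isna().any():
            raise GapError(f"no Tmin for {out.index[out.isna()][0].date()}")
        return out.to_numpy()

    def rh(self, dates) -> np.ndarray:
        """Relative humidity (%) for one date or an array of dates."""
        idx = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(dates))).normalize()
        return self.frame["rh_pct"].reindex(idx).to_numpy()

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "date"
        out.to_csv(path, float_format="%.6g")

    @staticmethod
    def read_csv(path) -> "CityTemperatureSeries":
        df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
        return CityTemperatureSeries(df[["tmin_f", "tmean_f", "rh_pct"]])


def average_stations(stations: list[StationSeries]) -> CityTemperatureSeries:
    """Average daily station records into a citywide series.

    Each component (Tmin, Tmean, dew point) is the unweighted arithmetic
    mean over the stations reporting it that day; stations missing a day
    are simply skipped.  A day on which *no* station reports Tmin is a
    hard gap and raises :class:`GapError` naming the date.  RH is
    computed from the averaged Tmean and dew point and is NaN on days
    where either is unavailable.
    """
    if not stations:
        raise ValueError("average_stations requires at least one station")
    frames = [s.frame for s in stations]
    idx = frames[0].index
    for f in frames[1:]:
        idx = idx.union(f.index)
    idx = pd.date_range(idx.min(), idx.max(), freq="D")
    aligned = [f.reindex(idx) for f in frames]
    tmin = pd.concat([f["tmin_f"] for f in aligned], axis=1).mean(axis=1)
    tmean = pd.concat([f["tmean_f"] for f in aligned], axis=1).mean(axis=1)
    tdew = pd.concat([f["tdew_f"] for f in aligned], axis=1).mean(axis=1)
    if tmin.isna().any():
        bad = idx[tmin.isna()][0]
        raise GapError(f"no station reports Tmin on {bad.date()}")
    ok = tmean.notna() & tdew.notna()
    rh = pd.Series(np.nan, index=idx)
    if ok.any():
        rh[ok] = relative_humidity(tmean[ok].to_numpy(), tdew[ok].to_numpy())
    frame = pd.DataFrame({"tmin_f": tmin, "tmean_f": tmean, "rh_pct": rh})
    return CityTemperatureSeries(
        frame, metadata={"stations": [s.station_id for s in stations]}
    )


def relative_humidity(tmean_f, tdew_f):
    """Relative humidity (%) from mean and dew-point temperature (°F).

    Uses the Magnus approximation RH = 100·e(Td)/e(T) with saturation
    vapour pressure e(T°C) ∝ exp(17.625·T/(243.04+T)).  The result is
    clamped to (0, 100].  Supersaturation (Td > T) is not modelled and
    raises ``ValueError``.
    """
    t = f_to_c(tmean_f)
    td = f_to_c(tdew_f)
    if not (np.isfinite(t).all() and np.isfinite(td).all()):
        raise ValueError("temperatures must be finite")
    if np.any(td > t + 1e-9):
        raise ValueError("dew point exceeds mean temperature (supersaturation)")
    rh = 100.0 * np.exp(_MAGNUS_A * td / (_MAGNUS_B + td) - _MAGNUS_A * t / (_MAGNUS_B + t))
    rh = np.clip(rh, np.finfo(float).tiny, 100.0)
    return float(rh) if np.isscalar(tmean_f) or np.ndim(tmean_f) == 0 else rh


def dew_point_from_rh(tmean_f, rh_pct):
    """Invert the Magnus formula: dew point (°F) from Tmean (°F) and RH (%)."""
    t = f_to_c(tmean_f)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("RH must lie in (0, 100]")
    gamma = np.log(rh / 100.0) + _MAGNUS_A * t / (_MAGNUS_B + t)
    td = _MAGNUS_B * gamma / (_MAGNUS_A - gamma)
    return c_to_f(td)


def exposure_percentile(
    series: CityTemperatureSeries, months, p: float
) -> float:
    """Quantile of daily Tmin restricted to the given calendar months.

    ``p`` is a fraction in (0, 1).  The quantile rule is linear
    interpolation between order statistics (the "type 7" convention,
    recorded in :data:`QUANTILE_RULE`).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    months = set(months)
    sel = series.frame.loc[series.frame.index.month.isin(months), "tmin_f"]
    if sel.empty:
        raise ValueError(f"no exposure days in months {sorted(months)}")
    return float(np.quantile(sel.to_numpy(), p, method="linear"))
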