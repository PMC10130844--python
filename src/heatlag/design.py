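"""Time-stratified case-crossover referent selection and stratum assembly.

Each encounter's admission day is its case day; the referents are every
other day in the same calendar month and year that falls on the same
weekday.  A weekday occurs 4 or 5 times in any month, so every case day
has exactly 3 or 4 referents.  Matching on (year, month, day-of-week)
removes long-term trend, seasonality and weekday effects by design, and
because cases serve as their own controls all time-invariant personal
factors cancel in the conditional likelihood.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import CityTemperatureSeries
from .dlnm import CrossBasisSpec, build_crossbasis
from .encounters import CohortEncounter

__all__ = ["Stratum", "StrataLog", "CoverageError", "select_referents", "build_strata"]


class CoverageError(ValueError):
    """The exposure series does not cover a required lag window."""


def select_referents(case_date: dt.date) -> list[dt.date]:
    """All other same-weekday days in the case day's month and year.

    Returned in ascending order; the case day itself is excluded.  The
    operation is an equivalence-class selection: any day in the returned
    set has the same case-plus-referents set as ``case_date``.
    """
    d = pd.Timestamp(case_date)
    first = d.replace(day=1)
    offset = (d.dayofweek - first.dayofweek) % 7
    days = []
    day = first + pd.Timedelta(days=offset)
    while day.month == d.month:
        if day != d:
            days.append(day.date())
        day += pd.Timedelta(days=7)
    return days


@dataclass
class Stratum:
    """One matched set: a case day plus its referent days.

    ``rows`` holds the design rows (cross-basis, plus any appended
    covariates) with the case row first, referents following in date
    order.  ``labels`` carries the encounter's subgroup labels.
    """

    case_date: dt.date
    referent_dates: tuple[dt.date, ...]
    labels: dict
    rows: np.ndarray
    informative: bool = True

    @property
    def n_referents(self) -> int:
        return len(self.referent_dates)


@dataclass
class StrataLog:
    """Attrition/diagnostic counts from stratum assembly."""

    n_built: int = 0
    n_dropped_gap: int = 0
    n_uninformative: int = 0


def build_strata(
    encounters: list[CohortEncounter],
    exposure: CityTemperatureSeries,
    spec: CrossBasisSpec,
) -> tuple[list[Stratum], StrataLog]:
    """Assemble one matched set per encounter with cross-basis rows.

    The exposure series must extend at least ``spec.lag_max`` days before
    the earliest case or referent day (a shortfall raises
    :class:`CoverageError` naming the earliest unservable date).  Strata
    whose lag window touches a declared gap day are dropped and counted.
    Strata whose rows are all identical (e.g. constant exposure) carry no
    information but are retained and counted.
    """
    log = StrataLog()
    if not encounters:
        return [], log

    # Referent sets and cross-basis rows are shared by all encounters on
    # the same day; compute each unique date's row once.
    unique_case_dates = sorted({e.record.admit_date for e in encounters})
    ref_map = {d: tuple(select_referents(d)) for d in unique_case_dates}
    all_dates = sorted(
        {d for cd in unique_case_dates for d in (cd, *ref_map[cd])}
    )
    earliest_needed = pd.Timestamp(all_dates[0]) - pd.Timedelta(days=spec.lag_max)
    if earliest_needed < exposure.start or pd.Timestamp(all_dates[-1]) > exposure.end:
        bad = all_dates[0] if earliest_needed < exposure.start else all_dates[-1]
        raise CoverageError(
            f"exposure coverage [{exposure.start.date()}, {exposure.end.date()}] "
            f"cannot serve lags 0-{spec.lag_max} for {bad}"
        )

    # A date is servable when no lagged day in its window is a gap.
    tmin = exposure.frame["tmin_f"]
    date_idx = pd.DatetimeIndex([pd.Timestamp(d) for d in all_dates])
    ok = np.ones(len(date_idx), dtype=bool)
    for lag in range(spec.lag_min, spec.lag_max + 1):
        ok &= tmin.reindex(date_idx - pd.Timedelta(days=lag)).notna().to_numpy()
    servable = {d: bool(o) for d, o in zip(all_dates, ok)}
    good_dates = [d for d in all_dates if servable[d]]
    rows_matrix = (
        build_crossbasis(exposure, good_dates, spec)
        if good_dates
        else np.empty((0, spec.n_columns))
    )
    row_of = {d: rows_matrix[i] for i, d in enumerate(good_dates)}

    strata: list[Stratum] = []
    for enc in encounters:
        cd = enc.record.admit_date
        refs = ref_map[cd]
        if not servable[cd] or not all(servable[r] for r in refs):
            log.n_dropped_gap += 1
            continue
        rows = np.vstack([row_of[cd]] + [row_of[r] for r in refs])
        informative = bool(np.ptp(rows, axis=0).max() > 0)
        if not informative:
            log.n_uninformative += 1
        strata.append(
            Stratum(
                case_date=cd,
                referent_dates=refs,
                labels={
                    "age_group": enc.age_group,
                    "sex": enc.record.sex,
                    "race_eth": enc.record.race_eth,
                    "payer": enc.record.payer,
                    "subcategory": enc.subcategory,
                    "suicide": enc.suicide,
                    "setting": enc.record.setting,
                },
                rows=rows,
                informative=informative,
            )
        )
        log.n_built += 1
    return strata, log


def strata_to_frame(strata: list[Stratum], spec: CrossBasisSpec) -> pd.DataFrame:
    """Serialize strata to a long table (one row per stratum-date) for audit."""
    recs = []
    cols = spec.column_names()
    extra = strata[0].rows.shape[1] - len(cols) if strata else 0
    cols = cols + [f"cov{i + 1}" for i in range(extra)]
    for sid, s in enumerate(strata):
        dates = [s.case_date, *s.referent_dates]
        for j, d in enumerate(dates):
            rec = {"stratum_id": sid, "date": d.isoformat(), "is_case": int(j == 0)}
            rec.update(dict(zip(cols, s.rows[j])))
            recs.append(rec)
    return pd.DataFrame(recs)
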