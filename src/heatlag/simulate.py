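"""Synthetic study generator.

Emulates the statistical structure the analysis assumes: a warm-season
citywide Tmin series (seasonal sinusoid plus AR(1) noise, calibrated to a
June–August mean of 67.9°F and SD of 5.4°F), and a visit-level encounter
line list whose daily counts are Poisson with a log-rate containing
day-of-week, month and year effects plus a known non-linear lag-0–5
temperature effect.  Calendar effects are constant within
(year, month, day-of-week) cells, so the time-stratified matched design
removes them exactly — tests can demonstrate, rather than assume, the
design's confounder control.

The default true exposure–response is a U-shaped quadratic with vertex
near 69°F and geometrically decaying lag weights summing to one, giving a
cumulative log-OR at the warm-season 95th percentile (≈76°F) vs the
vertex of about 0.2 (OR ≈ 1.2) — the magnitude scale of published
heat/mental-health case-crossover estimates.  Everything, including a
null (zero-effect) setting, is configurable, and all outputs are pure
functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import CityTemperatureSeries, dew_point_from_rh
from .encounters import AGE_GROUPS, DEFAULT_TAXONOMY, DiagnosisTaxonomy, EncounterRecord

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_temperature",
    "simulate_encounters",
    "simulate_study",
    "true_cumulative_log_or",
    "write_station_csv",
]



@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic study."""

    years: tuple[int, ...] = tuple(range(2005, 2012))
    # exposure: June–August Tmin moments and dependence structure
    season_mean_f: float = 67.9
    season_sd_f: float = 5.4
    ar1_rho: float = 0.7
    seasonal_amplitude_f: float = 4.0
    seasonal_peak_doy: int = 201  # ~July 20
    physical_range_f: tuple[float, float] = (40.0, 95.0)
    tmean_offset_f: float = 9.0  # Tmean − Tmin
    rh_mean_pct: float = 65.0
    rh_sd_pct: float = 10.0
    # outcome process
    baseline_daily: dict = field(
        default_factory=lambda: {"6-11": 9.7, "12-17": 34.5, "18-25": 84.6}
    )
    dow_log_effects: tuple[float, ...] = (0.05, 0.08, 0.08, 0.06, 0.02, -0.12, -0.17)
    month_log_effects: dict = field(default_factory=lambda: {6: 0.0, 7: 0.04, 8: -0.04})
    year_log_slope: float = 0.02  # log-rate drift per study year
    # true exposure–response: quadratic a·(t − v)² with per-lag weights
    response_vertex_f: float = 69.0
    response_curvature: float = 0.004  # per °F²
    lag_weights: tuple[float, ...] = (0.35, 0.25, 0.18, 0.12, 0.07, 0.03)
    effect_month_scale: dict = field(default_factory=lambda: {6: 1.0, 7: 1.0, 8: 1.0})
    # demographic / diagnostic mixtures (visit-level composition)
    sex_mix: dict = field(default_factory=lambda: {"male": 0.56, "female": 0.44})
    race_mix: dict = field(
        default_factory=lambda: {
            "nh_black": 0.35, "hispanic": 0.24, "nh_other": 0.23, "nh_white": 0.18
        }
    )
    payer_mix: dict = field(
        default_factory=lambda: {
            "commercial": 0.31, "medicaid": 0.25, "self_pay": 0.19, "other": 0.25
        }
    )
    # diagnosis mixture over taxonomy categories inside the default
    # 290–299 primary-case block
    diagnosis_mix: dict = field(
        default_factory=lambda: {
            "depression": 0.25,
            "psychosis": 0.23,
            "substance use": 0.20,
            "bipolar": 0.15,
            "autism": 0.07,
            "other mental health": 0.10,
        }
    )
    ed_fraction: float = 0.72
    suicide_ecode_rate: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.season_sd_f <= 0:
            raise ValueError("season_sd_f must be positive")
        if not np.isfinite(self.lag_weights).all():
            raise ValueError("lag weights must be finite")
        for name, mix in (
            ("sex_mix", self.sex_mix),
            ("race_mix", self.race_mix),
            ("payer_mix", self.payer_mix),
            ("diagnosis_mix", self.diagnosis_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["years"] = list(self.years)
        return doc


def _coverage_dates(years) -> pd.DatetimeIndex:
    """Contiguous daily coverage over the study years (whole calendar
    years, so early-June lag windows reaching into late May are served)."""
    return pd.date_range(dt.date(min(years), 1, 1), dt.date(max(years), 12, 31),
                         freq="D")


def _response(config: SimulationConfig, t) -> np.ndarray:
    return config.response_curvature * (np.asarray(t, dtype=float) - config.response_vertex_f) ** 2


def true_cumulative_log_or(
    config: SimulationConfig, t: float, reference: float
) -> float:
    """The estimand targeted by the case-crossover DLNM under the generator.

    With log-rate containing Σ_l w_l·f(tmin[d−l]), the cumulative lag-0–5
    log-OR for t vs reference is Σ_l w_l·[f(t) − f(reference)].
    """
    w = float(np.sum(config.lag_weights))
    return float(w * (_response(config, t) - _response(config, reference)))


def simulate_temperature(
    config: SimulationConfig, seed: int
) -> CityTemperatureSeries:
    """Generate the citywide daily series (coverage May 20–Aug 31 per year).

    Tmin = centered annual sinusoid + stationary AR(1) Gaussian noise,
    clipped to the configured physical range; the sinusoid's June–August
    mean is removed and the noise variance chosen so the June–August
    moments match (season_mean_f, season_sd_f).  Only the warm season is
    calibrated — winter values exist to keep the series contiguous and
    are not meaningful climatology.  Tmean is Tmin plus a fixed offset;
    the dew point is set to realize a Gaussian RH target.
    """
    rng = np.random.default_rng(seed)
    idx = _coverage_dates(config.years)
    doy = idx.dayofyear.to_numpy().astype(float)
    s = config.seasonal_amplitude_f * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_doy) / 365.25
    )
    jja = np.isin(idx.month, [6, 7, 8])
    s = s - s[jja].mean()
    sine_var = float(np.var(s[jja]))
    # the AR(1) marginal variance absorbs whatever the sinusoid does not;
    # a target SD at or below the sinusoid's own spread gives the
    # deterministic no-noise limit
    noise_sd = np.sqrt(max(config.season_sd_f**2 - sine_var, 0.0))
    n = len(idx)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, noise_sd)
    innov = rng.normal(0.0, noise_sd * np.sqrt(1 - config.ar1_rho**2), size=n - 1)
    for i in range(1, n):
        eps[i] = config.ar1_rho * eps[i - 1] + innov[i - 1]
    tmin = np.clip(config.season_mean_f + s + eps, *config.physical_range_f)
    tmean = tmin + config.tmean_offset_f
    rh = np.clip(rng.normal(config.rh_mean_pct, config.rh_sd_pct, size=n), 5.0, 100.0)
    tdew = dew_point_from_rh(tmean, rh)
    frame = pd.DataFrame(
        {"tmin_f": tmin, "tmean_f": tmean, "rh_pct": rh}, index=idx
    )
    out = CityTemperatureSeries(
        frame, metadata={"generator": "heatlag.simulate", "seed": int(seed)}
    )
    out._tdew = pd.Series(tdew, index=idx)  # used by write_station_csv
    return out


def _draw_codes(rng, category: str, tax: DiagnosisTaxonomy, size: int) -> list[str]:
    """Draw full ICD-9 codes (root.XY) uniformly from a category's prefixes."""
    if category == "other mental health":
        prefixes = ("290", "293", "294")
    else:
        prefixes = tax.prefixes_of(category)
    # keep the generated encounters inside the primary-case code block;
    # categories defined wholly outside it fall back to all prefixes
    in_range = tuple(p for p in prefixes if tax.root_in_range(p))
    prefixes = in_range or prefixes
    picks = rng.integers(0, len(prefixes), size=size)
    digits = rng.integers(0, 10, size=(size, 2))
    codes = []
    for i in range(size):
        stem = prefixes[picks[i]]
        full = (stem + f"{digits[i, 0]}{digits[i, 1]}")[:5]
        codes.append(full[:3] + "." + full[3:] if len(full) > 3 else full)
    return codes


def _choice(rng, mix: dict, size: int) -> np.ndarray:
    keys = list(mix.keys())
    return rng.choice(keys, size=size, p=[mix[k] for k in keys])


def simulate_encounters(
    config: SimulationConfig,
    exposure: CityTemperatureSeries,
    seed: int,
    tax: DiagnosisTaxonomy = DEFAULT_TAXONOMY,
) -> list[EncounterRecord]:
    """Draw the visit-level line list.

    Per age group and June–August day d, the count is Poisson with
    log-rate = log(baseline) + dow + month + year effects
    + s_month·Σ_l w_l·f(tmin[d−l]); each event gets demographics, payer
    and a primary diagnosis code from the configured mixtures.  Events,
    not persons, are simulated: matched sets are built from visit dates,
    so the conditional likelihood is identical under either scheme.
    """
    rng = np.random.default_rng(seed)
    days = exposure.frame.index[
        exposure.frame.index.month.isin([6, 7, 8])
        & exposure.frame.index.year.isin(config.years)
    ]
    tmin = exposure.frame["tmin_f"]
    lag_effect = np.zeros(len(days))
    for l, w in enumerate(config.lag_weights):
        lagged = tmin.reindex(days - pd.Timedelta(days=l)).to_numpy()
        lag_effect += w * _response(config, lagged)
    month_scale = np.array([config.effect_month_scale[m] for m in days.month])
    dow = np.array([config.dow_log_effects[d] for d in days.dayofweek])
    month = np.array([config.month_log_effects[m] for m in days.month])
    year0 = min(config.years)
    yr = config.year_log_slope * (days.year.to_numpy() - year0)
    base_log = dow + month + yr + month_scale * lag_effect
    if base_log.max() > 30:
        raise ValueError("log-rate overflow: implausible simulation config")

    records: list[EncounterRecord] = []
    for group, lo, hi in AGE_GROUPS:
        if group not in config.baseline_daily:
            continue
        rate = config.baseline_daily[group] * np.exp(base_log)
        counts = rng.poisson(rate)
        total = int(counts.sum())
        if total == 0:
            continue
        dates = np.repeat(days.to_numpy(), counts)
        ages = rng.integers(lo, hi + 1, size=total)
        sexes = _choice(rng, config.sex_mix, total)
        races = _choice(rng, config.race_mix, total)
        payers = _choice(rng, config.payer_mix, total)
        cats = _choice(rng, config.diagnosis_mix, total)
        codes = _draw_codes_by_cat(rng, cats, tax)
        settings = np.where(rng.random(total) < config.ed_fraction, "ED", "inpatient")
        suicide = rng.random(total) < config.suicide_ecode_rate
        sui_digit = rng.integers(0, 10, size=total)
        for i in range(total):
            records.append(
                EncounterRecord(
                    admit_date=pd.Timestamp(dates[i]).date(),
                    age_years=int(ages[i]),
                    sex=str(sexes[i]),
                    race_eth=str(races[i]),
                    payer=str(payers[i]),
                    primary_dx=codes[i],
                    ecodes=(f"E95{sui_digit[i]}.0",) if suicide[i] else (),
                    setting=str(settings[i]),
                    scheduled=False,
                )
            )
    records.sort(key=lambda r: (r.admit_date, r.age_years, r.primary_dx))
    return records


def _draw_codes_by_cat(rng, cats: np.ndarray, tax: DiagnosisTaxonomy) -> list[str]:
    codes = [""] * len(cats)
    for cat in np.unique(cats):
        idx = np.flatnonzero(cats == cat)
        drawn = _draw_codes(rng, str(cat), tax, len(idx))
        for j, c in zip(idx, drawn):
            codes[j] = c
    return codes


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus its generating truth."""

    config: SimulationConfig
    seed: int
    exposure: CityTemperatureSeries
    encounters: list[EncounterRecord]

    def true_cumulative_log_or(self, t: float, reference: float) -> float:
        return true_cumulative_log_or(self.config, t, reference)

    def write_truth(self, path) -> None:
        doc = {"seed": self.seed, "config": self.config.to_dict()}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Generate exposure and encounters from one seed (split internally)."""
    ss = np.random.SeedSequence(seed)
    s_temp, s_enc = (int(s) for s in ss.generate_state(2) >> np.uint32(1))
    exposure = simulate_temperature(config, s_temp)
    encounters = simulate_encounters(config, exposure, s_enc)
    return SimulatedStudy(config=config, seed=seed, exposure=exposure, encounters=encounters)


def write_station_csv(
    exposure: CityTemperatureSeries, path, n_stations: int = 4, seed: int = 0,
    jitter_sd_f: float = 0.8,
) -> None:
    """Export the city series as a synthetic multi-station CSV.

    Station-level jitter is centered across stations each day, so
    averaging the stations recovers the city series exactly.
    """
    rng = np.random.default_rng(seed)
    frame = exposure.frame.dropna(subset=["tmin_f"])
    tdew = getattr(exposure, "_tdew", None)
    rows = []
    n_days = len(frame)
    jit = rng.normal(0.0, jitter_sd_f, size=(n_stations, n_days, 3))
    jit -= jit.mean(axis=0, keepdims=True)
    for s in range(n_stations):
        for i, (date, rec) in enumerate(frame.iterrows()):
            td = tdew.loc[date] if tdew is not None else rec["tmean_f"] - 8.0
            tmean = rec["tmean_f"] + jit[s, i, 1]
            rows.append(
                {
                    "station_id": f"SYN{s + 1}",
                    "date": date.date().isoformat(),
                    "tmin_f": round(rec["tmin_f"] + jit[s, i, 0], 4),
                    "tmean_f": round(tmean, 4),
                    "tdew_f": round(min(td + jit[s, i, 2], tmean), 4),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
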