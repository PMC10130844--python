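"""End-to-end orchestration: cohort → strata → fit → curves → results.

One run analyzes each age group (children 6–11, adolescents 12–17, young
adults 18–25) separately: build the time-stratified matched sets, fit the
conditional-logistic DLNM, trace the cumulative exposure–response curve
over the observed warm-season Tmin range, locate the minimum-risk
temperature (MRT), and report the cumulative OR comparing the
warm-season 95th-percentile temperature to the MRT — overall and within
sex, race/ethnicity, payment-source, diagnosis-subcategory and
suicide-flag subgroups (subgroups under the minimum size, 500 by
default, are reported as skipped).  Cochran's Q summarizes heterogeneity
across each stratification variable's subgroup estimates.

Sensitivity variants: (a) RH-adjusted — a linear lag-0 relative-humidity
covariate appended to every design row; (b) month-restricted — strata
rebuilt from July–August cases only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import (
    QUANTILE_RULE,
    CityTemperatureSeries,
    exposure_percentile,
)
from .clogit import FitError, FitResult, fit_conditional_logistic
from .design import StrataLog, Stratum, build_strata
from .dlnm import CrossBasisSpec, SplineSpec
from .effects import (
    ExposureResponseCurve,
    cochran_q,
    cumulative_or,
    mrt_referenced_curve,
)
from .encounters import (
    AGE_GROUPS,
    DEFAULT_TAXONOMY,
    CohortEncounter,
    DiagnosisTaxonomy,
    EncounterRecord,
    apply_cohort_filters,
)

__all__ = ["RunConfig", "ResultsBundle", "run_analysis", "run_sensitivity"]

logger = logging.getLogger("heatlag")

SUBGROUP_VARS = ("sex", "race_eth", "payer", "subcategory", "suicide")
_UNKNOWN = {"unknown"}


@dataclass
class RunConfig:
    """Analysis configuration (defaults mirror the main analysis)."""

    years: tuple[int, int] = (2005, 2011)
    months: frozenset = frozenset({6, 7, 8})
    spline_df: int = 3
    lag_max: int = 5
    elevated_percentile: float = 0.95
    ci_level: float = 0.95
    min_subgroup_n: int = 500
    subgroup_vars: tuple[str, ...] = SUBGROUP_VARS
    mrt_step_f: float = 0.1
    mrt_reference: str = "subgroup"  # "subgroup" | "shared"
    rh_adjust: bool = False
    setting_filter: str | None = None  # None (pooled) | "ED" | "inpatient"
    taxonomy: DiagnosisTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)

    def __post_init__(self) -> None:
        if not set(self.months) <= {6, 7, 8}:
            raise ValueError("analysis months must be a subset of {6, 7, 8}")
        if not 0.0 < self.elevated_percentile < 1.0:
            raise ValueError("elevated_percentile must lie in (0, 1)")
        if self.mrt_reference not in ("subgroup", "shared"):
            raise ValueError("mrt_reference must be 'subgroup' or 'shared'")

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["months"] = sorted(self.months)
        doc["taxonomy"] = {
            "mh_root_range": list(self.taxonomy.mh_root_range),
            "suicide_ecode_prefix": self.taxonomy.suicide_ecode_prefix,
            "subcategories": [name for name, _ in self.taxonomy.subcategory_map],
        }
        return doc


@dataclass
class GroupResult:
    """Everything computed for one age group."""

    age_group: str
    fit: FitResult | None
    curve: ExposureResponseCurve | None
    spec: CrossBasisSpec | None
    n_encounters: int
    strata_log: StrataLog
    error: str | None = None


@dataclass
class ResultsBundle:
    """Tabular results plus per-group artifacts and the run manifest."""

    results: pd.DataFrame
    heterogeneity: pd.DataFrame
    groups: dict
    attrition: dict
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.csv", index=False, float_format="%.6g")
        self.heterogeneity.to_csv(
            out / "heterogeneity.csv", index=False, float_format="%.6g"
        )
        (out / "curves").mkdir(exist_ok=True)
        for name, gr in self.groups.items():
            if gr.curve is not None:
                pd.DataFrame(
                    {
                        "tmin_f": gr.curve.grid,
                        "cum_log_or": gr.curve.cum_log_or,
                        "se": gr.curve.se,
                    }
                ).to_csv(out / "curves" / f"{name}.csv", index=False, float_format="%.8g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        with open(out / "attrition.log", "w") as fh:
            for rule, n in self.attrition.items():
                fh.write(f"{rule}\t{n}\n")


def _append_rh_column(
    strata: list[Stratum], exposure: CityTemperatureSeries
) -> list[Stratum]:
    """Append a linear lag-0 RH covariate to every design row."""
    out = []
    for s in strata:
        dates = [s.case_date, *s.referent_dates]
        rh = exposure.rh([pd.Timestamp(d) for d in dates])
        if np.isnan(rh).any():
            bad = dates[int(np.flatnonzero(np.isnan(rh))[0])]
            raise ValueError(f"RH adjustment requested but RH missing on {bad}")
        rows = np.hstack([s.rows, rh[:, None]])
        informative = bool(np.ptp(rows, axis=0).max() > 0)
        out.append(
            dataclasses.replace(s, rows=rows, informative=informative)
        )
    return out


def _fit_and_summarize(
    strata: list[Stratum],
    spec: CrossBasisSpec,
    t_lo: float,
    t_hi: float,
    t_elev: float,
    config: RunConfig,
    reference: float | None = None,
):
    """Fit one stratum set and return (fit, curve, or, lo, hi)."""
    fit = fit_conditional_logistic(strata)
    if reference is None:
        curve = mrt_referenced_curve(fit, spec, t_lo, t_hi, step=config.mrt_step_f)
    else:
        from .effects import exposure_response_curve

        n = max(int(np.ceil((t_hi - t_lo) / config.mrt_step_f)), 1)
        grid = np.linspace(t_lo, t_hi, n + 1)
        curve = exposure_response_curve(fit, spec, grid, reference=reference)
        curve.mrt = reference
    or_, lo, hi = cumulative_or(curve, t_elev, level=config.ci_level)
    return fit, curve, or_, lo, hi


def _subgroup_levels(strata: list[Stratum], var: str) -> list:
    if var == "suicide":
        return [True]
    levels = sorted({s.labels[var] for s in strata} - _UNKNOWN)
    return levels


def run_analysis(
    exposure: CityTemperatureSeries,
    records: list[EncounterRecord],
    config: RunConfig | None = None,
) -> ResultsBundle:
    """Run the full analysis and return a results bundle.

    Per-subgroup fit failures are reported in the results table without
    aborting the run; schema violations and exposure-coverage shortfalls
    raise.
    """
    config = config or RunConfig()
    kept, attrition = apply_cohort_filters(
        records, config.taxonomy, years=config.years, months=frozenset(config.months)
    )
    if config.setting_filter is not None:
        kept = [e for e in kept if e.record.setting == config.setting_filter]

    # warm-season exposure distribution for the elevated-percentile contrast
    season = exposure.frame.loc[
        exposure.frame.index.month.isin(config.months)
        & exposure.frame.index.year.to_series(index=exposure.frame.index).between(*config.years),
        "tmin_f",
    ].dropna()
    if season.empty:
        raise ValueError("exposure series has no warm-season days in the analysis years")
    t_elev = exposure_percentile(exposure, config.months, config.elevated_percentile)

    rows: list[dict] = []
    qrows: list[dict] = []
    groups: dict[str, GroupResult] = {}
    for group, _, _ in AGE_GROUPS:
        encs = [e for e in kept if e.age_group == group]
        if not encs:
            groups[group] = GroupResult(group, None, None, None, 0, StrataLog(),
                                        error="no encounters")
            continue
        # knots from the age group's analysis sample: Tmin on the unique
        # case and referent days (subgroups share this basis)
        spec, strata, slog, sample = _group_basis_and_strata(encs, exposure, config)
        t_lo, t_hi = float(sample.min()), float(sample.max())
        n_group = len(strata)
        try:
            fit, curve, or_, lo, hi = _fit_and_summarize(
                strata, spec, t_lo, t_hi, t_elev, config
            )
        except FitError as exc:
            logger.warning("age group %s: fit failed: %s", group, exc)
            groups[group] = GroupResult(group, None, None, spec, n_group, slog,
                                        error=str(exc))
            rows.append(_row(group, "overall", "overall", n_group,
                             status=f"fit_failed: {exc}"))
            continue
        groups[group] = GroupResult(group, fit, curve, spec, n_group, slog)
        rows.append(
            _row(group, "overall", "overall", n_group, mrt=curve.mrt,
                 t_elev=t_elev, or_=or_, lo=lo, hi=hi, status="ok")
        )
        # subgroup analyses reuse the age group's basis (and optionally
        # its MRT as a shared reference)
        shared_ref = curve.mrt if config.mrt_reference == "shared" else None
        for var in config.subgroup_vars:
            estimates = []
            for level in _subgroup_levels(strata, var):
                sub = [s for s in strata if s.labels[var] == level]
                label = "suicide" if var == "suicide" else str(level)
                n_sub = len(sub)
                if n_sub < config.min_subgroup_n:
                    rows.append(_row(group, var, label, n_sub,
                                     status=f"skipped: n<{config.min_subgroup_n}"))
                    continue
                try:
                    _, scurve, sor, slo, shi = _fit_and_summarize(
                        sub, spec, t_lo, t_hi, t_elev, config, reference=shared_ref
                    )
                except FitError as exc:
                    logger.warning("subgroup %s/%s=%s: fit failed: %s",
                                   group, var, label, exc)
                    rows.append(_row(group, var, label, n_sub,
                                     status=f"fit_failed: {exc}"))
                    continue
                rows.append(
                    _row(group, var, label, n_sub, mrt=scurve.mrt, t_elev=t_elev,
                         or_=sor, lo=slo, hi=shi, status="ok")
                )
                estimates.append(scurve.at(t_elev))
            if len(estimates) >= 2:
                q, qdf, qp = cochran_q(estimates)
                qrows.append(
                    {"q_group": f"{group}:{var}", "age_group": group,
                     "variable": var, "k": len(estimates), "q": q, "df": qdf, "p": qp}
                )

    results = pd.DataFrame(rows)
    heterogeneity = pd.DataFrame(
        qrows, columns=["q_group", "age_group", "variable", "k", "q", "df", "p"]
    )
    manifest = _manifest(config, groups, attrition, t_elev)
    return ResultsBundle(results, heterogeneity, groups, dict(attrition), manifest)


def _group_basis_and_strata(
    encs: list[CohortEncounter],
    exposure: CityTemperatureSeries,
    config: RunConfig,
):
    from .design import select_referents

    dates = {e.record.admit_date for e in encs}
    all_days = sorted(dates | {r for d in dates for r in select_referents(d)})
    sample = exposure.frame["tmin_f"].reindex(
        pd.DatetimeIndex([pd.Timestamp(d) for d in all_days])
    ).dropna().to_numpy()
    spline = SplineSpec.from_data(sample, df=config.spline_df)
    spec = CrossBasisSpec(spline=spline, lag_min=0, lag_max=config.lag_max)
    strata, slog = build_strata(encs, exposure, spec)
    if slog.n_dropped_gap:
        logger.warning("dropped %d strata touching exposure gaps", slog.n_dropped_gap)
    if config.rh_adjust:
        strata = _append_rh_column(strata, exposure)
    return spec, strata, slog, sample


def _row(group, variable, level, n, *, mrt=np.nan, t_elev=np.nan,
         or_=np.nan, lo=np.nan, hi=np.nan, status="ok") -> dict:
    return {
        "age_group": group,
        "variable": variable,
        "level": level,
        "n": n,
        "mrt_f": mrt,
        "t_elevated_f": t_elev,
        "or": or_,
        "ci_low": lo,
        "ci_high": hi,
        "status": status,
        "q_group": f"{group}:{variable}",
    }


def _manifest(config: RunConfig, groups, attrition, t_elev) -> dict:
    cfg = config.to_dict()
    doc = {
        "package": "heatlag",
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "quantile_rule": QUANTILE_RULE,
        "t_elevated_f": t_elev,
        "attrition": dict(attrition),
        "groups": {
            name: {
                "n_strata": gr.n_encounters,
                "n_dropped_gap": gr.strata_log.n_dropped_gap,
                "n_uninformative": gr.strata_log.n_uninformative,
                "spec": gr.spec.to_dict() if gr.spec else None,
                "converged": gr.fit.converged if gr.fit else None,
                "iterations": gr.fit.iterations if gr.fit else None,
                "mrt_f": gr.curve.mrt if gr.curve else None,
                "error": gr.error,
            }
            for name, gr in groups.items()
        },
    }
    return doc


def run_sensitivity(
    exposure: CityTemperatureSeries,
    records: list[EncounterRecord],
    config: RunConfig | None = None,
    variant: str = "rh",
) -> ResultsBundle:
    """Run a sensitivity variant: ``"rh"`` or ``"jul_aug"``.

    RH-adjusted: a linear lag-0 relative-humidity covariate is appended
    to every design row before fitting.  July–August: strata are rebuilt
    from July and August cases only.  Output schema matches
    :func:`run_analysis`, tagged with the variant in the manifest.
    """
    config = config or RunConfig()
    if variant == "rh":
        varied = dataclasses.replace(config, rh_adjust=True)
    elif variant == "jul_aug":
        varied = dataclasses.replace(config, months=frozenset({7, 8}))
    else:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    bundle = run_analysis(exposure, records, varied)
    bundle.manifest["variant"] = variant
    return bundle
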