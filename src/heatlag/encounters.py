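"""Encounter line list: parsing, cohort filters, and outcome classification.

The cohort is visit-level: warm-season (June–August) emergency-department
visits and unscheduled hospitalizations by 6–25-year-olds whose *primary*
ICD-9 diagnosis falls in the mental-health block (290–299 by default).
Encounters with a mental-health code only in a secondary position are not
cases.  Suicide/self-inflicted injury is flagged from external-cause
E-codes (E95x) and analyzed as its own outcome group, orthogonal to the
diagnosis subcategory.

The subcategory taxonomy (anxiety, bipolar, depression, ...) is data, not
algorithm: a default prefix map is shipped but it is approximate and fully
overrideable via YAML.
"""

from __future__ import annotations

import datetime as dt
import re
from collections import OrderedDict
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "EncounterRecord",
    "DiagnosisTaxonomy",
    "DEFAULT_TAXONOMY",
    "CodeError",
    "classify_encounter",
    "apply_cohort_filters",
    "age_group_of",
    "read_linelist_csv",
    "write_linelist_csv",
]

_ICD9_RE = re.compile(r"^\d{3}(\.\d{1,2})?$")
_ECODE_RE = re.compile(r"^E\d{3}(\.\d)?$")

SEX_LEVELS = {"male", "female", "unknown"}
RACE_LEVELS = {"hispanic", "nh_black", "nh_white", "nh_other", "unknown"}
PAYER_LEVELS = {"commercial", "medicaid", "self_pay", "other"}

#: Age-group boundaries: children / adolescents / young adults.
AGE_GROUPS = (("6-11", 6, 11), ("12-17", 12, 17), ("18-25", 18, 25))

OTHER_MH = "other mental health"


class CodeError(ValueError):
    """A diagnosis code does not match the ICD-9 lexical pattern."""


def _norm_code(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class EncounterRecord:
    """One ED visit or hospitalization."""

    admit_date: dt.date
    age_years: int
    sex: str
    race_eth: str
    payer: str
    primary_dx: str
    ecodes: tuple[str, ...] = ()
    setting: str = "ED"
    scheduled: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if not self.primary_dx:
            raise CodeError("primary diagnosis code is empty")
        if not _ICD9_RE.match(self.primary_dx.strip()):
            raise CodeError(
                f"malformed primary ICD-9 code {self.primary_dx!r} "
                f"(admit {self.admit_date}, age {self.age_years})"
            )
        for ec in self.ecodes:
            if not _ECODE_RE.match(ec.strip().upper()):
                raise CodeError(
                    f"malformed E-code {ec!r} (admit {self.admit_date})"
                )


# Approximate prefix map for the 17 pediatric mental-health subcategories.
# Prefixes are dot-stripped ICD-9 stems matched first-wins in this order.
# Categories whose canonical codes lie outside the default 290–299
# primary-case block (anxiety, ADHD, reaction, ...) are retained so a
# widened root range picks them up; under the default range they can only
# arise if configured otherwise.
_DEFAULT_SUBCATEGORIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("psychosis", ("295", "297", "298")),
    ("bipolar", ("2960", "2961", "2964", "2965", "2966", "2967")),
    ("depression", ("2962", "2963", "3004", "311")),
    ("substance use", ("291", "292", "303", "304", "305")),
    ("autism", ("2990",)),
    ("developmental", ("2998", "2999", "315", "317", "318", "319")),
    ("anxiety", ("3000", "3002", "3003")),
    ("reaction", ("308", "309")),
    ("attachment", ("3138",)),
    ("externalizing", ("312", "313")),
    ("adhd", ("314",)),
    ("eating", ("3071", "3075")),
    ("elimination", ("3076", "3077")),
    ("motor", ("3072",)),
    ("personality", ("301",)),
    ("sexuality", ("302",)),
)


@dataclass
class DiagnosisTaxonomy:
    """Configurable grouping of ICD-9 codes into outcome categories.

    ``mh_root_range`` is the inclusive 3-digit root interval defining a
    primary mental-health case.  ``subcategory_map`` is an ordered list of
    (name, prefixes); classification is first-match-wins in list order,
    with unmatched cases falling into ``"other mental health"``.
    """

    mh_root_range: tuple[int, int] = (290, 299)
    subcategory_map: tuple[tuple[str, tuple[str, ...]], ...] = _DEFAULT_SUBCATEGORIES
    suicide_ecode_prefix: str = "E95"

    def __post_init__(self) -> None:
        lo, hi = self.mh_root_range
        if lo > hi:
            raise ValueError("mh_root_range must be an increasing interval")
        self.subcategory_map = tuple(
            (name, tuple(_norm_code(p) for p in prefixes))
            for name, prefixes in self.subcategory_map
        )

    def root_in_range(self, code: str) -> bool:
        stem = _norm_code(code)[:3]
        if not stem.isdigit():
            return False
        return self.mh_root_range[0] <= int(stem) <= self.mh_root_range[1]

    def category_names(self) -> list[str]:
        return [name for name, _ in self.subcategory_map] + [OTHER_MH]

    def prefixes_of(self, category: str) -> tuple[str, ...]:
        for name, prefixes in self.subcategory_map:
            if name == category:
                return prefixes
        raise KeyError(category)

    def to_yaml(self, path) -> None:
        doc = {
            "mh_root_range": list(self.mh_root_range),
            "suicide_ecode_prefix": self.suicide_ecode_prefix,
            "subcategories": [
                {"name": name, "prefixes": list(prefixes)}
                for name, prefixes in self.subcategory_map
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "DiagnosisTaxonomy":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return DiagnosisTaxonomy(
            mh_root_range=tuple(doc.get("mh_root_range", (290, 299))),
            subcategory_map=tuple(
                (d["name"], tuple(d["prefixes"])) for d in doc["subcategories"]
            ),
            suicide_ecode_prefix=doc.get("suicide_ecode_prefix", "E95"),
        )


DEFAULT_TAXONOMY = DiagnosisTaxonomy()


def classify_encounter(
    rec: EncounterRecord, tax: DiagnosisTaxonomy = DEFAULT_TAXONOMY
) -> tuple[bool, str | None, bool]:
    """Classify one encounter.

    Returns ``(is_case, subcategory, suicide_flag)``: case status is
    decided solely by the primary diagnosis root; the subcategory is the
    first matching prefix group (``"other mental health"`` for unmatched
    cases, ``None`` for non-cases); the suicide flag is set by any E-code
    with the configured prefix and is independent of case status.
    """
    is_case = tax.root_in_range(rec.primary_dx)
    subcategory = None
    if is_case:
        code = _norm_code(rec.primary_dx)
        subcategory = OTHER_MH
        for name, prefixes in tax.subcategory_map:
            if any(code.startswith(p) for p in prefixes):
                subcategory = name
                break
    sui_prefix = _norm_code(tax.suicide_ecode_prefix)
    suicide = any(_norm_code(ec).startswith(sui_prefix) for ec in rec.ecodes)
    return is_case, subcategory, suicide


@dataclass(frozen=True)
class CohortEncounter:
    """An encounter retained by the cohort filters, with derived labels."""

    record: EncounterRecord
    age_group: str
    subcategory: str
    suicide: bool


def age_group_of(age: int) -> str | None:
    for name, lo, hi in AGE_GROUPS:
        if lo <= age <= hi:
            return name
    return None


def apply_cohort_filters(
    records: list[EncounterRecord],
    tax: DiagnosisTaxonomy = DEFAULT_TAXONOMY,
    *,
    years: tuple[int, int] = (2005, 2011),
    months: frozenset[int] = frozenset({6, 7, 8}),
) -> tuple[list[CohortEncounter], "OrderedDict[str, int]"]:
    """Apply the cohort filters and return retained encounters + attrition.

    Filters are applied in a fixed order so attrition logs are comparable
    across runs: calendar window (month/year) → age 6–25 → unscheduled →
    primary mental-health diagnosis.  The attrition dict counts removals
    per rule and satisfies ``len(records) == len(kept) + sum(attrition)``.
    """
    attrition: OrderedDict[str, int] = OrderedDict(
        (k, 0) for k in ("month_year", "age", "scheduled", "diagnosis")
    )
    kept: list[CohortEncounter] = []
    for rec in records:
        d = rec.admit_date
        if d.month not in months or not years[0] <= d.year <= years[1]:
            attrition["month_year"] += 1
            continue
        group = age_group_of(rec.age_years)
        if group is None:
            attrition["age"] += 1
            continue
        if rec.scheduled:
            attrition["scheduled"] += 1
            continue
        is_case, subcat, suicide = classify_encounter(rec, tax)
        if not is_case:
            attrition["diagnosis"] += 1
            continue
        kept.append(CohortEncounter(rec, group, subcat, suicide))
    return kept, attrition


def read_linelist_csv(path) -> list[EncounterRecord]:
    """Read an encounter line list CSV.

    Columns: ``admit_date,age_years,sex,race_eth,payer,primary_dx,ecodes,
    setting,scheduled`` with ``ecodes`` semicolon-separated.
    """
    df = pd.read_csv(path, parse_dates=["admit_date"], dtype={"primary_dx": str})
    records = []
    for row in df.itertuples(index=False):
        ecodes = ()
        raw = getattr(row, "ecodes", "")
        if isinstance(raw, str) and raw.strip():
            ecodes = tuple(c.strip() for c in raw.split(";") if c.strip())
        records.append(
            EncounterRecord(
                admit_date=row.admit_date.date(),
                age_years=int(row.age_years),
                sex=str(row.sex),
                race_eth=str(row.race_eth),
                payer=str(row.payer),
                primary_dx=str(row.primary_dx),
                ecodes=ecodes,
                setting=str(row.setting),
                scheduled=bool(row.scheduled),
            )
        )
    return records


def write_linelist_csv(records: list[EncounterRecord], path) -> None:
    df = pd.DataFrame(
        {
            "admit_date": [r.admit_date.isoformat() for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "race_eth": [r.race_eth for r in records],
            "payer": [r.payer for r in records],
            "primary_dx": [r.primary_dx for r in records],
            "ecodes": [";".join(r.ecodes) for r in records],
            "setting": [r.setting for r in records],
            "scheduled": [r.scheduled for r in records],
        }
    )
    df.to_csv(path, index=False)
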