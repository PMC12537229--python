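"""Ingestion of FAERS-style quarterly ASCII tables.

FAERS (the FDA Adverse Event Reporting System) publishes quarterly file
sets of '$'-delimited ASCII tables keyed by report version (``primaryid``):
DEMO (demographics/administrative), DRUG, REAC (MedDRA-coded reactions)
and THER (therapy dates).  A *case* (``caseid``) may appear as several
report versions; FDA guidance keeps, per case, the version with the latest
``fda_dt`` (receipt date), breaking ties by the highest ``primaryid``.

This module reads the tables, normalises field values (dates, age units,
reporter occupation codes), deduplicates cases by that rule, restricts to a
receipt-date window, selects reports naming the drug of interest as
primary suspect (PS), and assembles the joined analysis dataset.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FaersDate",
    "SchemaError",
    "AnalysisConfig",
    "Dataset",
    "read_table",
    "parse_faers_date",
    "deduplicate",
    "filter_primary_suspect",
    "normalize_age_years",
    "reporter_category",
    "assemble_dataset",
]

#: Columns each table kind must provide (extra columns are preserved but ignored).
REQUIRED_COLUMNS: dict[str, list[str]] = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "drugname", "role_cod"],
    "REAC": ["primaryid", "pt"],
    "THER": ["primaryid", "start_dt"],
}

#: FAERS occupation codes -> reporter categories (Table-1 style).
REPORTER_MAP = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "health_professional",
    "OT": "health_professional",
}

#: Age-unit code -> factor converting the stated magnitude to years.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


class SchemaError(ValueError):
    """A required column is missing from a FAERS table."""


@dataclass(frozen=True, order=True)
class FaersDate:
    """A FAERS date with explicit precision.

    FAERS dates are digit strings of length 8 (YYYYMMDD), 6 (YYYYMM) or 4
    (YYYY).  Coarser-than-day dates are anchored at the first day of their
    period so they can participate in window comparisons.
    """

    date: dt.date | None
    precision: str  # 'day' | 'month' | 'year' | 'missing'

    @property
    def is_day(self) -> bool:
        return self.precision == "day"

    @property
    def is_missing(self) -> bool:
        return self.precision == "missing"


MISSING_DATE = FaersDate(None, "missing")


def parse_faers_date(raw: str | None) -> FaersDate:
    """Parse a FAERS date string into a :class:`FaersDate`.

    8 digits -> day precision, 6 -> month, 4 -> year; empty/NaN -> missing.
    Calendar-invalid digit strings (e.g. Feb 30) become missing with a
    logged warning.  Non-digit non-empty input raises ``ValueError``.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return MISSING_DATE
    s = str(raw).strip()
    if not s:
        return MISSING_DATE
    if not s.isdigit():
        raise ValueError(f"not a FAERS date (digits expected): {raw!r}")
    if len(s) not in (4, 6, 8):
        raise ValueError(f"FAERS date must have 4, 6 or 8 digits: {raw!r}")
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else 1
    day = int(s[6:8]) if len(s) == 8 else 1
    precision = {8: "day", 6: "month", 4: "year"}[len(s)]
    try:
        return FaersDate(dt.date(year, month, day), precision)
    except ValueError:
        logger.warning("invalid calendar date %r treated as missing", raw)
        return MISSING_DATE


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read one '$'-delimited FAERS ASCII table.

    One header line, no quoting; optional gzip (by ``.gz`` suffix).  Field
    values are stripped; empty strings become missing (NaN).  Column names
    are lower-cased.  Raises :class:`SchemaError` if a required column for
    ``schema`` (one of DEMO/DRUG/REAC/THER) is absent.
    """
    schema = schema.upper()
    if schema not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {schema!r}")
    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        engine="python",
        quoting=3,  # QUOTE_NONE: FAERS dialect has no quoting
        skipinitialspace=False,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{schema} table at {path} lacks required column {col!r}")
    obj_cols = df.select_dtypes(include="object").columns
    for c in obj_cols:
        df[c] = df[c].str.strip()
    df = df.replace("", pd.NA).where(df.notna(), pd.NA)
    return df


def _fda_sort_key(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    parsed = out["fda_dt"].map(lambda v: parse_faers_date(v if not pd.isna(v) else None))
    out["_fda_date"] = [p.date if p.date is not None else dt.date.min for p in parsed]
    out["_pid_num"] = pd.to_numeric(out["primaryid"], errors="raise").astype("int64")
    return out


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per case: latest ``fda_dt``, then highest ``primaryid``.

    ``primaryid`` ties are broken numerically (FAERS primaryids are numeric
    strings; lexicographic order would misorder differing lengths).  Output
    is sorted by numeric caseid for determinism.
    """
    if demo.empty:
        return demo.copy()
    keyed = _fda_sort_key(demo)
    keyed["_cid_num"] = pd.to_numeric(keyed["caseid"], errors="raise").astype("int64")
    keyed = keyed.sort_values(["_cid_num", "_fda_date", "_pid_num"], kind="mergesort")
    kept = keyed.groupby("_cid_num", sort=True).tail(1)
    return kept.drop(columns=["_fda_date", "_pid_num", "_cid_num"]).reset_index(drop=True)


def _normalize_name(name: str) -> str:
    return " ".join(str(name).upper().split())


def filter_primary_suspect(
    drugs: pd.DataFrame,
    synonyms: set[str] | frozenset[str],
    roles: set[str] = frozenset({"PS"}),
    substring: bool = False,
) -> set[str]:
    """Primaryids with >=1 drug row in ``roles`` whose name matches a synonym.

    Matching is on upper-cased whitespace-collapsed names; ``substring=True``
    switches from exact equality to containment of any synonym.
    """
    if not synonyms:
        raise ValueError("synonym set must not be empty")
    syn = {_normalize_name(s) for s in synonyms}
    sub = drugs.dropna(subset=["drugname", "role_cod"])
    sub = sub[sub["role_cod"].str.upper().isin({r.upper() for r in roles})]
    names = sub["drugname"].map(_normalize_name)
    if substring:
        mask = names.map(lambda n: any(s in n for s in syn))
    else:
        mask = names.isin(syn)
    return set(sub.loc[mask, "primaryid"])


def normalize_age_years(age, age_cod) -> float | None:
    """Convert a FAERS (age, age_cod) pair to years; None if unusable.

    A missing unit with a numeric age is taken as years (the dominant FAERS
    convention).  Results outside [0, 150] are treated as missing.
    """
    if age is None or pd.isna(age):
        return None
    try:
        magnitude = float(age)
    except (TypeError, ValueError):
        return None
    unit = "YR" if age_cod is None or pd.isna(age_cod) else str(age_cod).strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        return None
    years = magnitude * factor
    if not (0.0 <= years <= 150.0):
        return None
    return years


def reporter_category(occp_cod) -> str:
    if occp_cod is None or pd.isna(occp_cod):
        return "missing"
    return REPORTER_MAP.get(str(occp_cod).strip().upper(), "missing")


@dataclass
class AnalysisConfig:
    """Parameters steering dataset assembly."""

    synonyms: set[str] = field(default_factory=lambda: {"TYRVAYA"})
    roles: set[str] = field(default_factory=lambda: {"PS"})
    substring_match: bool = False
    #: inclusive fda_dt window as YYYYMMDD strings (None = unbounded)
    window_start: str | None = None
    window_end: str | None = None
    country_column: str = "occr_country"


@dataclass
class Dataset:
    """Assembled analysis dataset.

    ``cases`` holds one row per deduplicated in-window case naming the
    target drug as suspect (the CaseReport fields); ``reactions`` holds the
    report-reaction pairs of *all* in-window deduplicated cases, flagged by
    ``is_target`` — disproportionality needs the background too;
    ``therapies`` holds therapy-start rows of target cases.
    """

    cases: pd.DataFrame
    reactions: pd.DataFrame
    therapies: pd.DataFrame
    target_ids: set[str]
    counts: dict[str, int]


def _in_window(d: FaersDate, start: FaersDate | None, end: FaersDate | None) -> bool:
    if d.is_missing:
        return False
    if start is not None and start.date is not None and d.date < start.date:
        return False
    if end is not None and end.date is not None and d.date > end.date:
        return False
    return True


def assemble_dataset(
    demo: pd.DataFrame,
    drugs: pd.DataFrame,
    reactions: pd.DataFrame,
    therapies: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> Dataset:
    """Run the screening pipeline: dedup -> window -> PS filter -> join.

    Returns the target-drug CaseReports plus the full in-window pair table
    (background included) and stage counts for logging.
    """
    config = config or AnalysisConfig()
    counts = {"raw_demo_rows": int(len(demo))}

    deduped = deduplicate(demo)
    counts["dedup_cases"] = int(len(deduped))

    start = parse_faers_date(config.window_start) if config.window_start else None
    end = parse_faers_date(config.window_end) if config.window_end else None
    if start is not None or end is not None:
        fda = deduped["fda_dt"].map(lambda v: parse_faers_date(v if not pd.isna(v) else None))
        mask = [_in_window(d, start, end) for d in fda]
        windowed = deduped[pd.Series(mask, index=deduped.index)].reset_index(drop=True)
    else:
        windowed = deduped
    counts["windowed_cases"] = int(len(windowed))

    kept_ids = set(windowed["primaryid"])
    target_ids = filter_primary_suspect(
        drugs, config.synonyms, config.roles, config.substring_match
    ) & kept_ids
    counts["ps_cases"] = int(len(target_ids))

    reac = reactions.dropna(subset=["pt"]).copy()
    reac["pt"] = reac["pt"].map(lambda s: " ".join(str(s).split()))
    reac = reac[reac["primaryid"].isin(kept_ids)]
    reac = reac.drop_duplicates(subset=["primaryid", "pt"]).reset_index(drop=True)
    reac["is_target"] = reac["primaryid"].isin(target_ids)
    counts["target_pairs"] = int(reac["is_target"].sum())
    counts["total_pairs"] = int(len(reac))

    target_demo = windowed[windowed["primaryid"].isin(target_ids)].copy()
    cases = _build_case_reports(target_demo, config)

    ther = therapies[therapies["primaryid"].isin(target_ids)].copy().reset_index(drop=True)

    for stage, n in counts.items():
        logger.info("pipeline stage %s: %d", stage, n)
    return Dataset(cases=cases, reactions=reac, therapies=ther,
                   target_ids=target_ids, counts=counts)


def _build_case_reports(demo: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for rec in demo.to_dict("records"):
        fda = parse_faers_date(rec.get("fda_dt") if not pd.isna(rec.get("fda_dt")) else None)
        event_raw = rec.get("event_dt")
        event = parse_faers_date(event_raw if event_raw is not None and not pd.isna(event_raw) else None)
        country_val = rec.get(config.country_column, rec.get("country"))
        sex = rec.get("sex")
        rows.append(
            {
                "primaryid": rec["primaryid"],
                "caseid": rec["caseid"],
                "fda_date": fda.date,
                "fda_precision": fda.precision,
                "event_date": event.date,
                "event_precision": event.precision,
                "age_years": normalize_age_years(rec.get("age"), rec.get("age_cod")),
                "sex": str(sex).strip().upper() if sex is not None and not pd.isna(sex) else None,
                "reporter_category": reporter_category(rec.get("occp_cod")),
                "country": country_val if country_val is not None and not pd.isna(country_val) else None,
                "report_year": fda.date.year if fda.date is not None else None,
            }
        )
    cols = [
        "primaryid", "caseid", "fda_date", "fda_precision", "event_date",
        "event_precision", "age_years", "sex", "reporter_category", "country",
        "report_year",
    ]
    return pd.DataFrame(rows, columns=cols)
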