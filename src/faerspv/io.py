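"""Reading, deduplication and cleaning of FAERS-style quarterly ASCII tables.

The public FAERS quarterly extracts ship one "$"-delimited text table per
entity: DEMO (one row per report version), DRUG, REAC, THER, OUTC, INDI
(child tables keyed by ``primaryid``), plus RPSR which is accepted on read
but unused downstream.  This module parses that dialect, collapses report
versions to one row per case, normalises demographics, and applies the
cohort filters used in spontaneous-report signal detection: drug-name
matching restricted to a role code, and a reporter-occupation filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "ther", "outc", "indi")

#: Column-name aliases across FAERS yearly dialects (all lower-cased).
DEFAULT_ALIASES: dict[str, str] = {
    "gndr_cod": "sex",
    "case_id": "caseid",
    "isr": "primaryid",
    "reporter_country": "occr_country",
}

MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid"),
    "drug": ("primaryid", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid",),
    "outc": ("primaryid",),
    "indi": ("primaryid",),
}

ROLE_CODES = ("PS", "SS", "C", "I")

#: Multiplier from the FAERS AGE_COD unit to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_MIN, AGE_MAX = 0.0, 120.0

#: Reporter-occupation codes treated as healthcare professionals.
HP_OCCP_CODES = frozenset({"MD", "PH", "RN", "OT"})

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


class MissingColumnError(ValueError):
    """A mandatory column is absent from an input table."""

    def __init__(self, path: str | Path, table: str, columns: Sequence[str]):
        self.path = str(path)
        self.table = table
        self.columns = list(columns)
        super().__init__(
            f"table {table!r} at {path}: missing mandatory column(s) "
            + ", ".join(repr(c) for c in columns)
        )


@dataclass
class TableReadReport:
    """Row bookkeeping for one parsed table."""

    table: str
    path: str
    n_rows: int
    n_malformed: int
    malformed_lines: list[int] = field(default_factory=list)


@dataclass
class RawQuarter:
    """One quarter's worth of FAERS-style tables, parsed but uncleaned."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    quarter: str = ""
    read_reports: dict[str, TableReadReport] = field(default_factory=dict)
    n_orphans: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _read_dollar_table(
    path: str | Path,
    table: str,
    aliases: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, TableReadReport]:
    """Parse one '$'-delimited table with a header row.

    Rows whose field count differs from the header, or whose mandatory
    fields are blank, are skipped and tallied as malformed.
    """
    alias = dict(DEFAULT_ALIASES)
    if aliases:
        alias.update({k.lower(): v.lower() for k, v in aliases.items()})
    mandatory = MANDATORY_COLUMNS.get(table, ("primaryid",))

    with open(path, encoding="latin-1") as fh:
        header = fh.readline().rstrip("\r\n")
        cols = [alias.get(c.strip().lower(), c.strip().lower()) for c in header.split("$")]
        missing = [m for m in mandatory if m not in cols]
        if missing:
            raise MissingColumnError(path, table, missing)
        rows: list[list[str]] = []
        bad: list[int] = []
        mand_idx = [cols.index(m) for m in mandatory]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != len(cols) or any(not parts[i].strip() for i in mand_idx):
                bad.append(lineno)
                continue
            rows.append([p.strip() for p in parts])

    df = pd.DataFrame(rows, columns=cols, dtype=str) if rows else pd.DataFrame(columns=cols, dtype=str)
    report = TableReadReport(table, str(path), len(df), len(bad), bad)
    if bad:
        logger.warning(
            "%s (%s): skipped %d malformed row(s) at lines %s",
            table.upper(), path, len(bad), bad[:20],
        )
    logger.info("%s (%s): %d rows parsed", table.upper(), path, len(df))
    return df, report


def read_quarter(
    paths: Mapping[str, str | Path],
    quarter_label: str = "",
    aliases: Mapping[str, str] | None = None,
) -> RawQuarter:
    """Read one quarter of FAERS-style tables.

    ``paths`` maps table names (demo/drug/reac/ther/outc/indi, optionally
    rpsr which is ignored) to file locations.  Child-table rows whose
    ``primaryid`` is absent from DEMO are orphans: counted and dropped.
    """
    tables: dict[str, pd.DataFrame] = {}
    reports: dict[str, TableReadReport] = {}
    for name in TABLE_NAMES:
        if name in paths:
            tables[name], reports[name] = _read_dollar_table(paths[name], name, aliases)
        else:
            tables[name] = pd.DataFrame(columns=list(MANDATORY_COLUMNS[name]), dtype=str)

    known = set(tables["demo"]["primaryid"])
    orphans: dict[str, int] = {}
    for name in TABLE_NAMES[1:]:
        df = tables[name]
        if len(df):
            keep = df["primaryid"].isin(known)
            orphans[name] = int((~keep).sum())
            if orphans[name]:
                logger.warning("%s: dropped %d orphan row(s) with unknown primaryid",
                               name.upper(), orphans[name])
            tables[name] = df[keep].reset_index(drop=True)
        else:
            orphans[name] = 0

    return RawQuarter(quarter=quarter_label, read_reports=reports, n_orphans=orphans, **tables)


def pad_partial_date(value: object) -> str | None:
    """Pad YYYY / YYYYMM to the earliest covered day; None if unusable."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s.isdigit():
        return None
    if len(s) == 4:
        s += "0101"
    elif len(s) == 6:
        s += "01"
    return s if len(s) == 8 else None


@dataclass
class DedupResult:
    """Deduplicated multi-quarter report set with restricted child tables."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    n_input_versions: int
    n_removed: int

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def deduplicate(quarters: Iterable[RawQuarter]) -> DedupResult:
    """Collapse report versions to one row per case.

    For duplicate case ids the version with the latest FDA receipt date
    (FDA_DT) survives; on ties the larger ``primaryid`` wins.  Partial
    FDA_DT values are padded to their earliest day for comparison only.
    Child tables are restricted to surviving ``primaryid`` values.
    """
    quarters = list(quarters)
    concat = {
        name: pd.concat([q.table(name) for q in quarters], ignore_index=True)
        if quarters else pd.DataFrame(columns=list(MANDATORY_COLUMNS[name]), dtype=str)
        for name in TABLE_NAMES
    }
    demo = concat["demo"].copy()
    n_in = len(demo)
    if n_in:
        if "fda_dt" not in demo.columns:
            demo["fda_dt"] = ""
        sort_date = demo["fda_dt"].map(pad_partial_date).fillna("00000000")
        sort_pid = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(-1)
        order = pd.DataFrame({"caseid": demo["caseid"], "_dt": sort_date, "_pid": sort_pid})
        idx = order.sort_values(["caseid", "_dt", "_pid"], kind="stable").groupby("caseid").tail(1).index
        demo = demo.loc[idx].sort_index().reset_index(drop=True)
    survivors = set(demo["primaryid"])
    out = {"demo": demo}
    for name in TABLE_NAMES[1:]:
        df = concat[name]
        out[name] = df[df["primaryid"].isin(survivors)].reset_index(drop=True) if len(df) else df
    removed = n_in - len(demo)
    logger.info("deduplication: %d versions in, %d cases out, %d removed", n_in, len(demo), removed)
    return DedupResult(n_input_versions=n_in, n_removed=removed, **out)


def _age_to_years(age: str, unit: str) -> float:
    if not age:
        return float("nan")
    try:
        value = float(age)
    except ValueError:
        return float("nan")
    unit = (unit or "YR").strip().upper()
    if unit not in AGE_UNIT_TO_YEARS:
        logger.warning("unknown age unit code %r; age treated as missing", unit)
        return float("nan")
    return value * AGE_UNIT_TO_YEARS[unit]


def clean_demographics(dedup: DedupResult, age_rule: str = "null_field") -> pd.DataFrame:
    """Build one analysis-ready case record per deduplicated report.

    Ages are converted to years from the FAERS unit code; implausible
    values (outside [0, 120]) are nulled and the record retained by
    default (``age_rule='null_field'``), or the whole record dropped with
    ``age_rule='drop_record'``.  Outcome codes and indication PTs are
    aggregated from OUTC / INDI into sorted ';'-joined strings so the case
    set round-trips losslessly through CSV/parquet.
    """
    if age_rule not in ("null_field", "drop_record"):
        raise ValueError(f"age_rule must be 'null_field' or 'drop_record', got {age_rule!r}")
    demo = dedup.demo.copy()
    for col in ("age", "age_cod", "sex", "occp_cod", "occr_country", "event_dt", "fda_dt"):
        if col not in demo.columns:
            demo[col] = ""
        demo[col] = demo[col].fillna("").astype(str).str.strip()

    age_years = [
        _age_to_years(a, u) for a, u in zip(demo["age"], demo["age_cod"])
    ]
    age_years = pd.Series(age_years, index=demo.index, dtype=float)
    implausible = age_years.notna() & ((age_years < AGE_MIN) | (age_years > AGE_MAX))
    n_implausible = int(implausible.sum())
    if n_implausible:
        logger.info("demographics: %d implausible age(s) (%s)", n_implausible, age_rule)

    cases = pd.DataFrame({
        "primaryid": demo["primaryid"],
        "caseid": demo["caseid"],
        "fda_dt": demo["fda_dt"],
        "event_dt": demo["event_dt"],
        "age_years": age_years.mask(implausible),
        "sex": demo["sex"].str.upper().where(demo["sex"].str.upper().isin(["M", "F"]), ""),
        "occp_cod": demo["occp_cod"].str.upper(),
        "country": demo["occr_country"].str.upper(),
    })
    if age_rule == "drop_record":
        cases = cases[~implausible.values].reset_index(drop=True)

    def _agg_child(df: pd.DataFrame, col: str) -> pd.Series:
        if not len(df) or col not in df.columns:
            return pd.Series(dtype=str)
        s = df[[("primaryid"), col]].dropna()
        s = s[s[col].astype(str).str.strip() != ""]
        return s.groupby("primaryid")[col].apply(
            lambda v: ";".join(sorted(set(x.strip() for x in v)))
        )

    cases["outcome_codes"] = cases["primaryid"].map(
        _agg_child(dedup.outc, "outc_cod")).fillna("")
    cases["indication_pts"] = cases["primaryid"].map(
        _agg_child(dedup.indi, "indi_pt")).fillna("")

    fda_pad = cases["fda_dt"].map(pad_partial_date)
    cases["report_year"] = [s[:4] if s else "" for s in fda_pad.fillna("")]
    cases.attrs["n_implausible_age"] = n_implausible
    cases.attrs["age_rule"] = age_rule
    return cases.reset_index(drop=True)


def select_drug_cohort(
    cases: pd.DataFrame,
    drug: pd.DataFrame,
    name_patterns: Sequence[str],
    role: str = "PS",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict cases to those reporting the target drug in a given role.

    A report enters the cohort iff at least one of its drug mentions
    matches any pattern (case-insensitive substring over DRUGNAME or
    PROD_AI) *and* that same mention carries the requested role code.
    Returns ``(cohort_cases, matching_drug_rows)``; the drug rows carry
    the sequence numbers needed to join therapy dates later.
    """
    if not name_patterns:
        raise ValueError("name_patterns must be non-empty")
    pats = [p.lower() for p in name_patterns]
    d = drug.copy()
    for col in ("drugname", "prod_ai", "role_cod"):
        if col not in d.columns:
            d[col] = ""
        d[col] = d[col].fillna("").astype(str)
    name = d["drugname"].str.lower()
    ai = d["prod_ai"].str.lower()
    hit = pd.Series(False, index=d.index)
    for p in pats:
        hit |= name.str.contains(p, regex=False) | ai.str.contains(p, regex=False)
    hit &= d["role_cod"].str.strip().str.upper() == role.upper()
    matched = d[hit]
    cohort = cases[cases["primaryid"].isin(set(matched["primaryid"]))].reset_index(drop=True)
    logger.info("drug cohort: %d of %d cases match role=%s patterns=%s",
                len(cohort), len(cases), role, list(name_patterns))
    return cohort, matched.reset_index(drop=True)


def filter_healthcare_professional(
    cohort: pd.DataFrame,
    hp_codes: frozenset[str] | set[str] = HP_OCCP_CODES,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep reports submitted by healthcare professionals.

    Reports whose occupation code is outside ``hp_codes`` (consumers,
    lawyers, missing) are dropped.  Returns the filtered cohort and the
    per-code tally of the input, with blanks under ``"missing"``.
    """
    occ = cohort["occp_cod"].fillna("").astype(str).str.strip().str.upper()
    counts = occ.replace("", "missing").value_counts().to_dict()
    kept = cohort[occ.isin(hp_codes)].reset_index(drop=True)
    logger.info("HP filter: kept %d of %d reports (codes kept: %s)",
                len(kept), len(cohort), sorted(hp_codes))
    return kept, {str(k): int(v) for k, v in counts.items()}


def pct_half_up(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage with decimal half-up rounding (printed-table convention)."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def _outcome_category(codes: str) -> str:
    cs = set(codes.split(";")) if codes else set()
    if "DE" in cs:
        return "Death"
    if "LT" in cs:
        return "Life-threatening"
    if "HO" in cs:
        return "Hospitalization"
    return "Other serious events"


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographic summary of a cohort (counts and half-up percentages).

    Mirrors the usual characteristics table of FAERS drug-safety studies:
    sex, age bands (<18 / 18-64 / >=65 / missing), mutually exclusive
    outcome categories (precedence Death > Life-threatening >
    Hospitalization > Other serious events), top reporting country versus
    Others, reporter occupation, and reporting year.  Every characteristic's
    category counts sum to the cohort size.
    """
    if not len(cohort):
        raise ValueError("summarize_cohort: empty cohort")
    n = len(cohort)
    rows: list[tuple[str, str, int]] = []

    sex = cohort["sex"].fillna("").astype(str)
    rows.append(("sex", "Male", int((sex == "M").sum())))
    rows.append(("sex", "Female", int((sex == "F").sum())))
    rows.append(("sex", "Missing", int((~sex.isin(["M", "F"])).sum())))

    age = cohort["age_years"]
    rows.append(("age", "<18", int((age < 18).sum())))
    rows.append(("age", "18-64", int(((age >= 18) & (age < 65)).sum())))
    rows.append(("age", ">=65", int((age >= 65).sum())))
    rows.append(("age", "Missing", int(age.isna().sum())))

    outcome = cohort["outcome_codes"].fillna("").map(_outcome_category)
    for cat in ("Hospitalization", "Death", "Life-threatening", "Other serious events"):
        rows.append(("outcome", cat, int((outcome == cat).sum())))

    country = cohort["country"].fillna("").astype(str).replace("", "missing")
    top = country.value_counts().idxmax()
    rows.append(("country", str(top), int((country == top).sum())))
    rows.append(("country", "Others", int((country != top).sum())))

    occ = cohort["occp_cod"].fillna("").astype(str).replace("", "missing")
    for code, cnt in occ.value_counts().items():
        rows.append(("occupation", str(code), int(cnt)))

    year = cohort["report_year"].fillna("").astype(str).replace("", "missing")
    for y, cnt in sorted(year.value_counts().items()):
        rows.append(("year", str(y), int(cnt)))

    out = pd.DataFrame(rows, columns=["characteristic", "category", "count"])
    out["pct"] = [pct_half_up(c, n) for c in out["count"]]
    out.attrs["n"] = n
    return out


def write_case_set(cases: pd.DataFrame, parquet_path: str | Path | None = None,
                   csv_path: str | Path | None = None) -> None:
    """Persist the cleaned case set (columnar interchange and/or CSV)."""
    if parquet_path is not None:
        cases.to_parquet(parquet_path, index=False)
    if csv_path is not None:
        cases.to_csv(csv_path, index=False)


def read_case_set(path: str | Path) -> pd.DataFrame:
    """Re-read a case set written by :func:`write_case_set`."""
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    df = pd.read_csv(path, dtype={
        "primaryid": str, "caseid": str, "fda_dt": str, "event_dt": str,
        "sex": str, "occp_cod": str, "country": str,
        "outcome_codes": str, "indication_pts": str, "report_year": str,
    }, keep_default_na=False)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    return df
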