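"""Packaged reference fixtures: published summary tables and term maps.

The package ships small structured copies of the published
tralokinumab study tables — report characteristics, SOC-level and
PT-level signal statistics — together with a convenience PT-to-SOC map
and the set of PTs documented on the product label.  The PT-to-SOC map is
a hand-built fixture covering the fixture PTs plus the synthetic
generator's catalog; it is *not* the licensed MedDRA dictionary, which
users must supply for real analyses.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .signals import normalize_pt

#: Cohort size behind the fixture characteristic and signal tables.
FIXTURE_COHORT_SIZE = 1770


def _data(name: str) -> pd.DataFrame:
    with resources.files("faerspv").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


def load_characteristics() -> pd.DataFrame:
    """Characteristics table: characteristic / category / count / pct."""
    return _data("characteristics.csv")


def load_soc_signals() -> pd.DataFrame:
    """SOC-level signal statistics (25 rows)."""
    return _data("soc_signals.csv")


def load_pt_signals() -> pd.DataFrame:
    """PT-level signal statistics (49 rows), with the unexpected flag."""
    return _data("pt_signals.csv")


def load_pt_soc_map() -> dict[str, str]:
    """PT -> primary SOC lookup (normalised keys)."""
    df = _data("pt_soc_map.csv")
    return {normalize_pt(pt): soc for pt, soc in zip(df["pt"], df["soc"])}


def load_label_pts() -> set[str]:
    """PTs documented in the product label (normalised)."""
    df = _data("label_pts.csv")
    return {normalize_pt(p) for p in df["pt"]}


def pt_fixture_pairs() -> pd.DataFrame:
    """Expand the PT signal fixture into a cohort (report, PT) pair table.

    Each fixture row contributes ``cases`` pairs spread over synthetic
    report ids, reproducing the pair counts the grouped-proportion
    comparisons are computed from.  Report ids cycle through the fixture
    cohort so no report carries the same PT twice.
    """
    t3 = load_pt_signals()
    rows = []
    for _, row in t3.iterrows():
        for i in range(int(row["cases"])):
            rows.append({"primaryid": f"F{i % FIXTURE_COHORT_SIZE:05d}",
                         "pt_display": row["pt"], "pt": normalize_pt(row["pt"]),
                         "arm": "target"})
    return pd.DataFrame(rows)


def cohort_from_characteristics(table1: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand the characteristics fixture into an explicit case set.

    Builds one case record per report with marginal counts matching the
    fixture exactly (characteristics are assigned independently, which is
    all a marginal summary can see), so the cohort summariser reproduces
    the printed percentages.
    """
    t1 = table1 if table1 is not None else load_characteristics()

    def counts(char: str) -> list[tuple[str, int]]:
        sub = t1[t1["characteristic"] == char]
        return list(zip(sub["category"], sub["count"].astype(int)))

    n = int(t1.loc[t1["characteristic"] == "total", "count"].iloc[0])

    def expand(pairs: list[tuple[str, int]], mapping: dict[str, object]) -> np.ndarray:
        out: list[object] = []
        for cat, cnt in pairs:
            out.extend([mapping.get(cat, cat)] * cnt)
        if len(out) != n:
            raise ValueError(f"fixture counts sum to {len(out)}, expected {n}")
        return np.array(out, dtype=object)

    sex = expand(counts("sex"), {"Male": "M", "Female": "F", "Missing": ""})
    age = expand(counts("age"),
                 {"<18": 10.0, "18-64": 40.0, ">=65": 72.0, "Missing": np.nan})
    outcome = expand(counts("outcome"), {
        "Hospitalization": "HO", "Death": "DE", "Life-threatening": "LT",
        "Other serious events": "OT",
    })
    country = expand(counts("country"), {"USA": "US", "Others": "GB"})
    occ = expand(counts("occupation"), {"Physician": "MD", "Pharmacist": "PH"})
    year = expand(counts("year"), {})

    return pd.DataFrame({
        "primaryid": [f"T{i:05d}" for i in range(n)],
        "caseid": [f"C{i:05d}" for i in range(n)],
        "fda_dt": [f"{str(y)[:4]}0601" for y in year],
        "event_dt": [""] * n,
        "age_years": age.astype(float),
        "sex": sex,
        "occp_cod": occ,
        "country": country,
        "outcome_codes": outcome,
        "indication_pts": [""] * n,
        "report_year": [str(y)[:4] for y in year],
    })
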