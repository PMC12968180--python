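"""Time-to-onset of adverse events relative to therapy initiation.

Onset is the calendar-day interval from the suspect drug's earliest
therapy start date (THER START_DT) to the report's adverse-event date
(DEMO EVENT_DT), computed per report.  Reports with partial or missing
dates, or with the event preceding the start, are excluded and tallied by
reason.  Summaries are descriptive only: median, quartiles and fixed
reporting-interval bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reporting-interval bins in days: closed on both ends as labelled,
#: the last bin open above 180.
ONSET_BINS: tuple[tuple[str, int, float], ...] = (
    ("0-30", 0, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-180", 91, 180),
    (">180", 181, float("inf")),
)

EXCLUSION_REASONS = ("missing_start", "partial_date", "missing_event", "event_before_start")


@dataclass
class OnsetSummary:
    n: int
    median_days: float
    q1_days: float
    q3_days: float
    bin_props: dict[str, float]
    quartile_method: str = "linear"


def _full_date(value: object) -> pd.Timestamp | None:
    """Parse a strict YYYYMMDD date; anything else is None."""
    s = str(value).strip() if value is not None else ""
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return pd.Timestamp(f"{s[:4]}-{s[4:6]}-{s[6:]}")
    except ValueError:
        return None


def compute_onsets(
    cohort: pd.DataFrame,
    ther: pd.DataFrame,
    drug_mentions: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-report onset days with an exclusion tally.

    ``drug_mentions`` are the matched suspect-drug rows (carrying
    ``drug_seq``); THER rows are joined on (primaryid, dsg_drug_seq) so
    only therapy episodes of the matched drug contribute.  When several
    THER rows exist, the earliest full start date is used.  Exclusion
    reasons: missing_start (no joinable THER row or blank date),
    partial_date (start present but not full YYYYMMDD), missing_event,
    event_before_start.
    """
    ther = ther.copy()
    seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else "drug_seq"
    if "start_dt" not in ther.columns:
        ther["start_dt"] = ""
    dm = drug_mentions[["primaryid", "drug_seq"]].astype(str)
    th = ther[["primaryid", seq_col, "start_dt"]].astype(str).rename(
        columns={seq_col: "drug_seq"})
    joined = dm.merge(th, on=["primaryid", "drug_seq"], how="left")
    joined["start_dt"] = joined["start_dt"].fillna("")

    rows: list[dict] = []
    tally = {r: 0 for r in EXCLUSION_REASONS}
    event_by_id = cohort.set_index("primaryid")["event_dt"]
    for pid, grp in joined.groupby("primaryid", sort=False):
        starts_raw = [s for s in grp["start_dt"] if s and s.strip() and s.strip().lower() != "nan"]
        if not starts_raw:
            tally["missing_start"] += 1
            continue
        starts = [_full_date(s) for s in starts_raw]
        if all(s is None for s in starts):
            tally["partial_date"] += 1
            continue
        start = min(s for s in starts if s is not None)
        event = _full_date(event_by_id.get(pid, ""))
        if event is None:
            tally["missing_event"] += 1
            continue
        days = (event - start).days
        if days < 0:
            tally["event_before_start"] += 1
            continue
        rows.append({"primaryid": pid, "start_dt": start.strftime("%Y%m%d"),
                     "event_dt": event.strftime("%Y%m%d"), "days": int(days)})

    records = pd.DataFrame(rows, columns=["primaryid", "start_dt", "event_dt", "days"])
    n_missing_ther = len(set(cohort["primaryid"]) - set(joined["primaryid"]))
    tally["missing_start"] += n_missing_ther
    logger.info("onset: %d retained, exclusions %s", len(records), tally)
    return records, tally


def summarize_onsets(records: pd.DataFrame, quartile_method: str = "linear") -> OnsetSummary:
    """Median, quartiles and fixed-bin proportions of onset days.

    Quartiles use linear interpolation (the inclusive/Tukey spreadsheet
    convention) by default; any numpy percentile method name is accepted
    and echoed in the summary metadata.
    """
    if not len(records):
        raise ValueError("summarize_onsets: no onset records")
    days = records["days"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(days, [25, 50, 75], method=quartile_method)
    props = {}
    for label, lo, hi in ONSET_BINS:
        props[label] = float(np.mean((days >= lo) & (days <= hi)))
    return OnsetSummary(len(days), float(med), float(q1), float(q3), props, quartile_method)


def onset_summary_frame(summary: OnsetSummary) -> pd.DataFrame:
    """One-row-per-quantity CSV-ready view of an onset summary."""
    rows = [
        ("n", summary.n),
        ("median_days", summary.median_days),
        ("q1_days", summary.q1_days),
        ("q3_days", summary.q3_days),
    ]
    rows += [(f"prop_{label}", p) for label, p in summary.bin_props.items()]
    rows.append(("quartile_method", summary.quartile_method))
    return pd.DataFrame(rows, columns=["quantity", "value"])
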