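"""Between-drug comparison of grouped adverse-event reporting proportions.

Clinically related MedDRA PTs (for example every "injection site ..."
term) are pooled into named groups, counted within each drug's cohort,
and the two reporting proportions are compared with a Pearson chi-square
test on the 2x2 table (Yates-corrected when any expected cell is below
5).  The counting unit follows FAERS-study practice: the numerator sums
unique (report, PT) pairs matching the group while the denominator is
the cohort's report count; a report-based numerator is also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .signals import normalize_pt


@dataclass(frozen=True)
class EventGroup:
    """A named set of PTs, by exact member or trailing-``*`` prefix pattern."""

    name: str
    members: frozenset[str] = frozenset()
    patterns: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.members and not self.patterns:
            raise ValueError(f"event group {self.name!r} needs members or patterns")
        object.__setattr__(self, "members", frozenset(normalize_pt(m) for m in self.members))
        object.__setattr__(
            self, "patterns", tuple(normalize_pt(p.rstrip("*")) for p in self.patterns)
        )

    def matches(self, pt: str) -> bool:
        key = normalize_pt(pt)
        return key in self.members or any(key.startswith(p) for p in self.patterns)


def default_groups() -> list[EventGroup]:
    """The grouped AEs typically compared between atopic-dermatitis biologics."""
    return [
        EventGroup("injection site reactions", patterns=("injection site*",)),
        EventGroup("conjunctivitis", members=frozenset({"conjunctivitis", "conjunctivitis allergic"})),
        EventGroup("keratitis", members=frozenset({"keratitis"})),
    ]


@dataclass
class GroupCount:
    group_name: str
    x_pairs: int
    x_reports: int
    n: int


@dataclass
class ComparisonResult:
    group_name: str
    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    chi2: float
    p_value: float
    yates: bool = False
    degenerate: bool = False


def count_group(pairs: pd.DataFrame, n_reports: int, group: EventGroup) -> GroupCount:
    """Count group matches in one cohort's (report, PT) pair table.

    ``x_pairs`` sums matching unique pairs; ``x_reports`` counts reports
    with at least one match; ``n`` is the cohort's report count.
    """
    hit = pairs["pt"].map(group.matches)
    matched = pairs[hit]
    return GroupCount(group.name, int(len(matched)),
                      int(matched["primaryid"].nunique()), int(n_reports))


def compare(x1: int, n1: int, x2: int, n2: int, group_name: str = "") -> ComparisonResult:
    """Chi-square comparison of two reporting proportions.

    Builds the 2x2 table (x1, n1-x1; x2, n2-x2) and applies the Pearson
    statistic, Yates-corrected when any expected cell is below 5.
    Degenerate margins (no events in either cohort, or events in every
    report of both) yield chi2 = 0, p = 1, flagged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sizes must be positive")
    if x1 > n1 or x2 > n2:
        raise ValueError("group count cannot exceed cohort size")
    p1, p2 = x1 / n1, x2 / n2
    col1, col2 = x1 + x2, (n1 - x1) + (n2 - x2)
    if col1 == 0 or col2 == 0:
        return ComparisonResult(group_name, x1, n1, x2, n2, p1, p2, 0.0, 1.0,
                                degenerate=True)
    n = n1 + n2
    obs = [(x1, n1 - x1), (x2, n2 - x2)]
    expected = [(n1 * col1 / n, n1 * col2 / n), (n2 * col1 / n, n2 * col2 / n)]
    yates = any(e < 5 for row in expected for e in row)
    chi2 = 0.0
    for orow, erow in zip(obs, expected):
        for o, e in zip(orow, erow):
            diff = abs(o - e)
            if yates:
                diff = max(diff - 0.5, 0.0)
            chi2 += diff * diff / e
    p_value = float(stats.chi2.sf(chi2, df=1))
    return ComparisonResult(group_name, x1, n1, x2, n2, p1, p2, float(chi2),
                            p_value, yates=yates)


def compare_cohorts(
    pairs1: pd.DataFrame, n1: int,
    pairs2: pd.DataFrame, n2: int,
    groups: list[EventGroup] | None = None,
    unit: str = "pairs",
) -> pd.DataFrame:
    """Run the grouped comparison for every configured event group."""
    groups = groups if groups is not None else default_groups()
    rows = []
    for g in groups:
        c1 = count_group(pairs1, n1, g)
        c2 = count_group(pairs2, n2, g)
        x1 = c1.x_pairs if unit == "pairs" else c1.x_reports
        x2 = c2.x_pairs if unit == "pairs" else c2.x_reports
        r = compare(x1, n1, x2, n2, group_name=g.name)
        rows.append({
            "group": g.name, "x1": r.x1, "n1": r.n1, "x2": r.x2, "n2": r.n2,
            "p1": r.p1, "p2": r.p2, "chi2": r.chi2, "p_value": r.p_value,
            "yates": r.yates, "degenerate": r.degenerate,
        })
    return pd.DataFrame(rows)
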