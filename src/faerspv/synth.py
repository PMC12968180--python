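"""Synthetic FAERS-style quarterly data with known ground truth.

The generator emits DEMO/DRUG/REAC/THER/OUTC/INDI tables in the public
"$"-delimited dialect so every pipeline stage — parsing, deduplication,
demographic cleaning, cohort selection, disproportionality statistics and
time-to-onset — can be exercised and validated at desk scale without any
download.  Reports are split into a target-drug arm and a background arm;
event PTs are drawn per report from a catalog of background reporting
probabilities, multiplied by a per-PT relative risk in the target arm, so
the reporting odds ratio of a spiked PT converges to its configured RR.
Duplicate case versions, missing and implausible ages, mixed reporter
occupations, partial dates and negative onsets are injected at
configurable rates to exercise every cleaning and exclusion path.

Default rates mirror the structure of the tralokinumab report cohort:
~62/37 female/male split, ~18% missing age, onset days log-normal with
median 37 and quartiles near 13 and 111.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RawQuarter

TARGET_NAME_VARIANTS = ("Tralokinumab", "TRALOKINUMAB", "ADBRY", "Adbry")
TARGET_AI = "TRALOKINUMAB"

BACKGROUND_DRUGS = (
    ("DUPIXENT", "DUPILUMAB"),
    ("METHOTREXATE", "METHOTREXATE"),
    ("PREDNISONE", "PREDNISONE"),
    ("HUMIRA", "ADALIMUMAB"),
    ("IBUPROFEN", "IBUPROFEN"),
    ("LIPITOR", "ATORVASTATIN"),
    ("OTEZLA", "APREMILAST"),
    ("XELJANZ", "TOFACITINIB"),
)

#: (pt, primary soc, background per-report reporting probability)
DEFAULT_PT_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("rash", "Skin and subcutaneous tissue disorders", 0.030),
    ("pruritus", "Skin and subcutaneous tissue disorders", 0.020),
    ("alopecia", "Skin and subcutaneous tissue disorders", 0.006),
    ("dry skin", "Skin and subcutaneous tissue disorders", 0.008),
    ("injection site erythema", "General disorders and administration site conditions", 0.008),
    ("fatigue", "General disorders and administration site conditions", 0.050),
    ("conjunctivitis", "Infections and infestations", 0.004),
    ("eczema herpeticum", "Infections and infestations", 0.0006),
    ("dry eye", "Eye disorders", 0.004),
    ("keratitis", "Eye disorders", 0.001),
    ("headache", "Nervous system disorders", 0.050),
    ("nausea", "Gastrointestinal disorders", 0.040),
    ("arthralgia", "Musculoskeletal and connective tissue disorders", 0.030),
    ("cough", "Respiratory, thoracic, and mediastinal disorders", 0.020),
)

_PROB_FIELDS = (
    "duplicate_rate", "target_drug_share", "hp_reporter_prob", "missing_age_prob",
    "implausible_age_prob", "negative_onset_prob", "missing_start_prob",
    "partial_date_prob",
)


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the study-scale conditions."""

    n_cases: int = 5000
    n_quarters: int = 4
    start_year: int = 2022
    duplicate_rate: float = 0.08
    target_drug_share: float = 0.05
    pt_catalog: tuple[tuple[str, str, float], ...] = DEFAULT_PT_CATALOG
    target_rr: dict[str, float] = field(default_factory=dict)
    events_per_report: float = 1.8
    hp_reporter_prob: float = 0.9
    missing_age_prob: float = 0.18
    implausible_age_prob: float = 0.01
    sex_split: tuple[float, float, float] = (0.371, 0.624, 0.005)  # M, F, missing
    onset_lognormal: tuple[float, float] = (math.log(37.0), 1.6)
    negative_onset_prob: float = 0.03
    missing_start_prob: float = 0.15
    partial_date_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        bad = [f for f in _PROB_FIELDS if not 0.0 <= getattr(self, f) <= 1.0]
        bad += [f"sex_split[{i}]" for i, v in enumerate(self.sex_split) if not 0 <= v <= 1]
        if self.n_cases < 1:
            bad.append("n_cases")
        if self.n_quarters < 1:
            bad.append("n_quarters")
        if any(p <= 0 or p > 1 for _, _, p in self.pt_catalog):
            bad.append("pt_catalog")
        if any(rr <= 0 for rr in self.target_rr.values()):
            bad.append("target_rr")
        if self.events_per_report <= 0:
            bad.append("events_per_report")
        if self.onset_lognormal[1] <= 0:
            bad.append("onset_lognormal")
        if bad:
            raise ValueError("invalid SyntheticConfig field(s): " + ", ".join(bad))

    def pt_soc_map(self) -> dict[str, str]:
        return {pt: soc for pt, soc, _ in self.pt_catalog}


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    canonical: dict[str, str]          # caseid -> surviving primaryid
    is_target: dict[str, bool]         # caseid -> target-arm flag
    target_rr: dict[str, float]
    onset_mu: float
    onset_sigma: float
    n_cases: int
    n_duplicates: int
    n_target: int
    n_hp_target: int
    pt_soc: dict[str, str]


@dataclass
class SyntheticDataset:
    quarters: list[RawQuarter]
    truth: GroundTruth
    config: SyntheticConfig


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one PRNG stream per table so adding a table never perturbs another
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _fmt(dates: np.ndarray) -> np.ndarray:
    """datetime64 array -> YYYYMMDD strings (object dtype)."""
    iso = np.datetime_as_string(dates.astype("datetime64[D]"))
    return np.char.replace(iso, "-", "").astype(object)


def _days(n: np.ndarray | int) -> np.ndarray | np.timedelta64:
    return np.asarray(n).astype("timedelta64[D]") if not np.isscalar(n) else np.timedelta64(n, "D")


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; deterministic given ``config.seed``."""
    config.validate()
    n = config.n_cases
    rng_case = _rng(config.seed, 0)
    rng_demo = _rng(config.seed, 1)
    rng_drug = _rng(config.seed, 2)
    rng_reac = _rng(config.seed, 3)
    rng_ther = _rng(config.seed, 4)
    rng_outc = _rng(config.seed, 5)
    rng_indi = _rng(config.seed, 6)

    # seed-dependent id base, so different seeds yield different caseids
    base = 10_000_000 + int(rng_case.integers(0, 10_000_000))
    caseid = np.array([str(base + i) for i in range(n)])
    quarter_idx = rng_case.integers(0, config.n_quarters, size=n)
    is_target = rng_case.random(n) < config.target_drug_share
    is_dup = rng_case.random(n) < config.duplicate_rate
    dup_same_date = rng_case.random(n) < 0.3

    qyear = config.start_year + quarter_idx // 4
    qmonth = 3 * (quarter_idx % 4) + 1
    qstart = pd.to_datetime(
        {"year": qyear, "month": qmonth, "day": np.ones(n, dtype=int)}
    ).to_numpy()
    qlabels = np.array([f"{y}Q{m // 3 + 1}" for y, m in zip(qyear, qmonth)])

    # --- DEMO -------------------------------------------------------------
    fda1 = qstart + _days(rng_demo.integers(0, 85, size=n))
    fda2 = fda1 + _days(np.where(dup_same_date, 0, 1 + rng_demo.integers(0, 9, size=n)))
    sex = rng_demo.choice(["M", "F", ""], size=n,
                          p=np.array(config.sex_split) / sum(config.sex_split))
    age_years = np.round(rng_demo.uniform(5, 90, size=n), 0)
    age_unit = rng_demo.choice(["YR", "MON", "DEC"], size=n, p=[0.95, 0.03, 0.02])
    age_val = np.select(
        [age_unit == "YR", age_unit == "MON", age_unit == "DEC"],
        [age_years, age_years * 12, age_years / 10.0],
    )
    miss_age = rng_demo.random(n) < config.missing_age_prob
    implaus = (~miss_age) & (rng_demo.random(n) < config.implausible_age_prob)
    age_val = np.where(implaus, 150.0, age_val)
    age_unit = np.where(implaus, "YR", age_unit)
    age_str = np.where(miss_age, "", np.char.mod("%g", age_val))
    age_unit = np.where(miss_age, "", age_unit)

    hp = rng_demo.random(n) < config.hp_reporter_prob
    occ_hp = rng_demo.choice(["MD", "PH", "RN", "OT"], size=n, p=[0.3, 0.4, 0.2, 0.1])
    occ_other = rng_demo.choice(["CN", "LW", ""], size=n, p=[0.8, 0.1, 0.1])
    occp = np.where(hp, occ_hp, occ_other)
    country = rng_demo.choice(["US", "GB", "DE", "JP", "FR"], size=n,
                              p=[0.93, 0.02, 0.02, 0.02, 0.01])

    # --- THER / onset -----------------------------------------------------
    start = qstart + _days(rng_ther.integers(0, 45, size=n))
    raw_days = np.maximum(
        np.round(rng_ther.lognormal(config.onset_lognormal[0],
                                    config.onset_lognormal[1], size=n)), 0
    ).astype(int)
    negative = rng_ther.random(n) < config.negative_onset_prob
    event = start + _days(np.where(negative, -(raw_days + 1), raw_days))
    has_ther = rng_ther.random(n) >= config.missing_start_prob
    partial = has_ther & (rng_ther.random(n) < config.partial_date_prob)
    start_str = _fmt(start)
    start_str = np.where(partial, np.array([s[:6] for s in start_str], dtype=object), start_str)
    event_str = _fmt(event)

    # --- DRUG -------------------------------------------------------------
    tgt_name = rng_drug.choice(TARGET_NAME_VARIANTS, size=n)
    bg_idx = rng_drug.integers(0, len(BACKGROUND_DRUGS), size=n)
    bg_name = np.array([BACKGROUND_DRUGS[i][0] for i in bg_idx])
    bg_ai = np.array([BACKGROUND_DRUGS[i][1] for i in bg_idx])
    ps_name = np.where(is_target, tgt_name, bg_name)
    ps_ai = np.where(is_target, TARGET_AI, bg_ai)
    has_conmed = rng_drug.random(n) < 0.3
    # a few background cases carry the target drug as a concomitant, which
    # the PS-role filter must ignore
    conmed_is_target = (~is_target) & (rng_drug.random(n) < 0.05)
    conmed_name = np.where(conmed_is_target, "Tralokinumab", "CETIRIZINE")
    conmed_ai = np.where(conmed_is_target, TARGET_AI, "CETIRIZINE")
    has_conmed = has_conmed | conmed_is_target

    # --- REAC -------------------------------------------------------------
    pts = np.array([pt for pt, _, _ in config.pt_catalog])
    base_p = np.array([p for _, _, p in config.pt_catalog])
    rr = np.array([config.target_rr.get(pt, 1.0) for pt in pts])
    w_bg = base_p / base_p.sum()
    w_tg = (base_p * rr) / (base_p * rr).sum()
    k = np.maximum(1, rng_reac.poisson(config.events_per_report, size=n))
    case_rep = np.repeat(np.arange(n), k)
    arm_rep = is_target[case_rep]
    draws = np.empty(case_rep.shape[0], dtype=int)
    draws[arm_rep] = rng_reac.choice(len(pts), size=int(arm_rep.sum()), p=w_tg)
    draws[~arm_rep] = rng_reac.choice(len(pts), size=int((~arm_rep).sum()), p=w_bg)
    pair_key = case_rep * len(pts) + draws
    pair_key = np.unique(pair_key)
    reac_case = pair_key // len(pts)
    reac_pt = pts[pair_key % len(pts)]
    upper_mask = rng_reac.random(len(reac_pt)) < 0.3
    reac_pt = np.where(upper_mask, np.char.upper(reac_pt.astype(str)), reac_pt)

    # --- OUTC / INDI ------------------------------------------------------
    outc = rng_outc.choice(["OT", "HO", "DE", "LT", "DS"], size=n,
                           p=[0.925, 0.04, 0.011, 0.004, 0.02])
    indi = rng_indi.choice(["Atopic dermatitis", "Dermatitis", "Asthma"], size=n,
                           p=[0.678, 0.2, 0.122])

    # --- assemble per-version rows ---------------------------------------
    pid1 = np.array([c + "1" for c in caseid])
    pid2 = np.array([c + "2" for c in caseid])

    def demo_rows(pids: np.ndarray, fda: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "primaryid": pids[mask], "caseid": caseid[mask],
            "fda_dt": _fmt(fda)[mask],
            "event_dt": event_str[mask],
            "age": age_str[mask], "age_cod": age_unit[mask], "sex": sex[mask],
            "occp_cod": occp[mask], "occr_country": country[mask],
            "_q": qlabels[mask],
        })

    all_mask = np.ones(n, dtype=bool)
    demo = pd.concat([demo_rows(pid1, fda1, all_mask), demo_rows(pid2, fda2, is_dup)],
                     ignore_index=True)

    def child_concat(build) -> pd.DataFrame:
        return pd.concat([build(pid1, all_mask), build(pid2, is_dup)], ignore_index=True)

    def drug_rows(pids: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
        ps = pd.DataFrame({
            "primaryid": pids[mask], "drug_seq": "1", "role_cod": "PS",
            "drugname": ps_name[mask], "prod_ai": ps_ai[mask], "_q": qlabels[mask],
        })
        cm_mask = mask & has_conmed
        cm = pd.DataFrame({
            "primaryid": pids[cm_mask], "drug_seq": "2", "role_cod": "C",
            "drugname": conmed_name[cm_mask], "prod_ai": conmed_ai[cm_mask],
            "_q": qlabels[cm_mask],
        })
        return pd.concat([ps, cm], ignore_index=True)

    def reac_rows(pids: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
        keep = mask[reac_case]
        return pd.DataFrame({
            "primaryid": pids[reac_case[keep]], "pt": reac_pt[keep],
            "_q": qlabels[reac_case[keep]],
        })

    def ther_rows(pids: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
        m = mask & has_ther
        end = _fmt(start + _days(30))
        return pd.DataFrame({
            "primaryid": pids[m], "dsg_drug_seq": "1",
            "start_dt": start_str[m], "end_dt": end[m], "_q": qlabels[m],
        })

    def outc_rows(pids: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"primaryid": pids[mask], "outc_cod": outc[mask],
                             "_q": qlabels[mask]})

    def indi_rows(pids: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"primaryid": pids[mask], "indi_drug_seq": "1",
                             "indi_pt": indi[mask], "_q": qlabels[mask]})

    tables = {
        "demo": demo,
        "drug": child_concat(drug_rows),
        "reac": child_concat(reac_rows),
        "ther": child_concat(ther_rows),
        "outc": child_concat(outc_rows),
        "indi": child_concat(indi_rows),
    }

    labels = sorted(set(qlabels))
    quarters = []
    for lab in labels:
        parts = {}
        for name, df in tables.items():
            sub = df[df["_q"] == lab].drop(columns="_q").reset_index(drop=True)
            parts[name] = sub
        quarters.append(RawQuarter(quarter=lab, **parts))

    canonical = {c: (p2 if dup else p1)
                 for c, p1, p2, dup in zip(caseid, pid1, pid2, is_dup)}
    truth = GroundTruth(
        canonical=canonical,
        is_target={c: bool(t) for c, t in zip(caseid, is_target)},
        target_rr=dict(config.target_rr),
        onset_mu=config.onset_lognormal[0],
        onset_sigma=config.onset_lognormal[1],
        n_cases=n,
        n_duplicates=int(is_dup.sum()),
        n_target=int(is_target.sum()),
        n_hp_target=int((is_target & hp).sum()),
        pt_soc=config.pt_soc_map(),
    )
    return SyntheticDataset(quarters=quarters, truth=truth, config=config)


def write_files(dataset: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Write each quarter's tables as '$'-delimited text files."""
    outdir = Path(outdir)
    written = []
    for q in dataset.quarters:
        qdir = outdir / q.quarter
        qdir.mkdir(parents=True, exist_ok=True)
        for name in ("demo", "drug", "reac", "ther", "outc", "indi"):
            df = q.table(name)
            path = qdir / f"{name.upper()}{q.quarter}.txt"
            lines = ["$".join(df.columns)]
            for row in df.itertuples(index=False):
                lines.append("$".join(str(v) for v in row))
            path.write_text("\n".join(lines) + "\n")
            written.append(path)
    return written


def quarter_paths(outdir: str | Path, label: str) -> dict[str, Path]:
    """Per-table file locations for one written quarter."""
    qdir = Path(outdir) / label
    return {name: qdir / f"{name.upper()}{label}.txt"
            for name in ("demo", "drug", "reac", "ther", "outc", "indi")}


def truth_check(
    truth: GroundTruth,
    dedup_demo: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Reports deduplication recall (fraction of cases whose surviving
    primaryid is the canonical version) and, when an event-pair table is
    given, the estimated ROR per RR-spiked PT.
    """
    surviving = dict(zip(dedup_demo["caseid"], dedup_demo["primaryid"]))
    hits = sum(1 for c, p in surviving.items() if truth.canonical.get(c) == p)
    report: dict = {
        "dedup_recall": hits / len(surviving) if surviving else float("nan"),
        "n_cases_out": len(surviving),
    }
    if pairs is not None:
        from .signals import contingency, ror
        rr_est = {}
        for pt, true_rr in truth.target_rr.items():
            t = contingency(pairs, pt, level="PT")
            r = ror(t)
            rr_est[pt] = {"true_rr": true_rr, "ror": r.ror,
                          "ci_low": r.ci_low, "ci_high": r.ci_high, "a": t.a}
        report["rr_estimates"] = rr_est
    return report
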