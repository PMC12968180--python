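"""End-to-end analysis orchestration from a single validated config.

``run_pipeline`` drives ingest -> dedup -> clean -> drug/role filter ->
reporter filter -> event pairs -> PT and SOC signal tables -> onset
summary -> optional between-drug comparison, writing CSV outputs, a
markdown report and a JSON run manifest with the row counts at every
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, comparison, io, onset, signals, synth, tables

logger = logging.getLogger(__name__)


class GroupSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    members: list[str] = Field(default_factory=list)
    patterns: list[str] = Field(default_factory=list)


class ThresholdSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_cases: int = 3
    ror_ci_low: float = 1.0
    prr: float = 2.0
    chi2: float = 4.0
    ic025: float = 0.0
    ebgm05: float = 2.0


class SynthSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cases: int = 5000
    n_quarters: int = 4
    start_year: int = 2022
    duplicate_rate: float = 0.08
    target_drug_share: float = 0.05
    target_rr: dict[str, float] = Field(default_factory=dict)
    events_per_report: float = 1.8
    hp_reporter_prob: float = 0.9
    missing_age_prob: float = 0.18
    implausible_age_prob: float = 0.01
    negative_onset_prob: float = 0.03
    missing_start_prob: float = 0.15
    partial_date_prob: float = 0.02


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    quarters: dict[str, dict[str, str]] = Field(default_factory=dict)
    synth: Optional[SynthSpec] = None
    target_patterns: list[str] = ["tralokinumab", "adbry"]
    comparator_patterns: Optional[list[str]] = None
    role: str = "PS"
    hp_codes: list[str] = ["MD", "PH", "RN", "OT"]
    age_rule: str = "null_field"
    counting_unit: str = "pairs"
    mgps_mode: str = "simplified"
    thresholds: ThresholdSpec = ThresholdSpec()
    event_groups: Optional[list[GroupSpec]] = None
    label_pts: Optional[list[str]] = None
    pt_soc_map: Optional[str] = None  # path to a 2-column CSV; packaged map if unset
    outdir: str = "pv_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


@dataclass
class Bundle:
    """All pipeline outputs plus the run manifest."""

    cases: pd.DataFrame
    cohort: pd.DataFrame
    summary: pd.DataFrame
    signals_pt: pd.DataFrame
    signals_soc: pd.DataFrame
    onset_records: pd.DataFrame
    onset_summary: Optional[onset.OnsetSummary]
    comparison: Optional[pd.DataFrame]
    manifest: dict = field(default_factory=dict)


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]


def _load_quarters(cfg: RunConfig) -> tuple[list[io.RawQuarter], synth.GroundTruth | None]:
    if cfg.synth is not None:
        scfg = synth.SyntheticConfig(seed=cfg.seed, **cfg.synth.model_dump())
        ds = synth.generate(scfg)
        return ds.quarters, ds.truth
    if not cfg.quarters:
        raise ValueError("config must provide either input quarters or a synth block")
    return [io.read_quarter(paths, label) for label, paths in sorted(cfg.quarters.items())], None


def _pt_soc_map(cfg: RunConfig) -> dict[str, str]:
    if cfg.pt_soc_map:
        df = pd.read_csv(cfg.pt_soc_map)
        return {signals.normalize_pt(pt): soc for pt, soc in zip(df["pt"], df["soc"])}
    return tables.load_pt_soc_map()


def cohort_event_pairs(
    quarters: list[io.RawQuarter],
    patterns: list[str],
    role: str = "PS",
    hp_codes: set[str] = io.HP_OCCP_CODES,
) -> tuple[pd.DataFrame, int, io.DedupResult]:
    """Dedup -> drug/role filter -> reporter filter -> event pairs.

    The fast path shared by the full pipeline, recovery simulations and
    the acceptance checks: returns the pair table (target = HP-filtered
    cohort, background = all reports without a matching suspect-drug
    mention), the cohort size, and the deduplicated tables.
    """
    dedup = io.deduplicate(quarters)
    cohort, _ = io.select_drug_cohort(dedup.demo, dedup.drug, patterns, role=role)
    all_target = set(cohort["primaryid"])
    cohort, _ = io.filter_healthcare_professional(cohort, hp_codes)
    ids = set(cohort["primaryid"])
    pairs = signals.build_event_pairs(
        dedup.reac[dedup.reac["primaryid"].isin(ids)],
        dedup.reac[~dedup.reac["primaryid"].isin(all_target)],
    )
    return pairs, len(cohort), dedup


def run_pipeline(cfg: RunConfig, write: bool = True) -> Bundle:
    """Execute the full analysis; any stage error aborts naming the stage."""
    manifest: dict = {"version": __version__, "config_hash": _config_hash(cfg),
                      "seed": cfg.seed, "stages": {}}
    stage = "ingest"
    try:
        quarters, _truth = _load_quarters(cfg)
        manifest["stages"]["ingest"] = {
            "n_quarters": len(quarters),
            "demo_rows": int(sum(len(q.demo) for q in quarters)),
        }

        stage = "deduplicate"
        dedup = io.deduplicate(quarters)
        manifest["stages"]["deduplicate"] = {
            "versions_in": dedup.n_input_versions, "cases_out": len(dedup.demo),
            "removed": dedup.n_removed,
        }

        stage = "clean"
        cases = io.clean_demographics(dedup, age_rule=cfg.age_rule)
        manifest["stages"]["clean"] = {
            "cases": len(cases),
            "implausible_ages": cases.attrs.get("n_implausible_age", 0),
        }

        stage = "select_cohort"
        cohort, drug_rows = io.select_drug_cohort(
            cases, dedup.drug, cfg.target_patterns, role=cfg.role)
        all_target_ids = set(cohort["primaryid"])
        manifest["stages"]["select_cohort"] = {"cohort": len(cohort)}

        stage = "hp_filter"
        cohort, occ_counts = io.filter_healthcare_professional(cohort, set(cfg.hp_codes))
        drug_rows = drug_rows[drug_rows["primaryid"].isin(set(cohort["primaryid"]))]
        manifest["stages"]["hp_filter"] = {"cohort": len(cohort), "occp_counts": occ_counts}
        if not len(cohort):
            raise ValueError("empty cohort after filters")

        stage = "summarize"
        summary = io.summarize_cohort(cohort)

        stage = "event_pairs"
        # background excludes every PS target-drug report, filtered or not,
        # so non-HP target reports cannot contaminate the comparator arm
        cohort_ids = set(cohort["primaryid"])
        reac_target = dedup.reac[dedup.reac["primaryid"].isin(cohort_ids)]
        reac_background = dedup.reac[~dedup.reac["primaryid"].isin(all_target_ids)]
        pairs = signals.build_event_pairs(reac_target, reac_background)
        manifest["stages"]["event_pairs"] = {
            "target_pairs": int((pairs["arm"] == "target").sum()),
            "background_pairs": int((pairs["arm"] == "background").sum()),
        }

        stage = "signals"
        thr = signals.SignalThresholds(**cfg.thresholds.model_dump())
        res_pt = signals.compute_signals(pairs, level="PT", unit=cfg.counting_unit,
                                         mgps_mode=cfg.mgps_mode, thresholds=thr,
                                         seed=cfg.seed)
        label_pts = (set(cfg.label_pts) if cfg.label_pts is not None
                     else tables.load_label_pts())
        res_pt = signals.flag_unexpected(res_pt, label_pts)
        soc_pairs = signals.rollup_to_soc(pairs, _pt_soc_map(cfg))
        res_soc = signals.compute_signals(soc_pairs, level="SOC", unit=cfg.counting_unit,
                                          mgps_mode=cfg.mgps_mode, thresholds=thr,
                                          seed=cfg.seed)
        signals_pt = signals.signals_to_frame(res_pt)
        signals_soc = signals.signals_to_frame(res_soc)
        manifest["stages"]["signals"] = {
            "pt_events": len(signals_pt), "soc_events": len(signals_soc),
            "pt_all_four": int(signals_pt["all_four"].sum()) if len(signals_pt) else 0,
        }

        stage = "onset"
        onset_records, tally = onset.compute_onsets(cohort, dedup.ther, drug_rows)
        onset_summary = onset.summarize_onsets(onset_records) if len(onset_records) else None
        manifest["stages"]["onset"] = {"n": len(onset_records), "exclusions": tally}

        stage = "comparison"
        comp = None
        if cfg.comparator_patterns:
            comp_cohort, _ = io.select_drug_cohort(
                cases, dedup.drug, cfg.comparator_patterns, role=cfg.role)
            comp_cohort, _ = io.filter_healthcare_professional(comp_cohort, set(cfg.hp_codes))
            comp_ids = set(comp_cohort["primaryid"])
            pairs1 = pairs[pairs["arm"] == "target"]
            reac_comp = dedup.reac[dedup.reac["primaryid"].isin(comp_ids)]
            if len(comp_cohort) and len(reac_comp):
                pairs2 = signals.build_event_pairs(reac_comp, reac_background)
                pairs2 = pairs2[pairs2["arm"] == "target"]
                groups = ([comparison.EventGroup(g.name, frozenset(g.members), tuple(g.patterns))
                           for g in cfg.event_groups] if cfg.event_groups
                          else comparison.default_groups())
                comp = comparison.compare_cohorts(pairs1, len(cohort),
                                                  pairs2, len(comp_cohort),
                                                  groups, unit=cfg.counting_unit)
                manifest["stages"]["comparison"] = {"groups": len(comp)}
            else:
                manifest["stages"]["comparison"] = "skipped (empty comparator cohort)"
        else:
            manifest["stages"]["comparison"] = "skipped"
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted at stage {stage!r} (counts so far: {manifest['stages']})"
        ) from exc

    bundle = Bundle(cases, cohort, summary, signals_pt, signals_soc,
                    onset_records, onset_summary, comp, manifest)
    if write:
        render_tables(bundle, cfg.outdir)
    return bundle


def _fmt_est_ci(est: float, lo: float, hi: float) -> str:
    return f"{est:.2f} ({lo:.2f} - {hi:.2f})"


def render_tables(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write CSV tables, a markdown report and the JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["summary"] = out / "cohort_summary.csv"
    bundle.summary.to_csv(paths["summary"], index=False)

    for name, df in (("signals_pt", bundle.signals_pt), ("signals_soc", bundle.signals_soc)):
        pretty = df.copy()
        if len(pretty):
            pretty["ROR (95% CI)"] = [
                _fmt_est_ci(r, lo, hi)
                for r, lo, hi in zip(df["ror"], df["ror_low"], df["ror_high"])
            ]
            pretty["MHRA (chi2)"] = [f"{p:.2f} ({c:.2f})" for p, c in zip(df["prr"], df["chi2"])]
            pretty["EBGM (EBGM05)"] = [f"{e:.2f} ({l:.2f})" for e, l in zip(df["ebgm"], df["ebgm05"])]
            pretty["IC (IC025)"] = [f"{i:.2f} ({l:.2f})" for i, l in zip(df["ic"], df["ic025"])]
        paths[name] = out / f"{name}.csv"
        pretty.to_csv(paths[name], index=False)

    paths["onset_records"] = out / "onset_records.csv"
    bundle.onset_records.to_csv(paths["onset_records"], index=False)
    if bundle.onset_summary is not None:
        paths["onset_summary"] = out / "onset_summary.csv"
        onset.onset_summary_frame(bundle.onset_summary).to_csv(paths["onset_summary"], index=False)
    if bundle.comparison is not None:
        paths["comparison"] = out / "comparison.csv"
        bundle.comparison.to_csv(paths["comparison"], index=False)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)

    md = ["# Pharmacovigilance run report", ""]
    md.append(f"Cohort size: {len(bundle.cohort)}")
    md.append(f"PT signals meeting all four criteria: "
              f"{int(bundle.signals_pt['all_four'].sum()) if len(bundle.signals_pt) else 0}")
    if bundle.onset_summary is not None:
        s = bundle.onset_summary
        md.append(f"Onset: n={s.n}, median {s.median_days:.0f} days "
                  f"(IQR {s.q1_days:.0f}-{s.q3_days:.0f})")
    paths["report"] = out / "report.md"
    paths["report"].write_text("\n".join(md) + "\n")
    return paths
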