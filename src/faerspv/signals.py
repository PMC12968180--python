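"""Disproportionality statistics and combined signal criteria.

Spontaneous-report signal detection compares how often a drug-event pair
is reported against its expectation under independence across the whole
database, summarised in a 2x2 contingency table

    ==============  ===========  ============
    .               target event  other events
    target drug          a            b
    other drugs          c            d
    ==============  ===========  ============

Four families of statistics are computed per event, at MedDRA PT or SOC
level:

* ROR    - reporting odds ratio ``ad/bc`` with a 95% Wald interval;
* MHRA   - proportional reporting ratio PRR with a Yates-corrected chi2;
* BCPNN  - Bayesian information component IC = log2 of observed over
  expected joint reporting probability, with a closed-form posterior
  mean/variance and the lower bound IC025 = E(IC) - 2*sqrt(V(IC));
* MGPS   - gamma-Poisson shrinkage.  ``simplified`` mode uses the relative
  report rate a*N/((a+b)(a+c)) with a Wald-style lower bound, matching
  common FAERS-study practice; ``full_eb`` fits DuMouchel's two-component
  gamma mixture prior by maximum marginal likelihood over all event rows
  and reports the posterior geometric mean EBGM and 5th percentile EBGM05.

A pair is a *signal* on the combined criterion when it has at least
``min_cases`` reports and all four per-algorithm thresholds hold
simultaneously (ROR lower CI > 1; PRR >= 2 with chi2 >= 4; IC025 > 0;
EBGM05 > 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile
LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event counts; ``N = a+b+c+d``."""

    a: float
    b: float
    c: float
    d: float
    level: str = "PT"
    event_label: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe +0.5 on every cell (zero-cell policy)."""
        return replace(self, a=self.a + 0.5, b=self.b + 0.5, c=self.c + 0.5, d=self.d + 0.5)

    @property
    def has_zero(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def normalize_pt(pt: str) -> str:
    """Matching key for a MedDRA term: trimmed, lower-cased."""
    return str(pt).strip().lower()


def build_event_pairs(
    target_reac: pd.DataFrame, background_reac: pd.DataFrame
) -> pd.DataFrame:
    """Unique (report, PT) pairs for the target cohort and the background.

    Within-report repeated PTs count once.  The output has columns
    ``primaryid``, ``pt`` (normalised key), ``pt_display`` (trimmed
    original casing) and ``arm`` in {target, background}; the grand total
    of rows is the N used by all four statistics in pair-counting mode.
    """
    if not len(background_reac):
        raise ValueError("background required: cannot build pairs with an empty background")

    def _pairs(df: pd.DataFrame, arm: str) -> pd.DataFrame:
        out = pd.DataFrame({
            "primaryid": df["primaryid"].astype(str),
            "pt_display": df["pt"].astype(str).str.strip(),
        })
        out["pt"] = out["pt_display"].str.lower()
        out = out[out["pt"] != ""]
        out = out.drop_duplicates(["primaryid", "pt"])
        out["arm"] = arm
        return out

    pairs = pd.concat(
        [_pairs(target_reac, "target"), _pairs(background_reac, "background")],
        ignore_index=True,
    )
    return pairs


def rollup_to_soc(pairs: pd.DataFrame, pt_to_soc: Mapping[str, str]) -> pd.DataFrame:
    """Map (report, PT) pairs to (report, SOC) pairs.

    A report contributing several PTs of one SOC counts once at that SOC.
    PTs absent from the map are routed to ``"UNMAPPED"`` and a warning is
    emitted with the distinct unmapped terms.
    """
    lookup = {normalize_pt(k): v for k, v in pt_to_soc.items()}
    out = pairs.copy()
    soc = out["pt"].map(lookup)
    unmapped = sorted(out.loc[soc.isna(), "pt"].unique())
    if unmapped:
        logger.warning("rollup_to_soc: %d unmapped PT(s): %s", len(unmapped), unmapped[:20])
    out["pt_display"] = soc.fillna("UNMAPPED")
    out["pt"] = out["pt_display"].str.lower()
    out = out.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True)
    out.attrs["unmapped_pts"] = unmapped
    return out


def contingency(
    pairs: pd.DataFrame, event_label: str, level: str = "PT", unit: str = "pairs"
) -> ContingencyTable:
    """Build the 2x2 table for one event from an event-pair table.

    ``unit='pairs'`` (default) counts unique report-event pairs, so N is
    the total number of pairs; ``unit='reports'`` counts reports, so N is
    the number of distinct reports.
    """
    key = normalize_pt(event_label)
    is_target = pairs["arm"] == "target"
    is_event = pairs["pt"] == key
    if unit == "pairs":
        a = int((is_target & is_event).sum())
        b = int((is_target & ~is_event).sum())
        c = int((~is_target & is_event).sum())
        d = int((~is_target & ~is_event).sum())
    elif unit == "reports":
        grp = pairs.groupby(["arm", "primaryid"], sort=False)["pt"].agg(lambda s: key in set(s))
        grp = grp.reset_index()
        tgt = grp["arm"] == "target"
        a = int((tgt & grp["pt"]).sum())
        b = int((tgt & ~grp["pt"]).sum())
        c = int((~tgt & grp["pt"]).sum())
        d = int((~tgt & ~grp["pt"]).sum())
    else:
        raise ValueError(f"unit must be 'pairs' or 'reports', got {unit!r}")
    if a + c == 0:
        logger.warning("contingency: event %r absent from pair table", event_label)
    return ContingencyTable(a, b, c, d, level=level, event_label=str(event_label).strip())


# ---------------------------------------------------------------------------
# the four statistics


@dataclass(frozen=True)
class RORResult:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool = False


@dataclass(frozen=True)
class MHRAResult:
    prr: float
    chi2: float
    corrected: bool = False


@dataclass(frozen=True)
class BCPNNPrior:
    """Pseudo-counts of the Bayesian IC formulation (standard defaults)."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("BCPNN prior pseudo-counts must be strictly positive")


@dataclass(frozen=True)
class BCPNNResult:
    e_ic: float
    v_ic: float
    ic025: float
    ic_naive: float


@dataclass(frozen=True)
class MGPSHyperparams:
    """Gamma-mixture prior for the gamma-Poisson shrinker.

    DuMouchel's classic FAERS fit is ``(0.2, 0.1, 2.0, 4.0, 1/3)``.
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    p_mix: float = 1.0 / 3.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes/rates must be strictly positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class MGPSResult:
    ebgm: float
    ebgm05: float
    mode: str
    hyper: MGPSHyperparams | None = None
    converged: bool | None = None


def _wald_se(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def ror(table: ContingencyTable) -> RORResult:
    """Reporting odds ratio ``ad/bc`` with 95% Wald interval.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all
    four cells and the result is flagged ``corrected``.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("ROR undefined: a row margin is zero")
    corrected = table.has_zero
    t = table.corrected() if corrected else table
    est = (t.a * t.d) / (t.b * t.c)
    se = _wald_se(t)
    return RORResult(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), corrected)


def mhra(table: ContingencyTable) -> MHRAResult:
    """PRR plus Yates-corrected chi-square (MHRA comprehensive criterion).

    PRR = [a/(a+b)] / [c/(c+d)].  The chi-square uses the raw counts:
    ``N (|ad-bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)]`` with the continuity
    correction floored at zero.  A zero PRR denominator (c = 0 or an empty
    margin) triggers the +0.5 correction for the PRR only, flagged.
    """
    corrected = table.c == 0 or table.a + table.b == 0 or table.c + table.d == 0
    t = table.corrected() if corrected else table
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))

    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0 or n == 0:
        chi2 = 0.0
    else:
        num = max(abs(a * d - b * c) - n / 2.0, 0.0)
        chi2 = n * num * num / den
    return MHRAResult(prr, chi2, corrected)


def bcpnn(table: ContingencyTable, prior: BCPNNPrior = BCPNNPrior()) -> BCPNNResult:
    """Bayesian information component with exact posterior moments.

    The standard beta pseudo-count formulation: posterior reporting
    probabilities are independent betas, with the joint pseudo-count
    ``gamma`` tuned so the prior IC expectation is near zero.  Because
    ``IC = log2 p11 - log2 p1. - log2 p.1`` is a sum of independent
    log-beta variables, its posterior mean and variance are exact in
    digamma/trigamma functions; the signal bound is
    IC025 = E(IC) - 2*sqrt(V(IC)).  The naive ``log2(aN/((a+b)(a+c)))``
    is returned for diagnostics.
    """
    a, n = table.a, table.n
    row, col = table.a + table.b, table.a + table.c
    if row == 0 or col == 0:
        raise ValueError("BCPNN undefined: empty row or column margin")
    if n <= 0:
        raise ValueError("BCPNN undefined: N must be positive")
    p = prior
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((row + p.alpha1) * (col + p.beta1))
    dg, tg = special.digamma, lambda x: special.polygamma(1, x)
    e_ic = float(
        dg(a + p.gamma11) - dg(n + gamma)
        - dg(row + p.alpha1) + dg(n + p.alpha)
        - dg(col + p.beta1) + dg(n + p.beta)
    ) / LN2
    v_ic = float(
        tg(a + p.gamma11) - tg(n + gamma)
        + tg(row + p.alpha1) - tg(n + p.alpha)
        + tg(col + p.beta1) - tg(n + p.beta)
    ) / (LN2 ** 2)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    ic_naive = math.log2(a * n / (row * col)) if a > 0 else float("-inf")
    return BCPNNResult(e_ic, v_ic, ic025, ic_naive)


# ---------------------------------------------------------------------------
# MGPS


def mgps_simplified(table: ContingencyTable) -> MGPSResult:
    """Relative report rate with a Wald-style lower bound.

    EBGM = aN/((a+b)(a+c)); EBGM05 = exp(ln EBGM - 1.96*sqrt(sum 1/cell)).
    Zero cells trigger the +0.5 correction, as for the ROR.
    """
    t = table.corrected() if table.has_zero else table
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    ebgm05 = ebgm * math.exp(-Z95 * _wald_se(t))
    return MGPSResult(ebgm, ebgm05, "simplified")


def _nb_logpmf(a: float, shape: float, rate: float, e: float) -> float:
    """Log marginal of the count under a Gamma(shape, rate) prior on lambda.

    a | lambda ~ Poisson(lambda * E) integrated over the prior gives a
    negative binomial with r = shape and p = rate/(rate + E).
    """
    return stats.nbinom.logpmf(a, shape, rate / (rate + e))


def _posterior_mix_weight(a: float, e: float, h: MGPSHyperparams) -> float:
    """Posterior probability of the first mixture component given the count."""
    l1 = math.log(h.p_mix) + _nb_logpmf(a, h.alpha1, h.beta1, e)
    l2 = math.log(1 - h.p_mix) + _nb_logpmf(a, h.alpha2, h.beta2, e)
    m = max(l1, l2)
    return math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))


def mgps_posterior(a: float, e: float, h: MGPSHyperparams) -> MGPSResult:
    """Posterior EBGM and EBGM05 for one cell count under fixed hyperparameters.

    The posterior of the relative report rate lambda is a two-component
    gamma mixture ``Q Gamma(alpha1+a, beta1+E) + (1-Q) Gamma(alpha2+a,
    beta2+E)``; EBGM = exp(E[ln lambda]) via digamma, EBGM05 solves the
    mixture CDF at 0.05.
    """
    q = _posterior_mix_weight(a, e, h)
    s1, r1 = h.alpha1 + a, h.beta1 + e
    s2, r2 = h.alpha2 + a, h.beta2 + e
    mean_log = q * (special.digamma(s1) - math.log(r1)) + (1 - q) * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    lo = min(stats.gamma.ppf(0.05, s1, scale=1 / r1), stats.gamma.ppf(0.05, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(0.05, s1, scale=1 / r1), stats.gamma.ppf(0.05, s2, scale=1 / r2))
    if hi <= lo:
        ebgm05 = lo
    else:
        ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo * (1 - 1e-9), hi * (1 + 1e-9),
                                 xtol=1e-12, rtol=1e-12)
    return MGPSResult(ebgm, ebgm05, "full_eb", hyper=h)


def _neg_marginal_loglik(theta: np.ndarray, counts: np.ndarray, expected: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    p = special.expit(theta[4])
    l1 = np.log(p) + stats.nbinom.logpmf(counts, a1, b1 / (b1 + expected))
    l2 = np.log1p(-p) + stats.nbinom.logpmf(counts, a2, b2 / (b2 + expected))
    return -float(np.sum(np.logaddexp(l1, l2)))


class MGPSConvergenceError(RuntimeError):
    """Hyperparameter optimisation failed; carries the best point found."""

    def __init__(self, best: MGPSHyperparams, loglik_trace: list[float]):
        self.best = best
        self.loglik_trace = loglik_trace
        super().__init__(f"MGPS hyperparameter fit did not converge (best={best})")


def fit_mgps_hyperparams(
    tables: Sequence[ContingencyTable], seed: int = 0, tol: float = 1e-8
) -> tuple[MGPSHyperparams, bool]:
    """Maximum marginal likelihood fit of the gamma-mixture prior.

    Jointly over all (event, table) rows: derivative-free Nelder-Mead
    polishing followed by L-BFGS-B on log/logit-transformed parameters,
    multi-started from DuMouchel's classic point plus seeded jitter.
    """
    counts = np.array([t.a for t in tables], dtype=float)
    expected = np.array([t.expected for t in tables], dtype=float)
    rng = np.random.default_rng(seed)
    classic = MGPSHyperparams()
    start0 = np.array([
        math.log(classic.alpha1), math.log(classic.beta1),
        math.log(classic.alpha2), math.log(classic.beta2),
        special.logit(classic.p_mix),
    ])
    starts = [start0] + [start0 + rng.normal(0, 0.5, size=5) for _ in range(2)]

    trace: list[float] = []
    best_x, best_f = None, math.inf
    for x0 in starts:
        res = optimize.minimize(_neg_marginal_loglik, x0, args=(counts, expected),
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": tol, "maxiter": 4000})
        res = optimize.minimize(_neg_marginal_loglik, res.x, args=(counts, expected),
                                method="L-BFGS-B", options={"ftol": tol})
        trace.append(-res.fun)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    converged = bool(np.isfinite(best_f))
    a1, b1, a2, b2 = np.exp(best_x[:4])
    fitted = MGPSHyperparams(float(a1), float(b1), float(a2), float(b2),
                             float(special.expit(best_x[4])))
    if not converged:
        raise MGPSConvergenceError(fitted, trace)
    return fitted, converged


def mgps(
    table: ContingencyTable,
    mode: str = "simplified",
    hyper: MGPSHyperparams | str | None = None,
    all_tables: Sequence[ContingencyTable] | None = None,
    seed: int = 0,
) -> MGPSResult:
    """Gamma-Poisson shrinker in ``simplified`` or ``full_eb`` mode.

    ``full_eb`` needs either fixed ``hyper`` or, with ``hyper='estimate'``,
    the full set of tables (shrinkage is joint across events).
    """
    if mode == "simplified":
        return mgps_simplified(table)
    if mode != "full_eb":
        raise ValueError(f"mode must be 'simplified' or 'full_eb', got {mode!r}")
    converged = None
    if hyper is None or hyper == "estimate":
        if all_tables is None:
            raise ValueError("full_eb with hyper='estimate' requires all_tables")
        hyper, converged = fit_mgps_hyperparams(all_tables, seed=seed)
    res = mgps_posterior(table.a, table.expected, hyper)
    return replace(res, converged=converged)


# ---------------------------------------------------------------------------
# combined criteria


@dataclass(frozen=True)
class SignalThresholds:
    """Combined-criterion thresholds (pharmacovigilance defaults)."""

    min_cases: int = 3
    ror_ci_low: float = 1.0
    prr: float = 2.0
    chi2: float = 4.0
    ic025: float = 0.0
    ebgm05: float = 2.0


@dataclass
class SignalResult:
    event_label: str
    level: str
    a: int
    table: ContingencyTable
    ror_result: RORResult
    mhra_result: MHRAResult
    bcpnn_result: BCPNNResult
    mgps_result: MGPSResult
    flags: dict[str, bool] = field(default_factory=dict)
    expected: bool | None = None


def flags_from_stats(
    a: float,
    ror_ci_low: float,
    prr: float,
    chi2: float,
    ic025: float,
    ebgm05: float,
    thresholds: SignalThresholds = SignalThresholds(),
) -> dict[str, bool]:
    """Per-algorithm and combined flags from the five decision statistics."""
    enough = a >= thresholds.min_cases
    f = {
        "ror": bool(enough and ror_ci_low > thresholds.ror_ci_low),
        "mhra": bool(enough and prr >= thresholds.prr and chi2 >= thresholds.chi2),
        "bcpnn": bool(enough and ic025 > thresholds.ic025),
        "mgps": bool(enough and ebgm05 > thresholds.ebgm05),
    }
    f["all_four"] = all(f.values())
    return f


def evaluate_table(
    table: ContingencyTable,
    prior: BCPNNPrior = BCPNNPrior(),
    mgps_mode: str = "simplified",
    mgps_hyper: MGPSHyperparams | None = None,
    thresholds: SignalThresholds = SignalThresholds(),
) -> SignalResult:
    """All four statistics plus flags for one drug-event table."""
    r = ror(table)
    m = mhra(table)
    b = bcpnn(table, prior)
    if mgps_mode == "full_eb":
        g = mgps_posterior(table.a, table.expected, mgps_hyper or MGPSHyperparams())
    else:
        g = mgps_simplified(table)
    flags = flags_from_stats(table.a, r.ci_low, m.prr, m.chi2, b.ic025, g.ebgm05, thresholds)
    return SignalResult(table.event_label, table.level, int(table.a), table, r, m, b, g, flags)


def compute_signals(
    pairs: pd.DataFrame,
    level: str = "PT",
    unit: str = "pairs",
    prior: BCPNNPrior = BCPNNPrior(),
    mgps_mode: str = "simplified",
    thresholds: SignalThresholds = SignalThresholds(),
    seed: int = 0,
) -> list[SignalResult]:
    """Evaluate every event in a pair table against the combined criteria.

    Events with fewer than ``thresholds.min_cases`` target-cohort cases
    are excluded from the output entirely, mirroring the usual
    minimum-case rule of FAERS studies.
    """
    target = pairs[pairs["arm"] == "target"]
    counts = target.groupby("pt", sort=False).size()
    display = target.drop_duplicates("pt").set_index("pt")["pt_display"]
    events = [e for e in counts.index if counts[e] >= thresholds.min_cases]
    tables = [contingency(pairs, e, level=level, unit=unit) for e in events]

    hyper = None
    if mgps_mode == "full_eb" and tables:
        hyper, _ = fit_mgps_hyperparams(tables, seed=seed)

    results = []
    for e, t in zip(events, tables):
        t = replace(t, event_label=str(display[e]))
        results.append(evaluate_table(t, prior=prior, mgps_mode=mgps_mode,
                                      mgps_hyper=hyper, thresholds=thresholds))
    results.sort(key=lambda r: (-r.a, r.event_label))
    return results


def flag_unexpected(
    results: Iterable[SignalResult], label_pts: Iterable[str]
) -> list[SignalResult]:
    """Mark each signal expected (on the product label) or unexpected."""
    labelled = {normalize_pt(p) for p in label_pts}
    out = []
    for r in results:
        r.expected = normalize_pt(r.event_label) in labelled
        out.append(r)
    return out


def signals_to_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Flatten signal results to the standard output table."""
    rows = []
    for r in results:
        rows.append({
            "event": r.event_label,
            "level": r.level,
            "a": r.a,
            "ror": r.ror_result.ror,
            "ror_low": r.ror_result.ci_low,
            "ror_high": r.ror_result.ci_high,
            "prr": r.mhra_result.prr,
            "chi2": r.mhra_result.chi2,
            "ic": r.bcpnn_result.e_ic,
            "ic025": r.bcpnn_result.ic025,
            "ebgm": r.mgps_result.ebgm,
            "ebgm05": r.mgps_result.ebgm05,
            "flag_ror": r.flags["ror"],
            "flag_mhra": r.flags["mhra"],
            "flag_bcpnn": r.flags["bcpnn"],
            "flag_mgps": r.flags["mgps"],
            "all_four": r.flags["all_four"],
            "expected": r.expected,
        })
    return pd.DataFrame(rows)
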