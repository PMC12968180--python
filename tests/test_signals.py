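import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faerspv import signals, tables
from faerspv.signals import (
    BCPNNPrior, ContingencyTable, SignalThresholds, bcpnn, build_event_pairs,
    contingency, evaluate_table, flag_unexpected, flags_from_stats, mhra,
    mgps_simplified, ror, rollup_to_soc,
)

from conftest import random_tables


def pairs_frame(target, background):
    """Build REAC-like frames and run build_event_pairs."""
    t = pd.DataFrame(target, columns=["primaryid", "pt"])
    b = pd.DataFrame(background, columns=["primaryid", "pt"])
    return build_event_pairs(t, b)


class TestPairsAndTables:
    def test_within_report_pts_count_once(self):
        pairs = pairs_frame([("R1", "rash"), ("R1", "Rash ")], [("R3", "x")])
        assert len(pairs[pairs["arm"] == "target"]) == 1

    def test_total_pair_count(self):
        target = [(f"T{i}", pt) for i in range(3) for pt in ("a", "b")]
        background = [(f"B{i}", "a") for i in range(10)]
        pairs = pairs_frame(target, background)
        assert len(pairs) == 16

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background required"):
            pairs_frame([("R1", "rash")], [])

    def test_contingency_manual_count(self):
        pairs = pairs_frame(
            [("R1", "X"), ("R1", "Y"), ("R2", "X")],
            [("R3", "X"), ("R3", "Y"), ("R4", "Y"), ("R4", "Z")],
        )
        t = contingency(pairs, "X")
        assert (t.a, t.b, t.c, t.d, t.n) == (2, 1, 1, 3, 7)

    def test_event_absent_from_background(self):
        pairs = pairs_frame([("R1", "X")], [("R2", "Y")])
        assert contingency(pairs, "X").c == 0

    def test_report_counting_unit(self):
        pairs = pairs_frame([("R1", "X"), ("R1", "Y"), ("R2", "Y")],
                            [("R3", "X"), ("R4", "Y")])
        t = contingency(pairs, "X", unit="reports")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_brute_force_rebuild_matches(self, rng):
        # independent scan over raw pairs reproduces the cell counts
        ids = rng.integers(0, 40, size=200)
        pts = rng.integers(0, 6, size=200)
        arm = rng.random(200) < 0.3
        target = [(f"T{i}", f"pt{p}") for i, p in zip(ids[arm], pts[arm])]
        background = [(f"B{i}", f"pt{p}") for i, p in zip(ids[~arm], pts[~arm])]
        pairs = pairs_frame(target, background)
        t = contingency(pairs, "pt3")
        tset = set(map(tuple, pd.DataFrame(target).drop_duplicates().values))
        bset = set(map(tuple, pd.DataFrame(background).drop_duplicates().values))
        a = sum(1 for _, p in tset if p == "pt3")
        c = sum(1 for _, p in bset if p == "pt3")
        assert (t.a, t.b, t.c, t.d) == (a, len(tset) - a, c, len(bset) - c)


class TestSOCRollup:
    MAP = {"rash": "SOC skin", "erythema": "SOC skin", "headache": "SOC nervous"}

    def test_same_soc_counts_once(self):
        pairs = pairs_frame([("R1", "rash"), ("R1", "erythema")], [("R2", "rash")])
        soc = rollup_to_soc(pairs, self.MAP)
        assert len(soc[soc["arm"] == "target"]) == 1

    def test_two_socs_two_pairs(self):
        pairs = pairs_frame([("R1", "rash"), ("R1", "headache")], [("R2", "rash")])
        soc = rollup_to_soc(pairs, self.MAP)
        assert len(soc[soc["arm"] == "target"]) == 2

    def test_unmapped_routed_and_reported(self):
        pairs = pairs_frame([("R1", "vertigo")], [("R2", "rash")])
        soc = rollup_to_soc(pairs, self.MAP)
        assert "UNMAPPED" in set(soc["pt_display"])
        assert soc.attrs["unmapped_pts"] == ["vertigo"]


class TestROR:
    def test_hand_value(self):
        r = ror(ContingencyTable(5, 10, 20, 400))
        assert r.ror == pytest.approx(10.0)
        assert r.ci_low < 10.0 < r.ci_high

    def test_symmetry_and_independence(self):
        assert ror(ContingencyTable(1, 1, 1, 1)).ror == pytest.approx(1.0)
        r = ror(ContingencyTable(1, 9, 9, 81))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_zero_cell_correction_flagged(self):
        r = ror(ContingencyTable(3, 10, 0, 400))
        assert r.corrected and math.isfinite(r.ror)

    def test_empty_margin_is_error(self):
        with pytest.raises(ValueError):
            ror(ContingencyTable(0, 0, 5, 5))


class TestMHRA:
    def test_hand_prr(self):
        assert mhra(ContingencyTable(5, 10, 20, 400)).prr == pytest.approx(7.0)

    def test_independence_floors_chi2(self):
        m = mhra(ContingencyTable(1, 9, 9, 81))
        assert m.prr == pytest.approx(1.0)
        assert m.chi2 == 0.0

    def test_yates_chi2_matches_scipy(self):
        for t in (ContingencyTable(5, 10, 20, 400), ContingencyTable(40, 60, 55, 45)):
            expected = stats.chi2_contingency(
                [[t.a, t.b], [t.c, t.d]], correction=True)[0]
            assert mhra(t).chi2 == pytest.approx(expected, abs=1e-10)

    def test_zero_c_correction(self):
        m = mhra(ContingencyTable(4, 10, 0, 400))
        assert m.corrected and math.isfinite(m.prr)


class TestBCPNN:
    def test_independence_gives_zero_naive_ic(self):
        assert bcpnn(ContingencyTable(1, 9, 9, 81)).ic_naive == pytest.approx(0.0)

    def test_naive_ic_hand_value(self):
        b = bcpnn(ContingencyTable(5, 10, 20, 400))
        assert b.ic_naive == pytest.approx(math.log2(5.8), abs=1e-12)

    def test_ic025_below_expectation(self, rng):
        for t in random_tables(rng, 50):
            b = bcpnn(t)
            assert b.ic025 <= b.e_ic and b.v_ic > 0

    def test_monte_carlo_posterior_oracle(self):
        # closed-form IC025 vs the 2.5th percentile of posterior IC draws
        rng = np.random.default_rng(7)
        prior = BCPNNPrior()
        tabs = random_tables(rng, 20, lo=5, hi=60)
        for t in tabs:
            a, n = t.a, t.n
            row, col = t.a + t.b, t.a + t.c
            gamma = prior.gamma11 * (n + prior.alpha) * (n + prior.beta) / (
                (row + prior.alpha1) * (col + prior.beta1))
            m = 1_000_000
            p11 = rng.beta(prior.gamma11 + a, gamma - prior.gamma11 + n - a, size=m)
            p1 = rng.beta(prior.alpha1 + row, prior.alpha - prior.alpha1 + n - row, size=m)
            p2 = rng.beta(prior.beta1 + col, prior.beta - prior.beta1 + n - col, size=m)
            ic_draws = np.log2(p11 / (p1 * p2))
            mc025 = np.percentile(ic_draws, 2.5)
            assert bcpnn(t, prior).ic025 == pytest.approx(mc025, abs=0.1)


class TestOracleEquivalence:
    def test_direct_formula_oracle_on_random_tables(self, rng):
        # independent textbook evaluation of every statistic, 1000 tables
        for t in random_tables(rng, 1000):
            a, b, c, d = t.a, t.b, t.c, t.d
            n = a + b + c + d
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert ror(t).ror == pytest.approx(a * d / (b * c), rel=1e-12)
            assert ror(t).ci_low == pytest.approx(
                math.exp(math.log(a * d / (b * c)) - 1.959963984540054 * se), rel=1e-12)
            assert mhra(t).prr == pytest.approx(
                (a / (a + b)) / (c / (c + d)), rel=1e-12)
            assert mhra(t).chi2 == pytest.approx(
                n * max(abs(a * d - b * c) - n / 2, 0) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d)), rel=1e-12)
            assert bcpnn(t).ic_naive == pytest.approx(
                math.log2(a * n / ((a + b) * (a + c))), rel=1e-12)
            assert mgps_simplified(t).ebgm == pytest.approx(
                a * n / ((a + b) * (a + c)), rel=1e-12)

    def test_ror_dominates_prr_above_one(self, rng):
        for t in random_tables(rng, 200):
            m, r = mhra(t), ror(t)
            if m.prr >= 1.0:
                assert r.ror >= m.prr - 1e-12


class TestCriteria:
    def test_published_soc_row_flags(self):
        # immune-system SOC row: only ROR and BCPNN fire
        f = flags_from_stats(59, 1.11, 1.43, 7.62, 0.13, 1.1)
        assert f == {"ror": True, "mhra": False, "bcpnn": True,
                     "mgps": False, "all_four": False}

    def test_published_skin_soc_row_all_four(self):
        f = flags_from_stats(1141, 7.17, 5.27, 4222.59, 2.29, 4.88)
        assert f["all_four"]

    def test_below_min_cases_never_flags(self):
        f = flags_from_stats(2, 50.0, 50.0, 500.0, 3.0, 20.0)
        assert not any(f.values())

    def test_low_count_events_excluded_entirely(self):
        target = [("R1", "x"), ("R2", "x"), ("R3", "x"), ("R1", "y"), ("R2", "y")]
        background = [(f"B{i}", "z") for i in range(20)] + [("B0", "x")]
        pairs = pairs_frame(target, background)
        res = signals.compute_signals(pairs)
        assert {r.event_label for r in res} == {"x"}  # y has a=2

    def test_flags_monotone_in_a(self):
        # growing a with b,c,d fixed never turns a flag off
        for b, c, d in [(50, 30, 800), (10, 10, 100), (200, 40, 4000)]:
            prev = {k: False for k in ("ror", "mhra", "bcpnn", "mgps")}
            for a in range(3, 120, 4):
                res = evaluate_table(ContingencyTable(a, b, c, d))
                for k, v in prev.items():
                    assert not (v and not res.flags[k]), (a, b, c, d, k)
                prev = {k: res.flags[k] for k in prev}

    def test_independence_limit(self):
        t = ContingencyTable(4, 36, 36, 324)  # aN=(a+b)(a+c) and ad=bc
        assert ror(t).ror == pytest.approx(1.0)
        assert bcpnn(t).ic_naive == pytest.approx(0.0)
        assert mgps_simplified(t).ebgm == pytest.approx(1.0)


class TestExpectedness:
    def test_label_lookup(self):
        res = [evaluate_table(ContingencyTable(5, 10, 20, 400, event_label=e))
               for e in ("Conjunctivitis", "alopecia")]
        out = flag_unexpected(res, ["conjunctivitis", "keratitis"])
        assert out[0].expected is True and out[1].expected is False

    def test_empty_label_list_all_unexpected(self):
        res = [evaluate_table(ContingencyTable(5, 10, 20, 400, event_label="rash"))]
        assert flag_unexpected(res, [])[0].expected is False


class TestFixtureFlags:
    def test_all_published_pt_rows_meet_all_four(self):
        t3 = tables.load_pt_signals()
        flags = [flags_from_stats(r.cases, r.ror_low, r.prr, r.chi2, r.ic025,
                                  r.ebgm05)["all_four"] for r in t3.itertuples()]
        assert all(flags) and len(flags) == 49

    def test_published_soc_rows(self):
        t2 = tables.load_soc_signals()
        flags = [flags_from_stats(r.cases, r.ror_low, r.prr, r.chi2, r.ic025,
                                  r.ebgm05) for r in t2.itertuples()]
        assert sum(f["all_four"] for f in flags) == 2
        any_method = sum(any(f[k] for k in ("ror", "mhra", "bcpnn", "mgps"))
                         for f in flags)
        assert any_method == 4
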