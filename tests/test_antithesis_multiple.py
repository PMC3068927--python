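import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antithesis_cpi import (
    CaseControlSpec,
    CpiSimConfig,
    DrugRoster,
    Table2x2,
    ZMatrix,
    binarize,
    class_enrichment,
    count_pocket,
    prioritize,
    relative_ratio,
    report_rate_test,
    simulate_cpi,
    twodiz,
)
from antithesis_cpi.cpi_data import PocketAnnotation, PocketRecord


def zmat(vals, ids=None, pockets=None):
    vals = np.asarray(vals, dtype=float)
    return ZMatrix(
        drug_ids=ids or [f"D{j}" for j in range(vals.shape[1])],
        pocket_ids=pockets or [f"P{i}" for i in range(vals.shape[0])],
        values=vals,
        missing=np.isnan(vals),
    )


class TestBinarize:
    @pytest.mark.parametrize(
        "z,interactive", [(-0.49, True), (-0.47, False), (-0.48, False)]
    )
    def test_threshold_convention(self, z, interactive):
        b = binarize(zmat([[z, 0.0], [0.0, 0.0]]))
        assert bool(b.values[0, 0] == 1.0) is interactive

    def test_missing_column_stays_missing(self):
        b = binarize(zmat([[np.nan, 1.0], [np.nan, -1.0]]))
        assert b.missing[:, 0].all() and not b.missing[:, 1].any()


class TestCountPocket:
    def test_study_scale_margins(self):
        roles = {f"CASE{i}": "case" for i in range(39)}
        roles.update({f"CTRL{i}": "control" for i in range(15)})
        roster = DrugRoster(roles=roles)
        # 21 of 39 cases and 1 of 15 controls interactive
        row = [-1.0] * 21 + [0.0] * 18 + [-1.0] * 1 + [0.0] * 14
        b = binarize(zmat([row, [0.0] * 54], ids=list(roles)))
        t = count_pocket(b, "P0", roster)
        assert (t.a, t.b, t.c, t.d) == (21, 1, 18, 14)

    def test_missing_reduces_margin(self):
        roster = DrugRoster(
            roles={"A": "case", "B": "case", "C": "case", "X": "control"}
        )
        b = binarize(zmat([[-1.0, np.nan, 0.0, -1.0]], ids=["A", "B", "C", "X"]))
        t = count_pocket(b, "P0", roster)
        assert t.a + t.c == 2

    def test_background_excluded(self, roster):
        ids = ["CASE0", "CASE1", "CASE2", "CTRL0", "CTRL1", "BG0"]
        b = binarize(zmat([[-1.0] * 6], ids=ids))
        t = count_pocket(b, "P0", roster)
        assert t.n == 5

    def test_all_missing_flagged(self, roster):
        ids = ["CASE0", "CASE1", "CASE2", "CTRL0", "CTRL1", "BG0"]
        vals = np.full((1, 6), np.nan)
        vals[0, 5] = -1.0  # only the background drug has a score
        b = binarize(zmat(vals, ids=ids))
        with pytest.raises(ValueError, match="missing"):
            count_pocket(b, "P0", roster)

    def test_unknown_pocket(self, roster):
        b = binarize(zmat([[0.0] * 6, [0.0] * 6],
                          ids=["CASE0", "CASE1", "CASE2", "CTRL0", "CTRL1", "BG0"]))
        with pytest.raises(KeyError):
            count_pocket(b, "NOPE", roster)


class TestRelativeRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((21, 1, 18, 14), 1.697),
            ((24, 2, 15, 13), 1.723),
            ((8, 0, 12, 14), 2.167),
            ((17, 0, 22, 15), 1.682),
        ],
    )
    def test_printed_ratios(self, cells, expected):
        assert round(relative_ratio(Table2x2(*cells)), 3) == expected

    def test_equal_proportions(self):
        assert relative_ratio(Table2x2(3, 5, 3, 5)) == pytest.approx(1.0)

    def test_infinite_when_no_noninteractive_case(self):
        assert relative_ratio(Table2x2(4, 2, 0, 3)) == math.inf

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            relative_ratio(Table2x2(0, 0, 3, 4))

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_interactive_row_swap_reciprocal(self, cells):
        # exchanging the interactive / not-interactive calls inverts RR
        a, b, c, d = cells
        rr = relative_ratio(Table2x2(a, b, c, d))
        rr_swapped = relative_ratio(Table2x2(c, d, a, b))
        assert rr * rr_swapped == pytest.approx(1.0, rel=1e-9)

    def test_b_zero_rows_reduce_to_margin_ratio(self):
        # with b = 0 the ratio collapses to (c+d)/c
        for a, c, d in [(17, 22, 15), (8, 12, 14), (16, 23, 15)]:
            t = Table2x2(a, 0, c, d)
            assert relative_ratio(t) == pytest.approx((c + d) / c)


class TestPrioritize:
    def test_nqo1_row_retained(self):
        roles = {f"CASE{i}": "case" for i in range(39)}
        roles.update({f"CTRL{i}": "control" for i in range(15)})
        roster = DrugRoster(roles=roles)
        row = [-1.0] * 16 + [0.0] * 23 + [0.0] * 15  # (16, 0, 23, 15)
        res = prioritize(zmat([row, [0.0] * 54], ids=list(roles)), roster)
        assert len(res) == 1
        assert round(res[0].p, 3) == 0.002
        assert res[0].counts.a == 16

    def test_all_rr_below_one_empty(self):
        roster = DrugRoster(
            roles={"A": "case", "B": "case", "C": "control", "D": "control"}
        )
        # controls interactive, cases not: RR < 1 everywhere
        res = prioritize(zmat([[0.0, 0.0, -1.0, -1.0]] * 2, ids=list("ABCD")), roster)
        assert res == []

    def test_invariant_to_row_and_column_order(self, rng):
        roles = {f"CASE{i}": "case" for i in range(10)}
        roles.update({f"CTRL{i}": "control" for i in range(5)})
        roster = DrugRoster(roles=roles)
        vals = rng.normal(size=(12, 15)) - 0.3
        ids = list(roles)
        pockets = [f"P{i}" for i in range(12)]
        res1 = prioritize(zmat(vals, ids=ids, pockets=pockets), roster)
        perm_d = rng.permutation(15)
        perm_p = rng.permutation(12)
        res2 = prioritize(
            zmat(
                vals[np.ix_(perm_p, perm_d)],
                ids=[ids[j] for j in perm_d],
                pockets=[pockets[i] for i in perm_p],
            ),
            roster,
        )
        assert [(r.pocket_id, r.p) for r in res1] == [
            (r.pocket_id, r.p) for r in res2
        ]

    def test_planted_mediators_recovered(self):
        recovered = 0
        false_rates = []
        for seed in range(20):
            cfg = CpiSimConfig(
                n_drugs=60, n_pockets=80, missing_rate=0.02,
                case_control=CaseControlSpec(
                    n_cases=30, n_controls=15, n_mediator_pockets=3, boost=-5.0
                ),
                seed=seed,
            )
            m, roster, _, truth = simulate_cpi(cfg)
            res = prioritize(twodiz(m), roster)
            got = {r.pocket_id for r in res}
            recovered += set(truth.mediator_pockets) <= got
            false_rates.append(len(got - set(truth.mediator_pockets)) / 77)
        assert recovered >= 19
        assert np.mean(false_rates) <= 0.05


class TestClassEnrichment:
    @staticmethod
    def annotations(class_members, n):
        return PocketAnnotation(records={
            f"P{i}": PocketRecord(
                f"P{i}", f"X{i}", [f"G{i}"],
                classes=frozenset(["OR"] if i in class_members else []),
            )
            for i in range(n)
        })

    def test_class_equals_universe(self):
        ann = self.annotations(set(range(10)), 10)
        universe = {f"P{i}" for i in range(10)}
        *_, p = class_enrichment({"P0", "P1"}, "OR", ann, universe)
        assert p == 1.0

    def test_matches_enumeration(self):
        from scipy.special import comb

        ann = self.annotations(set(range(5)), 20)
        universe = {f"P{i}" for i in range(20)}
        prioritized = {"P0", "P1", "P2", "P3", "P10", "P11"}  # k=4 of K=5, n=6
        k, n, K, N, p = class_enrichment(prioritized, "OR", ann, universe)
        assert (k, n, K, N) == (4, 6, 5, 20)
        expected = sum(
            comb(5, x, exact=True) * comb(15, 6 - x, exact=True)
            for x in range(4, 6)
        ) / comb(20, 6, exact=True)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_no_members_gives_one(self):
        ann = self.annotations(set(), 10)
        universe = {f"P{i}" for i in range(10)}
        *_, p = class_enrichment({"P0"}, "OR", ann, universe)
        assert p == 1.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            class_enrichment(set(), "OR", self.annotations(set(), 2), set())


class TestReportRateTest:
    def test_printed_rates_and_p(self):
        rate1, rate2, stat, p = report_rate_test(185, 16813, 16, 11304)
        assert round(rate1, 1) == 1.1
        assert round(rate2, 2) == 0.14
        assert float(f"{p:.1e}") == pytest.approx(8.2e-21)

    def test_equal_rates(self):
        _, _, stat, p = report_rate_test(5, 50, 10, 100)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_identical_groups(self):
        *_, stat, _ = report_rate_test(1, 10, 1, 10)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            report_rate_test(0, 0, 1, 10)
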