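import itertools

import numpy as np
import pandas as pd
import pytest

from mafld_traj import pairs


def event_frame(rows):
    """rows: (pid, category, date)"""
    return pd.DataFrame(rows, columns=["participant_id", "category", "date"])


class TestEnumeratePairs:
    def test_three_categories(self):
        assert len(pairs.enumerate_pairs(["A", "B", "C"])) == 6

    def test_stage_one_count(self):
        assert len(pairs.enumerate_pairs([f"C{i}" for i in range(113)])) == 12_656

    def test_degenerate(self):
        assert pairs.enumerate_pairs(["A"]) == []
        assert pairs.enumerate_pairs([]) == []


class TestCooccurrence:
    def test_threshold_arithmetic(self):
        assert pairs.cooccurrence_threshold(1000, 0.005) == 5
        assert pairs.cooccurrence_threshold(163_303, 0.005) == 816

    def test_strictly_greater_boundary(self):
        rows = []
        for i in range(5):  # exactly floor(0.005 * 1000) = 5 holders -> dropped
            rows += [(f"P{i}", "A", "2011-01-01"), (f"P{i}", "B", "2012-01-01")]
        ev = event_frame(rows)
        ids = [f"P{i}" for i in range(1000)]
        out = pairs.run_pair_inference(ev, ids, ["A", "B"], n_exposed=1000)
        assert not out["passes_cooccurrence"].any()
        rows += [("P5", "A", "2011-01-01"), ("P5", "B", "2012-01-01")]
        out = pairs.run_pair_inference(event_frame(rows), ids + ["P5"], ["A", "B"],
                                       n_exposed=1000)
        assert out["passes_cooccurrence"].sum() == 2

    def test_empty_intersection_dropped(self):
        ev = event_frame([("P1", "A", "2011-01-01"), ("P2", "B", "2011-01-01")])
        out = pairs.run_pair_inference(ev, ["P1", "P2"], ["A", "B"], n_exposed=2,
                                       fraction=0.1)
        assert (out["n_both"] == 0).all()


class TestBinomialDirection:
    def test_eight_of_ten(self):
        frac, p = pairs.binomial_direction_test(8, 10, 0)
        assert frac == pytest.approx(0.8)
        assert p == pytest.approx(56 / 1024, abs=1e-12)

    def test_twenty_of_twenty(self):
        _, p = pairs.binomial_direction_test(20, 20, 0)
        assert p == pytest.approx(2.0 ** -20, rel=1e-9)

    def test_majority_rule(self):
        frac, p = pairs.binomial_direction_test(5, 10, 0)
        assert frac == 0.5  # not > 0.5: direction must fail regardless of p

    def test_ties_excluded_from_trials(self):
        frac, p = pairs.binomial_direction_test(8, 12, 2)
        f2, p2 = pairs.binomial_direction_test(8, 10, 0)
        assert (frac, p) == (f2, p2)

    def test_all_tied_non_testable(self):
        frac, p = pairs.binomial_direction_test(0, 5, 5)
        assert np.isnan(frac) and np.isnan(p)

    @pytest.mark.parametrize("n", range(1, 13))
    def test_exact_matches_bruteforce_enumeration(self, n):
        # enumerate all 2^n orderings of who-came-first
        tail = np.zeros(n + 1)
        for seq in itertools.product([0, 1], repeat=n):
            k = sum(seq)
            tail[: k + 1] += 1  # contributes to P(X >= j) for all j <= k
        tail /= 2.0 ** n
        for k in range(n + 1):
            _, p = pairs.binomial_direction_test(k, n, 0)
            assert p == pytest.approx(tail[k], abs=1e-12)

    def test_normal_approximation_close_for_large_n(self):
        _, exact = pairs.binomial_direction_test(560, 1000, 0)
        _, approx = pairs.binomial_direction_test(560, 1000, 0, method="normal")
        assert approx == pytest.approx(exact, rel=0.2)


class TestLogisticPair:
    @staticmethod
    def build(n_d1_d2, n_d1_only, n_d2_only, n_neither):
        rows, pid = [], 0
        for _ in range(n_d1_d2):
            rows += [(f"P{pid}", "A", "2011-01-01"), (f"P{pid}", "B", "2012-01-01")]
            pid += 1
        for _ in range(n_d1_only):
            rows += [(f"P{pid}", "A", "2011-01-01")]
            pid += 1
        for _ in range(n_d2_only):
            rows += [(f"P{pid}", "B", "2012-01-01")]
            pid += 1
        pid += n_neither
        ev = event_frame(rows)
        ids = pd.Index([f"P{i}" for i in range(pid)])
        dates = pairs.event_date_index(ev)
        return dates.get("A"), dates.get("B"), ids

    def test_cross_product_oracle(self):
        # 30/100 D2 among D1 vs 10/100 among non-D1 -> OR = 2700/700
        d1, d2, ids = self.build(30, 70, 10, 90)
        res = pairs.logistic_pair_test(d1, d2, ids)
        assert res["status"] == "ok"
        assert res["or"] == pytest.approx((30 * 90) / (70 * 10), rel=1e-4)

    def test_null_association(self):
        d1, d2, ids = self.build(20, 80, 20, 80)
        res = pairs.logistic_pair_test(d1, d2, ids)
        assert res["or"] == pytest.approx(1.0, rel=1e-6)

    def test_zero_cell_flagged(self):
        d1, d2, ids = self.build(30, 70, 0, 100)
        res = pairs.logistic_pair_test(d1, d2, ids)
        assert res["status"] == "zero_cell"
        assert np.isnan(res["or"])

    @pytest.mark.parametrize("cells", [(25, 75, 15, 85), (40, 60, 5, 95),
                                       (12, 88, 30, 70)])
    def test_or_equals_cross_product_to_4_sig_figs(self, cells):
        a, b, c, d = cells
        d1, d2, ids = self.build(a, b, c, d)
        res = pairs.logistic_pair_test(d1, d2, ids)
        expected = (a * d) / (b * c)
        assert res["or"] == pytest.approx(expected, rel=1e-4)


class TestRunPairInference:
    def make_events(self, n, rng, order_frac=0.9):
        rows = []
        for i in range(n):
            d1 = pd.Timestamp("2011-01-01") + pd.Timedelta(days=int(rng.integers(0, 300)))
            offset = int(rng.integers(30, 400))
            if rng.random() < order_frac:
                d2 = d1 + pd.Timedelta(days=offset)
            else:
                d2 = d1 - pd.Timedelta(days=offset)
            rows += [(f"P{i}", "A", d1.date().isoformat()),
                     (f"P{i}", "B", d2.date().isoformat())]
        # single-disease participants so the 2x2 table has no zero cells
        for i in range(n, n + n // 4):
            rows.append((f"P{i}", "A", "2011-06-01"))
        for i in range(n + n // 4, n + n // 4 + n // 2):
            rows.append((f"P{i}", "B", "2012-06-01"))
        return event_frame(rows)

    def test_directed_pair_confirmed_and_reverse_rejected(self):
        rng = np.random.default_rng(0)
        ev = self.make_events(200, rng)
        ids = [f"P{i}" for i in range(500)]  # both / single / neither mix
        out = pairs.run_pair_inference(ev, ids, ["A", "B"], n_exposed=500)
        by_pair = out.set_index(["d1", "d2"])
        assert bool(by_pair.loc[("A", "B"), "confirmed"])
        assert not bool(by_pair.loc[("B", "A"), "direction_ok"])

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(1)
        for frac in (0.3, 0.5, 0.7):
            ev = self.make_events(100, rng, order_frac=frac)
            ids = [f"P{i}" for i in range(100)]
            out = pairs.run_pair_inference(ev, ids, ["A", "B"], n_exposed=100)
            assert out["direction_ok"].sum() <= 1

    def test_or_below_one_rejected_after_direction(self):
        # directed in time but D1 NEGATIVELY associated with D2:
        # every D2 case lacks prior D1 except a directed minority
        rows = []
        for i in range(60):   # D1 then D2 (directed, passes binomial)
            rows += [(f"P{i}", "A", "2011-01-01"), (f"P{i}", "B", "2012-01-01")]
        for i in range(60, 460):  # D1 only (dilutes the association)
            rows += [(f"P{i}", "A", "2011-01-01")]
        for i in range(460, 760):  # D2 only
            rows += [(f"P{i}", "B", "2012-01-01")]
        ids = [f"P{i}" for i in range(800)]
        out = pairs.run_pair_inference(event_frame(rows), ids, ["A", "B"],
                                       n_exposed=800)
        row = out.set_index(["d1", "d2"]).loc[("A", "B")]
        assert bool(row["direction_ok"])
        assert row["or"] < 1
        assert not bool(row["confirmed"])

    def test_select_pairs(self):
        rng = np.random.default_rng(2)
        ev = self.make_events(200, rng)
        ids = [f"P{i}" for i in range(500)]
        out = pairs.run_pair_inference(ev, ids, ["A", "B"], n_exposed=500)
        sel = pairs.select_pairs(out)
        assert (sel["confirmed"]).all()
        assert set(sel.columns) == set(out.columns)
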