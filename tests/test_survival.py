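import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test

from atdosim.errors import ValidationError
from atdosim.survival import (
    SurvivalRecord,
    km_curve,
    logrank,
    median_survival,
    read_survival,
    survival_percent,
)

from conftest import make_records


class TestKMCurve:
    def test_four_deaths_no_censoring(self):
        c = km_curve(make_records([(10, 1), (20, 1), (30, 1), (40, 1)]))
        assert np.allclose(c.survival, [0.75, 0.50, 0.25, 0.0])

    def test_all_censored_stays_at_one(self):
        c = km_curve(make_records([(5, 0), (9, 0), (160, 0)]))
        assert len(c.times) == 0
        assert c.s(100.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # deaths at 5, 12(x2), 25; censored at 8 and 20
        c = km_curve(make_records([(5, 1), (8, 0), (12, 1), (12, 1), (20, 0), (25, 1)]))
        assert np.allclose(c.times, [5, 12, 25])
        assert np.allclose(c.survival, [5 / 6, 5 / 12, 0.0])
        assert np.array_equal(c.at_risk, [6, 4, 1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_curve([])

    @given(
        times=st.lists(st.integers(1, 50), min_size=1, max_size=15)
    )
    @settings(max_examples=50, deadline=None)
    def test_no_censoring_equals_one_minus_ecdf(self, times):
        recs = make_records([(t, 1) for t in times])
        c = km_curve(recs)
        ts = np.array(times, dtype=float)
        for t in sorted(set(times)):
            assert c.s(t) == pytest.approx(np.mean(ts > t))


class TestMedianSurvival:
    def test_first_time_at_or_below_half(self):
        c = km_curve(make_records([(10, 1), (20, 1), (30, 1), (40, 1)]))
        assert median_survival(c) == 20.0

    def test_undefined_when_curve_stays_high(self):
        c = km_curve(make_records([(10, 1), (160, 0), (160, 0), (160, 0)]))
        assert median_survival(c) is None

    def test_invariant_to_record_order(self, rng):
        pairs = [(int(t), int(e)) for t, e in zip(rng.integers(1, 100, 12), rng.integers(0, 2, 12))]
        m1 = median_survival(km_curve(make_records(pairs)))
        m2 = median_survival(km_curve(make_records(pairs[::-1])))
        assert m1 == m2


class TestLogrank:
    def test_identical_groups_no_signal(self):
        g = [(10, 1), (20, 1), (30, 0)]
        res = logrank(make_records(g, group="a"), make_records(g, group="b"))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_six_record_example(self):
        # O-E = 1.85, V = 0.6775 summed over event times 3, 6, 9, 10, 16
        a = make_records([(3, 1), (6, 1), (9, 1)], group="a")
        b = make_records([(10, 1), (14, 0), (16, 1)], group="b")
        res = logrank(a, b)
        assert res.statistic == pytest.approx(1.85**2 / 0.6775, rel=1e-9)
        assert res.p_value == pytest.approx(0.02460235, rel=1e-5)

    def test_symmetric_in_group_labels(self):
        a = make_records([(3, 1), (6, 1), (9, 0)], group="a")
        b = make_records([(10, 1), (16, 1)], group="b")
        assert logrank(a, b).statistic == pytest.approx(logrank(b, a).statistic, rel=1e-12)

    def test_fully_separated_groups(self):
        a = make_records([(t, 1) for t in range(1, 11)], group="a")
        b = make_records([(t, 1) for t in range(50, 60)], group="b")
        assert logrank(a, b).p_value < 0.001

    def test_zero_events_flagged_undefined(self):
        a = make_records([(10, 0)], group="a")
        b = make_records([(20, 0)], group="b")
        assert not logrank(a, b).defined

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_lifelines_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(4, 12, 2)
        ta = rng.integers(1, 60, na).astype(float)
        tb = rng.integers(1, 80, nb).astype(float)
        ea = rng.integers(0, 2, na).astype(bool)
        eb = rng.integers(0, 2, nb).astype(bool)
        if not (ea.any() or eb.any()):
            ea[0] = True
        a = [SurvivalRecord(f"a{i}", "a", t, bool(e)) for i, (t, e) in enumerate(zip(ta, ea))]
        b = [SurvivalRecord(f"b{i}", "b", t, bool(e)) for i, (t, e) in enumerate(zip(tb, eb))]
        res = logrank(a, b)
        ref = logrank_test(ta, tb, ea, eb)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_chi2_p_consistent_with_exhaustive_permutation(self):
        times = [3.0, 6.0, 9.0, 10.0, 14.0, 16.0]
        events = [1, 1, 1, 1, 0, 1]

        def stat(idx_a):
            a = [SurvivalRecord(f"x{i}", "a", times[i], bool(events[i])) for i in idx_a]
            b = [
                SurvivalRecord(f"y{i}", "b", times[i], bool(events[i]))
                for i in range(6)
                if i not in idx_a
            ]
            return logrank(a, b).statistic

        obs = stat({0, 1, 2})
        perm = [stat(set(c)) for c in itertools.combinations(range(6), 3)]
        p_perm = np.mean([s >= obs - 1e-12 for s in perm])
        a = [SurvivalRecord(f"x{i}", "a", times[i], bool(events[i])) for i in (0, 1, 2)]
        b = [SurvivalRecord(f"y{i}", "b", times[i], bool(events[i])) for i in (3, 4, 5)]
        p_chi2 = logrank(a, b).p_value
        # at n=6 the chi-square approximation is crude and the permutation
        # p has granularity 1/20; require coarse agreement only
        assert abs(p_chi2 - p_perm) <= 0.1


class TestSurvivalPercent:
    @pytest.mark.parametrize(
        "alive, total, expected", [(11, 17, 65.0), (0, 8, 0.0), (8, 8, 100.0)]
    )
    def test_rounded_percent(self, alive, total, expected):
        assert survival_percent(alive, total, decimals=0) == expected

    def test_unrounded(self):
        assert survival_percent(11, 17) == pytest.approx(64.70588, rel=1e-6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            survival_percent(0, 0)


class TestReadSurvival:
    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "animal,group,time_days,event,cause\n"
            "m1,control,45,1,paraplegia\n"
            "m2,740kBq,160,0,censored\n"
        )
        recs = read_survival(p)
        assert len(recs) == 2
        assert recs[0].event and recs[0].cause == "paraplegia"
        assert not recs[1].event

    def test_cause_event_consistency_enforced(self):
        with pytest.raises(ValidationError):
            SurvivalRecord("m1", "g", 45.0, True, "censored")
        with pytest.raises(ValidationError):
            SurvivalRecord("m1", "g", 45.0, False, "paraplegia")
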