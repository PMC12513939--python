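"""Benchmark registry, deviation flagging and run-rule signals."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import benchcycle as bc
from benchcycle.errors import ConfigurationError, RegistryKeyError
from conftest import make_point


def brute_force_runs(flags, k):
    """Oracle: maximal runs of consecutive True with length >= k."""
    runs, i = [], 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            if j - i + 1 >= k:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


class TestRegistry:
    @pytest.mark.parametrize(
        "outcome, stratum, cutoff, lo, hi, direction",
        [
            ("anastomotic_leak", "ideal", 9.8, 0.0, 15.6, "lower_better"),
            ("ln_ge_12", "ideal", 74.5, 65.5, 100.0, "higher_better"),
            ("ln_ge_12", "non_ideal", 68.3, 54.3, 94.7, "higher_better"),
            ("cdc_ge_3a_discharge", "ideal", 12.2, 2.3, 16.7, "lower_better"),
            ("cdc_ge_3a_discharge", "non_ideal", 13.7, 3.3, 26.0, "lower_better"),
            ("readmission_3mo", "ideal", 15.3, 0.0, 19.0, "lower_better"),
            ("readmission_3mo", "non_ideal", 21.7, 3.2, 28.6, "lower_better"),
        ],
    )
    def test_packaged_lar_cutoffs(self, registry, outcome, stratum, cutoff, lo, hi, direction):
        e = registry.get("LAR", outcome, stratum)
        assert (e.cutoff, e.range_low, e.range_high) == (cutoff, lo, hi)
        assert str(e.direction) == direction

    def test_absent_key_raises_named_error(self, registry):
        with pytest.raises(RegistryKeyError, match="pancreatectomy"):
            registry.get("pancreatectomy", "anastomotic_leak", "ideal")

    def test_cutoff_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bc.BenchmarkEntry("LAR", "x", "ideal", 20.0, 0.0, 15.0, "lower_better")

    def test_duplicate_key_rejected(self):
        e = bc.BenchmarkEntry("LAR", "x", "ideal", 5.0, 0.0, 10.0, "lower_better")
        with pytest.raises(ConfigurationError):
            bc.BenchmarkRegistry([e, e])

    def test_registry_roundtrip_is_exact(self, tmp_path, registry):
        path = tmp_path / "reg.yaml"
        registry.to_yaml(path)
        reloaded = bc.load_registry(path)
        assert sorted(e.key for e in reloaded) == sorted(e.key for e in registry)
        for e in registry:
            r = reloaded.get(*e.key)
            assert (r.cutoff, r.range_low, r.range_high, r.direction) == (
                e.cutoff, e.range_low, e.range_high, e.direction,
            )


class TestDeriveBenchmark:
    def test_equal_medians_degenerate(self):
        e = bc.derive_benchmark([4.2, 4.2, 4.2], "lower_better")
        assert (e.cutoff, e.range_low, e.range_high) == (4.2, 4.2, 4.2)

    def test_lower_better_uses_75th_percentile(self):
        # linear interpolation: index 0.75*(4-1)=2.25 -> 10 + 0.25*5
        e = bc.derive_benchmark([0, 5, 10, 15], "lower_better")
        assert e.cutoff == pytest.approx(11.25)
        assert (e.range_low, e.range_high) == (0, 15)

    def test_higher_better_uses_25th_percentile(self):
        # index 0.25*(4-1)=0.75 -> 60 + 0.75*14.5
        e = bc.derive_benchmark([60, 74.5, 80, 100], "higher_better")
        assert e.cutoff == pytest.approx(70.875)

    def test_single_centre_rejected(self):
        with pytest.raises(ConfigurationError):
            bc.derive_benchmark([5.0], "lower_better")


class TestFlagDeviation:
    def test_zero_rate_below_lower_better_cutoff_is_compliant(self, registry):
        entry = registry.get("LAR", "cdc_ge_3a_discharge", "ideal")
        point = make_point("p1", 0.0, outcome="cdc_ge_3a_discharge")
        deviation, _ = bc.flag_deviation(point, entry)
        assert deviation is False

    def test_high_readmission_magnitude_in_percentage_points(self, registry):
        entry = registry.get("LAR", "readmission_3mo", "ideal")
        deviation, magnitude = bc.flag_deviation(make_point("p8", 0.31), entry)
        assert deviation is True
        assert magnitude == pytest.approx(15.7)

    def test_value_exactly_at_cutoff_is_not_a_deviation(self, registry):
        entry = registry.get("LAR", "readmission_3mo", "ideal")
        deviation, magnitude = bc.flag_deviation(make_point("p1", 0.153), entry)
        assert deviation is False and magnitude == pytest.approx(0.0)

    def test_higher_better_flags_low_values(self, registry):
        entry = registry.get("LAR", "ln_ge_12", "ideal")
        dev_low, _ = bc.flag_deviation(
            make_point("p1", 0.60, outcome="ln_ge_12"), entry
        )
        dev_high, _ = bc.flag_deviation(
            make_point("p1", 0.90, outcome="ln_ge_12"), entry
        )
        assert dev_low is True and dev_high is False

    def test_mismatched_outcome_is_key_error(self, registry):
        entry = registry.get("LAR", "readmission_3mo", "ideal")
        with pytest.raises(RegistryKeyError):
            bc.flag_deviation(make_point("p1", 0.1, outcome="anastomotic_leak"), entry)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        value=st.floats(0.0, 1.0),
        cutoff=st.floats(5.0, 95.0),
    )
    def test_direction_symmetry(self, value, cutoff):
        """Mirroring values and flipping direction preserves deviations."""
        low = bc.BenchmarkEntry("P", "o", "ideal", cutoff, 0.0, 100.0,
                                "lower_better", units="%")
        high = bc.BenchmarkEntry("P", "o", "ideal", 100.0 - cutoff, 0.0, 100.0,
                                 "higher_better", units="%")
        d1, m1 = bc.flag_deviation(make_point("p1", value, outcome="o"), low)
        d2, m2 = bc.flag_deviation(make_point("p1", 1.0 - value, outcome="o"), high)
        assert d1 == d2
        assert m1 == pytest.approx(m2, abs=1e-9)


class TestRunRule:
    def test_no_deviations_no_signals(self):
        assert bc.run_rule([False] * 10, 2) == []

    def test_terminal_run_detected(self):
        flags = [False] * 6 + [True] * 4  # deviations at p7..p10
        assert bc.run_rule(flags, 2) == [(6, 9)]

    def test_k1_returns_every_maximal_run(self):
        flags = [True, False, True, True, False, True]
        assert bc.run_rule(flags, 1) == [(0, 0), (2, 3), (5, 5)]

    @settings(derandomize=True, max_examples=500, deadline=None)
    @given(flags=st.lists(st.booleans(), max_size=30), k=st.integers(1, 5))
    def test_matches_brute_force_scan(self, flags, k):
        assert bc.run_rule(flags, k) == brute_force_runs(flags, k)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(flags=st.lists(st.booleans(), max_size=30), k=st.integers(1, 5))
    def test_total_flagged_windows_invariant_to_k(self, flags, k):
        base = bc.run_rule(flags, 1)
        assert sum(e - s + 1 for s, e in base) == sum(flags)
        # every k-run is contained in a maximal run
        for s, e in bc.run_rule(flags, k):
            assert any(bs <= s and e <= be for bs, be in base)


class TestEvaluate:
    def _series(self, values, outcome="readmission_3mo", stratum="ideal"):
        return [
            make_point(f"p{i + 1}", v, outcome=outcome, stratum=stratum,
                       defined=v is not None)
            for i, v in enumerate(values)
        ]

    def test_series_entirely_better_has_no_flags(self, registry):
        series = self._series([0.05] * 10)
        report = bc.evaluate(series, registry, k=2)
        assert report.n_deviations == 0 and report.signals == []

    def test_two_consecutive_deviations_fire_one_signal(self, registry):
        values = [0.1, 0.30, 0.31, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        report = bc.evaluate(self._series(values), registry, k=2)
        assert [(s.start_label, s.end_label, s.run_length) for s in report.signals] == [
            ("p2", "p3", 2)
        ]

    def test_undefined_point_breaks_a_run(self, registry):
        values = [0.30, 0.30, None, 0.30, 0.30]
        report = bc.evaluate(self._series(values), registry, k=3)
        assert report.signals == []  # no run of 3 spans the undefined p3
        report2 = bc.evaluate(self._series(values), registry, k=2)
        assert [(s.start_label, s.end_label) for s in report2.signals] == [
            ("p1", "p2"), ("p4", "p5"),
        ]

    def test_missing_registry_entry_names_key(self, registry):
        series = self._series([0.1] * 3, outcome="anastomotic_leak", stratum="non_ideal")
        with pytest.raises(RegistryKeyError, match="anastomotic_leak"):
            bc.evaluate(series, registry, k=2)

    def test_report_json_roundtrip(self, tmp_path, registry):
        values = [0.1, 0.30, 0.31, 0.1, None, 0.25, 0.28, 0.1, 0.1, 0.1]
        report = bc.evaluate(self._series(values), registry, k=2)
        path = tmp_path / "flags.json"
        report.to_json(path)
        assert bc.FlagReport.from_json(path) == report
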