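"""TBC arithmetic, standard curve, normalizations, kinetics binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsdpore import quantify as qt


def rec(ch, label, start, end):
    return qt.CaptureRecord(ch, label, start, end)


class TestTimeBetweenCaptures:
    def test_gap_with_noise_occupancy_subtracted(self):
        records = [
            rec(0, "A", 5.0, 10.0),
            rec(0, "noise", 12.0, 18.0),
            rec(0, "A", 25.0, 30.0),
        ]
        assert qt.time_between_captures(records, "A") == [25.0 - 10.0 - 6.0]

    def test_gap_without_occupancy_is_plain_difference(self):
        records = [rec(0, "A", 0.0, 1.0), rec(0, "A", 4.0, 5.0)]
        assert qt.time_between_captures(records, "A") == [3.0]

    def test_other_barcode_occupancy_also_subtracted(self):
        records = [
            rec(0, "A", 0.0, 1.0),
            rec(0, "B", 2.0, 3.0),
            rec(0, "unclassified", 4.0, 4.5),
            rec(0, "A", 6.0, 7.0),
        ]
        assert qt.time_between_captures(records, "A") == [6.0 - 1.0 - 1.0 - 0.5]

    def test_gaps_pooled_across_channels(self):
        records = [
            rec(0, "A", 0.0, 1.0),
            rec(0, "A", 3.0, 4.0),
            rec(1, "A", 0.0, 2.0),
            rec(1, "A", 7.0, 8.0),
        ]
        assert sorted(qt.time_between_captures(records, "A")) == [2.0, 5.0]

    def test_overlapping_records_raise_integrity_error(self):
        records = [rec(0, "A", 0.0, 2.0), rec(0, "noise", 1.0, 3.0)]
        with pytest.raises(qt.IntegrityError, match="overlap"):
            qt.time_between_captures(records, "A")

    def test_mean_tbc_against_generator_expectation(self, channel_config, barcode_model):
        """Pooled mean TBC on a fixed-concentration run must sit within 10%
        of the generator's closed-form 1/(rate*C) over >= 200 gaps."""
        from dsdpore import pipeline as pl
        from dsdpore import synth

        bundle = pl.build_reference_bundle([barcode_model], None, seed=0)
        events, _ = pl.extract_streamed_run(
            8,
            synth.Schedule.constant({"B0": 0.5}),
            [barcode_model],
            channel_config,
            600.0,
            seed=21,
        )
        records, _ = pl.records_from_events(events, bundle)
        gaps = qt.time_between_captures(records, "B0")
        assert len(gaps) >= 200
        expected = 1.0 / (channel_config.capture_rate_per_uM * 0.5)
        assert np.mean(gaps) == pytest.approx(expected, rel=0.10)

    def test_exposure_tbc_definition(self):
        assert qt.exposure_tbc(4, 40.0) == 10.0
        with pytest.raises(ValueError):
            qt.exposure_tbc(0, 40.0)


class TestStandardCurve:
    def test_exact_inverse_law_recovered(self):
        conc = np.array([0.02, 0.1, 0.2, 0.5, 1.0])
        tbc = 2.0 / conc
        curve = qt.fit_standard_curve(conc, tbc)
        assert curve.a == pytest.approx(2.0, abs=1e-6)
        assert curve.b == pytest.approx(0.0, abs=1e-6)
        assert curve.monotone_warning is None

    def test_doubling_tbcs_doubles_a(self):
        conc = np.array([0.1, 0.2, 0.5])
        c1 = qt.fit_standard_curve(conc, 3.0 / conc)
        c2 = qt.fit_standard_curve(conc, 6.0 / conc)
        assert c2.a == pytest.approx(2 * c1.a, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            qt.fit_standard_curve([0.1, 0.2], [10.0, 5.0])

    def test_non_monotone_data_flagged(self):
        curve = qt.fit_standard_curve([0.1, 0.2, 0.5], [10.0, 12.0, 2.0])
        assert curve.monotone_warning is not None

    def test_inversion_and_round_trip(self):
        curve = qt.StandardCurve(2.0, 0.0, (0.02, 1.0), (2.0, 100.0))
        assert qt.concentration_from_tbc(curve, 4.0) == pytest.approx(0.5)

    def test_tbc_at_or_below_offset_undefined(self):
        curve = qt.StandardCurve(2.0, 1.0, (0.02, 1.0), (3.0, 100.0))
        with pytest.raises(ValueError, match="undefined"):
            qt.concentration_from_tbc(curve, 0.5)

    def test_extrapolation_flagged(self):
        curve = qt.StandardCurve(2.0, 0.0, (0.02, 1.0), (2.0, 100.0))
        with pytest.warns(UserWarning, match="extrapolat"):
            qt.concentration_from_tbc(curve, 500.0)


class TestNormalizations:
    def test_eq1_endpoints_and_midpoint_exact(self):
        assert qt.normalize_eq1(100.0, 100.0, 10.0) == 0.0
        assert qt.normalize_eq1(10.0, 100.0, 10.0) == 1.0
        assert qt.normalize_eq1(55.0, 100.0, 10.0) == 0.5

    def test_eq2_endpoints_exact(self):
        assert qt.normalize_eq2(0.3, 0.3, 2.0) == 0.0
        assert qt.normalize_eq2(2.0, 0.3, 2.0) == 1.0

    @given(
        bg=st.floats(-1e3, 1e3),
        sat=st.floats(-1e3, 1e3),
        x=st.floats(-1e3, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_identity_properties(self, bg, sat, x):
        if bg == sat:
            with pytest.raises(ValueError):
                qt.normalize_eq1(x, bg, sat)
            return
        v = qt.normalize_eq1(x, bg, sat)
        assert v == (x - bg) / (sat - bg)  # exact, no clamping
        assert qt.normalize_eq1(bg, bg, sat) == 0.0
        assert qt.normalize_eq1(sat, bg, sat) == 1.0

    def test_values_outside_unit_interval_permitted(self):
        assert qt.normalize_eq1(5.0, 100.0, 10.0) > 1.0


class TestCaptureFrequency:
    def test_reads_per_good_channel_per_minute(self):
        records = [rec(i % 12, "A", i * 1.0, i * 1.0 + 0.5) for i in range(120)]
        assert qt.capture_frequency(records, "A", 12, 10.0) == 1.0

    def test_zero_channels_or_duration_rejected(self):
        with pytest.raises(ValueError):
            qt.capture_frequency([], "A", 0, 10.0)
        with pytest.raises(ValueError):
            qt.capture_frequency([], "A", 3, 0.0)


class TestKineticsSeries:
    def test_run_must_cover_two_bins(self):
        with pytest.raises(ValueError, match="two bins"):
            qt.kinetics_series([], "A", duration=400.0)

    def test_empty_bins_emitted_as_missing_not_zero(self):
        records = [rec(0, "A", 100.0 + i, 100.5 + i) for i in range(5)]
        series = qt.kinetics_series(
            records, "A", duration=1200.0, metric="tbc", background=10.0, saturated=1.0
        )
        assert np.isnan(series.raw[-1])  # no gaps land in the last bin
        assert np.isfinite(series.raw[0])

    def test_gap_assigned_to_bin_of_midpoint(self):
        records = [rec(0, "A", 280.0, 290.0), rec(0, "A", 330.0, 340.0)]
        series = qt.kinetics_series(
            records, "A", duration=600.0, metric="tbc", background=100.0, saturated=10.0
        )
        assert np.isnan(series.raw[0])  # midpoint 310 s lies in the second bin
        assert series.raw[1] == pytest.approx(40.0)

    def test_frequency_metric_normalized_by_eq2(self):
        records = [rec(0, "A", 10.0 * i, 10.0 * i + 1) for i in range(30)]
        series = qt.kinetics_series(
            records,
            "A",
            duration=600.0,
            metric="frequency",
            background=0.0,
            saturated=6.0,
            n_good_channels=1,
        )
        assert series.raw[0] == pytest.approx(6.0)  # 30 events/5 min
        assert series.normalized[0] == pytest.approx(1.0)

    def test_no_input_run_normalized_near_zero(self, channel_config, barcode_model):
        from dsdpore import pipeline as pl
        from dsdpore import synth

        bundle = pl.build_reference_bundle([barcode_model], None, seed=0)
        events, _ = pl.extract_streamed_run(
            4,
            synth.Schedule.constant({"B0": 0.0}),
            [barcode_model],
            channel_config,
            900.0,
            seed=3,
        )
        records, _ = pl.records_from_events(events, bundle)
        series = qt.kinetics_series(
            records,
            "B0",
            duration=900.0,
            metric="frequency",
            background=0.0,
            saturated=4.0,
        )
        assert np.all(np.abs(series.normalized) < 0.05)
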