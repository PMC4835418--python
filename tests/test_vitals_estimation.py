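"""Ratio-of-ratios vitals estimation: formulas, pulses, smoothing, pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxiloop import (
    NoFinger,
    PhysioProfile,
    VitalsRecord,
    compute_ratio,
    detect_pulses,
    estimate_stream,
    heart_rate,
    inject_artifacts,
    perfusion_index,
    smooth_wma,
    spo2_from_ratio,
    synthesize_stream,
)
from oxiloop.errors import ParseError, ValidationError
from oxiloop.vitals_estimation import (
    read_vitals_csv,
    read_vitals_jsonl,
    write_vitals_csv,
    write_vitals_jsonl,
)


class TestRatioAndCalibration:
    @pytest.mark.parametrize(
        "args,expected",
        [((0.02, 2.0, 0.02, 2.0), 1.0), ((0.01, 1.0, 0.02, 1.0), 0.5)],
    )
    def test_ratio_arithmetic(self, args, expected):
        assert compute_ratio(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(0.01, 0.0, 0.02, 1.0), (0.01, 1.0, 0.0, 1.0), (0.01, 1.0, 0.02, -1.0)])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValidationError):
            compute_ratio(*bad)

    @pytest.mark.parametrize("r,expected", [(0.5, 97.5), (0.0, 100.0), (1.6, 70.0), (4.5, 0.0)])
    def test_calibration_line_with_clamp(self, r, expected):
        assert spo2_from_ratio(r) == pytest.approx(expected)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValidationError):
            spo2_from_ratio(-0.1)

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=1e-6, max_value=10.0))
    @settings(derandomize=True, max_examples=200)
    def test_strictly_decreasing_before_clamp(self, r, dr):
        """Higher R never maps to higher SpO2; strictly lower inside [0,100]."""
        lo, hi = spo2_from_ratio(r + dr), spo2_from_ratio(r)
        assert lo <= hi
        if 0.0 < hi < 100.0 and lo > 0.0:
            assert lo < hi


class TestPulseDetection:
    def test_count_matches_cardiac_rate(self):
        stream = synthesize_stream(PhysioProfile(heart_rate=75.0), 8.0)
        ir = stream.samples.reshape(-1, 4)[:, 2]
        peaks = detect_pulses(ir - ir.mean(), 125.0)
        assert abs(len(peaks) - 10) <= 1  # 75 bpm over 8 s

    def test_flat_input_zero_pulses(self):
        assert len(detect_pulses(np.full(500, 1.3), 125.0)) == 0
        assert len(detect_pulses(np.zeros(500), 125.0)) == 0

    def test_refractory_merges_close_peaks(self):
        x = np.zeros(125)
        x[40] = 1.0
        x[52] = 1.0  # 0.096 s later: inside the 0.25 s refractory interval
        assert len(detect_pulses(x, 125.0)) == 1


class TestHeartRateFormula:
    @pytest.mark.parametrize(
        "fs,n_samples,n_pulses,expected",
        [(125.0, 100.0, 1.0, 75.0), (125.0, 250.0, 2.0, 60.0), (500.0, 400.0, 1.0, 75.0)],
    )
    def test_samples_per_pulse_arithmetic(self, fs, n_samples, n_pulses, expected):
        assert heart_rate(fs, n_samples, n_pulses) == pytest.approx(expected)

    def test_zero_pulses_rejected(self):
        with pytest.raises(ValidationError):
            heart_rate(125.0, 100.0, 0.0)


class TestPerfusionIndex:
    def test_definition(self):
        assert perfusion_index(0.02, 2.0) == pytest.approx(1.0)
        assert perfusion_index(0.0, 2.0) == 0.0

    def test_nonpositive_dc_rejected(self):
        with pytest.raises(ValidationError):
            perfusion_index(0.02, 0.0)


class TestWeightedMovingAverage:
    def test_constant_history(self):
        assert smooth_wma([7.0] * 5, [1, 2, 3, 4, 5]) == pytest.approx(7.0)

    def test_two_point_weighted_mean(self):
        assert smooth_wma([90.0, 100.0], [1.0, 3.0]) == pytest.approx(97.5)

    def test_single_element_truncates_weights(self):
        assert smooth_wma([92.0], [1, 2, 3, 4, 5]) == pytest.approx(92.0)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=5))
    @settings(derandomize=True, max_examples=100)
    def test_output_bounded_by_window(self, history):
        out = smooth_wma(history, [1, 2, 3, 4, 5])
        assert min(history) - 1e-9 <= out <= max(history) + 1e-9

    def test_empty_history_rejected(self):
        with pytest.raises(ValidationError):
            smooth_wma([], [1.0])


class TestRecordContract:
    def test_invalid_records_carry_no_vitals(self):
        with pytest.raises(ValidationError):
            VitalsRecord(t=0, spo2=95.0, heart_rate=None, perfusion_index=None, valid=False, r_ratio=None)

    def test_valid_record_range_checks(self):
        with pytest.raises(ValidationError):
            VitalsRecord(t=0, spo2=120.0, heart_rate=70.0, perfusion_index=1.0, valid=True, r_ratio=0.1)
        with pytest.raises(ValidationError):
            VitalsRecord(t=0, spo2=95.0, heart_rate=20.0, perfusion_index=1.0, valid=True, r_ratio=0.6)


class TestReaderPipeline:
    def test_one_record_per_second(self):
        stream = synthesize_stream(PhysioProfile(), 30.0)
        records = estimate_stream(stream)
        assert len(records) == 30
        assert [r.t for r in records] == list(map(float, range(30)))

    @pytest.mark.parametrize(
        "spo2,hr", list(itertools.product([80.0, 85.0, 90.0, 94.0, 98.0], [50.0, 75.0, 120.0]))
    )
    def test_noise_free_parameter_recovery(self, spo2, hr):
        """Grid recovery: |SpO2 error| <= 1 point, |HR error| <= 2 bpm after warm-up."""
        profile = PhysioProfile(true_spo2=spo2, heart_rate=hr, perfusion_index=2.0)
        records = estimate_stream(synthesize_stream(profile, 20.0))
        tail = [r for r in records if r.t >= 12.0]
        assert all(r.valid for r in tail)
        for r in tail:
            assert abs(r.spo2 - spo2) <= 1.0
            assert abs(r.heart_rate - hr) <= 2.0

    def test_perfusion_index_recovery_with_filter_droop(self):
        """PI tracks the profile up to the noise filter's in-band droop
        (5-17 % depending on HR; see the cascade-gain test in the DSP suite)."""
        for hr in (50.0, 75.0, 120.0):
            profile = PhysioProfile(perfusion_index=2.0, heart_rate=hr)
            records = estimate_stream(synthesize_stream(profile, 20.0))
            assert records[-1].perfusion_index == pytest.approx(2.0, abs=0.4)

    def test_no_finger_interval_invalidates_records(self):
        """Seconds fully inside a dropout are invalid (<= 1 s detection lag)."""
        stream = inject_artifacts(
            synthesize_stream(PhysioProfile(), 16.0), [NoFinger(5.0, 8.0)]
        )
        records = estimate_stream(stream)
        assert len(records) == 16
        statuses = {int(r.t): r.valid for r in records}
        assert not statuses[6] and not statuses[7]  # fully inside, beyond any lag
        assert statuses[5] is False or statuses[6] is False  # onset within 1 s
        assert all(statuses[t] for t in range(10, 16))  # recovered after return

    def test_noisy_stream_still_recovers(self):
        profile = PhysioProfile(true_spo2=94.0, noise_sd=0.005, seed=21)
        records = estimate_stream(synthesize_stream(profile, 20.0))
        tail = [r for r in records if r.t >= 12.0 and r.valid]
        assert tail and abs(np.mean([r.spo2 for r in tail]) - 94.0) <= 1.0


class TestWireFormats:
    @pytest.fixture
    def records(self):
        stream = inject_artifacts(
            synthesize_stream(PhysioProfile(), 10.0), [NoFinger(4.0, 6.0)]
        )
        return estimate_stream(stream)

    def test_csv_round_trip(self, tmp_path, records):
        write_vitals_csv(records, tmp_path / "v.csv")
        assert read_vitals_csv(tmp_path / "v.csv") == records

    def test_jsonl_round_trip(self, tmp_path, records):
        write_vitals_jsonl(records, tmp_path / "v.jsonl")
        assert read_vitals_jsonl(tmp_path / "v.jsonl") == records

    def test_missing_column_raises_parse_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("t,spo2\n0,95\n")
        with pytest.raises(ParseError):
            read_vitals_csv(tmp_path / "bad.csv")

    def test_empty_file_yields_no_records(self, tmp_path):
        (tmp_path / "empty.jsonl").write_text("")
        assert read_vitals_jsonl(tmp_path / "empty.jsonl") == []
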