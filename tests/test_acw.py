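"""Autocorrelation-window estimation: oracles, crossings, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import lfilter, resample

from neuroacw.acw import (
    ACFCurve,
    DegenerateSignalError,
    ParcellatedRecording,
    TimeSeries,
    acw0,
    acw50,
    acw_from_acf,
    acw_map,
    compute_acf,
)
from .conftest import direct_acf

FS = 508.62


def make_sine(freq: float, duration_s: float = 30.0, fs: float = FS) -> TimeSeries:
    t = np.arange(int(duration_s * fs)) / fs
    return TimeSeries(np.sin(2 * np.pi * freq * t), fs)


class TestComputeAcf:
    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            compute_acf(TimeSeries(np.full(100, 3.2), FS))

    def test_fft_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=512)
        acf = compute_acf(TimeSeries(x, FS), max_lag=256)
        assert np.max(np.abs(acf.coefficients - direct_acf(x, 256))) < 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(16, 512),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_fft_equals_direct_sum_property(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        max_lag = n // 2
        acf = compute_acf(TimeSeries(x, FS), max_lag=max_lag)
        assert np.max(np.abs(acf.coefficients - direct_acf(x, max_lag))) < 1e-10

    def test_white_noise_coefficients_within_large_sample_bound(self):
        n = 100_000
        x = np.random.default_rng(1).normal(size=n)
        acf = compute_acf(TimeSeries(x, FS), max_lag=50)
        assert np.all(np.abs(acf.coefficients[1:]) < 4 / np.sqrt(n))

    def test_coefficients_bounded_and_normalized(self):
        x = np.random.default_rng(2).standard_t(df=3, size=4096)
        acf = compute_acf(TimeSeries(x, FS), max_lag=2000)
        assert acf.coefficients[0] == 1.0
        assert np.all(np.abs(acf.coefficients) <= 1 + 1e-12)

    def test_max_lag_out_of_range_rejected(self):
        ts = TimeSeries(np.random.default_rng(3).normal(size=64), FS)
        with pytest.raises(ValueError):
            compute_acf(ts, max_lag=64)
        with pytest.raises(ValueError):
            compute_acf(ts, max_lag=0)


class TestCrossings:
    def test_sine_half_max_crossing_matches_cosine_oracle(self):
        # cos(2*pi*f*k/fs) < 0.5 first at k = ceil(fs/(6f)) = 9 for 10 Hz
        acf = compute_acf(make_sine(10.0), max_lag=200)
        value, found = acw50(acf)
        assert found and round(value / (1000 / FS)) == 9
        assert value == pytest.approx(17.70, abs=0.01)

    def test_sine_zero_crossing_is_quarter_period(self):
        acf = compute_acf(make_sine(10.0), max_lag=200)
        value, found = acw0(acf)
        assert found and round(value / (1000 / FS)) == 13
        # quarter period 25 ms, within one sample period
        assert abs(value - 1000 / (4 * 10.0)) <= 1000 / FS

    def test_ar1_crossing_matches_phi_power_theory(self):
        # phi^k < 0.5 first at k = 14 for phi = 0.95
        rng = np.random.default_rng(7)
        x = lfilter([1.0], [1.0, -0.95], rng.normal(size=200_000))
        acf = compute_acf(TimeSeries(x, FS), max_lag=100)
        value, found = acw50(acf)
        assert found
        assert abs(round(value / (1000 / FS)) - 14) <= 1

    def test_never_crossing_acf_reports_not_found(self):
        acf = ACFCurve(np.array([1.0, 0.9, 0.9, 0.9]), FS)
        assert acw50(acf) == (pytest.approx(float("nan"), nan_ok=True), False)
        assert not acw0(acf)[1]

    def test_constructed_acf_zero_crossing_at_first_nonpositive(self):
        acf = ACFCurve(np.array([1.0, 0.9, 0.4, -0.1]), FS)
        value, found = acw0(acf)
        assert found and value == pytest.approx(3 * 1000 / FS)

    def test_interpolated_crossing_between_bracketing_lags(self):
        acf = ACFCurve(np.array([1.0, 0.8, 0.2]), 1000.0)
        exact, _ = acw50(acf, interpolate=True)
        assert 1.0 < exact < 2.0
        assert exact == pytest.approx(1.5)  # 0.8 -> 0.2 crosses 0.5 halfway

    def test_zero_window_never_precedes_half_max_window(self, default_catalogue):
        both = default_catalogue.dropna(subset=["acw50_ms", "acw0_ms"])
        assert (both["acw0_ms"] >= both["acw50_ms"]).all()

    def test_result_values_are_lag_multiples(self):
        acf = compute_acf(make_sine(4.3), max_lag=400)
        res = acw_from_acf(acf)
        period = 1000 / FS
        assert res.acw50_ms / period == pytest.approx(round(res.acw50_ms / period))
        assert res.acw0_ms / period == pytest.approx(round(res.acw0_ms / period))

    def test_resampling_leaves_ms_values_within_one_sample_period(self):
        ts = make_sine(10.0)
        down = TimeSeries(resample(ts.values, ts.values.size // 2), FS / 2)
        coarse_period = 1000 / down.fs_hz
        for extractor in (acw50, acw0):
            fine, _ = extractor(compute_acf(ts, max_lag=200))
            coarse, _ = extractor(compute_acf(down, max_lag=100))
            assert abs(fine - coarse) <= coarse_period


class TestAcwMap:
    def make_recording(self, matrix, **kwargs):
        defaults = dict(
            region_ids=[f"R{i}" for i in range(matrix.shape[0])],
            subject_id="sub001",
            condition="Rest",
            fs_hz=FS,
        )
        defaults.update(kwargs)
        return ParcellatedRecording(matrix=matrix, **defaults)

    def test_identical_rows_give_identical_results(self):
        row = np.random.default_rng(0).normal(size=2000)
        rec = self.make_recording(np.vstack([row, row]))
        table = acw_map(rec)
        assert table.loc[0, "acw50_ms"] == table.loc[1, "acw50_ms"]
        assert table.loc[0, "acw0_ms"] == table.loc[1, "acw0_ms"]

    def test_degenerate_row_flagged_others_computed(self):
        rng = np.random.default_rng(1)
        matrix = np.vstack([rng.normal(size=2000), np.zeros(2000), rng.normal(size=2000)])
        table = acw_map(self.make_recording(matrix))
        assert table["degenerate"].tolist() == [False, True, False]
        assert np.isnan(table.loc[1, "acw0_ms"])
        assert table.loc[[0, 2], "acw0_found"].all()

    def test_row_permutation_permutes_results(self):
        rng = np.random.default_rng(2)
        matrix = rng.normal(size=(5, 1500))
        perm = [3, 0, 4, 1, 2]
        base = acw_map(self.make_recording(matrix)).set_index("region_id")
        shuffled = acw_map(
            self.make_recording(matrix[perm], region_ids=[f"R{i}" for i in perm])
        ).set_index("region_id")
        for rid in base.index:
            assert base.loc[rid, "acw0_ms"] == shuffled.loc[rid, "acw0_ms"]

    def test_recording_roundtrip(self, tmp_path):
        rec = self.make_recording(np.random.default_rng(3).normal(size=(3, 100)))
        path = tmp_path / "rec.tsv"
        rec.save(path)
        loaded = ParcellatedRecording.load(path)
        np.testing.assert_allclose(loaded.matrix, rec.matrix)
        assert loaded.region_ids == rec.region_ids
        assert loaded.condition == rec.condition

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            self.make_recording(np.zeros((1, 10)) + np.arange(10), condition="Nap")
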