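"""Filtering, nuisance regression, FD/DVARS, and scrubbing."""

import numpy as np
import pandas as pd
import pytest

from neteff.preprocess import (
    MOTION_COLUMNS,
    TimeSeriesMatrix,
    UnusableSubjectError,
    bandpass_filter,
    compute_dvars,
    compute_fd,
    read_motion_tsv,
    read_timeseries_tsv,
    regress_nuisance,
    scrub,
    write_motion_tsv,
    write_timeseries_tsv,
)
from neteff.synthetic import generate_motion_trace


def _sinusoid_ts(freq_hz: float, tr: float = 2.0, n_frames: int = 400, n_nodes: int = 3):
    t = np.arange(n_frames) * tr
    values = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_nodes, 1))
    return TimeSeriesMatrix(values, tr=tr)


def _quiet_ts(n_nodes=50, n_frames=100, seed=0, tr=2.0):
    """Signal with mean ~1000 and tiny fluctuations: DVARS far below 0.5%."""
    rng = np.random.default_rng(seed)
    return TimeSeriesMatrix(1000.0 + 0.1 * rng.standard_normal((n_nodes, n_frames)), tr=tr)


class TestBandpass:
    def test_in_band_sinusoid_retained(self):
        ts = _sinusoid_ts(0.05)
        out = bandpass_filter(ts, 0.009, 0.08)
        assert out.values.var() >= 0.8 * ts.values.var()

    def test_stop_band_sinusoid_attenuated(self):
        ts = _sinusoid_ts(0.2)
        out = bandpass_filter(ts, 0.009, 0.08)
        assert out.values.var() <= 0.1 * ts.values.var()

    def test_constant_series_zeroed(self):
        ts = TimeSeriesMatrix(np.full((4, 200), 7.5), tr=2.0)
        out = bandpass_filter(ts, 0.009, 0.08)
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        ts = _sinusoid_ts(0.05)
        with pytest.raises(ValueError):
            bandpass_filter(ts, 0.009, 0.3)  # Nyquist is 0.25 Hz at tr=2


class TestNuisanceRegression:
    def test_regressor_replicated_over_nodes_gives_zero(self):
        rng = np.random.default_rng(0)
        reg = rng.standard_normal(100)
        ts = TimeSeriesMatrix(np.tile(reg, (5, 1)), tr=2.0)
        out = regress_nuisance(ts, reg[:, None])
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_orthogonal_regressor_leaves_series_unchanged(self):
        n = 200
        t = np.arange(n)
        series = np.sin(2 * np.pi * t / 50)  # zero-mean
        reg = np.cos(2 * np.pi * t / 50)  # orthogonal over whole periods
        ts = TimeSeriesMatrix(np.tile(series, (3, 1)), tr=2.0)
        out = regress_nuisance(ts, reg[:, None])
        assert np.allclose(out.values, ts.values, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(1)
        ts = TimeSeriesMatrix(rng.standard_normal((10, 80)), tr=2.0)
        reg = rng.standard_normal((80, 3))
        out = regress_nuisance(ts, reg)
        scale = np.abs(ts.values).max() * np.abs(reg).max() * 80
        assert np.abs(out.values @ reg).max() < 1e-8 * scale

    def test_rank_deficient_regressors_warn(self):
        rng = np.random.default_rng(2)
        ts = TimeSeriesMatrix(rng.standard_normal((4, 50)), tr=2.0)
        col = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning):
            regress_nuisance(ts, np.column_stack([col, 2 * col]))


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert np.all(compute_fd(np.zeros((10, 6))) == 0.0)

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[2:, 0] = 0.1  # x jumps by 0.1 mm at transition into frame 2
        fd = compute_fd(m)
        assert fd[1] == pytest.approx(0.1)
        assert fd[0] == 0.0 and np.all(fd[2:] == 0.0)

    def test_rotation_step_scaled_by_radius(self):
        m = np.zeros((4, 6))
        m[1:, 4] = 0.01  # pitch step of 0.01 rad
        fd = compute_fd(m, rotation_radius=50.0)
        assert fd[0] == pytest.approx(0.5)  # 50 mm * 0.01 rad

    def test_non_finite_rejected(self):
        m = np.zeros((5, 6))
        m[3, 2] = np.nan
        with pytest.raises(ValueError):
            compute_fd(m)


class TestDvars:
    def test_constant_matrix_is_zero(self):
        ts = TimeSeriesMatrix(np.full((8, 10), 1000.0), tr=2.0)
        assert np.all(compute_dvars(ts) == 0.0)

    def test_uniform_jump_percent_of_mean(self):
        # 10 frames averaging exactly 1000; every node jumps +10 then -20
        values = np.full((20, 10), 1000.0)
        values[:, 5] = 1010.0
        values[:, 6] = 990.0
        ts = TimeSeriesMatrix(values, tr=2.0)
        dvars = compute_dvars(ts)
        assert dvars[4] == pytest.approx(1.0)
        assert dvars[5] == pytest.approx(2.0)
        assert dvars[6] == pytest.approx(1.0)
        assert np.all(dvars[:4] == 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        v = 500.0 + rng.standard_normal((6, 30))
        a = compute_dvars(TimeSeriesMatrix(v, tr=2.0))
        b = compute_dvars(TimeSeriesMatrix(2 * v, tr=2.0))
        assert np.allclose(a, b)

    def test_node_reordering_invariance(self):
        rng = np.random.default_rng(4)
        v = 100.0 + rng.standard_normal((9, 40))
        perm = rng.permutation(9)
        a = compute_dvars(TimeSeriesMatrix(v, tr=2.0))
        b = compute_dvars(TimeSeriesMatrix(v[perm], tr=2.0))
        assert np.allclose(a, b)

    def test_zero_mean_requires_reference(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((5, 20))
        v -= v.mean()
        with pytest.raises(ValueError):
            compute_dvars(TimeSeriesMatrix(v, tr=2.0))


class TestScrub:
    def test_constructed_spikes_removed_exactly(self):
        ts = _quiet_ts()
        motion = generate_motion_trace(100, spike_frames=[10, 50], spike_fd=1.0, seed=1)
        clean, report = scrub(ts, motion, fd_thresh=0.5, dvars_thresh=0.5)
        assert report.removed_frames == [10, 50]
        assert report.n_removed == 2
        assert clean.n_frames == 98
        assert 10 not in clean.frame_ids and 50 not in clean.frame_ids

    def test_clean_trace_removes_nothing(self):
        ts = _quiet_ts(seed=6)
        motion = generate_motion_trace(100, seed=6)
        _, report = scrub(ts, motion)
        assert report.n_removed == 0

    def test_threshold_boundary(self):
        """One transition at FD 0.6 against the published 0.5 mm threshold."""
        ts = _quiet_ts(n_frames=50, seed=7)
        m = np.zeros((50, 6))
        m[20:, 1] = 0.6
        _, report = scrub(ts, pd.DataFrame(m, columns=list(MOTION_COLUMNS)))
        assert report.removed_frames == [20]

    def test_idempotent_on_scrubbed_data(self):
        ts = _quiet_ts(seed=8)
        motion = generate_motion_trace(100, spike_frames=[10, 50, 51], spike_fd=2.0, seed=8)
        ref = float(np.mean(ts.values))
        clean, report = scrub(ts, motion)
        assert report.n_removed == 3
        keep = np.isin(np.arange(100), clean.frame_ids)
        motion2 = motion.iloc[keep].reset_index(drop=True)
        _, report2 = scrub(clean, motion2, reference_mean=ref)
        assert report2.n_removed == 0

    def test_extension_window(self):
        ts = _quiet_ts(seed=9)
        motion = generate_motion_trace(100, spike_frames=[40], spike_fd=1.0, seed=9)
        _, report = scrub(ts, motion, extend_before=1, extend_after=2)
        assert report.removed_frames == [39, 40, 41, 42]

    def test_all_frames_removed_is_unusable(self):
        # frame 0 never terminates a transition, so total removal needs
        # the extension window
        ts = _quiet_ts(n_frames=5, seed=10)
        motion = generate_motion_trace(5, spike_frames=[1, 2, 3, 4], spike_fd=1.0, seed=10)
        with pytest.raises(UnusableSubjectError):
            scrub(ts, motion, extend_before=1)

    def test_report_json_roundtrip(self, tmp_path):
        ts = _quiet_ts(seed=11)
        motion = generate_motion_trace(100, spike_frames=[30], spike_fd=1.0, seed=11)
        _, report = scrub(ts, motion)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["removed_frames"] == [30]
        assert loaded["n_removed"] == 1
        assert len(loaded["fd"]) == 99


class TestIO:
    def test_timeseries_roundtrip_preserves_frame_ids(self, tmp_path):
        rng = np.random.default_rng(12)
        ts = TimeSeriesMatrix(
            rng.standard_normal((4, 6)), tr=2.0, frame_ids=np.array([0, 2, 3, 5, 8, 9])
        )
        p = tmp_path / "ts.tsv"
        write_timeseries_tsv(ts, p)
        back = read_timeseries_tsv(p, tr=2.0)
        assert np.allclose(back.values, ts.values)
        assert np.array_equal(back.frame_ids, ts.frame_ids)

    def test_motion_roundtrip(self, tmp_path):
        motion = generate_motion_trace(20, seed=13)
        p = tmp_path / "motion.tsv"
        write_motion_tsv(motion, p)
        back = read_motion_tsv(p)
        assert np.allclose(back.to_numpy(), motion.to_numpy())
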