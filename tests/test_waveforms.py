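"""Waveform engine: timebase, trigger, sweeps, trajectories, shutters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sheetctl as sc
from sheetctl.errors import ConfigurationError, RangeError
from sheetctl.waveforms import FLYBACK, rising_edges


class TestTimebase:
    def test_exact_division(self, paper_cfg):
        tb = sc.make_timebase(paper_cfg)
        assert tb.samples_per_frame == 1000
        assert not tb.rate_was_adjusted

    def test_volume_sample_count(self, paper_cfg):
        # 50 planes + 10 flyback frames of 1000 samples each
        tb = sc.make_timebase(paper_cfg)
        assert tb.samples_per_volume == 60_000

    def test_frame_period_ms(self, paper_cfg):
        tb = sc.make_timebase(paper_cfg)
        assert round(tb.frame_period_ms, 1) == 10.2

    def test_rate_adjustment_reported(self):
        cfg = sc.AcquisitionConfig(plane_rate_hz=97.0, sample_rate_hz=98_000)
        tb = sc.make_timebase(cfg)
        assert tb.samples_per_frame == round(98_000 / 97.0)
        assert tb.rate_was_adjusted

    def test_sample_rate_too_low_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.AcquisitionConfig(plane_rate_hz=98.0, sample_rate_hz=5_000)


class TestCameraTrigger:
    def test_one_edge_per_plane(self, paper_cfg):
        tb = sc.make_timebase(paper_cfg)
        trig = sc.build_camera_trigger(tb, paper_cfg)
        assert rising_edges(trig).size == 50

    def test_multi_volume_edge_count(self):
        # a 43-plane volume acquired twice
        cfg = sc.AcquisitionConfig(n_planes=43, flyback_frames=0, n_volumes=2,
                                   sample_rate_hz=9800)
        trig = sc.build_camera_trigger(sc.make_timebase(cfg), cfg)
        assert rising_edges(trig).size == 86

    def test_bidirectional_edges_uniformly_spaced(self):
        cfg = sc.AcquisitionConfig(n_planes=5, flyback_frames=0, n_volumes=2,
                                   scan_mode=sc.ScanMode.BIDIRECTIONAL,
                                   sample_rate_hz=9800)
        tb = sc.make_timebase(cfg)
        edges = rising_edges(sc.build_camera_trigger(tb, cfg))
        assert np.array_equal(edges, np.arange(10) * tb.samples_per_frame)

    def test_no_edges_during_flyback(self, small_cfg):
        tb = sc.make_timebase(small_cfg)
        traj = sc.build_depth_trajectory(tb, small_cfg)
        trig = sc.build_camera_trigger(tb, small_cfg, labels=traj.labels)
        assert not np.any(trig[traj.flyback_mask])

    @pytest.mark.parametrize("mode", ["scan_down", "scan_up", "bidirectional"])
    def test_trigger_conservation_across_modes(self, mode):
        cfg = sc.AcquisitionConfig(n_planes=7, flyback_frames=0, n_volumes=3,
                                   sample_rate_hz=9800).with_mode(mode)
        trig = sc.build_camera_trigger(sc.make_timebase(cfg), cfg)
        assert rising_edges(trig).size == 7 * 3


class TestXSweep:
    def test_zero_width_is_flat(self, calib):
        cfg = sc.AcquisitionConfig(paths=(sc.PathConfig(sheet_width_um=0.0),),
                                   n_planes=2, sample_rate_hz=9800)
        x = sc.build_x_sweep(sc.make_timebase(cfg), cfg, cfg.paths[0], calib)
        assert np.all(x == 0.0)

    def test_three_scans_three_maxima(self, paper_cfg, calib):
        tb = sc.make_timebase(paper_cfg)
        x = sc.build_x_sweep(tb, paper_cfg, paper_cfg.paths[0], calib)
        frame = x[: tb.samples_per_frame]
        strict_max = np.sum((frame[1:-1] > frame[:-2])
                            & (frame[1:-1] > frame[2:]))
        assert strict_max == 3

    def test_amplitude_from_width_and_scale(self, paper_cfg, calib):
        # 500 um sheet at 0.01 V/um -> +/-2.5 V
        tb = sc.make_timebase(paper_cfg)
        x = sc.build_x_sweep(tb, paper_cfg, paper_cfg.paths[0], calib)
        assert x.max() == pytest.approx(2.5)
        assert x.min() == pytest.approx(-2.5)

    def test_frame_boundary_returns_to_start(self, paper_cfg, calib):
        tb = sc.make_timebase(paper_cfg)
        x = sc.build_x_sweep(tb, paper_cfg, paper_cfg.paths[0], calib)
        starts = x[:: tb.samples_per_frame]
        assert np.allclose(starts, starts[0])

    def test_range_error_names_channel(self, paper_cfg):
        hot = sc.CalibrationState(x_scale={1: 0.1, 2: 0.1})  # 25 V amplitude
        with pytest.raises(RangeError, match="x_mirror_path1"):
            sc.build_x_sweep(sc.make_timebase(paper_cfg), paper_cfg,
                             paper_cfg.paths[0], hot)


class TestDepthTrajectory:
    def test_single_plane_constant_zero(self):
        cfg = sc.AcquisitionConfig(n_planes=1, flyback_frames=0,
                                   sample_rate_hz=9800)
        traj = sc.build_depth_trajectory(sc.make_timebase(cfg), cfg)
        assert np.all(traj.depth_um == 0.0)

    def test_scan_up_reverses_plane_sequence(self, paper_cfg):
        tb = sc.make_timebase(paper_cfg)
        down = sc.build_depth_trajectory(tb, paper_cfg)
        up = sc.build_depth_trajectory(tb, paper_cfg.with_mode("scan_up"))
        d = down.depth_um[down.plane_mask]
        u = up.depth_um[up.plane_mask]
        assert u[0] == 98.0 and u[-1] == 0.0
        assert np.array_equal(u, d[::-1])

    def test_bidirectional_depth_sequence(self):
        cfg = sc.AcquisitionConfig(n_planes=3, flyback_frames=0, n_volumes=2,
                                   scan_mode=sc.ScanMode.BIDIRECTIONAL,
                                   z_spacing_um=2.0, sample_rate_hz=9800)
        tb = sc.make_timebase(cfg)
        traj = sc.build_depth_trajectory(tb, cfg)
        per_frame = traj.depth_um[:: tb.samples_per_frame]
        assert np.array_equal(per_frame, [0, 2, 4, 4, 2, 0])

    def test_bidirectional_has_no_flyback_samples(self):
        cfg = sc.AcquisitionConfig(n_planes=4, flyback_frames=3, n_volumes=2,
                                   scan_mode=sc.ScanMode.BIDIRECTIONAL,
                                   sample_rate_hz=9800)
        with pytest.warns(UserWarning, match="flyback"):
            traj = sc.build_depth_trajectory(sc.make_timebase(cfg), cfg)
        assert not np.any(traj.flyback_mask)

    def test_bidirectional_inter_volume_continuity(self):
        cfg = sc.AcquisitionConfig(n_planes=6, flyback_frames=0, n_volumes=4,
                                   scan_mode=sc.ScanMode.BIDIRECTIONAL,
                                   sample_rate_hz=9800)
        tb = sc.make_timebase(cfg)
        traj = sc.build_depth_trajectory(tb, cfg)
        spv = tb.samples_per_volume
        for k in range(3):
            assert traj.depth_um[(k + 1) * spv - 1] == traj.depth_um[(k + 1) * spv]

    def test_flyback_ramp_is_linear_back_to_start(self, paper_cfg):
        tb = sc.make_timebase(paper_cfg)
        traj = sc.build_depth_trajectory(tb, paper_cfg)
        fly = traj.depth_um[traj.labels == FLYBACK]
        assert fly[-1] == 0.0
        assert np.allclose(np.diff(fly), np.diff(fly)[0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(n_planes=st.integers(2, 40), z=st.floats(0.5, 5.0),
           volumes=st.integers(1, 3))
    def test_scan_up_is_time_reverse_of_scan_down(self, n_planes, z, volumes):
        cfg = sc.AcquisitionConfig(n_planes=n_planes, z_spacing_um=z,
                                   flyback_frames=0, n_volumes=volumes,
                                   sample_rate_hz=9800)
        tb = sc.make_timebase(cfg)
        down = sc.build_depth_trajectory(tb, cfg)
        up = sc.build_depth_trajectory(tb, cfg.with_mode("scan_up"))
        assert np.array_equal(up.depth_um, down.depth_um[::-1])


class TestDepthToCommands:
    def test_plane_step_in_millivolts(self, paper_cfg, calib):
        # 2 um steps at 40 mV/um -> 80 mV between consecutive plane levels
        tb = sc.make_timebase(paper_cfg)
        traj = sc.build_depth_trajectory(tb, paper_cfg)
        _, piezo = sc.depth_to_commands(traj, calib)
        levels = piezo[:: tb.samples_per_frame][:50]
        assert np.allclose(np.diff(levels), 0.080)

    def test_constant_depth_gives_offsets(self, calib):
        import dataclasses

        cal = dataclasses.replace(calib, piezo_offset=1.5,
                                  z_offset={1: 0.25, 2: 0.0})
        traj = sc.DepthTrajectory(np.zeros(100), np.zeros(100, dtype=int))
        z, piezo = sc.depth_to_commands(traj, cal)
        assert np.all(z == 0.25) and np.all(piezo == 1.5)

    def test_full_volume_piezo_span(self, paper_cfg, calib):
        # 98 um depth range at 40 mV/um -> 3.92 V span
        tb = sc.make_timebase(paper_cfg)
        traj = sc.build_depth_trajectory(tb, paper_cfg)
        _, piezo = sc.depth_to_commands(traj, calib)
        assert piezo.max() - piezo.min() == pytest.approx(3.92)

    def test_z_and_piezo_proportional_to_same_depth(self, small_cfg, calib):
        tb = sc.make_timebase(small_cfg)
        traj = sc.build_depth_trajectory(tb, small_cfg)
        z, piezo = sc.depth_to_commands(traj, calib)
        varying = traj.depth_um > 0
        r = np.corrcoef(z[varying], piezo[varying])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_range_error_before_emitting(self, calib):
        traj = sc.DepthTrajectory(np.full(10, 400.0), np.zeros(10, dtype=int))
        with pytest.raises(RangeError):
            sc.depth_to_commands(traj, calib, voltage_range_v=10.0)


class TestShutter:
    def test_unmasked_duty_is_one_on_planes(self, small_cfg):
        tb = sc.make_timebase(small_cfg)
        traj = sc.build_depth_trajectory(tb, small_cfg)
        sh = sc.build_shutter(tb, small_cfg, sc.MaskSpec(),
                              small_cfg.paths[0], labels=traj.labels)
        assert np.all(sh[traj.plane_mask] == 1)

    def test_edge_mask_duty_law(self, paper_cfg, edge_mask):
        # triangle position is uniform in time: open fraction = 1 - 2f,
        # up to the 4 mask-boundary samples of each scan
        tb = sc.make_timebase(paper_cfg)
        traj = sc.build_depth_trajectory(tb, paper_cfg)
        sh = sc.build_shutter(tb, paper_cfg, edge_mask, paper_cfg.paths[0],
                              labels=traj.labels)
        per_scan = tb.samples_per_frame / paper_cfg.scans_per_frame
        duty = sh[traj.plane_mask].mean()
        assert abs(duty - 0.8) <= 4.0 / per_scan

    def test_blank_return_closes_all_flyback(self, small_cfg):
        tb = sc.make_timebase(small_cfg)
        traj = sc.build_depth_trajectory(tb, small_cfg)
        sh = sc.build_shutter(tb, small_cfg, sc.MaskSpec(blank_return=True),
                              small_cfg.paths[0], labels=traj.labels)
        assert not np.any(sh[traj.flyback_mask])

    def test_eye_mask_outside_sheet_rejected(self, small_cfg):
        bad = sc.MaskSpec(eye_enabled=True, eye_center_um=240.0,
                          eye_halfwidth_um=50.0)
        with pytest.raises(ConfigurationError):
            sc.build_shutter(sc.make_timebase(small_cfg), small_cfg, bad,
                             small_cfg.paths[0])

    def test_lag_shifts_open_window(self, paper_cfg, edge_mask):
        tb = sc.make_timebase(paper_cfg)
        traj = sc.build_depth_trajectory(tb, paper_cfg)
        sh0 = sc.build_shutter(tb, paper_cfg, edge_mask, paper_cfg.paths[0],
                               lag_s=0.0, labels=traj.labels)
        k = 5
        shk = sc.build_shutter(tb, paper_cfg, edge_mask, paper_cfg.paths[0],
                               lag_s=k * tb.sample_period_s, labels=traj.labels)
        assert np.array_equal(shk[k:], sh0[:-k])


class TestAssemble:
    def test_dual_path_has_eight_channels(self, dual_cfg, calib):
        wfs = sc.assemble_waveforms(dual_cfg, calib)
        assert wfs.n_channels == 8

    def test_single_path_has_five_channels(self, paper_cfg, calib):
        wfs = sc.assemble_waveforms(paper_cfg, calib)
        assert wfs.n_channels == 5
        assert wfs.channel_order[0] == "camera_trigger"
        assert wfs.channel_order[-1] == "piezo"

    def test_plain_recording_length(self, small_cfg, calib):
        tb = sc.make_timebase(small_cfg)
        wfs = sc.assemble_waveforms(small_cfg, calib)
        assert wfs.n_samples == tb.samples_per_volume * small_cfg.n_volumes

    def test_session_triggers_only_inside_recordings(self, small_cfg, calib):
        session = sc.SessionPlan(n_recordings=3, adaptation_enabled=True,
                                 adaptation_depth_um=1.0,
                                 adaptation_duration_s=0.05,
                                 inter_recording_gap_s=0.05)
        wfs = sc.assemble_waveforms(small_cfg, calib, session)
        trig = wfs.channels["camera_trigger"]
        edges = rising_edges(trig)
        assert edges.size == small_cfg.n_planes * small_cfg.n_volumes * 3
        assert np.all(wfs.labels[edges] >= 0)
        # adaptation keeps the sheet on throughout
        sh = wfs.channels["laser_shutter_path1"]
        assert np.all(sh[wfs.labels == sc.waveforms.ADAPTATION] == 1)

    def test_gap_without_adaptation_closes_shutter(self, small_cfg, calib):
        session = sc.SessionPlan(n_recordings=2, inter_recording_gap_s=0.05)
        wfs = sc.assemble_waveforms(small_cfg, calib, session)
        idle = wfs.labels == sc.waveforms.IDLE
        assert idle.sum() > 0
        assert not np.any(wfs.channels["laser_shutter_path1"][idle])

    def test_all_channels_length_equal(self, dual_cfg, calib):
        wfs = sc.assemble_waveforms(dual_cfg, calib)
        assert {c.size for c in wfs.channels.values()} == {wfs.n_samples}

    def test_csv_and_binary_export_roundtrip(self, small_cfg, calib, tmp_path):
        wfs = sc.assemble_waveforms(small_cfg, calib)
        wfs.to_csv(tmp_path / "w.csv")
        loaded = np.loadtxt(tmp_path / "w.csv", delimiter=",", skiprows=1)
        assert loaded.shape == (wfs.n_samples, wfs.n_channels + 1)
        bin_path, hdr_path = wfs.to_binary(tmp_path, "w")
        import json

        hdr = json.loads(hdr_path.read_text())
        arr = np.fromfile(bin_path, dtype=hdr["dtype"]).reshape(hdr["shape"])
        assert np.array_equal(arr, wfs.as_array())
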