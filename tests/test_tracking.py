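"""Detection, linking and filtering of bead trajectories."""
import numpy as np
import pandas as pd
import pytest

from pcmrheo import MediumModel, RenderConfig, SimConfig, TrajectorySet, render_video, simulate_trajectories
from pcmrheo.media import analytic_msd
from pcmrheo.rheology import ensemble_msd
from pcmrheo.tracking import (
    bandpass,
    filter_trajectories,
    link_features,
    locate_features,
    locate_stack,
    static_msd_offset,
)


def _single_spot_image(x, y, shape=(32, 32), peak=5000.0, background=100.0, sigma=1.3, seed=0):
    rng = np.random.default_rng(seed)
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    field = background + peak * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return rng.poisson(field).astype(float)


class TestBandpass:
    def test_flat_field_maps_to_zero(self):
        out = bandpass(np.full((32, 32), 7.5), 1.0, 9)
        assert np.allclose(out, 0.0)

    def test_spot_maximum_preserved(self):
        img = _single_spot_image(15.0, 17.0)
        out = bandpass(img, 1.0, 13)
        iy, ix = np.unravel_index(np.argmax(out), out.shape)
        jy, jx = np.unravel_index(np.argmax(img), img.shape)
        assert abs(iy - jy) <= 1 and abs(ix - jx) <= 1

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 10.0, (64, 64))
        out = bandpass(img, 1.0, 9)
        assert out.var() < img.var()

    def test_scale_validation(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            bandpass(img, 3.0, 2)
        with pytest.raises(ValueError):
            bandpass(img, 1.0, 16)


class TestLocateFeatures:
    def test_subpixel_accuracy_over_noise_realizations(self):
        # SNR ≈ 10 spot: RMS localization error below 0.1 px
        rng = np.random.default_rng(42)
        errors = []
        for i in range(100):
            x = 15.0 + rng.uniform(-0.5, 0.5)
            y = 16.0 + rng.uniform(-0.5, 0.5)
            img = _single_spot_image(x, y, peak=400.0, background=100.0, seed=i)
            feats = locate_features(bandpass(img, 1.0, 17), diameter=9, min_mass=150.0)
            assert len(feats) == 1
            errors.append((feats["x"][0] - x) ** 2 + (feats["y"][0] - y) ** 2)
        rms = np.sqrt(np.mean(errors))
        assert rms < 0.1

    def test_empty_field_gives_no_detections(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(100.0, (32, 32)).astype(float)
        feats = locate_features(bandpass(img, 1.0, 13), diameter=7, min_mass=150.0)
        assert len(feats) == 0

    def test_two_separated_beads(self):
        img = _single_spot_image(10.0, 12.0, shape=(64, 64))
        img += _single_spot_image(45.0, 40.0, shape=(64, 64), background=0.0, seed=3)
        feats = locate_features(bandpass(img, 1.0, 13), diameter=7, min_mass=500.0)
        assert len(feats) == 2
        feats = feats.sort_values("x").reset_index(drop=True)
        assert feats["x"][0] == pytest.approx(10.0, abs=0.2)
        assert feats["x"][1] == pytest.approx(45.0, abs=0.2)

    def test_diameter_validation(self):
        with pytest.raises(ValueError):
            locate_features(np.zeros((16, 16)), diameter=4)


class TestLinkFeatures:
    @staticmethod
    def _walk_features(n_frames=20, x0=10.0, y0=10.0, seed=0):
        rng = np.random.default_rng(seed)
        xs = x0 + np.cumsum(rng.normal(0, 0.3, n_frames))
        ys = y0 + np.cumsum(rng.normal(0, 0.3, n_frames))
        return pd.DataFrame({"frame": np.arange(n_frames), "x": xs, "y": ys})

    def test_single_bead_single_trajectory(self):
        traj = link_features(self._walk_features(), max_disp=5.0, memory=0)
        assert traj.n_trajectories == 1
        assert traj.lengths().iloc[0] == 20

    def test_memory_bridges_single_gap(self):
        feats = self._walk_features()
        feats = feats[feats["frame"] != 10].reset_index(drop=True)
        with_memory = link_features(feats, max_disp=5.0, memory=1)
        without = link_features(feats, max_disp=5.0, memory=0)
        assert with_memory.n_trajectories == 1
        assert without.n_trajectories == 2

    def test_low_density_links_match_ground_truth(self):
        # sparse field, steps far below spacing: ≥ 99% correct links
        rng = np.random.default_rng(7)
        n_beads, n_frames = 20, 50
        x = rng.uniform(10, 190, n_beads)
        y = rng.uniform(10, 190, n_beads)
        rows = []
        for f in range(n_frames):
            if f:
                x = x + rng.normal(0, 0.5, n_beads)
                y = y + rng.normal(0, 0.5, n_beads)
            for b in range(n_beads):
                rows.append((f, x[b], y[b], b))
        feats = pd.DataFrame(rows, columns=["frame", "x", "y", "true_id"])
        linked = link_features(feats[["frame", "x", "y"]], max_disp=5.0, memory=0)
        merged = linked.data.sort_values(["frame", "x_um"]).reset_index(drop=True)
        truth = feats.sort_values(["frame", "x"]).reset_index(drop=True)
        merged["true_id"] = truth["true_id"]
        # a link is correct when consecutive samples of one trajectory
        # carry the same ground-truth identity
        correct = total = 0
        for _, g in merged.groupby("trajectory_id"):
            ids = g.sort_values("frame")["true_id"].to_numpy()
            correct += int((ids[1:] == ids[:-1]).sum())
            total += len(ids) - 1
        assert total >= (n_frames - 1) * n_beads * 0.99
        assert correct / total >= 0.99

    def test_no_duplicate_frames_within_trajectory(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(10), 3),
                "x": rng.uniform(0, 50, 30),
                "y": rng.uniform(0, 50, 30),
            }
        )
        linked = link_features(feats, max_disp=50.0, memory=2)
        dup = linked.data.groupby(["trajectory_id", "frame"]).size()
        assert (dup == 1).all()

    def test_parameter_validation(self):
        feats = self._walk_features()
        with pytest.raises(ValueError):
            link_features(feats, max_disp=0.0)
        with pytest.raises(ValueError):
            link_features(feats.drop(columns=["y"]), max_disp=5.0)


class TestFilterTrajectories:
    @staticmethod
    def _toy_set():
        rows = []
        for tid, n, (cx, cy) in [(0, 10, (0.0, 0.0)), (1, 4, (0.0, 0.0)), (2, 10, (4.0, 0.0))]:
            for f in range(n):
                rows.append((tid, f, f * 0.015, cx + 0.01 * f, cy))
        data = pd.DataFrame(rows, columns=["trajectory_id", "frame", "t_s", "x_um", "y_um"])
        return TrajectorySet(data=data, dt=0.015)

    def test_no_filtering_is_identity(self):
        traj = self._toy_set()
        out = filter_trajectories(traj, min_length=2)
        pd.testing.assert_frame_equal(out.data, traj.data)

    def test_min_length_boundary(self):
        traj = self._toy_set()
        out = filter_trajectories(traj, min_length=5)
        assert set(out.data["trajectory_id"].unique()) == {0, 2}

    def test_center_mask_removes_rim_beads(self):
        # condensate of radius 4 µm at origin: default analysis mask is
        # the half-radius disk, which keeps centre beads only
        traj = self._toy_set()
        out = filter_trajectories(traj, min_length=2, center_mask=(0.0, 0.0, 2.0))
        assert set(out.data["trajectory_id"].unique()) == {0, 1}


class TestRoundTrip:
    def test_tracked_msd_matches_ground_truth(self, bead_grid_trajectories, render_hi_snr):
        medium, traj = bead_grid_trajectories
        stack = render_video(traj, render_hi_snr, seed=3)
        feats = locate_stack(stack, diameter=7, min_mass=500.0)
        linked = link_features(
            feats, max_disp=5.0, memory=3, dt=traj.dt, pixel_size_um=render_hi_snr.pixel_size_um
        )
        linked = filter_trajectories(linked, min_length=90)
        assert linked.n_trajectories == 5
        lags = np.arange(5, 21) * traj.dt
        tracked = ensemble_msd(linked, lag_grid=lags)
        truth = ensemble_msd(traj, lag_grid=lags)
        assert np.all(np.abs(tracked.msd / truth.msd - 1.0) < 0.10)

    def test_stationary_beads_report_noise_floor(self, render_hi_snr):
        # immobilized beads: apparent MSD is the constant 4σ_loc²
        pos = pd.DataFrame(
            {
                "trajectory_id": np.repeat(np.arange(4), 50),
                "frame": np.tile(np.arange(50), 4),
                "t_s": np.tile(np.arange(50) * 0.015, 4),
                "x_um": np.repeat([2.4, 2.4, 7.2, 7.2], 50) + 0.03,
                "y_um": np.repeat([2.4, 7.2, 2.4, 7.2], 50) - 0.02,
            }
        )
        traj = TrajectorySet(data=pos, dt=0.015, pixel_size_um=0.1)
        stack = render_video(traj, render_hi_snr, seed=5)
        feats = locate_stack(stack, diameter=7, min_mass=500.0)
        linked = link_features(feats, max_disp=2.0, memory=0, dt=0.015, pixel_size_um=0.1)
        offset = static_msd_offset(linked)
        assert 0.0 < offset < 1e-3  # well below any bead-motion MSD used here
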