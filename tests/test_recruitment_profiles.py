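"""ROI extraction, peak alignment, normalization, lifetimes and timing."""

import numpy as np
import pandas as pd
import pytest

import pinodyn as p
from pinodyn.io import MovieStack, channel_column
from pinodyn.recruitment_profiles import (
    ProfileParams,
    align_tracks,
    roi_mask_offsets,
)


def one_track(values, channel="phafin2", dt=5.0, **extra_channels):
    n = len(values)
    d = {
        "track_id": 0,
        "frame": np.arange(n),
        "t_s": np.arange(n) * dt,
        "x_px": 10.0,
        "y_px": 10.0,
        "area_um2": 2.0,
        channel_column(channel): values,
    }
    for name, vals in extra_channels.items():
        d[channel_column(name)] = vals
    return pd.DataFrame(d)


class TestRoi:
    def test_mask_matches_exhaustive_enumeration(self):
        offs = roi_mask_offsets(10.0)
        brute = [
            (dy, dx)
            for dy in range(-6, 7)
            for dx in range(-6, 7)
            if dy * dy + dx * dx <= 25.0
        ]
        assert sorted(map(tuple, offs)) == sorted(brute)

    def test_constant_image_returns_value(self):
        movie = MovieStack(
            np.full((3, 1, 32, 32), 42.0), 0.08, 5.0, ["phafin2"]
        )
        track = one_track([0, 0, 0])[["track_id", "frame", "x_px", "y_px"]]
        track[["x_px", "y_px"]] = 16.0
        series = p.extract_roi_intensity(movie, track, ProfileParams())
        assert np.allclose(series.intensities["phafin2"], 42.0)
        assert not series.edge_flags.any()

    def test_half_off_edge_uses_inframe_pixels_and_flags(self):
        data = np.full((1, 1, 32, 32), 5.0)
        movie = MovieStack(data, 0.08, 5.0, ["phafin2"])
        track = pd.DataFrame(
            {"track_id": [0], "frame": [0], "x_px": [0.0], "y_px": [16.0]}
        )
        series = p.extract_roi_intensity(movie, track, ProfileParams())
        assert series.edge_flags[0]
        assert series.intensities["phafin2"][0] == 5.0

    def test_roi_fully_outside_is_error(self):
        movie = MovieStack(np.zeros((1, 1, 32, 32)), 0.08, 5.0, ["phafin2"])
        track = pd.DataFrame(
            {"track_id": [9], "frame": [0], "x_px": [-30.0], "y_px": [-30.0]}
        )
        with pytest.raises(ValueError, match="track 9"):
            p.extract_roi_intensity(movie, track, ProfileParams())


class TestAlign:
    def test_peak_frame_maps_to_zero(self):
        vals = np.zeros(20)
        vals[7] = 1.0
        ens = align_tracks(one_track(vals), "phafin2", ProfileParams())
        mat = ens.profiles["phafin2"]
        assert mat[0].idxmax() == 0
        assert mat.loc[0, 0] == 1.0
        # frame 7 sits at t=0, so the first frame sits at -35 s
        assert ens.times_s()[~mat[0].isna().to_numpy()][0] == -35.0

    def test_tied_maxima_take_earliest(self):
        vals = np.zeros(20)
        vals[4] = vals[9] = 1.0
        ens = align_tracks(one_track(vals), "phafin2", ProfileParams())
        first_defined = (~ens.profiles["phafin2"][0].isna()).idxmax()
        assert first_defined == -4

    def test_short_tracks_excluded_with_count(self):
        long = one_track(np.r_[np.zeros(5), [1.0], np.zeros(14)])
        short = one_track(np.r_[0.0, 1.0, 0.0])
        short["track_id"] = 1
        ens = align_tracks(
            pd.concat([long, short], ignore_index=True),
            "phafin2",
            ProfileParams(),
        )
        assert ens.n_tracks == 1
        assert ens.n_excluded == 1

    def test_jittered_peaks_align_to_zero_sd(self):
        rng = np.random.default_rng(0)
        parts = []
        for tid in range(12):
            vals = np.zeros(30)
            vals[int(rng.integers(3, 13))] = 1.0
            t = one_track(vals)
            t["track_id"] = tid
            parts.append(t)
        ens = align_tracks(
            pd.concat(parts, ignore_index=True), "phafin2", ProfileParams()
        )
        mat = ens.profiles["phafin2"]
        peak_offsets = [mat[c].idxmax() for c in mat.columns]
        assert np.std(peak_offsets) == 0.0

    def test_alignment_idempotent(self):
        k = p.KineticParams(noise_sd=0.02)
        tracks, _ = p.simulate_track_set(k, 10, 60, seed=2)
        ens1 = align_tracks(tracks, "phafin2", ProfileParams())
        ens2 = align_tracks(ens1.to_tracks(), "phafin2", ProfileParams())
        for ch in ens1.channels:
            a = ens1.profiles[ch]
            b = ens2.profiles[ch]
            common = a.index.intersection(b.index)
            pd.testing.assert_frame_equal(
                a.loc[common], b.loc[common], check_dtype=False
            )


class TestNormalize:
    def test_full_range_minmax(self):
        params = ProfileParams(p_low=0, p_high=100)
        scaled, flag = p.normalize_profile(np.array([2.0, 4.0, 6.0]), params)
        assert np.allclose(scaled, [0, 0.5, 1])
        assert not flag

    def test_constant_series_flagged_zero(self):
        scaled, flag = p.normalize_profile(np.full(10, 3.0), ProfileParams())
        assert np.allclose(scaled, 0.0)
        assert flag

    def test_outlier_clipped_at_p99(self):
        x = np.concatenate([np.linspace(0, 1, 200), [50.0]])
        scaled, _ = p.normalize_profile(x, ProfileParams())
        assert scaled[-1] == 1.0
        assert np.nanpercentile(x, 99) < 50.0
        assert np.all((scaled >= 0) & (scaled <= 1))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            p.normalize_profile(np.array([]), ProfileParams())

    def test_ensemble_normalization_bounds(self):
        k = p.KineticParams(noise_sd=0.1)
        tracks, _ = p.simulate_track_set(k, 15, 60, seed=4)
        ens = p.normalize_ensemble(
            align_tracks(tracks, "phafin2", ProfileParams()), ProfileParams()
        )
        for mat in ens.profiles.values():
            vals = mat.to_numpy()
            vals = vals[~np.isnan(vals)]
            assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestAggregate:
    def test_single_track_mean_no_ci(self):
        vals = np.r_[np.zeros(5), [1.0], np.zeros(14)]
        ens = align_tracks(one_track(vals), "phafin2", ProfileParams())
        agg = p.aggregate_profiles(ens)["phafin2"]
        assert np.allclose(agg["mean"].to_numpy(), vals)
        assert agg["ci_low"].isna().all()

    def test_identical_tracks_zero_ci_width(self):
        vals = np.r_[np.zeros(5), [1.0], np.zeros(14)]
        parts = []
        for tid in range(4):
            t = one_track(vals)
            t["track_id"] = tid
            parts.append(t)
        ens = align_tracks(
            pd.concat(parts, ignore_index=True), "phafin2", ProfileParams()
        )
        agg = p.aggregate_profiles(ens)["phafin2"]
        assert np.allclose(agg["ci_high"] - agg["ci_low"], 0.0)


class TestLifetime:
    def test_rectangular_pulse_exact(self):
        x = np.array([0.0] * 6 + [1.0] * 8 + [0.0] * 6)
        est = p.estimate_first_phase_lifetime(x, 5.0, ProfileParams())
        assert est.lifetime_s == pytest.approx(40.0)

    def test_triangular_pulse_half_maximum(self):
        B, dt = 30.0, 1.0
        t = np.arange(0, 121, dt)
        tri = np.clip(1 - np.abs(t - 60) / B, 0, None)
        x = np.concatenate([np.zeros(5), tri])
        exact = p.estimate_first_phase_lifetime(
            x, dt, ProfileParams(lifetime_smooth_frames=1)
        )
        assert exact.lifetime_s == pytest.approx(B, abs=1e-9)
        smoothed = p.estimate_first_phase_lifetime(x, dt, ProfileParams())
        assert smoothed.lifetime_s == pytest.approx(B, rel=0.05)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [np.zeros(6), np.sin(np.linspace(0, np.pi, 9)), np.zeros(6)]
        ) + rng.normal(0, 0.01, 21)
        base = p.estimate_first_phase_lifetime(x, 5.0, ProfileParams())
        shifted = p.estimate_first_phase_lifetime(x + 7.3, 5.0, ProfileParams())
        scaled = p.estimate_first_phase_lifetime(x * 4.2, 5.0, ProfileParams())
        assert shifted.lifetime_s == pytest.approx(base.lifetime_s, abs=1e-9)
        assert scaled.lifetime_s == pytest.approx(base.lifetime_s, abs=1e-9)

    def test_flat_profile_flagged(self):
        est = p.estimate_first_phase_lifetime(np.zeros(20), 5.0, ProfileParams())
        assert np.isnan(est.lifetime_s)
        assert "no_peak" in est.flags


class TestMarkerTiming:
    def test_anchor_channel_peaks_at_zero(self):
        k = p.KineticParams(noise_sd=0.0, success_prob=1.0)
        tracks, _ = p.simulate_track_set(k, 10, 80, seed=6)
        ens = align_tracks(tracks, "phafin2", ProfileParams())
        timing = p.marker_timing(ens, "phafin2")
        assert timing.peak_s == 0.0
        assert timing.onset_s <= 0.0

    def test_companion_offset_recovered(self):
        k = p.KineticParams(
            noise_sd=0.0, success_prob=1.0, marker_offsets_s={"m": 30.0}
        )
        tracks, _ = p.simulate_track_set(k, 10, 80, seed=7)
        ens = align_tracks(tracks, "phafin2", ProfileParams())
        timing = p.marker_timing(ens, "m")
        assert abs(timing.peak_s - 30.0) <= 5.0  # one frame

    def test_marker_order_recovered(self):
        """Anchor pulse onset < companion onsets in the configured order."""
        k = p.KineticParams(
            noise_sd=0.0,
            success_prob=1.0,
            marker_offsets_s={"appl1": 20.0, "rab5": 60.0},
        )
        tracks, _ = p.simulate_track_set(k, 12, 90, seed=8)
        ens = align_tracks(tracks, "phafin2", ProfileParams())
        onsets = {
            ch: p.marker_timing(ens, ch).onset_s
            for ch in ("phafin2", "appl1", "rab5")
        }
        assert onsets["phafin2"] < onsets["appl1"] < onsets["rab5"]

    def test_missing_channel_is_error(self):
        tracks, _ = p.simulate_track_set(p.KineticParams(), 5, 60, seed=9)
        ens = align_tracks(tracks, "phafin2", ProfileParams())
        with pytest.raises(KeyError):
            p.marker_timing(ens, "nope")
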