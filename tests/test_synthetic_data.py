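"""Generator contracts: determinism, kinetic shapes, conservation, fates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pinodyn as p
from pinodyn.io import channel_column


class TestTrackSet:
    def test_empty(self, default_kinetics):
        tracks, gt = p.simulate_track_set(default_kinetics, 0, 50, seed=0)
        assert len(tracks) == 0
        assert gt.vesicles == []

    def test_deterministic_under_fixed_seed(self, default_kinetics):
        a, _ = p.simulate_track_set(default_kinetics, 12, 60, seed=7)
        b, _ = p.simulate_track_set(default_kinetics, 12, 60, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c, _ = p.simulate_track_set(default_kinetics, 12, 60, seed=8)
        assert not a.equals(c)

    def test_pulse_spends_eight_frames_above_half_maximum(self):
        """40 s FWHM sampled at 5 s -> 8 frames above half of (peak - baseline)."""
        k = p.KineticParams(
            noise_sd=0.0, first_phase_duration_s=40.0, frame_interval_s=5.0
        )
        tracks, _ = p.simulate_track_set(k, 20, 80, seed=3)
        for _, g in tracks.groupby("track_id"):
            a = g[channel_column(p.ANCHOR_CHANNEL)].to_numpy()
            thr = k.baseline + 0.5 * (a.max() - k.baseline)
            above = a > thr
            # contiguous run containing the pulse maximum
            i = int(np.argmax(a))
            lo = i
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = i
            while hi < len(a) - 1 and above[hi + 1]:
                hi += 1
            assert hi - lo + 1 == 8

    def test_single_local_maximum_before_phase2(self):
        k = p.KineticParams(noise_sd=0.0, success_prob=1.0)
        tracks, gt = p.simulate_track_set(k, 15, 90, seed=5)
        for ves in gt.vesicles:
            g = tracks[tracks.track_id == ves["id"]].sort_values("frame")
            a = g[channel_column(p.ANCHOR_CHANNEL)].to_numpy()
            stop = np.searchsorted(
                g["frame"].to_numpy(), ves["phase2_onset_frame"]
            )
            seg = a[:stop]
            # plateau-aware: count rises that are immediately followed by a
            # non-increase (the two samples straddling the true peak tie)
            maxima = np.sum((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]))
            assert maxima == 1

    def test_ground_truth_event_ordering_and_fate_semantics(self):
        k = p.KineticParams(noise_sd=0.0)
        tracks, gt = p.simulate_track_set(k, 40, 80, seed=9)
        for ves in gt.vesicles:
            assert ves["birth_frame"] <= ves["sealing_frame"]
            if ves["fate"] == "collapse":
                assert ves["collapse_frame"] is not None
                assert ves["sealing_frame"] <= ves["collapse_frame"]
                g = tracks[tracks.track_id == ves["id"]]
                fyve = g[channel_column(p.ENDOSOMAL_CHANNEL)].to_numpy()
                assert np.allclose(fyve, k.baseline)  # no marker gain

    def test_fate_fraction_matches_success_prob(self):
        k = p.KineticParams(success_prob=0.4)
        _, gt = p.simulate_track_set(k, 1000, 40, seed=21)
        n_succ = sum(v["fate"] == "success" for v in gt.vesicles)
        lo, hi = stats.binom.interval(0.999, 1000, 0.4)
        assert lo <= n_succ <= hi

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            p.KineticParams(frame_interval_s=0)
        with pytest.raises(ValueError):
            p.KineticParams(success_prob=1.5)
        with pytest.raises(ValueError):
            p.simulate_track_set(p.KineticParams(), -1, 10, seed=0)


class TestRenderMovie:
    def test_noise_free_background_only(self):
        img = p.ImageParams(poisson_gain=0.0, read_noise_sd=0.0)
        from pinodyn.io import empty_track_table

        movie, _ = p.render_movie(
            empty_track_table(["v"]), img, seed=0, channels=["v"], n_frames=2
        )
        assert np.all(movie.data == img.background_level)

    def test_disk_area_matches_circle(self):
        """0.5 um disk at 0.08 um px: above-background area ~ pi 0.25 um^2."""
        img = p.ImageParams(
            pixel_size_um=0.08,
            psf_sigma_px=0.0,
            read_noise_sd=0.0,
            poisson_gain=1000.0,
            frame_shape=(64, 64),
        )
        tracks = pd.DataFrame(
            [
                {
                    "track_id": 0,
                    "frame": 0,
                    "t_s": 0.0,
                    "x_px": 32.0,
                    "y_px": 32.0,
                    "area_um2": np.pi * 0.5**2,
                    channel_column("v"): 1.0,
                }
            ]
        )
        movie, _ = p.render_movie(tracks, img, seed=0, apply_noise=False)
        above = movie.data[0, 0] > img.background_level
        area = above.sum() * img.pixel_size_um**2
        r_px = 0.5 / 0.08
        ring = 2 * np.pi * r_px * (img.pixel_size_um**2)  # one pixel ring
        assert abs(area - np.pi * 0.25) <= ring

    def test_photon_sum_conservation_and_gain_linearity(self):
        tracks = pd.DataFrame(
            [
                {
                    "track_id": 0,
                    "frame": 0,
                    "t_s": 0.0,
                    "x_px": 24.0,
                    "y_px": 24.0,
                    "area_um2": 1.0,
                    channel_column("v"): 2.0,
                }
            ]
        )
        sums = {}
        for gain in (500.0, 1000.0):
            img = p.ImageParams(
                poisson_gain=gain,
                read_noise_sd=0.0,
                frame_shape=(48, 48),
                psf_sigma_px=1.0,
            )
            movie, _ = p.render_movie(tracks, img, seed=0, apply_noise=False)
            sums[gain] = (movie.data[0, 0] - img.background_level).sum()
            # noise-free: total photons = intensity x gain (blur conserves sum)
            assert np.isclose(sums[gain], 2.0 * gain, rtol=1e-6)
        assert np.isclose(sums[1000.0], 2 * sums[500.0], rtol=1e-6)

    def test_poisson_sampling_preserves_mean_photon_sum(self):
        tracks = pd.DataFrame(
            [
                {
                    "track_id": 0,
                    "frame": 0,
                    "t_s": 0.0,
                    "x_px": 24.0,
                    "y_px": 24.0,
                    "area_um2": 1.0,
                    channel_column("v"): 1.0,
                }
            ]
        )
        img = p.ImageParams(
            poisson_gain=2000.0, read_noise_sd=0.0, frame_shape=(48, 48)
        )
        totals = []
        for s in range(100):
            movie, _ = p.render_movie(tracks, img, seed=s)
            totals.append((movie.data[0, 0] - img.background_level).sum())
        mean = np.mean(totals)
        # MC mean of a Poisson(2000) sum: sd ~ sqrt(2000/100) ~ 4.5
        assert abs(mean - 2000.0) < 5 * np.sqrt(2000.0 / 100)

    def test_out_of_field_track_named_in_error(self):
        tracks = pd.DataFrame(
            [
                {
                    "track_id": 3,
                    "frame": 0,
                    "t_s": 0.0,
                    "x_px": 500.0,
                    "y_px": 24.0,
                    "area_um2": 1.0,
                    channel_column("v"): 1.0,
                }
            ]
        )
        with pytest.raises(ValueError, match="track 3"):
            p.render_movie(tracks, p.ImageParams(frame_shape=(48, 48)), seed=0)


class TestScissionTraces:
    def test_zero_amplitude_gives_flat_trace_with_truth(self, default_kinetics):
        perf = p.PerfusionParams()
        traces, gt = p.simulate_scission_traces(
            default_kinetics, perf, 3, seed=1, quench_amplitude=0.0
        )
        for tr, ves in zip(traces, gt.vesicles):
            assert np.ptp(tr.quench) == 0.0
            assert ves["sealing_frame"] is not None

    def test_quench_constant_after_sealing(self, default_kinetics):
        perf = p.PerfusionParams()
        traces, gt = p.simulate_scission_traces(
            default_kinetics, perf, 10, seed=2
        )
        for tr, ves in zip(traces, gt.vesicles):
            post = tr.quench[ves["sealing_frame"] :]
            assert np.var(post) == 0.0
            pre = tr.quench[: ves["sealing_frame"]]
            assert np.ptp(pre) > 0.0

    def test_egta_mode_inverts_polarity_same_sealing(self, default_kinetics):
        ph = p.PerfusionParams(polarity="quench-low")
        ca = p.PerfusionParams(polarity="quench-high")
        t_ph, gt_ph = p.simulate_scission_traces(default_kinetics, ph, 5, seed=3)
        t_ca, gt_ca = p.simulate_scission_traces(default_kinetics, ca, 5, seed=3)
        for a, b, va, vb in zip(t_ph, t_ca, gt_ph.vesicles, gt_ca.vesicles):
            assert va["sealing_frame"] == vb["sealing_frame"]
            s = va["sealing_frame"]
            # pre-sealing alternation is mirrored between the two modes
            assert not np.allclose(a.quench[:s], b.quench[:s])
            assert np.allclose(a.quench[:s] + b.quench[:s], a.quench.max() + b.quench.min())

    def test_negative_n_rejected(self, default_kinetics):
        with pytest.raises(ValueError):
            p.simulate_scission_traces(
                default_kinetics, p.PerfusionParams(), -1, seed=0
            )


class TestPopulationAndUptake:
    def test_empty_population(self, default_kinetics):
        df, gt = p.simulate_population(
            default_kinetics, default_kinetics, 0, 5, seed=0
        )
        assert len(df) == 0

    def test_population_reproducible_and_hierarchical(self, default_kinetics):
        ko = p.KineticParams(success_prob=0.2)
        a, _ = p.simulate_population(default_kinetics, ko, 9, 6, seed=4)
        b, _ = p.simulate_population(default_kinetics, ko, 9, 6, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["group"]) == {"wt", "ko"}
        # every cell maps to exactly one experiment
        assert (a.groupby("cell_id")["experiment_id"].nunique() == 1).all()
        assert a["experiment_id"].nunique() == 3

    def test_uptake_zero_puncta(self):
        img = p.ImageParams(frame_shape=(96, 96))
        dex, mem, gt = p.simulate_uptake_image(img, 0, 100.0, seed=0)
        assert gt.extra["photon_sum"] == 0.0

    def test_uptake_noise_free_sum_exact(self):
        img = p.ImageParams(frame_shape=(96, 96))
        dex, mem, gt = p.simulate_uptake_image(
            img, 7, 350.0, seed=5, apply_noise=False
        )
        in_cell = np.array(gt.extra["cell_mask"], dtype=bool)
        measured = (dex - img.background_level)[in_cell].sum()
        assert np.isclose(measured, 7 * 350.0, rtol=1e-9)

    def test_uptake_reproducible(self):
        img = p.ImageParams(frame_shape=(96, 96))
        a, _, _ = p.simulate_uptake_image(img, 5, 100.0, seed=6)
        b, _, _ = p.simulate_uptake_image(img, 5, 100.0, seed=6)
        assert np.array_equal(a, b)
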