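"""Synthetic macropinosome dynamics with ground truth.

Generates the data the analysis stages assume, at track level (per-frame
intensity tables), image level (rendered multi-channel movies and endpoint
uptake images) and trace level (alternating-quench scission traces), each
paired with a :class:`~pinodyn.io.GroundTruth` record of the true event
times, fates and kinetic parameters so every estimator can be tested by
parameter recovery.

The kinetic template is biphasic reporter recruitment: a vesicle is born
near the cell periphery by scission of a macropinocytic cup, the anchor
reporter (Phafin2-like) shows a short raised-cosine pulse whose full width
at half maximum is the configured first-phase duration (~40 s), companion
markers (APPL1/RAB5-like) follow with configured onset offsets, and — on
vesicles that successfully gain endosomal identity — a slow logistic second
phase rises to a plateau.  Failed vesicles collapse back to the plasma
membrane after the first phase with no marker gain.

The first-phase pulse peak is placed midway between two frame samples, so
sampling straddles the true maximum symmetrically; at 40 s FWHM and 5 s
frames the sampled pulse spends exactly 8 frames above half-maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .io import GroundTruth, MovieStack, channel_column, empty_track_table
from .scission_assay import PerfusionParams, ScissionTrace

#: Name of the anchor (biphasic) reporter channel in generated tables.
ANCHOR_CHANNEL = "phafin2"
#: Name of the endosomal-identity marker channel (2xFYVE-like).
ENDOSOMAL_CHANNEL = "fyve"

#: Default log-normal (mu, sigma) of vesicle radius in micrometres;
#: median radius 0.8 um -> median first-frame area ~2 um^2, comfortably
#: above the 0.64 um^2 macropinosome floor.
DEFAULT_RADIUS_LOGNORMAL = (math.log(0.8), 0.25)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class KineticParams:
    """Kinetics of biphasic reporter recruitment on one vesicle.

    Times are seconds, intensities arbitrary units.  Defaults encode the
    study conditions: 5 s frames, ~40 s first-phase lifetime, ~40% success.
    """

    frame_interval_s: float = 5.0
    first_phase_duration_s: float = 40.0  # FWHM of the pulse
    first_phase_amplitude: float = 1.0
    gap_s: float = 60.0  # phase-1 end -> phase-2 onset
    second_phase_rise_s: float = 30.0  # logistic time constant
    second_phase_amplitude: float = 0.8
    marker_offsets_s: dict[str, float] = field(
        default_factory=lambda: {"appl1": 20.0, "rab5": 60.0}
    )
    baseline: float = 0.1
    noise_sd: float = 0.0
    success_prob: float = 0.4
    collapse_delay_s: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "frame_interval_s",
            "first_phase_duration_s",
            "gap_s",
            "second_phase_rise_s",
            "collapse_delay_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValueError("success_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KineticParams":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class ImageParams:
    """Rendering geometry, optics and camera noise for synthetic movies."""

    pixel_size_um: float = 0.08
    frame_shape: tuple[int, int] = (128, 128)  # (height, width)
    psf_sigma_px: float = 1.0
    background_level: float = 100.0
    poisson_gain: float = 200.0  # photons emitted per unit track intensity
    read_noise_sd: float = 2.0
    vesicle_radius_um_lognormal: tuple[float, float] = DEFAULT_RADIUS_LOGNORMAL
    min_analysis_area_um2: float = 0.64

    #: Light-sheet preset pixel size (91 nm final pixel).
    LIGHT_SHEET_PIXEL_UM = 0.091

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if min(self.frame_shape) < 32:
            raise ValueError("frame_shape dims must be >= 32")
        if self.min_analysis_area_um2 < 0:
            raise ValueError("min_analysis_area_um2 must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImageParams":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        if "vesicle_radius_um_lognormal" in d:
            d["vesicle_radius_um_lognormal"] = tuple(
                d["vesicle_radius_um_lognormal"]
            )
        return cls(**d)


# ---------------------------------------------------------------------------
# kinetic building blocks


def raised_cosine_pulse(
    t: np.ndarray, t_peak: float, fwhm: float, amplitude: float
) -> np.ndarray:
    """Smooth pulse with full width at half maximum ``fwhm`` (base 2*fwhm)."""
    tau = t - t_peak
    out = np.zeros_like(t, dtype=float)
    inside = np.abs(tau) <= fwhm
    out[inside] = 0.5 * amplitude * (1.0 + np.cos(np.pi * tau[inside] / fwhm))
    return out


def logistic_rise(
    t: np.ndarray, t_half: float, tau: float, amplitude: float
) -> np.ndarray:
    """Logistic rise to a plateau; half-maximum crossed at ``t_half``."""
    return amplitude / (1.0 + np.exp(-(t - t_half) / tau))


# ---------------------------------------------------------------------------
# track-level simulation


def simulate_track_set(
    kinetics: KineticParams,
    n_tracks: int,
    duration_frames: int,
    seed: int,
    *,
    field_shape_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.08,
    radius_lognormal: tuple[float, float] = DEFAULT_RADIUS_LOGNORMAL,
    motion_sd_px: float = 0.3,
    pre_frames: int = 5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-frame intensity tables for a set of vesicle tracks.

    Returns a tidy track table (one row per track x frame with columns
    ``track_id, frame, t_s, x_px, y_px, area_um2, ch_*_mean``) and the
    ground truth of every event frame.  Identical (params, seed) pairs give
    bit-identical output.
    """
    if n_tracks < 0:
        raise ValueError("n_tracks must be >= 0")
    if duration_frames < 1:
        raise ValueError("duration_frames must be >= 1")
    rng = np.random.default_rng(seed)
    dt = kinetics.frame_interval_s
    fwhm = kinetics.first_phase_duration_s
    n_fwhm = max(1, round(fwhm / dt))

    channels = [ANCHOR_CHANNEL, ENDOSOMAL_CHANNEL] + list(
        kinetics.marker_offsets_s
    )
    gt = GroundTruth(params=_params_dict(kinetics), seed=seed)
    if n_tracks == 0:
        return empty_track_table(channels), gt

    h, w = field_shape_px
    margin = 12.0
    rows: list[pd.DataFrame] = []
    for tid in range(n_tracks):
        # Birth early enough that the whole biphasic program (pulse, gap and
        # the phase-2 rise to its midpoint) fits inside the movie, so no
        # event is censored by the acquisition window.
        tail = (
            pre_frames
            + 2 * n_fwhm
            + math.ceil(kinetics.gap_s / dt)
            + math.ceil(2 * kinetics.second_phase_rise_s / dt)
        )
        max_birth = max(1, duration_frames - tail)
        birth = int(rng.integers(1, max_birth + 1))
        fate = "success" if rng.random() < kinetics.success_prob else "collapse"

        # The track records `pre_frames` of baseline before the pulse rises;
        # the true pulse peak sits midway between two frames (see module docs).
        peak_frame = birth + pre_frames + n_fwhm
        t_peak = (peak_frame + 0.5) * dt
        phase1_end_s = t_peak + fwhm
        phase2_onset_frame = None
        collapse_frame = None
        if fate == "success":
            end_frame = duration_frames - 1
            t_half2 = phase1_end_s + kinetics.gap_s + 2 * kinetics.second_phase_rise_s
            phase2_onset_frame = int(round((phase1_end_s + kinetics.gap_s) / dt))
        else:
            collapse_frame = min(
                duration_frames - 1,
                int(round(phase1_end_s / dt))
                + max(1, round(kinetics.collapse_delay_s / dt)),
            )
            end_frame = collapse_frame

        frames = np.arange(birth, end_frame + 1)
        t = frames * dt

        anchor = kinetics.baseline + raised_cosine_pulse(
            t, t_peak, fwhm, kinetics.first_phase_amplitude
        )
        fyve = np.full_like(t, kinetics.baseline)
        companions = {
            name: np.full_like(t, kinetics.baseline)
            for name in kinetics.marker_offsets_s
        }
        if fate == "success":
            # Logistic rise, truncated to exactly zero before phase-2 onset
            # so the first phase is strictly the only pre-onset signal.
            rise = np.where(
                t < phase1_end_s + kinetics.gap_s,
                0.0,
                logistic_rise(
                    t,
                    t_half2,
                    kinetics.second_phase_rise_s,
                    kinetics.second_phase_amplitude,
                ),
            )
            anchor = anchor + rise
            fyve = fyve + rise
            for name, off in kinetics.marker_offsets_s.items():
                companions[name] = companions[name] + raised_cosine_pulse(
                    t, t_peak + off, fwhm, kinetics.first_phase_amplitude
                )

        radius_um = float(rng.lognormal(*radius_lognormal))
        area = np.full_like(t, math.pi * radius_um**2)
        if fate == "collapse":
            # Area decays during the collapse (vesicle recedes to the membrane).
            decay_start = int(round(phase1_end_s / dt))
            decaying = frames >= decay_start
            span = max(1, end_frame - decay_start)
            frac = 1.0 - 0.9 * (frames[decaying] - decay_start) / span
            area[decaying] = area[decaying] * np.clip(frac, 0.1, 1.0)

        # Random-walk centroid starting away from the field edge.
        x0 = rng.uniform(margin, w - 1 - margin)
        y0 = rng.uniform(margin, h - 1 - margin)
        steps = rng.normal(0.0, motion_sd_px, size=(len(frames), 2))
        steps[0] = 0.0
        path = np.cumsum(steps, axis=0) + (x0, y0)
        path[:, 0] = np.clip(path[:, 0], margin, w - 1 - margin)
        path[:, 1] = np.clip(path[:, 1], margin, h - 1 - margin)

        table = pd.DataFrame(
            {
                "track_id": tid,
                "frame": frames,
                "t_s": t,
                "x_px": path[:, 0],
                "y_px": path[:, 1],
                "area_um2": area,
            }
        )
        series = {ANCHOR_CHANNEL: anchor, ENDOSOMAL_CHANNEL: fyve, **companions}
        for name in channels:
            vals = series[name]
            if kinetics.noise_sd > 0:
                vals = vals + rng.normal(0.0, kinetics.noise_sd, size=len(vals))
            table[channel_column(name)] = vals
        rows.append(table)

        gt.vesicles.append(
            {
                "id": tid,
                "birth_frame": birth,
                "sealing_frame": birth,
                "fate": fate,
                "collapse_frame": collapse_frame,
                "peak_frame": peak_frame,
                "peak_time_s": t_peak,
                "phase2_onset_frame": phase2_onset_frame,
                "radius_um": radius_um,
                "path_px": path.tolist(),
                "path_um": (path * pixel_size_um).tolist(),
            }
        )

    tracks = pd.concat(rows, ignore_index=True)
    return tracks, gt


# ---------------------------------------------------------------------------
# image-level rendering


def _disk_offsets(radius_px: float) -> np.ndarray:
    """Integer (dy, dx) offsets whose pixel centers lie within radius_px."""
    r = int(math.ceil(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius_px**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def render_movie(
    tracks: pd.DataFrame,
    image: ImageParams,
    seed: int,
    *,
    channels: Sequence[str] | None = None,
    n_frames: int | None = None,
    frame_interval_s: float = 5.0,
    apply_noise: bool = True,
) -> tuple[MovieStack, GroundTruth]:
    """Render a track table into a multi-channel movie.

    Each vesicle contributes a uniform disk of its current radius whose
    total expected photon count is ``intensity x poisson_gain``; the disk
    is blurred with a Gaussian PSF (sum-preserving), Poisson shot noise is
    applied to the photon image, and a constant camera background plus
    Gaussian read noise is added.  ``apply_noise=False`` returns the
    noise-free expectation image.
    """
    rng = np.random.default_rng(seed)
    h, w = image.frame_shape
    if channels is None:
        from .io import channels_in_table

        channels = channels_in_table(tracks)
    if n_frames is None:
        n_frames = int(tracks["frame"].max()) + 1 if len(tracks) else 1

    if len(tracks):
        bad = tracks[
            (tracks["x_px"] < 0)
            | (tracks["x_px"] > w - 1)
            | (tracks["y_px"] < 0)
            | (tracks["y_px"] > h - 1)
        ]
        if len(bad):
            tid = int(bad["track_id"].iloc[0])
            raise ValueError(
                f"track {tid} has centroids outside the {h}x{w} field"
            )

    data = np.zeros((n_frames, len(channels), h, w), dtype=float)
    if len(tracks):
        for _, row in tracks.iterrows():
            f = int(row["frame"])
            if f >= n_frames:
                continue
            radius_px = math.sqrt(row["area_um2"] / math.pi) / image.pixel_size_um
            cy, cx = int(round(row["y_px"])), int(round(row["x_px"]))
            offs = _disk_offsets(radius_px)
            if len(offs) == 0:
                offs = np.array([[0, 0]])
            ys = np.clip(offs[:, 0] + cy, 0, h - 1)
            xs = np.clip(offs[:, 1] + cx, 0, w - 1)
            for ci, ch in enumerate(channels):
                flux = float(row[channel_column(ch)]) * image.poisson_gain
                np.add.at(data[f, ci], (ys, xs), flux / len(offs))

    if image.psf_sigma_px > 0:
        data = ndimage.gaussian_filter(
            data, sigma=(0, 0, image.psf_sigma_px, image.psf_sigma_px)
        )
    if apply_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    data += image.background_level
    if apply_noise and image.read_noise_sd > 0:
        data += rng.normal(0.0, image.read_noise_sd, size=data.shape)

    movie = MovieStack(
        data=data,
        pixel_size_um=image.pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=list(channels),
    )
    gt = GroundTruth(params=_params_dict(image), seed=seed)
    for tid, g in tracks.groupby("track_id") if len(tracks) else []:
        gt.vesicles.append(
            {
                "id": int(tid),
                "frames": g["frame"].astype(int).tolist(),
                "x_px": g["x_px"].tolist(),
                "y_px": g["y_px"].tolist(),
                "area_um2": g["area_um2"].tolist(),
            }
        )
    return movie, gt


# ---------------------------------------------------------------------------
# scission traces


def simulate_scission_traces(
    kinetics: KineticParams,
    perfusion: PerfusionParams,
    n: int,
    seed: int,
    *,
    duration_frames: int = 80,
    quench_amplitude: float = 0.8,
    recruit_lag_s: float = 10.0,
    sealing_frame_range: tuple[int, int] | None = None,
) -> tuple[list[ScissionTrace], GroundTruth]:
    """Simulate alternating-quench reporter traces with known sealing times.

    Before sealing the quench reporter follows the external buffer square
    wave (bright/dark every half-period); after sealing it holds the bright
    (unquenched) level.  ``polarity="quench-high"`` mirrors the alternation
    (EGTA/Ca2+ mode).  The recruitment channel rises logistically with its
    half-maximum at ``sealing + recruit_lag_s``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ratio_a = perfusion.half_period_s / kinetics.frame_interval_s
    ratio_b = kinetics.frame_interval_s / perfusion.half_period_s
    if (
        abs(ratio_a - round(ratio_a)) > 1e-9
        and abs(ratio_b - round(ratio_b)) > 1e-9
    ):
        raise ValueError(
            "perfusion half-period and frame interval must be integer "
            "multiples of one another"
        )
    rng = np.random.default_rng(seed)
    dt = kinetics.frame_interval_s
    t = np.arange(duration_frames) * dt
    fph = perfusion.half_period_s / dt

    if sealing_frame_range is None:
        lo = int(math.ceil(8 * max(fph, 1)))  # leave >= 4 pre-seal periods
        hi = max(lo + 1, duration_frames - int(math.ceil(8 * max(fph, 1))))
        sealing_frame_range = (lo, hi)

    high = 1.0
    low = high - quench_amplitude
    # Square wave: buffer phase at each sample time.
    phase = (np.floor(t / perfusion.half_period_s).astype(int)) % 2
    if perfusion.polarity == "quench-high":
        phase = 1 - phase
    wave = np.where(phase == 0, high, low)

    traces: list[ScissionTrace] = []
    gt = GroundTruth(
        params={**_params_dict(kinetics), **_params_dict(perfusion)}, seed=seed
    )
    for i in range(n):
        seal = int(rng.integers(*sealing_frame_range))
        quench = wave.copy()
        quench[seal:] = high  # sealed lumen no longer follows the buffer
        recruit = kinetics.baseline + logistic_rise(
            t,
            seal * dt + recruit_lag_s,
            kinetics.second_phase_rise_s / 6.0,
            kinetics.first_phase_amplitude,
        )
        if kinetics.noise_sd > 0:
            quench = quench + rng.normal(0, kinetics.noise_sd, duration_frames)
            recruit = recruit + rng.normal(0, kinetics.noise_sd, duration_frames)
        traces.append(
            ScissionTrace(
                quench=quench, recruit=recruit, frame_interval_s=dt, trace_id=i
            )
        )
        gt.vesicles.append(
            {
                "id": i,
                "sealing_frame": seal,
                "recruit_half_rise_s": seal * dt + recruit_lag_s,
            }
        )
    return traces, gt


# ---------------------------------------------------------------------------
# population-level simulation


def simulate_population(
    wt: KineticParams,
    ko: KineticParams,
    n_cells_per_group: int,
    tracks_per_cell: int | Sequence[int],
    seed: int,
    *,
    labels: tuple[str, str] = ("wt", "ko"),
    n_experiments: int = 3,
    radius_lognormal: tuple[float, float] = DEFAULT_RADIUS_LOGNORMAL,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-cell fate and size records for two genotype groups.

    ``tracks_per_cell`` is either a Poisson mean (int) or an explicit
    per-cell sequence.  Output rows are one per track with columns
    ``experiment_id, cell_id, group, track_id, fate, first_area_um2``;
    cells are assigned round-robin to ``n_experiments`` experiments, so the
    hierarchical track -> cell -> experiment structure is preserved.
    """
    if labels[0] == labels[1]:
        raise ValueError("group labels must be distinct")
    if n_cells_per_group < 0:
        raise ValueError("n_cells_per_group must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[dict[str, Any]] = []
    gt = GroundTruth(
        params={labels[0]: _params_dict(wt), labels[1]: _params_dict(ko)},
        seed=seed,
    )
    next_track = 0
    for label, kin in zip(labels, (wt, ko)):
        for ci in range(n_cells_per_group):
            if np.isscalar(tracks_per_cell):
                k = int(rng.poisson(tracks_per_cell))
            else:
                k = int(tracks_per_cell[ci])
            exp_id = f"exp{ci % n_experiments + 1}"
            cell_id = f"{label}_cell{ci}"
            for _ in range(k):
                fate = (
                    "success" if rng.random() < kin.success_prob else "collapse"
                )
                radius = float(rng.lognormal(*radius_lognormal))
                records.append(
                    {
                        "experiment_id": exp_id,
                        "cell_id": cell_id,
                        "group": label,
                        "track_id": next_track,
                        "fate": fate,
                        "first_area_um2": math.pi * radius**2,
                    }
                )
                gt.vesicles.append(
                    {
                        "id": next_track,
                        "cell_id": cell_id,
                        "group": label,
                        "fate": fate,
                        "radius_um": radius,
                    }
                )
                next_track += 1
    cols = [
        "experiment_id",
        "cell_id",
        "group",
        "track_id",
        "fate",
        "first_area_um2",
    ]
    df = pd.DataFrame(records, columns=cols)
    return df, gt


# ---------------------------------------------------------------------------
# uptake endpoint images


def _gaussian_kernel(sigma: float, half: int) -> np.ndarray:
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return k / k.sum()  # exact unit sum so photon counts are conserved


def simulate_uptake_image(
    image: ImageParams,
    n_puncta: int,
    punctum_photons: float,
    seed: int,
    *,
    apply_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Simulate a dextran-uptake endpoint image pair for one cell.

    Returns ``(dextran, membrane, ground_truth)``.  A single elliptical
    cell sits centred in the field; the membrane channel shows a bright
    outline (segmentation guide) and the dextran channel contains
    ``n_puncta`` discrete puncta of ``punctum_photons`` photons each placed
    strictly inside the cell, over a uniform camera background.  Ground
    truth stores the true cell mask, background level and in-cell photon
    sum.
    """
    if n_puncta < 0:
        raise ValueError("n_puncta must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2 + rng.uniform(-h * 0.05, h * 0.05), w / 2 + rng.uniform(
        -w * 0.05, w * 0.05
    )
    ry, rx = h * 0.32, w * 0.30
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    # Membrane channel: bright rim of the cell mask.
    rim = mask & ~ndimage.binary_erosion(mask, iterations=2)
    membrane = np.full((h, w), image.background_level, dtype=float)
    membrane[rim] += 10.0 * max(image.background_level, 1.0)
    membrane[mask & ~rim] += 0.5 * max(image.background_level, 1.0)

    kern_half = 3
    kern = _gaussian_kernel(1.2, kern_half)
    interior = ndimage.binary_erosion(mask, iterations=kern_half + 2)
    iy, ix = np.nonzero(interior)
    signal = np.zeros((h, w), dtype=float)
    centers = []
    for _ in range(n_puncta):
        j = int(rng.integers(len(iy)))
        py, px = int(iy[j]), int(ix[j])
        signal[
            py - kern_half : py + kern_half + 1,
            px - kern_half : px + kern_half + 1,
        ] += kern * punctum_photons
        centers.append((px, py))

    if apply_noise:
        signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
    dextran = signal + image.background_level
    if apply_noise and image.read_noise_sd > 0:
        dextran = dextran + rng.normal(0, image.read_noise_sd, size=(h, w))
        membrane = membrane + rng.normal(0, image.read_noise_sd, size=(h, w))

    gt = GroundTruth(
        params=_params_dict(image),
        seed=seed,
        extra={
            "cell_mask": mask.astype(int).tolist(),
            "background_level": image.background_level,
            "photon_sum": float(n_puncta) * float(punctum_photons),
            "puncta_xy": centers,
        },
    )
    return dextran, membrane, gt


# ---------------------------------------------------------------------------
# helpers


def _params_dict(params: Any) -> dict[str, Any]:
    import dataclasses

    d = dataclasses.asdict(params)
    return {k: v for k, v in d.items()}


def with_overrides(params: KineticParams, **kw: Any) -> KineticParams:
    """A copy of ``params`` with fields replaced (convenience for sweeps)."""
    return replace(params, **kw)
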