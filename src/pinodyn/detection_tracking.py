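"""Vesicle detection, track linking, and macropinosome size/formation metrics.

Detection is multi-scale Laplacian-of-Gaussian blob finding with a local
Otsu region grown at each blob site for the area measurement; linking is
greedy gated nearest-neighbour with gap closing.  Downstream filters encode
the macropinosome criteria: first-appearance area >= 0.64 um^2 for the size
analysis, and equivalent diameter > 1 um within a 20 min window for
formation counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from .io import channel_column


@dataclass
class DetectionParams:
    """Detector, linker and macropinosome-filter settings.

    ``blob_scale_um`` brackets the vesicle radii searched by the LoG
    detector; ``detection_threshold`` is in robust-noise (MAD) units of the
    normalized image.  Linking gates displacement at
    ``max_displacement_um`` per frame step and closes gaps up to
    ``max_gap_frames``.  ``min_analysis_area_um2`` (0.64) and
    ``min_formation_diameter_um`` (1.0) with ``formation_window_s`` (20
    min) are the macropinosome selection criteria.
    """

    blob_scale_um: tuple[float, float] = (0.3, 1.5)
    detection_threshold: float = 4.0
    max_displacement_um: float = 1.0
    max_gap_frames: int = 2
    min_analysis_area_um2: float = 0.64
    min_formation_diameter_um: float = 1.0
    formation_window_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.blob_scale_um[0] <= 0 or self.blob_scale_um[1] <= self.blob_scale_um[0]:
            raise ValueError("blob_scale_um must be a non-empty (lo, hi) range")
        if self.detection_threshold < 0 or self.max_displacement_um < 0:
            raise ValueError("thresholds must be >= 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class Detection:
    """One detected vesicle in one frame."""

    frame: int
    x_px: float
    y_px: float
    area_um2: float
    intensities: dict[str, float] = field(default_factory=dict)


def equivalent_diameter_um(area_um2: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the circle with the given area: d = 2 sqrt(A / pi)."""
    return 2.0 * np.sqrt(np.asarray(area_um2, dtype=float) / math.pi)


def equivalent_area_um2(diameter_um: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`equivalent_diameter_um`: A = pi (d/2)^2."""
    return math.pi * (np.asarray(diameter_um, dtype=float) / 2.0) ** 2


def _robust_sigma(img: np.ndarray) -> float:
    """Noise scale as 1.4826 x median absolute deviation from the median."""
    med = np.median(img)
    return 1.4826 * float(np.median(np.abs(img - med)))


def detect_vesicles(
    frame_image: np.ndarray,
    pixel_size_um: float,
    params: DetectionParams,
    *,
    measure_channels: dict[str, np.ndarray] | None = None,
) -> list[Detection]:
    """Detect vesicles in one single-channel 2D frame.

    The image is normalized to robust-noise units; LoG maxima above
    ``detection_threshold`` seed detections, and each blob's area is the
    Otsu-thresholded connected region in a local window around it,
    converted to um^2 with ``pixel_size_um**2``.  ``measure_channels``
    optionally maps channel names to same-shaped images over which region
    mean intensities are recorded.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("a positive pixel_size_um calibration is required")
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_vesicles expects a single-channel 2D image")

    sigma_noise = _robust_sigma(img)
    if sigma_noise == 0.0:
        return []  # constant (or near-constant) image: nothing to detect
    normed = (img - np.median(img)) / sigma_noise

    # blob radius r relates to LoG sigma as r = sigma * sqrt(2)
    min_sigma = max(1.0, params.blob_scale_um[0] / pixel_size_um / math.sqrt(2))
    max_sigma = max(min_sigma + 0.5, params.blob_scale_um[1] / pixel_size_um / math.sqrt(2))
    blobs = blob_log(
        normed,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=8,
        threshold=0.2,
        overlap=0.5,
    )
    # Amplitude gate on a lightly smoothed image: the LoG threshold above is
    # permissive; acceptance is decided in robust-noise units here.
    smoothed = ndimage.gaussian_filter(normed, 1.0)

    detections: list[Detection] = []
    h, w = img.shape
    for by, bx, bsigma in blobs:
        if smoothed[int(round(by)), int(round(bx))] < params.detection_threshold:
            continue
        r_win = int(max(4, round(3 * bsigma)))
        y0, y1 = max(0, int(by) - r_win), min(h, int(by) + r_win + 1)
        x0, x1 = max(0, int(bx) - r_win), min(w, int(bx) + r_win + 1)
        window = img[y0:y1, x0:x1]
        if np.ptp(window) == 0:
            continue
        try:
            thr = threshold_otsu(window)
        except ValueError:
            continue
        binary = window > thr
        labels, _ = ndimage.label(binary)
        lab = labels[int(round(by)) - y0, int(round(bx)) - x0]
        if lab == 0:
            # blob center fell between thresholded pixels; take nearest region
            if not binary.any():
                continue
            yy, xx = np.nonzero(binary)
            j = np.argmin((yy - (by - y0)) ** 2 + (xx - (bx - x0)) ** 2)
            lab = labels[yy[j], xx[j]]
        region = labels == lab
        area_um2 = float(region.sum()) * pixel_size_um**2
        ys, xs = np.nonzero(region)
        weights = window[region] - window[~region].mean() if (~region).any() else window[region]
        weights = np.clip(weights, 1e-12, None)
        cx = float(np.average(xs, weights=weights)) + x0
        cy = float(np.average(ys, weights=weights)) + y0

        intensities = {}
        if measure_channels:
            for name, chan in measure_channels.items():
                intensities[name] = float(np.asarray(chan, dtype=float)[y0:y1, x0:x1][region].mean())
        detections.append(
            Detection(frame=0, x_px=cx, y_px=cy, area_um2=area_um2, intensities=intensities)
        )
    return detections


def detect_movie(
    movie, channel: str, params: DetectionParams
) -> list[list[Detection]]:
    """Run :func:`detect_vesicles` on every frame of a movie channel."""
    stack = movie.channel(channel)
    others = {
        name: movie.channel(name)
        for name in movie.channel_names
    }
    per_frame: list[list[Detection]] = []
    for f in range(movie.n_frames):
        dets = detect_vesicles(
            stack[f],
            movie.pixel_size_um,
            params,
            measure_channels={k: v[f] for k, v in others.items()},
        )
        for d in dets:
            d.frame = f
        per_frame.append(dets)
    return per_frame


def link_tracks(
    detections_per_frame: Sequence[Sequence[Detection]],
    params: DetectionParams,
    pixel_size_um: float,
    frame_interval_s: float = 5.0,
) -> pd.DataFrame:
    """Link per-frame detections into tracks by greedy gated assignment.

    Candidate (track, detection) pairs within the displacement gate
    (``max_displacement_um`` per elapsed frame) are assigned greedily in
    order of increasing distance, ties broken toward the lower track id;
    tracks unmatched for more than ``max_gap_frames`` frames are closed,
    and unmatched detections seed new tracks.  Returns a track table in
    the shared CSV schema.
    """
    active: list[dict] = []  # each: track_id, last detection, last frame, rows
    finished: list[dict] = []
    next_id = 0
    rows: list[dict] = []

    for f, dets in enumerate(detections_per_frame):
        dets = list(dets)
        # close tracks that exceeded the gap allowance
        still = []
        for tr in active:
            if f - tr["last_frame"] > params.max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        pairs = []
        for ti, tr in enumerate(active):
            elapsed = f - tr["last_frame"]
            gate = params.max_displacement_um * elapsed / pixel_size_um
            for di, d in enumerate(dets):
                dist = math.hypot(d.x_px - tr["x"], d.y_px - tr["y"])
                if dist <= gate:
                    pairs.append((dist, tr["track_id"], ti, di))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, _tid, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            d = dets[di]
            tr.update(last_frame=f, x=d.x_px, y=d.y_px)
            rows.append(_track_row(tr["track_id"], d, f, frame_interval_s))
        for di, d in enumerate(dets):
            if di in used_d:
                continue
            tr = {
                "track_id": next_id,
                "last_frame": f,
                "x": d.x_px,
                "y": d.y_px,
            }
            next_id += 1
            active.append(tr)
            rows.append(_track_row(tr["track_id"], d, f, frame_interval_s))

    cols = ["track_id", "frame", "t_s", "x_px", "y_px", "area_um2"]
    if rows:
        df = pd.DataFrame(rows)
        ordered = cols + [c for c in df.columns if c not in cols]
        return df[ordered].sort_values(["track_id", "frame"]).reset_index(drop=True)
    return pd.DataFrame(columns=cols)


def _track_row(track_id: int, d: Detection, frame: int, dt: float) -> dict:
    row = {
        "track_id": track_id,
        "frame": frame,
        "t_s": frame * dt,
        "x_px": d.x_px,
        "y_px": d.y_px,
        "area_um2": d.area_um2,
    }
    for name, v in d.intensities.items():
        row[channel_column(name)] = v
    return row


def first_frame_areas(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track first-appearance area (the size before fusion/fission).

    Returns one row per track with ``track_id, first_frame, first_area_um2``
    and, when present, the ``cell_id`` label.
    """
    if len(tracks) == 0:
        cols = ["track_id", "first_frame", "first_area_um2"]
        return pd.DataFrame(columns=cols)
    firsts = tracks.sort_values("frame").groupby("track_id").first()
    out = pd.DataFrame(
        {
            "track_id": firsts.index,
            "first_frame": firsts["frame"].astype(int),
            "first_area_um2": firsts["area_um2"].astype(float),
        }
    ).reset_index(drop=True)
    if "cell_id" in tracks.columns:
        out["cell_id"] = firsts["cell_id"].values
    return out


def measure_and_filter_sizes(
    tracks: pd.DataFrame, params: DetectionParams
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """First-frame sizes, the macropinosome-filtered subset, per-cell means.

    Vesicles with first-appearance area below ``min_analysis_area_um2``
    (0.64 um^2) are filtered out (the boundary value is kept); per-cell
    mean sizes are computed over retained tracks only, and cells with no
    retained track are excluded (reported via the ``attrs['empty_cells']``
    list).
    """
    sizes = first_frame_areas(tracks)
    retained = sizes[sizes["first_area_um2"] >= params.min_analysis_area_um2]
    if "cell_id" in sizes.columns and len(sizes):
        per_cell = (
            retained.groupby("cell_id")["first_area_um2"]
            .agg(mean_size_um2="mean", n_tracks="count")
            .reset_index()
        )
        empty = sorted(set(sizes["cell_id"]) - set(retained["cell_id"]))
    else:
        per_cell = pd.DataFrame(columns=["cell_id", "mean_size_um2", "n_tracks"])
        empty = []
    per_cell.attrs["empty_cells"] = empty
    return sizes, retained.reset_index(drop=True), per_cell


def count_new_macropinosomes(
    tracks: pd.DataFrame, params: DetectionParams
) -> pd.DataFrame:
    """Newly formed macropinosomes per cell within the formation window.

    A formation event is a track whose first-frame equivalent diameter
    exceeds ``min_formation_diameter_um`` (1 um) and whose birth time falls
    inside ``formation_window_s`` (20 min).  Returns ``cell_id, n_formed``.
    """
    sizes = first_frame_areas(tracks)
    if len(sizes) == 0:
        return pd.DataFrame(columns=["cell_id", "n_formed"])
    if "cell_id" not in sizes.columns:
        sizes = sizes.assign(cell_id="cell0")
    birth_t = tracks.sort_values("frame").groupby("track_id")["t_s"].first()
    sizes = sizes.assign(birth_t_s=birth_t.loc[sizes["track_id"]].values)
    diam = equivalent_diameter_um(sizes["first_area_um2"].to_numpy())
    formed = sizes[
        (diam > params.min_formation_diameter_um)
        & (sizes["birth_t_s"] <= params.formation_window_s)
    ]
    counts = formed.groupby("cell_id").size().rename("n_formed").reset_index()
    all_cells = pd.DataFrame({"cell_id": sorted(sizes["cell_id"].unique())})
    return all_cells.merge(counts, on="cell_id", how="left").fillna(
        {"n_formed": 0}
    ).astype({"n_formed": int})
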