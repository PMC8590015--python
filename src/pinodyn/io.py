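"""Containers and file formats shared by all pipeline stages.

Movies are multi-page TIFF stacks with axis order T x C x Y x X and a JSON
sidecar carrying the physical calibration; tracks travel as tidy CSV tables
so that simulated and real data share one schema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

#: Columns every track table carries, in order; per-channel mean-intensity
#: columns follow as ``ch_<name>_mean``.
TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_px", "y_px", "area_um2"]


def channel_column(name: str) -> str:
    """Column name holding the mean intensity of channel *name*."""
    return f"ch_{name}_mean"


def channels_in_table(tracks: pd.DataFrame) -> list[str]:
    """Channel names present in a track table, in column order."""
    return [
        c[len("ch_") : -len("_mean")]
        for c in tracks.columns
        if c.startswith("ch_") and c.endswith("_mean")
    ]


@dataclass
class MovieStack:
    """A multi-channel 2D time-lapse with physical calibration.

    Parameters
    ----------
    data
        Pixel data, shape ``(T, C, Y, X)``.
    pixel_size_um
        Lateral pixel size in micrometres.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_names
        One name per channel, length ``C``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be T x C x Y x X, got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """The ``(T, Y, X)`` stack of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[:, idx]

    def save(self, tiff_path: str | Path) -> None:
        """Write the stack as 16-bit TIFF plus a calibration sidecar JSON."""
        tiff_path = Path(tiff_path)
        clipped = np.clip(np.rint(self.data), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(tiff_path, clipped.astype(np.uint16))
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channel_names": list(self.channel_names),
            "axes": "TCYX",
        }
        tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, tiff_path: str | Path) -> "MovieStack":
        tiff_path = Path(tiff_path)
        sidecar_path = tiff_path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"calibration sidecar {sidecar_path} is required"
            )
        meta = json.loads(sidecar_path.read_text())
        data = tifffile.imread(tiff_path)
        if data.ndim == 3:  # single channel stored without a C axis
            data = data[:, None]
        return cls(
            data=data,
            pixel_size_um=meta["pixel_size_um"],
            frame_interval_s=meta["frame_interval_s"],
            channel_names=list(meta["channel_names"]),
        )


@dataclass
class GroundTruth:
    """Simulator record of true events and parameters, for recovery tests.

    ``vesicles`` holds one dict per simulated object (birth/sealing/collapse
    frames, fate, kinetic truth); ``params`` echoes the generator settings;
    ``extra`` carries generator-specific arrays (e.g. a true cell mask).
    """

    vesicles: list[dict[str, Any]] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Per-vesicle records as a DataFrame (empty frame if no vesicles)."""
        return pd.DataFrame(self.vesicles)

    def to_json(self, path: str | Path) -> None:
        def _default(o: Any) -> Any:
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"cannot serialize {type(o)}")

        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), default=_default, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def empty_track_table(channels: list[str] | None = None) -> pd.DataFrame:
    cols = TRACK_COLUMNS + [channel_column(c) for c in (channels or [])]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols}).astype(
        {"track_id": int, "frame": int}, errors="ignore"
    )


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track CSV, checking the mandatory schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    return df


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.to_csv(path, index=False)
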