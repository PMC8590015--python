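import numpy as np
import pandas as pd
import pytest

from pinodyn.io import channel_column


@pytest.fixture
def default_kinetics():
    from pinodyn import KineticParams

    return KineticParams()


def constant_intensity_tracks(
    rng: np.random.Generator,
    n_vesicles: int,
    n_frames: int,
    field: int,
    *,
    min_sep_px: float = 30.0,
    radius_um_range: tuple[float, float] = (0.5, 0.9),
    step_sd_px: float = 0.3,
    channel: str = "v",
    frame_interval_s: float = 5.0,
) -> pd.DataFrame:
    """Well-separated constant-brightness tracks for rendering fixtures."""
    pts: list[np.ndarray] = []
    while len(pts) < n_vesicles:
        cand = rng.uniform(18, field - 19, size=2)
        if all(np.hypot(*(cand - q)) >= min_sep_px for q in pts):
            pts.append(cand)
    rows = []
    for i, start in enumerate(pts):
        steps = rng.normal(0, step_sd_px, size=(n_frames, 2))
        steps[0] = 0
        path = np.clip(start + np.cumsum(steps, axis=0), 12, field - 13)
        r_um = rng.uniform(*radius_um_range)
        for f in range(n_frames):
            rows.append(
                {
                    "track_id": i,
                    "frame": f,
                    "t_s": f * frame_interval_s,
                    "x_px": path[f, 0],
                    "y_px": path[f, 1],
                    "area_um2": np.pi * r_um**2,
                    channel_column(channel): 1.0,
                }
            )
    return pd.DataFrame(rows)
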