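"""Sealing-time inference from alternating-quench reporter traces.

A surface-displayed pH-sensitive reporter (pHuji) is alternately quenched
and unquenched by perfusing buffers at pH 5.5 / 7.5 every 5 s; once the
macropinocytic cup seals into a closed vesicle its lumen no longer follows
the external pH and the oscillation stops.  The calcium-sensor variant
(GCaMP6 quenched by EGTA, unquenched by calcium) behaves identically with
inverted polarity.  Sealing is detected as the first sustained loss of
demodulated oscillation amplitude; recruitment signals are then re-aligned
to the sealing frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

# Fraction of the trace range below which a reference amplitude is treated
# as "never oscillated" (pre-sealed vesicle).
_FLAT_REL_TOL = 1e-6


@dataclass
class PerfusionParams:
    """Perfusion protocol and sealing-call rule.

    half_period_s
        Duration of each buffer phase; the study alternated every 5 s.
    polarity
        ``"quench-low"``: the quenching buffer darkens the reporter (pH
        mode).  ``"quench-high"``: inverted (EGTA/Ca2+ mode traces are
        mirrored).  The sealing call is amplitude-based and therefore
        polarity-independent.
    amplitude_drop_fraction
        Oscillation is considered lost once the windowed amplitude falls
        below this fraction of the pre-sealing reference amplitude.
    confirm_windows
        Number of consecutive sub-threshold windows required to call
        sealing (guards against single noisy windows).
    """

    half_period_s: float = 5.0
    polarity: Literal["quench-low", "quench-high"] = "quench-low"
    amplitude_drop_fraction: float = 0.25
    confirm_windows: int = 2

    def __post_init__(self) -> None:
        if self.half_period_s <= 0:
            raise ValueError("half_period_s must be positive")
        if not 0 < self.amplitude_drop_fraction < 1:
            raise ValueError("amplitude_drop_fraction must be in (0, 1)")
        if self.confirm_windows < 1:
            raise ValueError("confirm_windows must be >= 1")


@dataclass
class ScissionTrace:
    """One vesicle's reporter traces under alternating quench."""

    quench: np.ndarray
    recruit: np.ndarray
    frame_interval_s: float
    trace_id: int = 0
    sealing_frame: int | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.quench = np.asarray(self.quench, dtype=float)
        self.recruit = np.asarray(self.recruit, dtype=float)
        if self.quench.shape != self.recruit.shape:
            raise ValueError("quench and recruit series must be equal length")
        if self.sealing_frame is not None and not (
            0 <= self.sealing_frame < len(self.quench)
        ):
            raise ValueError("sealing_frame outside trace")

    @property
    def n_frames(self) -> int:
        return len(self.quench)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_frames) * self.frame_interval_s
        return pd.DataFrame(
            {
                "trace_id": self.trace_id,
                "frame": np.arange(self.n_frames),
                "t_s": t,
                "quench": self.quench,
                "recruit": self.recruit,
            }
        )


def _frames_per_half(trace: ScissionTrace, perfusion: PerfusionParams) -> int:
    ratio = perfusion.half_period_s / trace.frame_interval_s
    fph = int(round(ratio))
    if fph < 1 or abs(ratio - fph) > 1e-9:
        raise ValueError(
            "perfusion half-period must be an integer multiple (>= 1) of the "
            f"frame interval to resolve the oscillation; got ratio {ratio}"
        )
    return fph


def _window_amplitudes(
    x: np.ndarray, fph: int, phase_offset: int
) -> tuple[np.ndarray, np.ndarray]:
    """Signed demodulated amplitude of each sliding two-period window.

    Frames are classified into the two buffer phases by the square wave
    with the given phase offset (in frames); the window statistic is
    mean(phase A) - mean(phase B).  Keeping the sign (the phase/sign
    convention is fixed per trace during registration) keeps pure post-
    sealing noise centred on zero instead of folding it to positive
    amplitudes.  Returns (window start frames, signed amplitudes); stride
    is one half-period.
    """
    n = len(x)
    win = 4 * fph  # two full periods
    if n < win:
        return np.array([], dtype=int), np.array([])
    phase = ((np.arange(n) + phase_offset) // fph) % 2
    starts = np.arange(0, n - win + 1, fph)
    amps = np.empty(len(starts))
    for i, s in enumerate(starts):
        seg = x[s : s + win]
        ph = phase[s : s + win]
        amps[i] = seg[ph == 0].mean() - seg[ph == 1].mean()
    return starts, amps


def detect_sealing_frame(
    trace: ScissionTrace, perfusion: PerfusionParams
) -> int | None:
    """Infer the frame at which the vesicle sealed, or ``None``.

    The quench channel is demodulated against the perfusion square wave in
    sliding two-period windows; sealing is called at the start of the first
    run of ``confirm_windows`` windows whose amplitude drops below
    ``amplitude_drop_fraction`` x the pre-sealing reference amplitude
    (median amplitude of the first four periods).  The square wave's phase
    relative to the frame clock is estimated from the trace itself.

    Side effects: sets ``trace.sealing_frame`` and quality flags.
    """
    fph = _frames_per_half(trace, perfusion)
    x = trace.quench
    if len(x) < 8 * fph:  # at least four perfusion periods
        raise ValueError(
            f"trace of {len(x)} frames spans fewer than 4 perfusion periods"
        )

    # Phase/sign registration: pick the offset (and implicit sign) that
    # maximizes the median demodulated amplitude over the early trace.
    best = None
    for off in range(2 * fph):
        starts, amps = _window_amplitudes(x, fph, off)
        early = amps[: max(1, min(len(amps), 4))]
        for sign in (1.0, -1.0):
            score = float(np.median(sign * early)) if len(early) else 0.0
            if best is None or score > best[0]:
                best = (score, off, starts, sign * amps)
    _, _, starts, amps = best

    ref_window = starts < 8 * fph  # first four periods
    ref_amp = float(np.median(amps[ref_window])) if ref_window.any() else 0.0
    span = float(np.ptp(x))
    if span == 0.0 or ref_amp <= _FLAT_REL_TOL * span:
        trace.flags["pre_sealed"] = True
        trace.sealing_frame = 0
        return 0

    # Gate: the first run of confirm_windows windows below the drop
    # threshold decides THAT sealing occurred (and roughly where).
    thresh = perfusion.amplitude_drop_fraction * ref_amp
    k = perfusion.confirm_windows
    call = None
    for i in range(len(amps) - k + 1):
        if np.all(amps[i : i + k] < thresh):
            call = i
            break
    if call is None:
        trace.flags["no_sealing"] = True
        trace.sealing_frame = None
        return None

    # Refine WHEN by a frame-domain step fit: adjacent demodulation windows
    # share most of their frames, so window-level rules can be pulled a
    # full period off by a single noisy frame.  Fitting the trace itself
    # to "square wave before sealing, constant after" and taking the
    # least-squares change point localizes sealing to the last frame that
    # still followed the buffer.
    n = len(x)
    f0 = int(starts[call])
    off = best[1]  # registered phase offset
    phase = ((np.arange(n) + off) // fph) % 2
    pre = np.arange(n) < max(f0, 4 * fph)
    lvl = {}
    for ph in (0, 1):
        sel = pre & (phase == ph)
        lvl[ph] = float(np.median(x[sel])) if sel.any() else float(np.median(x))
    wave_model = np.where(phase == 0, lvl[0], lvl[1])
    tail = x[f0 + 4 * fph :]
    post_level = float(np.median(tail)) if len(tail) else max(lvl.values())

    lo = max(0, f0 - 8 * fph)
    hi = min(n, f0 + 8 * fph)
    best_s, best_sse = f0, np.inf
    for s in range(lo, hi + 1):
        model = np.where(np.arange(n) < s, wave_model, post_level)
        sse = float(((x - model) ** 2).sum())
        if sse < best_sse:
            best_s, best_sse = s, sse
    trace.sealing_frame = int(best_s)
    return int(best_s)
    trace.flags["no_sealing"] = True
    trace.sealing_frame = None
    return None


def align_to_sealing(
    traces: Sequence[ScissionTrace],
    perfusion: PerfusionParams,
    min_tracks_for_ci: int = 3,
) -> pd.DataFrame:
    """Sealing-relative ensemble of the recruitment channel.

    Each trace is re-indexed so t = 0 falls at its sealing frame (detected
    on demand if not already set); traces without a sealing call are
    excluded and counted in the output attrs.  Returns a tidy frame with
    per-timepoint mean and Student-t 95% CI, as for recruitment ensembles.
    """
    from .recruitment_profiles import _mean_ci  # shared CI convention

    usable: list[tuple[int, np.ndarray]] = []
    n_excluded = 0
    for tr in traces:
        if tr.sealing_frame is None:
            detect_sealing_frame(tr, perfusion)
        if tr.sealing_frame is None:
            n_excluded += 1
            continue
        usable.append((tr.sealing_frame, tr.recruit))
    if not usable:
        raise ValueError("no traces with a detected sealing frame")

    dt = traces[0].frame_interval_s
    lo = min(-s for s, _ in usable)
    hi = max(len(r) - 1 - s for s, r in usable)
    offsets = np.arange(lo, hi + 1)
    mat = np.full((len(usable), len(offsets)), np.nan)
    for i, (s, r) in enumerate(usable):
        mat[i, (np.arange(len(r)) - s) - lo] = r

    mean, ci_lo, ci_hi, n = _mean_ci(mat, min_tracks_for_ci)
    out = pd.DataFrame(
        {
            "t_s": offsets * dt,
            "mean": mean,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
            "n": n,
        }
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def read_traces(path, frame_interval_s: float | None = None) -> list[ScissionTrace]:
    """Read traces from a CSV with columns trace_id, frame, t_s, quench, recruit."""
    df = pd.read_csv(path)
    traces = []
    for tid, g in df.groupby("trace_id"):
        g = g.sort_values("frame")
        dt = frame_interval_s
        if dt is None:
            tvals = g["t_s"].to_numpy()
            dt = float(tvals[1] - tvals[0]) if len(tvals) > 1 else 1.0
        traces.append(
            ScissionTrace(
                quench=g["quench"].to_numpy(),
                recruit=g["recruit"].to_numpy(),
                frame_interval_s=dt,
                trace_id=int(tid),
            )
        )
    return traces
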