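"""Pupil-trace preprocessing: artifact rejection, downsampling, filtering,
epoching and baseline correction.

The fixed order of operations is: mark invalid samples -> downsample to
20 Hz -> 500 ms square-window filter -> epoch and baseline-correct.
Excluded samples are dropped, never interpolated; every downstream mean is
validity-weighted.

Exclusion rules (applied to the raw 500 Hz trace):

* pupil unrealistically small, < 0.1 mm (blinks/signal loss);
* pupil more than 1 mm from the median of its trial;
* rate of change faster than 25 mm/s — the surrounding 20 ms window
  (±10 ms around both bracketing samples) is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PupilTrace",
    "Epoch",
    "PreprocessConfig",
    "mark_invalid",
    "downsample",
    "square_window_filter",
    "epoch_and_baseline",
    "preprocess_session",
]

logger = logging.getLogger(__name__)

MIN_PUPIL_MM = 0.1
MAX_DEV_FROM_MEDIAN_MM = 1.0
MAX_VELOCITY_MM_S = 25.0
VELOCITY_WINDOW_S = 0.020


@dataclass
class PupilTrace:
    """Uniformly sampled pupil/gaze recording with a validity mask."""

    time: np.ndarray  # s
    pupil: np.ndarray  # mm
    gaze_x: np.ndarray  # deg
    gaze_y: np.ndarray  # deg
    sampling_rate: float  # Hz
    valid: np.ndarray = None  # bool

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.pupil = np.asarray(self.pupil, float)
        self.gaze_x = np.asarray(self.gaze_x, float)
        self.gaze_y = np.asarray(self.gaze_y, float)
        if self.valid is None:
            self.valid = np.ones(len(self.time), dtype=bool)
        self.valid = np.asarray(self.valid, bool)
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be strictly increasing and uniform")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pupil_mm": self.pupil,
                "gaze_x_deg": self.gaze_x,
                "gaze_y_deg": self.gaze_y,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sampling_rate: float | None = None) -> "PupilTrace":
        t = df["time_s"].to_numpy(float)
        if sampling_rate is None:
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(
            time=t,
            pupil=df["pupil_mm"].to_numpy(float),
            gaze_x=df["gaze_x_deg"].to_numpy(float),
            gaze_y=df["gaze_y_deg"].to_numpy(float),
            sampling_rate=float(sampling_rate),
            valid=df["valid"].to_numpy(bool) if "valid" in df else None,
        )


@dataclass
class Epoch:
    """One trial's baseline-corrected time course, aligned to stimulus onset."""

    trial_id: int
    rel_time: np.ndarray  # s from onset
    pupil: np.ndarray  # mm, baseline-corrected
    valid: np.ndarray
    condition: dict = field(default_factory=dict)
    baseline_mm: float = 0.0


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate_hz: float = 20.0
    filter_window_ms: float = 500.0
    filter_mode: str = "smooth"  # "smooth" (literal convolution) or "subtract"
    epoch_pre_s: float = 1.0
    epoch_post_s: float = 7.0
    baseline_ms: float = 200.0


def mark_invalid(trace: PupilTrace, events: pd.DataFrame | None = None) -> np.ndarray:
    """Validity mask after the three artifact-rejection rules.

    The trial median for the 1 mm rule is computed over each trial's raw
    span (onset - 1 s to offset + 1 s) when ``events`` is given, else over
    the whole trace.  Returns the new mask (existing invalidity is kept:
    masks only grow).
    """
    p = trace.pupil
    n = len(p)
    bad = ~trace.valid.copy()

    bad |= p < MIN_PUPIL_MM

    if events is not None and len(events):
        for _, ev in events.iterrows():
            sel = (trace.time >= ev["onset_s"] - 1.0) & (trace.time <= ev["offset_s"] + 1.0)
            if sel.any():
                med = np.median(p[sel])
                bad[sel] |= np.abs(p[sel] - med) > MAX_DEV_FROM_MEDIAN_MM
    else:
        med = np.median(p)
        bad |= np.abs(p - med) > MAX_DEV_FROM_MEDIAN_MM

    if n > 1:
        dt = 1.0 / trace.sampling_rate
        v = np.abs(np.diff(p)) / dt
        fast = v > MAX_VELOCITY_MM_S  # attributed to both bracketing samples
        if fast.any():
            half = int(round(VELOCITY_WINDOW_S / 2 / dt))
            hit = np.zeros(n, dtype=bool)
            hit[:-1] |= fast
            hit[1:] |= fast
            idx = np.flatnonzero(hit)
            for i in idx:
                bad[max(0, i - half): i + half + 1] = True

    return ~bad


def downsample(trace: PupilTrace, mask: np.ndarray | None = None,
               target_rate: float = 20.0) -> PupilTrace:
    """Bin-average to ``target_rate``; bins with no valid sample are invalid."""
    mask = trace.valid if mask is None else np.asarray(mask, bool)
    factor = trace.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target_rate must divide the sampling rate evenly")
    factor = int(round(factor))
    n_out = len(trace.pupil) // factor
    if n_out == 0:
        raise ValueError("trace shorter than one output bin")

    def bin_mean(x):
        xm = np.where(mask[: n_out * factor], x[: n_out * factor], 0.0).reshape(n_out, factor)
        w = mask[: n_out * factor].reshape(n_out, factor).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(w > 0, xm.sum(axis=1) / np.maximum(w, 1), np.nan), w

    p, w = bin_mean(trace.pupil)
    gx, _ = bin_mean(trace.gaze_x)
    gy, _ = bin_mean(trace.gaze_y)
    t = trace.time[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    return PupilTrace(time=t, pupil=p, gaze_x=gx, gaze_y=gy,
                      sampling_rate=target_rate, valid=w > 0)


def square_window_filter(trace: PupilTrace, window_ms: float = 500.0,
                         mode: str = "smooth") -> PupilTrace:
    """Validity-aware convolution with a unit-area square window.

    ``mode='smooth'`` is the literal stated operation (a moving average);
    ``mode='subtract'`` removes the moving average instead (a true
    high-pass), provided as a non-default alternative.
    """
    dt = 1.0 / trace.sampling_rate
    w = max(1, int(round(window_ms / 1000.0 / dt)))
    if w < 1:
        raise ValueError("window must cover at least one sample")
    kernel = np.ones(w)
    v = trace.valid.astype(float)
    num = np.convolve(np.where(trace.valid, trace.pupil, 0.0), kernel, mode="same")
    den = np.convolve(v, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        sm = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    if mode == "smooth":
        p = sm
    elif mode == "subtract":
        p = np.where(trace.valid, trace.pupil - sm, np.nan)
    else:
        raise ValueError("mode must be 'smooth' or 'subtract'")
    return replace(trace, pupil=p, valid=trace.valid & (den > 0))


def epoch_and_baseline(
    trace: PupilTrace,
    events: pd.DataFrame,
    pre: float = 1.0,
    post: float = 7.0,
    baseline_ms: float = 200.0,
) -> list[Epoch]:
    """Cut per-trial epochs on a common relative-time grid and subtract each
    trial's mean pupil over the ``baseline_ms`` before stimulus onset.

    Epochs whose baseline window holds no valid sample are dropped with a
    logged warning.  Events outside the trace span raise ValueError.
    """
    dt = 1.0 / trace.sampling_rate
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    rel = np.arange(-n_pre, n_post) * dt
    n_bl = max(1, int(round(baseline_ms / 1000.0 / dt)))
    out: list[Epoch] = []
    cond_cols = [c for c in events.columns if c not in ("trial", "onset_s", "offset_s")]
    for _, ev in events.iterrows():
        onset = float(ev["onset_s"])
        i_on = int(np.searchsorted(trace.time, onset))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > len(trace.pupil):
            raise ValueError(f"trial {ev.get('trial')} extends outside the trace span")
        p = trace.pupil[i0:i1].copy()
        v = trace.valid[i0:i1].copy()
        bl_slice = slice(n_pre - n_bl, n_pre)
        bl_valid = v[bl_slice]
        if not bl_valid.any():
            logger.warning("dropping trial %s: no valid baseline samples", ev.get("trial"))
            continue
        baseline = float(np.mean(p[bl_slice][bl_valid]))
        out.append(
            Epoch(
                trial_id=int(ev.get("trial", len(out))),
                rel_time=rel.copy(),
                pupil=np.where(v, p - baseline, np.nan),
                valid=v,
                condition={c: ev[c] for c in cond_cols},
                baseline_mm=baseline,
            )
        )
    return out


def preprocess_session(
    trace: PupilTrace,
    events: pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
) -> list[Epoch]:
    """Full fixed-order pipeline: mask -> downsample -> filter -> epoch."""
    mask = mark_invalid(trace, events)
    ds = downsample(trace, mask, target_rate=config.target_rate_hz)
    filt = square_window_filter(ds, window_ms=config.filter_window_ms, mode=config.filter_mode)
    return epoch_and_baseline(
        filt, events, pre=config.epoch_pre_s, post=config.epoch_post_s,
        baseline_ms=config.baseline_ms,
    )


def epochs_to_frame(epochs: list[Epoch]) -> pd.DataFrame:
    """Tidy long-format export (trial, condition columns, rel_time_s, pupil_mm, valid)."""
    rows = []
    for e in epochs:
        df = pd.DataFrame({
            "trial": e.trial_id,
            "rel_time_s": e.rel_time,
            "pupil_mm": e.pupil,
            "valid": e.valid.astype(int),
        })
        for k, v in e.condition.items():
            df[k] = v
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["trial", "rel_time_s", "pupil_mm", "valid"]
    )
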