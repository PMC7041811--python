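"""Stride segmentation, per-stride statistics and trial aggregation.

At trot the trunk bounces twice per stride: the vertical displacement of the
sacrum shows two minima per stride, while pelvic roll completes exactly one
cycle.  Stride boundaries are therefore placed at every second minimum of
the (low-pass filtered) vertical sacrum trajectory, choosing the minima at
which pelvic roll is increasing so that each interval spans one full stride
starting at a consistent phase.

A trial ("trot-up") is summarised per stride — range of motion (max - min)
for the oscillating angles, signed mean for head swivel, body tracking and
speed — and then aggregated to a single measurement record.  Measurements
with five or fewer complete strides are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .io_markers import MarkerConfig, MarkerFrameSeries
from .kinematics import (
    AngleSeries,
    DegenerateGeometryError,
    HorseFrame,
    MEAN_PARAMETERS,
    compute_angles,
    heading_frame,
    lean_correct,
    lowpass_filter,
    pelvic_angles,
    _fill_gaps,
)

__all__ = [
    "StrideSegmentation",
    "TrialResult",
    "segment_strides",
    "per_stride_values",
    "aggregate_measurement",
    "analyze_trial",
    "circle_diameter",
    "MIN_STRIDES",
]

logger = logging.getLogger(__name__)

#: A measurement needs more than five complete strides to be kept
#: (discard when complete strides <= 5).
MIN_STRIDES = 6


@dataclass
class StrideSegmentation:
    """Ordered, non-overlapping half-open frame intervals, one per stride."""

    intervals: list[tuple[int, int]]
    sampling_rate: float

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if not start < end:
                raise ValueError("empty stride interval")
            if start < prev_end:
                raise ValueError("stride intervals overlap or are unordered")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        """Per-stride duration in seconds: (end - start) / rate."""
        return np.array([(e - s) / self.sampling_rate for s, e in self.intervals])


def segment_strides(
    sacrum_z: np.ndarray,
    pelvic_roll: AngleSeries | np.ndarray,
    sampling_rate: float,
    min_amplitude_mm: float = 5.0,
    smooth_cutoff_hz: float = 10.0,
) -> StrideSegmentation:
    """Segment a trial into strides from sacrum height and pelvic roll.

    Candidate boundaries are the minima of the low-pass filtered vertical
    sacrum displacement (two per stride at trot); the boundary set is the
    subset where pelvic roll (one cycle per stride) is increasing.  Returns
    an empty segmentation — not an exception — when no oscillation of at
    least ``min_amplitude_mm`` half-range is present or the trial is shorter
    than 2 s.
    """
    z = np.asarray(sacrum_z, dtype=float)
    roll = pelvic_roll.values if isinstance(pelvic_roll, AngleSeries) else np.asarray(pelvic_roll, float)
    n = len(z)
    empty = StrideSegmentation([], sampling_rate)
    if n < 2 * sampling_rate:
        return empty
    if smooth_cutoff_hz < sampling_rate / 2:
        z = lowpass_filter(z, smooth_cutoff_hz, sampling_rate)
        roll = lowpass_filter(roll, smooth_cutoff_hz, sampling_rate)
    zd = z - z.mean()
    if (zd.max() - zd.min()) / 2.0 < min_amplitude_mm:
        return empty

    # Dominant oscillation frequency (~2x stride frequency) sets the minimum
    # spacing between the candidate minima.
    spec = np.abs(np.fft.rfft(zd))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    usable = freqs > 0.5  # ignore drift below 0.5 Hz
    if not usable.any() or spec[usable].max() <= 0:
        return empty
    f_osc = freqs[usable][np.argmax(spec[usable])]
    if f_osc <= 0:
        return empty
    distance = max(1, int(0.6 * sampling_rate / f_osc))
    minima, _ = signal.find_peaks(-z, distance=distance)
    if len(minima) < 2:
        return empty

    droll = np.gradient(roll)
    starts = [int(i) for i in minima if droll[i] > 0]
    if len(starts) < 2:
        # Flat pelvic roll (e.g. a rigid-pose trial) leaves the phase
        # ambiguous; fall back to every second minimum, phase arbitrary
        # but consistent.
        starts = [int(i) for i in minima[::2]]
    if len(starts) < 2:
        return empty
    intervals = list(zip(starts[:-1], starts[1:]))
    return StrideSegmentation(intervals, sampling_rate)


def per_stride_values(
    series: AngleSeries,
    seg: StrideSegmentation,
    mode: str,
) -> pd.Series:
    """Per-stride ROM (max - min) or signed mean of one parameter.

    Strides containing any invalid (gapped) frame of the series are dropped;
    the returned Series is indexed by stride number, dropped strides absent.
    """
    if mode not in ("rom", "mean"):
        raise ValueError("mode must be 'rom' or 'mean'")
    out: dict[int, float] = {}
    n = len(series.values)
    for k, (start, end) in enumerate(seg.intervals):
        if end > n:
            raise ValueError("stride interval outside series")
        if not series.valid[start:end].all():
            logger.info("stride %d dropped for %s: gapped frames", k, series.name)
            continue
        chunk = series.values[start:end]
        if chunk.size == 0:
            logger.info("stride %d skipped for %s: empty", k, series.name)
            continue
        out[k] = float(chunk.max() - chunk.min()) if mode == "rom" else float(chunk.mean())
    return pd.Series(out, dtype=float, name=series.name)


def aggregate_measurement(
    per_stride: pd.DataFrame,
    seg: StrideSegmentation,
    meta: Mapping[str, object],
    min_strides: int = MIN_STRIDES,
) -> tuple[dict | None, str | None]:
    """Aggregate a per-stride table to one measurement record.

    ``per_stride`` has one row per stride and one column per parameter (NaN
    where the stride was dropped for that parameter).  A *complete* stride
    has no NaN.  The record is discarded — ``(None, reason)`` — when the
    number of complete strides is below ``min_strides`` (default 6, i.e.
    five or fewer complete strides are not enough).

    The record holds the measurement mean of every parameter (equal stride
    weights), the mean stride duration and the mean stride frequency
    (per-stride reciprocal durations).
    """
    durations = seg.durations
    complete = per_stride.notna().all(axis=1) if len(per_stride) else pd.Series(dtype=bool)
    n_complete = int(complete.sum())
    if n_complete < min_strides:
        reason = (f"insufficient complete strides: {n_complete} "
                  f"(need >= {min_strides})")
        logger.warning("measurement discarded: %s (meta=%s)", reason, dict(meta))
        return None, reason
    record: dict[str, object] = dict(meta)
    record["n_strides"] = n_complete
    kept = per_stride.index[complete].to_numpy()
    record["stride_duration"] = float(np.mean(durations[kept]))
    record["stride_frequency"] = float(np.mean(1.0 / durations[kept]))
    for col in per_stride.columns:
        record[col] = float(per_stride[col].mean())
    return record, None


# ---------------------------------------------------------------------------
# Whole-trial pipeline
# ---------------------------------------------------------------------------


@dataclass
class TrialResult:
    """Everything computed from one trot-up."""

    angles: dict[str, AngleSeries]
    frame: HorseFrame
    segmentation: StrideSegmentation
    per_stride: pd.DataFrame
    record: dict | None
    discard_reason: str | None = None


def analyze_trial(
    series: MarkerFrameSeries,
    config: MarkerConfig,
    meta: Mapping[str, object] | None = None,
    cutoff_hz: float = 30.0,
    min_strides: int = MIN_STRIDES,
    heading_window_s: float = 0.5,
) -> TrialResult:
    """Compute all kinematic parameters of one trial and aggregate them.

    Pipeline: low-pass filter -> heading frame from the tuber sacrale track
    -> stride segmentation (uncorrected pelvic roll) -> per-stride body lean
    (stride-mean pelvic roll) -> lean-corrected frame -> all angle series ->
    per-stride ROM / means -> measurement record (or discard).
    """
    ts_label = config.label("tuber_sacrale")
    ts_filt = lowpass_filter(
        _fill_gaps(series.positions[ts_label], series.gap_mask[ts_label]),
        cutoff_hz, series.sampling_rate)
    frame0 = heading_frame(ts_filt[:, :2], series.sampling_rate,
                           window_s=heading_window_s)

    ltc = config.label("tuber_coxae_left")
    rtc = config.label("tuber_coxae_right")
    roll0, _, _ = pelvic_angles(
        ts_filt,
        lowpass_filter(_fill_gaps(series.positions[ltc], series.gap_mask[ltc]),
                       cutoff_hz, series.sampling_rate),
        lowpass_filter(_fill_gaps(series.positions[rtc], series.gap_mask[rtc]),
                       cutoff_hz, series.sampling_rate),
        frame0)
    seg = segment_strides(ts_filt[:, 2], roll0, series.sampling_rate)

    # Body lean = stride-mean pelvic roll, piecewise constant per stride.
    lean = np.zeros(series.n_frames)
    if len(seg):
        stride_means = np.array([roll0[s:e].mean() for s, e in seg.intervals])
        boundaries = np.array([s for s, _ in seg.intervals])
        idx = np.clip(np.searchsorted(boundaries, np.arange(series.n_frames),
                                      side="right") - 1, 0, len(seg) - 1)
        lean = stride_means[idx]
    frame = lean_correct(frame0, lean)

    angles = compute_angles(series, config, frame, cutoff_hz=cutoff_hz)

    cols = {}
    for name, ser in angles.items():
        mode = "mean" if name in MEAN_PARAMETERS else "rom"
        cols[name] = per_stride_values(ser, seg, mode)
    per_stride = pd.DataFrame(cols)
    per_stride.index.name = "stride"

    record, reason = aggregate_measurement(per_stride, seg, meta or {},
                                           min_strides=min_strides)
    return TrialResult(angles=angles, frame=frame, segmentation=seg,
                       per_stride=per_stride, record=record,
                       discard_reason=reason)


def angles_to_frame(angles: Mapping[str, AngleSeries],
                    sampling_rate: float) -> pd.DataFrame:
    """Tidy (frame, time_s, parameter, value) export of angle series."""
    rows = []
    for name, ser in angles.items():
        n = len(ser.values)
        rows.append(pd.DataFrame({
            "frame": np.arange(n),
            "time_s": np.arange(n) / sampling_rate,
            "parameter": name,
            "value": ser.values,
            "valid": ser.valid,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Circle geometry
# ---------------------------------------------------------------------------


def circle_diameter(ts_xy: np.ndarray) -> float:
    """Diameter (m) of the least-squares circle fit to a horizontal track (mm).

    Uses the algebraic (Kasa) fit.  Raises
    :class:`~equispine.kinematics.DegenerateGeometryError` for tracks that
    are straight or subtend less than half a revolution around the fitted
    centre.
    """
    xy = np.asarray(ts_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 3:
        raise ValueError("ts_xy must be (n >= 3, 2)")
    x, y = xy[:, 0], xy[:, 1]
    sv = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if sv[0] <= 0 or sv[1] / sv[0] < 1e-4:
        raise DegenerateGeometryError("collinear track: no circle to fit")
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateGeometryError("degenerate circle fit")
    r = float(np.sqrt(r2))
    # Straight tracks produce huge, ill-conditioned radii: require real
    # curvature (the track must bend around the centre by at least half a
    # revolution of unwrapped bearing).
    theta = np.unwrap(np.arctan2(y - cy, x - cx))
    if abs(theta[-1] - theta[0]) < np.pi:
        raise DegenerateGeometryError(
            "track subtends less than half a revolution: not a circle")
    return 2.0 * r / 1000.0
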