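"""Dual-rate signal conditioning, segmentation and peak synchronization.

The gold-standard stream samples at 180 Hz, the tracking sensors at
30 Hz, and nothing guarantees a shared start instant.  The pipeline:

1. fills short gaps, then smooths each angle series with a low-pass
   Butterworth filter (order 7; cutoff 5 Hz for 30 Hz streams, 30 Hz for
   the 180 Hz stream) followed by a 7-sample moving average;
2. finds the repetition maxima — the peaks are the one feature every
   stream shares at the same physical instant — and splits each series
   into three parts: start → first peak, first peak → last peak, last
   peak → end;
3. resamples each part of a sensor series onto the corresponding part of
   the gold series with quadratic interpolation, which simultaneously
   equalizes the lengths and phases of all streams.

The Butterworth filter is applied forward-backward (zero phase): peak
positions carry the timing information, so phase distortion would bias
the synchronization.  This doubles the effective order, which is
accepted and documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

from .errors import NoPeakError, RecordingLostError, SynchronizationError
from .series import AngleSeries

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth + moving-average smoothing parameters."""

    butterworth_order: int = 7
    cutoff: float | None = None  # None: 5 Hz below 60 Hz sampling, else 30 Hz
    moving_average_kernel: int = 7

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.moving_average_kernel % 2 != 1 or self.moving_average_kernel < 1:
            raise ValueError("moving-average kernel must be odd")

    def cutoff_for(self, rate: float) -> float:
        c = self.cutoff if self.cutoff is not None else (5.0 if rate < 60 else 30.0)
        if not 0 < c < rate / 2:
            raise ValueError(f"cutoff {c} Hz invalid for a {rate} Hz series")
        return c


def fill_gaps(series: AngleSeries, max_gap: int = 5) -> AngleSeries:
    """Linearly interpolate masked runs of at most ``max_gap`` samples.

    A longer gap means the recording cannot be conditioned reliably and
    raises :class:`RecordingLostError` (the recording is then counted as
    lost, not silently repaired).
    """
    mask = series.mask.copy()
    if mask.all():
        return series
    if not mask.any():
        raise RecordingLostError("series has no valid samples")
    # length of each invalid run
    idx = np.flatnonzero(~mask)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size > max_gap:
            raise RecordingLostError(
                f"gap of {run.size} samples exceeds the {max_gap}-sample limit"
            )
    valid_idx = np.flatnonzero(mask)
    filled = series.values.copy()
    filled[~mask] = np.interp(idx, valid_idx, series.values[valid_idx])
    return series.with_values(filled, mask=np.ones_like(mask))


def moving_average(x: np.ndarray, kernel: int) -> np.ndarray:
    """Length-preserving moving average with edge-reflection padding."""
    if kernel % 2 != 1 or kernel < 1:
        raise ValueError("kernel must be odd and positive")
    pad = kernel // 2
    padded = np.pad(np.asarray(x, float), pad, mode="reflect")
    return np.convolve(padded, np.full(kernel, 1.0 / kernel), mode="valid")


def smooth(series: AngleSeries, spec: FilterSpec | None = None) -> AngleSeries:
    """Low-pass Butterworth (zero-phase) then moving average; length preserved."""
    spec = spec or FilterSpec()
    x = series.values
    if not series.mask.all():
        series = fill_gaps(series)
        x = series.values
    padlen = 3 * spec.butterworth_order
    if x.size <= padlen:
        raise ValueError(
            f"series of {x.size} samples is too short for an order-"
            f"{spec.butterworth_order} zero-phase filter"
        )
    sos = sps.butter(
        spec.butterworth_order, spec.cutoff_for(series.rate), btype="low", fs=series.rate,
        output="sos",
    )
    y = sps.sosfiltfilt(sos, x, padlen=padlen)
    y = moving_average(y, spec.moving_average_kernel)
    return series.with_values(y)


@dataclass
class SegmentedSeries:
    """An angle series split at its repetition peaks into three parts.

    ``peak_positions`` optionally holds sub-sample (parabolic-vertex)
    refinements of the integer peak indices, and ``bounds`` fractional
    motion-onset/-end positions; both default to the integer values and
    are consumed by :func:`interpolate_segments` so that alignment is
    not limited to the sensor's sample grid.
    """

    series: AngleSeries
    peak_indices: np.ndarray
    peak_positions: np.ndarray | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.peak_indices.size < 1:
            raise NoPeakError("a segmented series needs at least one peak")
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        last = len(self.series) - 1
        if self.peak_indices[0] < 0 or self.peak_indices[-1] > last:
            raise ValueError("peak index out of range")
        if self.peak_positions is not None:
            self.peak_positions = np.asarray(self.peak_positions, dtype=float)
            if self.peak_positions.shape != self.peak_indices.shape:
                raise ValueError("peak_positions must match peak_indices")

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Inclusive (start, stop) index ranges: rise, repetitions, fall."""
        first, last = int(self.peak_indices[0]), int(self.peak_indices[-1])
        return [(0, first), (first, last), (last, len(self.series) - 1)]

    @property
    def boundaries(self) -> list[float]:
        """Fractional segment boundaries [start, first peak, last peak, end]."""
        pk = (
            self.peak_positions
            if self.peak_positions is not None
            else self.peak_indices.astype(float)
        )
        b0, b1 = self.bounds if self.bounds is not None else (0.0, float(len(self.series) - 1))
        return [b0, float(pk[0]), float(pk[-1]), b1]

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)


def _dominant_frequency(x: np.ndarray, rate: float) -> float:
    """Frequency of the strongest non-DC spectral line (repetition rate)."""
    x = x - x.mean()
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    spectrum[0] = 0.0
    i = int(np.argmax(spectrum))
    return float(freqs[i]) if freqs[i] > 0 else rate / x.size


def _refine_vertex(x: np.ndarray, p: int) -> float:
    """Sub-sample peak position by a parabola through (p-1, p, p+1)."""
    if p <= 0 or p >= x.size - 1:
        return float(p)
    denom = x[p - 1] - 2.0 * x[p] + x[p + 1]
    if denom >= -1e-12:  # not locally concave; keep the sample position
        return float(p)
    delta = 0.5 * (x[p - 1] - x[p + 1]) / denom
    return float(p) + float(np.clip(delta, -0.5, 0.5))


def detect_peaks(series: AngleSeries, frequency_hint: float | None = None) -> SegmentedSeries:
    """Find the repetition maxima and segment the series around them.

    Peaks are local maxima with prominence at least 20 % of the signal
    range, separated by at least half an (estimated) repetition period;
    each is refined to sub-sample precision with a parabolic vertex fit
    (the true maximum rarely falls on a 30 Hz sample).  A flat or
    monotone series has no such maxima and raises :class:`NoPeakError`.
    """
    x = series.values
    rng = float(np.nanmax(x) - np.nanmin(x))
    if not np.isfinite(rng) or rng < 1e-9:
        raise NoPeakError("flat series: no repetition peaks")
    f = frequency_hint or _dominant_frequency(x, series.rate)
    distance = max(1, int(round(0.5 / f * series.rate)))
    peaks, _ = sps.find_peaks(x, prominence=0.2 * rng, distance=distance)
    if peaks.size == 0:
        raise NoPeakError("no peak with sufficient prominence found")
    refined = np.array([_refine_vertex(x, int(p)) for p in peaks])
    return SegmentedSeries(series=series, peak_indices=peaks, peak_positions=refined)


def interpolate_segments(source: SegmentedSeries, target: SegmentedSeries) -> AngleSeries:
    """Resample each of the source's three parts onto the target's lengths.

    Quadratic (order-2) interpolation is used per part, which is exact on
    quadratic signals; a part with fewer than 3 samples falls back to
    linear with a logged warning.  The output has exactly the target
    length and its first/last peaks land on the target's peak positions.
    """
    x = source.series.values
    if x.size < 2:
        raise ValueError("cannot resample a single-sample series")
    fn = interp1d(np.arange(x.size), x, kind="quadratic" if x.size >= 3 else "linear")
    bounds = source.boundaries
    out = np.empty(len(target.series))
    for (a_f, b_f), (ta, tb) in zip(zip(bounds[:-1], bounds[1:]), target.segments):
        m = tb - ta + 1
        if a_f.is_integer() and b_f.is_integer() and m == int(b_f) - int(a_f) + 1:
            # grids coincide: copy the samples instead of re-evaluating
            out[ta : tb + 1] = x[int(a_f) : int(b_f) + 1]
            continue
        if b_f - a_f < 2.0:
            log.warning(
                "segment spanning %.1f samples resampled linearly "
                "(quadratic needs at least 3)",
                b_f - a_f + 1,
            )
            out[ta : tb + 1] = np.interp(np.linspace(a_f, b_f, m), np.arange(x.size), x)
            continue
        out[ta : tb + 1] = fn(np.linspace(a_f, b_f, m))
    return AngleSeries(
        values=out,
        rate=target.series.rate,
        movement_code=source.series.movement_code,
        source=source.series.source,
        t0=target.series.t0,
    )


def trim_to_motion(seg: SegmentedSeries, threshold_frac: float = 0.05) -> SegmentedSeries:
    """Cut a segmented series down to the motion execution.

    Streams recorded with different start offsets share the movement but
    not the length of the pre-movement hold, so the hold is trimmed
    before alignment: the series is cut at the last sample before the
    first peak (and the first after the last peak) whose value is within
    ``threshold_frac`` of the signal range above the resting minimum.
    """
    x = seg.series.values
    lo = float(np.min(x))
    thr = lo + threshold_frac * (float(np.max(x)) - lo)
    first, last = int(seg.peak_indices[0]), int(seg.peak_indices[-1])
    below = np.flatnonzero(x[: first + 1] <= thr)
    start = int(below[-1]) if below.size else 0
    below = np.flatnonzero(x[last:] <= thr)
    end = last + (int(below[0]) if below.size else x.size - 1 - last)

    # fractional threshold crossings give the onset/end to sub-sample precision
    def _cross(i: int, j: int) -> float:
        if j >= x.size or x[j] == x[i]:
            return float(i)
        return i + float(np.clip((thr - x[i]) / (x[j] - x[i]), 0.0, 1.0))

    start_f = _cross(start, start + 1) if start < first else float(start)
    end_f = _cross(end - 1, end) if end > last else float(end)
    if start == 0 and end == x.size - 1 and seg.bounds is None:
        return SegmentedSeries(
            series=seg.series,
            peak_indices=seg.peak_indices,
            peak_positions=seg.peak_positions,
            bounds=(start_f, end_f),
        )
    s = seg.series
    trimmed = AngleSeries(
        values=x[start : end + 1].copy(),
        rate=s.rate,
        movement_code=s.movement_code,
        source=s.source,
        mask=s.mask[start : end + 1].copy(),
        t0=s.t0 + start / s.rate,
    )
    positions = None if seg.peak_positions is None else seg.peak_positions - start
    return SegmentedSeries(
        series=trimmed,
        peak_indices=seg.peak_indices - start,
        peak_positions=positions,
        bounds=(start_f - start, end_f - start),
    )


def synchronize(
    sensor_series: list[AngleSeries],
    gold: AngleSeries,
    frequency_hint: float | None = None,
    trim: bool = True,
) -> tuple[AngleSeries, list[AngleSeries]]:
    """Align sensor series onto the gold series' length and phase.

    Each series is first trimmed to its motion execution (see
    :func:`trim_to_motion`) so that start offsets between streams drop
    out, then resampled segment-by-segment onto the gold segmentation.
    Every stream must show the same number of repetition peaks — the
    peaks mark the same physical instants — otherwise the recording
    cannot be trusted and a :class:`SynchronizationError` flags it as
    lost.

    Returns the (trimmed) gold series and the aligned sensor series; all
    returned series share the gold length, with their peaks on the gold
    peak indices.
    """
    gold_seg = detect_peaks(gold, frequency_hint)
    if trim:
        gold_seg = trim_to_motion(gold_seg)
    aligned = []
    for s in sensor_series:
        seg = detect_peaks(s, frequency_hint)
        if seg.n_peaks != gold_seg.n_peaks:
            raise SynchronizationError(
                f"{s.source or 'sensor'}: {seg.n_peaks} peaks vs "
                f"{gold_seg.n_peaks} in the gold stream"
            )
        if trim:
            seg = trim_to_motion(seg)
        aligned.append(interpolate_segments(seg, gold_seg))
    return gold_seg.series, aligned
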