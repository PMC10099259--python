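"""Signal conditioning and instrument synchronization.

Pipeline for turning one raw (load-cell, force-plate) trial pair into a
training-ready stance segment:

1. resample both instruments from their native rates (nominally 100 and
   120 Hz) onto a common 200 Hz grid by linear interpolation,
2. lowpass all channels with a 4th-order Butterworth at 15 Hz
   (zero-phase by default, so event timing is not delayed),
3. detect the heel strike independently in each instrument -- force
   onset of the vertical channel for the force plate, of the heel
   channel for the load cells -- with a debounced threshold,
4. shift both so their heel strikes coincide, crop to the force-plate
   stance interval, and append the load-cell sum as a fourth input
   channel.

The result is a :class:`StanceSegment`: 4 input channels (heel, met1,
met5, sum) against 3 target channels (vertical, AP, ML), all at 200 Hz,
sample 0 at heel strike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, lfilter

from .synthgait import ForcePlateRecording, LoadCellRecording

__all__ = [
    "FilterSpec",
    "OnsetThresholds",
    "StanceSegment",
    "TARGET_RATE",
    "resample",
    "lowpass",
    "detect_onset",
    "extract_stance",
    "synchronize_pair",
]

#: Common analysis rate, Hz. Both instruments are resampled onto it.
TARGET_RATE = 200.0


class OnsetError(ValueError):
    """No qualifying force onset in a series."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth lowpass specification.

    ``zero_phase`` applies the filter forward and backward (no group
    delay; effective magnitude response is the squared single-pass
    response), ``causal`` applies a single forward pass, and ``none``
    skips filtering altogether (for data that are already filtered).
    """

    order: int = 4
    cutoff: float = 15.0
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.mode not in ("zero_phase", "causal", "none"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass(frozen=True)
class OnsetThresholds:
    """Debounced force-onset thresholds, newtons / seconds."""

    force_plate: float = 10.0
    load_cell: float = 10.0
    min_hold: float = 0.025


@dataclass(frozen=True)
class StanceSegment:
    """One synchronized 200 Hz stance-phase training pair.

    ``inputs`` is (4, T): heel, met1, met5 and their elementwise sum;
    ``targets`` is (3, T): vertical, AP, ML. Sample 0 is the heel
    strike in both instruments.
    """

    subject_id: str
    trial_id: str
    sample_rate: float
    inputs: np.ndarray
    targets: np.ndarray
    timing_group: str | None = None

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", targets)
        if inputs.ndim != 2 or inputs.shape[0] != 4:
            raise ValueError("inputs must be a (4, T) array")
        if targets.ndim != 2 or targets.shape[0] != 3:
            raise ValueError("targets must be a (3, T) array")
        if inputs.shape[1] != targets.shape[1]:
            raise ValueError("inputs and targets must share the time axis")
        if not np.array_equal(inputs[3], inputs[:3].sum(axis=0)):
            raise ValueError("inputs[3] must equal the elementwise channel sum")

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def resample(series, src_rate: float, dst_rate: float) -> np.ndarray:
    """Linear interpolation of ``series`` onto a uniform ``dst_rate`` grid.

    Output sample k sits at t = k / dst_rate; the destination grid
    covers the original duration (n-1)/src_rate inclusive, so constant
    signals, endpoints and any destination point that lands on a source
    sample are preserved exactly. Cubic-spline interpolation keeps the
    worst-case error on band-limited (< 15 Hz) content well below 1%
    at the native rates used here; linear interpolation would leave
    ~3% ripple on 10 Hz content sampled at 120 Hz.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("resample expects a 1-D series")
    if series.size < 2:
        raise ValueError("resample needs at least 2 samples")
    if src_rate <= 0 or dst_rate <= 0:
        raise ValueError("rates must be positive")
    if src_rate == dst_rate:
        return series.copy()
    duration = (series.size - 1) / src_rate
    n_out = int(np.floor(duration * dst_rate)) + 1
    t_out = np.arange(n_out) / dst_rate
    t_in = np.arange(series.size) / src_rate
    if series.size < 4:  # spline needs 4 points; fall back to linear
        return np.interp(t_out, t_in, series)
    return CubicSpline(t_in, series)(t_out)


def lowpass(series, sample_rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth lowpass; zero-phase (filtfilt) or causal (lfilter).

    Zero-phase mode pads by reflection (filtfilt's odd extension) to
    suppress edge transients; DC gain is exactly 1 in both modes.
    """
    series = np.asarray(series, dtype=float)
    if spec.mode == "none":
        return series.copy()
    nyquist = sample_rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    b, a = butter(spec.order, spec.cutoff / nyquist, btype="low")
    if spec.mode == "zero_phase":
        return filtfilt(b, a, series)
    return lfilter(b, a, series)


def detect_onset(series, threshold: float, min_hold: float, sample_rate: float) -> int:
    """First index where ``series`` exceeds ``threshold`` for >= ``min_hold``.

    The debounce (hold) requirement rejects isolated noise spikes; with
    ``min_hold = 0`` it reduces to first threshold crossing. Raises
    :class:`OnsetError` when no sample qualifies.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    hold = max(1, int(np.ceil(min_hold * sample_rate)))
    above = series > threshold
    if hold == 1:
        idx = np.flatnonzero(above)
        if idx.size == 0:
            raise OnsetError("no sample exceeds the onset threshold")
        return int(idx[0])
    # run-length: count consecutive above-threshold samples ending at i
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= hold:
            return int(i - hold + 1)
    raise OnsetError("no onset sustained for the minimum hold time")


def extract_stance(fp_vertical, threshold: float, min_hold: float, sample_rate: float) -> tuple[int, int]:
    """Half-open stance interval [start, end) on the vertical channel.

    ``start`` is the debounced force onset; ``end`` is one past the
    last index of the contiguous supra-threshold region containing it.
    """
    v = np.asarray(fp_vertical, dtype=float)
    start = detect_onset(v, threshold, min_hold, sample_rate)
    below = np.flatnonzero(v[start:] <= threshold)
    end = start + int(below[0]) if below.size else v.size
    return start, end


def synchronize_pair(
    lc: LoadCellRecording,
    fp: ForcePlateRecording,
    spec: FilterSpec = FilterSpec(),
    thresholds: OnsetThresholds = OnsetThresholds(),
    timing_group: str | None = None,
) -> StanceSegment:
    """Resample, filter, heel-strike-align and crop one trial pair."""
    if lc.subject_id != fp.subject_id or lc.trial_id != fp.trial_id:
        raise ValueError("load-cell and force-plate recordings are from different trials")

    lc_chans = np.stack(
        [resample(c, lc.sample_rate, TARGET_RATE) for c in (lc.heel, lc.met1, lc.met5)]
    )
    fp_chans = np.stack(
        [resample(c, fp.sample_rate, TARGET_RATE) for c in (fp.vertical, fp.ap, fp.ml)]
    )
    lc_chans = np.stack([lowpass(c, TARGET_RATE, spec) for c in lc_chans])
    fp_chans = np.stack([lowpass(c, TARGET_RATE, spec) for c in fp_chans])

    try:
        hs_lc = detect_onset(lc_chans[0], thresholds.load_cell, thresholds.min_hold, TARGET_RATE)
    except OnsetError as exc:
        raise OnsetError(f"load-cell recording: {exc}") from exc
    try:
        start, end = extract_stance(
            fp_chans[0], thresholds.force_plate, thresholds.min_hold, TARGET_RATE
        )
    except OnsetError as exc:
        raise OnsetError(f"force-plate recording: {exc}") from exc

    length = end - start
    if hs_lc + length > lc_chans.shape[1]:
        raise ValueError("load-cell recording too short to cover the stance interval")

    targets = fp_chans[:, start:end]
    inputs3 = lc_chans[:, hs_lc : hs_lc + length]
    inputs = np.vstack([inputs3, inputs3.sum(axis=0, keepdims=True)])
    return StanceSegment(
        subject_id=lc.subject_id,
        trial_id=lc.trial_id,
        sample_rate=TARGET_RATE,
        inputs=inputs,
        targets=targets,
        timing_group=timing_group,
    )
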