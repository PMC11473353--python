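"""Micro-movement spike (MMS) extraction from angular velocity.

The MMS data type turns a biorhythmic time series — here the scalar
angular speed, the Euclidean norm of the triaxial gyroscope signal —
into a standardized series of peak amplitudes on [0, 1].  Each local
maximum is expressed as an absolute deviation from the empirically
estimated Gamma mean of the whole series (the person's baseline
activity) and scaled by the deviations of its two flanking local
minima:

    norm_peak = peak_dev / (peak_dev + avg_min_dev)

Because both numerator and denominator scale linearly with the
signal, anatomical (allometric) amplitude differences between people
cancel out, which is the whole point of the normalization: values are
comparable across bodies and ages.  Zeros between peaks stand for
"quiet moments" at the person's baseline; binarizing the peak
locations yields the spike trains consumed by the information-
dynamics estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, InputError
from .gamma_process import fit_gamma_mle
from .session_io import SensorStream

logger = logging.getLogger(__name__)


@dataclass
class SpeedSeries:
    """Scalar angular speed per sample, deg/s (non-negative)."""

    v: np.ndarray
    fs: float

    def __len__(self):
        return len(self.v)


@dataclass
class PeakSeries:
    """Interior local maxima with flanking-minimum structure.

    ``peak_dev[i]`` is |v[peak] - baseline_mean| and
    ``flank_min_dev[i]`` holds the same deviation for the two local
    minima flanking peak i (left, right).  ``baseline_mean`` is the
    Gamma-MLE mean of the whole session's speed.
    """

    peak_idx: np.ndarray
    peak_dev: np.ndarray
    flank_min_dev: np.ndarray  # shape (n_peaks, 2)
    baseline_mean: float
    fs: float
    # mean deviation of every sample spanning the min-to-min interval,
    # for the alternative normalization mode
    span_dev: np.ndarray | None = None

    def __len__(self):
        return len(self.peak_idx)


@dataclass
class MMSSeries:
    """Normalized spike amplitudes on [0, 1] at their sample indices."""

    values: np.ndarray
    idx: np.ndarray
    fs: float
    n_samples: int | None = None

    def __len__(self):
        return len(self.values)

    def dense(self, n_samples: int | None = None) -> np.ndarray:
        """Sample-aligned vector: 0 off-peak, norm_peak at peaks."""
        n = n_samples or self.n_samples
        if n is None:
            raise InputError("dense representation needs n_samples")
        out = np.zeros(n)
        out[self.idx] = self.values
        return out


@dataclass
class SpikeTrain:
    """Binary activity sequence on the sample grid."""

    bits: np.ndarray
    fs: float

    def __len__(self):
        return len(self.bits)


def angular_speed(stream: SensorStream) -> SpeedSeries:
    """Euclidean norm of the triaxial angular velocity, per sample."""
    w = stream.w
    bad = ~np.isfinite(w)
    if bad.any():
        i = int(np.flatnonzero(bad.any(axis=1))[0])
        raise DataError(f"non-finite velocity sample at index {i}")
    return SpeedSeries(v=np.sqrt(np.einsum("ij,ij->i", w, w)), fs=stream.fs)


def _peaks_and_valleys(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior extrema with a first-of-plateau tie rule.

    A peak is a sample whose last preceding value change was a rise
    and whose next value change is a fall (symmetrically for
    valleys); within a flat plateau the first sample is kept.
    """
    d = np.sign(np.diff(v))
    nonzero = np.flatnonzero(d)
    if nonzero.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # next nonzero sign at or after each position (backward fill)
    pos = np.searchsorted(nonzero, np.arange(len(d)), side="left")
    nz = np.where(pos < nonzero.size, d[nonzero[np.minimum(pos, nonzero.size - 1)]], 0)
    i = np.arange(1, len(v) - 1)
    peaks = i[(d[i - 1] > 0) & (nz[i] < 0)]
    valleys = i[(d[i - 1] < 0) & (nz[i] > 0)]
    return peaks.astype(int), valleys.astype(int)


def extract_peaks(v: SpeedSeries, baseline_mean: float | None = None) -> PeakSeries:
    """Locate interior speed peaks and their flanking minima.

    ``baseline_mean`` defaults to the Gamma-MLE mean of the whole
    series (zeros excluded), the person's empirical baseline; pass it
    explicitly to reuse a session-level fit on sub-segments.
    Deviations are absolute distances from this mean.  A constant
    series yields an empty PeakSeries; length < 3 is an error.
    """
    x = np.asarray(v.v, dtype=float)
    if len(x) < 3:
        raise InputError("need at least 3 samples to locate interior peaks")
    if np.ptp(x) == 0:
        return PeakSeries(np.empty(0, dtype=int), np.empty(0),
                          np.empty((0, 2)), baseline_mean or float(x[0] if len(x) else 0.0),
                          v.fs)
    if baseline_mean is None:
        fit = fit_gamma_mle(x, floor_n=3)
        baseline_mean = fit.mu
    peaks, valleys = _peaks_and_valleys(x)
    if peaks.size == 0:
        return PeakSeries(peaks, np.empty(0), np.empty((0, 2)),
                          float(baseline_mean), v.fs)
    # flanking minima; series endpoints serve as flanks when a peak
    # has no interior valley on one side (monotone run to the edge)
    v_ext = np.concatenate(([0], valleys, [len(x) - 1]))
    left_pos = np.searchsorted(v_ext, peaks, side="left") - 1
    left = v_ext[left_pos]
    right = v_ext[np.searchsorted(v_ext, peaks, side="right")]
    dev = np.abs(x - baseline_mean)
    flank = np.column_stack((dev[left], dev[right]))
    cs = np.concatenate(([0.0], np.cumsum(dev)))
    span = (cs[right + 1] - cs[left]) / (right - left + 1)
    return PeakSeries(peak_idx=peaks, peak_dev=dev[peaks],
                      flank_min_dev=flank, baseline_mean=float(baseline_mean),
                      fs=v.fs, span_dev=span)


def normalize_mms(p: PeakSeries, amplitude_floor: float = 0.0,
                  n_samples: int | None = None,
                  flank_mode: str = "flank_minima") -> MMSSeries:
    """Scale peak deviations to [0, 1] by their flanking-minima average.

    Each peak maps to peak_dev / (peak_dev + avg_min_dev) with
    avg_min_dev the mean of the two flanking-minima deviations
    (``flank_mode="flank_minima"``, the default) or the mean deviation
    of every sample spanning the min-to-min interval
    (``flank_mode="min_to_min_mean"``).  A peak where both terms are
    exactly zero sits at the baseline (a quiet moment); its value is
    defined as 0 and a warning is issued.  ``amplitude_floor``
    optionally drops peaks whose deviation does not exceed it (no
    floor by default).
    """
    if len(p) == 0:
        return MMSSeries(np.empty(0), np.empty(0, dtype=int), p.fs, n_samples)
    if flank_mode == "flank_minima":
        avg_min = p.flank_min_dev.mean(axis=1)
    elif flank_mode == "min_to_min_mean":
        if p.span_dev is None:
            raise InputError("PeakSeries lacks span deviations for "
                             "min_to_min_mean mode")
        avg_min = p.span_dev
    else:
        raise InputError(f"unknown flank_mode {flank_mode!r}")
    denom = p.peak_dev + avg_min
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} peak(s) at exact baseline; "
                      "normalized value defined as 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(zero, 0.0, p.peak_dev / np.where(zero, 1.0, denom))
    idx = p.peak_idx
    if amplitude_floor > 0:
        keep = p.peak_dev > amplitude_floor
        dropped = int((~keep).sum())
        if dropped:
            logger.info("amplitude floor dropped %d of %d peaks", dropped, len(keep))
        values, idx = values[keep], idx[keep]
    return MMSSeries(values=values, idx=idx, fs=p.fs, n_samples=n_samples)


def binarize(m: MMSSeries, n_samples: int) -> SpikeTrain:
    """Binary spike train: 1 at retained peak samples, 0 elsewhere."""
    if len(m) and m.idx.max() >= n_samples:
        raise InputError(
            f"n_samples={n_samples} smaller than max peak index {int(m.idx.max())}")
    bits = np.zeros(n_samples, dtype=np.uint8)
    if len(m):
        bits[m.idx] = 1
    return SpikeTrain(bits=bits, fs=m.fs)


def spike_rate(s: SpikeTrain) -> float:
    """Spikes per second: (number of 1s) * fs / length."""
    if len(s) == 0:
        raise InputError("spike rate of an empty train is undefined")
    return float(s.bits.sum()) * s.fs / len(s)


def mms_from_stream(stream: SensorStream, baseline_mean: float | None = None,
                    amplitude_floor: float = 0.0,
                    flank_mode: str = "flank_minima"
                    ) -> tuple[SpeedSeries, PeakSeries, MMSSeries]:
    """Convenience pipeline: stream -> speed -> peaks -> normalized MMS."""
    v = angular_speed(stream)
    p = extract_peaks(v, baseline_mean=baseline_mean)
    m = normalize_mms(p, amplitude_floor=amplitude_floor, n_samples=len(v),
                      flank_mode=flank_mode)
    return v, p, m
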