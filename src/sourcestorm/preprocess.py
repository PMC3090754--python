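"""Sensor-space preprocessing: baseline, filtering, resampling, averaging.

All operations are linear in the data, so filtering and trial averaging
commute; the test suite asserts this.  Filters are zero-phase Butterworth
(forward-backward), the standard choice for evoked-response work because it
removes phase distortion at the cost of doubling the effective order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .core_io import EpochSet, Recording


@dataclass(frozen=True)
class FilterSpec:
    """Band edges in Hz (either may be None), filter order, phase mode."""

    low: float | None = None
    high: float | None = None
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.low is None and self.high is None:
            raise ValueError("at least one of low/high must be set")
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(f"need low < high, got ({self.low}, {self.high})")
        if self.order < 1 or self.order % 2:
            raise ValueError("order must be a positive even integer")


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (seconds)."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"baseline window must have start < end, got {window}")
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    out = epochs.copy()
    out.epochs = out.epochs - out.epochs[:, :, mask].mean(axis=2, keepdims=True)
    return out


def _apply_to_data(obj, fn):
    if isinstance(obj, Recording):
        out = obj.copy()
        out.data = fn(out.data)
        return out
    if isinstance(obj, EpochSet):
        out = obj.copy()
        out.epochs = fn(out.epochs)
        return out
    raise TypeError(f"expected Recording or EpochSet, got {type(obj)}")


def _sfreq_of(obj) -> float:
    return obj.sfreq


def bandpass_filter(obj, spec: FilterSpec):
    """Zero-phase Butterworth band-pass / high-pass / low-pass filter.

    Reflect padding of ``min(3 * order / low, n / 2)`` samples (order/high for
    a pure low-pass) limits edge transients.
    """
    sfreq = _sfreq_of(obj)
    nyq = sfreq / 2.0
    if spec.high is not None and spec.high >= nyq:
        raise ValueError(f"high edge {spec.high} Hz >= Nyquist {nyq} Hz")
    if spec.low is not None and spec.low <= 0:
        raise ValueError("low edge must be positive")

    if spec.low is not None and spec.high is not None:
        sos = signal.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                            fs=sfreq, output="sos")
    elif spec.low is not None:
        sos = signal.butter(spec.order, spec.low, btype="highpass", fs=sfreq,
                            output="sos")
    else:
        sos = signal.butter(spec.order, spec.high, btype="lowpass", fs=sfreq,
                            output="sos")

    edge_freq = spec.low if spec.low is not None else spec.high

    def fn(data):
        n = data.shape[-1]
        pad = int(min(3 * spec.order * sfreq / edge_freq, n // 2))
        if spec.zero_phase:
            return signal.sosfiltfilt(sos, data, axis=-1, padtype="even", padlen=pad)
        return signal.sosfilt(sos, data, axis=-1)

    return _apply_to_data(obj, fn)


def resample(obj, new_sfreq: float):
    """Polyphase resampling with anti-alias filtering.

    Output length is ``round(n * new / old)``; a band-limited signal below
    the new Nyquist is preserved.
    """
    if new_sfreq <= 0:
        raise ValueError("new_sfreq must be positive")
    old_sfreq = _sfreq_of(obj)
    if np.isclose(new_sfreq, old_sfreq):
        return _apply_to_data(obj, lambda d: d.copy())
    frac = Fraction(new_sfreq / old_sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator

    def fn(data):
        n_out = int(round(data.shape[-1] * new_sfreq / old_sfreq))
        out = signal.resample_poly(data, up, down, axis=-1, padtype="line")
        if out.shape[-1] > n_out:
            out = out[..., :n_out]
        elif out.shape[-1] < n_out:
            pad = n_out - out.shape[-1]
            out = np.concatenate([out, np.repeat(out[..., -1:], pad, axis=-1)], axis=-1)
        return out

    out = _apply_to_data(obj, fn)
    if isinstance(out, Recording):
        out.sfreq = new_sfreq
    else:
        n_out = out.epochs.shape[-1]
        out.times = obj.times[0] + np.arange(n_out) / new_sfreq
    return out


def average_epochs(epochs: EpochSet) -> Recording:
    """Arithmetic mean over non-rejected trials, returned as a Recording."""
    good = epochs.good()
    if good.shape[0] == 0:
        raise ValueError("no usable (non-rejected) trials to average")
    return Recording(data=good.mean(axis=0), sfreq=epochs.sfreq,
                     t0=float(epochs.times[0]), sensors=epochs.sensors)


def detect_bad_channels(obj, z_thresh: float = 5.0) -> list[str]:
    """Flag channels whose log-variance is a robust outlier within its kind.

    For every sensor kind with at least 4 channels, computes each channel's
    log10 variance and a median/MAD z-score; channels with ``|z| > z_thresh``
    are reported.  The MAD is floored at a small epsilon so that a flat
    channel among otherwise identical ones is still caught.
    """
    if isinstance(obj, Recording):
        data = obj.data
        sensors = obj.sensors
    elif isinstance(obj, EpochSet):
        e = obj.epochs
        data = e.transpose(1, 0, 2).reshape(e.shape[1], -1)
        sensors = obj.sensors
    else:
        raise TypeError(f"expected Recording or EpochSet, got {type(obj)}")

    variances = data.var(axis=1)
    log_var = np.log10(np.maximum(variances, 1e-300))
    bad: list[str] = []
    kinds = np.array(sensors.kinds())
    for kind in np.unique(kinds):
        idx = np.flatnonzero(kinds == kind)
        if idx.size < 4:
            warnings.warn(f"kind {kind}: fewer than 4 channels, skipping detection")
            continue
        lv = log_var[idx]
        med = np.median(lv)
        mad = np.median(np.abs(lv - med))
        mad = max(mad, 1e-6)  # clamp so identical channels yield z=0, flats explode
        z = (lv - med) / (1.4826 * mad)
        for i, zi in zip(idx, z):
            if abs(zi) > z_thresh:
                bad.append(sensors.channels[i].name)
    return bad
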