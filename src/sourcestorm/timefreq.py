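"""Morlet-wavelet time-frequency decomposition with band grouping.

The wavelet family is parameterized by its shape at a reference frequency:
a complex exponential under a Gaussian envelope whose temporal FWHM at
``f0 = 1 Hz`` is ``fwhm_t = 3 s``.  At analysis frequency f the envelope
scales as ``sigma_t(f) = sigma_t(f0) * f0 / f``, trading temporal for
spectral resolution as frequency grows.  Decomposition is FFT-based complex
convolution with 'same' alignment; edges within two envelope widths of the
signal boundary are flagged invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: conventional frequency bands (Hz)
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 29.0),
    "gamma": (30.0, 59.0),
}


@dataclass(frozen=True)
class MorletSpec:
    """Wavelet shape: reference frequency f0 (Hz), temporal FWHM at f0 (s),
    and the analysis frequencies."""

    freqs: tuple
    f0: float = 1.0
    fwhm_t: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        if self.f0 <= 0 or self.fwhm_t <= 0:
            raise ValueError("f0 and fwhm_t must be positive")
        if len(self.freqs) == 0:
            raise ValueError("no analysis frequencies given")
        if any(b <= a for a, b in zip(self.freqs, self.freqs[1:])):
            raise ValueError("freqs must be strictly increasing")
        if min(self.freqs) * self.fwhm_t * self.f0 < 1.0:
            raise ValueError("lowest frequency unresolvable with this envelope "
                             "(need min(freq) * fwhm_t * f0 >= 1)")

    def sigma_t(self, freq: float) -> float:
        return self.fwhm_t * _FWHM_TO_SIGMA * self.f0 / freq


@dataclass
class TimeFreqMap:
    """signals x freqs x time array of complex coefficients or power."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    kind: str  # complex | power | magnitude
    band_labels: list[str] | None = None
    valid: np.ndarray | None = None  # freqs x time edge-validity flags

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.kind not in ("complex", "power", "magnitude"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.kind == "power" and np.any(self.values < 0):
            raise ValueError("power map must be non-negative")
        if self.band_labels is not None and len(self.band_labels) != self.values.shape[1]:
            raise ValueError("band_labels length must equal the frequency axis")


def morlet_kernel(freq: float, spec: MorletSpec, sfreq: float) -> np.ndarray:
    """Complex Morlet kernel at ``freq``, L2-normalized, truncated at 4 sigma."""
    if freq >= sfreq / 2:
        raise ValueError(f"frequency {freq} Hz >= Nyquist {sfreq / 2} Hz")
    if freq <= 0:
        raise ValueError("frequency must be positive")
    sigma = spec.sigma_t(freq)
    half = int(np.ceil(4 * sigma * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    kernel = np.exp(-(t ** 2) / (2 * sigma ** 2)) * np.exp(2j * np.pi * freq * t)
    return kernel / np.linalg.norm(kernel)


def tf_decompose(signals: np.ndarray, spec: MorletSpec, sfreq: float,
                 output_kind: str = "power",
                 times: np.ndarray | None = None) -> TimeFreqMap:
    """Morlet decomposition of one or more time series.

    ``signals`` is (n_signals, n_samples) or (n_samples,).  Zero padding is
    used at the edges; samples within ``2 sigma_t`` of either boundary are
    marked invalid in the ``valid`` mask.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    n_sig, n_samp = x.shape
    if times is None:
        times = np.arange(n_samp) / sfreq
    freqs = np.asarray(spec.freqs)

    coeffs = np.empty((n_sig, freqs.size, n_samp), dtype=complex)
    valid = np.ones((freqs.size, n_samp), dtype=bool)
    for fi, f in enumerate(freqs):
        kernel = morlet_kernel(f, spec, sfreq)
        if kernel.size > n_samp:
            warnings.warn(f"{f} Hz: kernel support ({kernel.size}) exceeds signal "
                          f"length ({n_samp}); edges dominate")
        coeffs[:, fi, :] = sps.fftconvolve(x, kernel[None, :], mode="same", axes=-1)
        edge = min(int(np.ceil(2 * spec.sigma_t(f) * sfreq)), n_samp)
        valid[fi, :edge] = False
        if edge > 0:
            valid[fi, -edge:] = False

    if output_kind == "complex":
        values = coeffs
    elif output_kind == "power":
        values = np.abs(coeffs) ** 2
    elif output_kind == "magnitude":
        values = np.abs(coeffs)
    else:
        raise ValueError(f"unknown output kind {output_kind!r}")
    return TimeFreqMap(values=values, freqs=freqs, times=times,
                       kind=output_kind, valid=valid)


def band_average(tfmap: TimeFreqMap, bands: dict[str, tuple[float, float]]
                 ) -> TimeFreqMap:
    """Average power/magnitude over frequency bins falling in each band.

    A bin belongs to band (low, high) when its center frequency lies in the
    closed interval; a band capturing no bins is an error.
    """
    if tfmap.kind == "complex":
        raise ValueError("cannot band-average complex coefficients; "
                         "convert to power or magnitude first")
    labels, rows, valid_rows = [], [], []
    for name, (low, high) in bands.items():
        if not low < high:
            raise ValueError(f"band {name!r}: need low < high")
        mask = (tfmap.freqs >= low) & (tfmap.freqs <= high)
        if not mask.any():
            raise ValueError(f"band {name!r} ({low}-{high} Hz) captures no "
                             "frequency bins")
        rows.append(tfmap.values[:, mask, :].mean(axis=1))
        if tfmap.valid is not None:
            valid_rows.append(tfmap.valid[mask].all(axis=0))
        labels.append(name)
    values = np.stack(rows, axis=1)
    valid = np.stack(valid_rows) if valid_rows else None
    return TimeFreqMap(values=values,
                       freqs=np.array([np.mean(bands[b]) for b in labels]),
                       times=tfmap.times, kind=tfmap.kind,
                       band_labels=labels, valid=valid)
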