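"""EMG intensity via a bank of 11 non-linearly scaled wavelets.

Surface EMG power is resolved in time and frequency with a filter bank of 11
wavelets whose center frequencies follow the non-linear scaling
``cf_j = (1/scale) * (j + q) ** r`` with the standard parameters
``scale = 0.3, q = 1.45, r = 1.959`` — spanning 6.90 Hz to 395.44 Hz.  Each
wavelet is defined in the frequency domain as

    W_j(f) = (f / cf_j) ** (cf_j * scale) * exp((1 - f / cf_j) * cf_j * scale)

for f >= 0, which peaks at ``f = cf_j`` with unit gain.  Band intensity is the
envelope power (squared magnitude of the analytic signal) of the band-filtered
trace; this analytic-signal demodulation is an approximation of the original
Gauss-filtered instantaneous-power scheme, equivalent for these band widths.
The first (lowest) wavelet is excluded from the total intensity to suppress
low-frequency motion artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .synthetic import EmgTrace

__all__ = [
    "WaveletBank",
    "IntensityTrace",
    "center_frequencies",
    "build_bank",
    "intensity",
    "normalize_intensity",
]


def center_frequencies(
    n: int = 11, scale: float = 0.3, q: float = 1.45, r: float = 1.959
) -> np.ndarray:
    """Center frequencies ``cf_j = (1/scale)*(j+q)**r`` for ``j = 0..n-1``.

    With the default parameters the 11 bands span 6.90–395.44 Hz.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale <= 0 or r <= 0:
        raise ValueError("scale and r must be positive")
    j = np.arange(n, dtype=float)
    return (1.0 / scale) * (j + q) ** r


@dataclass
class WaveletBank:
    """Frequency-domain wavelet filter bank evaluated on an FFT grid."""

    n_wavelets: int
    scale: float
    q: float
    r: float
    center_frequencies_hz: np.ndarray
    frequencies_hz: np.ndarray
    gains: np.ndarray  # (n_wavelets, n_freqs), non-negative
    sampling_rate_hz: float
    n_samples: int
    normalization: str = "peak"
    excluded_bands: tuple[int, ...] = field(default=(0,))


def _wavelet_gain(f: np.ndarray, cf: float, scale: float) -> np.ndarray:
    """Un-normalised frequency response of one wavelet (log-domain evaluation)."""
    p = cf * scale
    g = np.zeros_like(f)
    pos = f > 0
    g[pos] = np.exp(p * (np.log(f[pos] / cf) + 1.0 - f[pos] / cf))
    return g


def build_bank(
    fs: float,
    n_samples: int,
    n: int = 11,
    scale: float = 0.3,
    q: float = 1.45,
    r: float = 1.959,
    normalization: str = "peak",
) -> WaveletBank:
    """Build the wavelet bank on the one-sided FFT grid of a trace.

    ``normalization='peak'`` scales each filter to unit maximum gain
    (default).  ``normalization='sum'`` additionally rescales all filters by a
    common factor so that the summed gain is ~1 across the pass band, for
    users who need the signal to be approximately reconstructable from the
    sum of the band outputs.
    """
    if normalization not in ("peak", "sum"):
        raise ValueError("normalization must be 'peak' or 'sum'")
    cfs = center_frequencies(n, scale, q, r)
    nyq = fs / 2.0
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    gains = np.empty((n, len(freqs)))
    for jdx, cf in enumerate(cfs):
        if cf >= nyq:
            warnings.warn(
                f"wavelet {jdx} center frequency {cf:.1f} Hz is at/above the "
                f"Nyquist frequency {nyq:.1f} Hz; gain above Nyquist is zero"
            )
        g = _wavelet_gain(freqs, cf, scale)
        peak = g.max()
        gains[jdx] = g / peak if peak > 0 else g
    if normalization == "sum":
        total = gains.sum(axis=0)
        band = (freqs >= cfs[0]) & (freqs <= min(cfs[-1], nyq))
        plateau = np.median(total[band]) if band.any() else total.max()
        if plateau > 0:
            gains = gains / plateau
    return WaveletBank(
        n_wavelets=n, scale=scale, q=q, r=r, center_frequencies_hz=cfs,
        frequencies_hz=freqs, gains=gains, sampling_rate_hz=fs,
        n_samples=n_samples, normalization=normalization,
    )


@dataclass
class IntensityTrace:
    """Per-band and total EMG intensity (units: signal squared)."""

    band_intensities: np.ndarray  # (n_wavelets, n_samples)
    total_intensity: np.ndarray   # sum over bands 1..n-1 (band 0 excluded)
    sampling_rate_hz: float
    included_bands: tuple[int, ...]
    normalization_peak: float | None = None
    normalization_label: str | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.total_intensity.shape[-1]) / self.sampling_rate_hz


def intensity(
    trace: EmgTrace, bank: WaveletBank, include_band0: bool = False
) -> IntensityTrace:
    """Band-resolved EMG intensity of a trace.

    Each band output is the inverse FFT of the spectrum multiplied by the
    band's gain; its intensity is the squared magnitude of the analytic
    signal (envelope power).  The total is the sum over bands 1..n-1; the
    first wavelet is excluded to mitigate motion artifact unless
    ``include_band0`` is set.
    """
    x = trace.values
    if len(x) < 64:
        raise ValueError("trace must contain at least 64 samples")
    if len(x) != bank.n_samples or trace.sampling_rate_hz != bank.sampling_rate_hz:
        raise ValueError("bank was built for a different trace length or rate")
    X = np.fft.rfft(x)
    n = len(x)
    bands = np.empty((bank.n_wavelets, n))
    for jdx in range(bank.n_wavelets):
        xb = np.fft.irfft(X * bank.gains[jdx], n)
        bands[jdx] = np.abs(hilbert(xb)) ** 2
    included = tuple(
        j for j in range(bank.n_wavelets) if (j != 0 or include_band0)
    )
    total = bands[list(included)].sum(axis=0)
    return IntensityTrace(bands, total, trace.sampling_rate_hz, included)


def normalize_intensity(
    traces: dict[str, IntensityTrace]
) -> dict[str, IntensityTrace]:
    """Normalise total intensities to the single peak across all conditions.

    Every condition's series are divided by the one maximum total intensity
    observed across the whole ensemble, so the normalised ensemble peaks at
    exactly 1.
    """
    if not traces:
        raise ValueError("at least one condition required")
    peak = -np.inf
    peak_label = None
    for label, tr in traces.items():
        m = float(tr.total_intensity.max())
        if m > peak:
            peak, peak_label = m, label
    if peak <= 0:
        raise ValueError("cannot normalise silent EMG")
    out = {}
    for label, tr in traces.items():
        out[label] = IntensityTrace(
            band_intensities=tr.band_intensities / peak,
            total_intensity=tr.total_intensity / peak,
            sampling_rate_hz=tr.sampling_rate_hz,
            included_bands=tr.included_bands,
            normalization_peak=peak,
            normalization_label=peak_label,
        )
    return out
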