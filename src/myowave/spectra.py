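"""Displacement spectral statistics of aponeurosis landmark trajectories.

Segmented landmark rows are converted to transverse displacement in mm
relative to a quiet-standing reference (positive = toward the skin surface),
high-pass filtered at the stride frequency to remove gross gait motion, and
Fourier-analysed over 0-40 Hz.  Two summary statistics are extracted per
landmark: the peak of the power-frequency curve (mm^2) and the cumulative
frequency CF50 at which the area under the curve reaches half its total.
Landmarks are grouped into distal / mid / proximal image regions for the
statistical layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfiltfilt

from .asm import LandmarkShape, LandmarkTrajectory

__all__ = [
    "DisplacementSet",
    "SpectrumSummary",
    "transverse_displacement",
    "highpass_stride",
    "power_spectrum",
    "assign_regions",
    "region_summary",
    "resample_stance",
    "REGIONS",
    "summarize_displacement",
]

# Image regions in 0-based landmark indices (1-based 2-6 / 8-12 / 14-18).
REGIONS: dict[str, tuple[int, ...]] = {
    "distal": tuple(range(1, 6)),
    "mid": tuple(range(7, 12)),
    "proximal": tuple(range(13, 18)),
}


@dataclass
class DisplacementSet:
    """Per-landmark transverse displacement (mm) over one stance phase.

    Sign convention: positive = superficial (toward the skin/probe), negative
    = deep.  ``displacement_mm`` has shape ``(19, n_frames)``.
    """

    displacement_mm: np.ndarray
    frame_rate_hz: float
    reference_rows: np.ndarray
    condition: str | None = None
    stride_frequency_hz: float | None = None

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.displacement_mm.ndim != 2 or self.displacement_mm.shape[0] != 19:
            raise ValueError("displacement must be a (19, n_frames) array")


@dataclass
class SpectrumSummary:
    """Power-frequency table and summary statistics for one landmark."""

    frequencies_hz: np.ndarray
    power_mm2: np.ndarray
    peak_power_mm2: float
    cumulative_frequency_hz: float
    landmark_index: int = -1
    region: str = "none"
    all_zero: bool = False


def transverse_displacement(
    traj: LandmarkTrajectory,
    standing: LandmarkShape,
    mm_per_px_y: float,
    condition: str | None = None,
    stride_frequency_hz: float | None = None,
) -> DisplacementSet:
    """Displacement of tracked landmarks relative to a quiet-standing shape.

    ``d_j(t) = -(y_j(t) - y_j,standing) * mm_per_px_y``: image rows grow with
    depth, so a growing row index maps to negative (deep) displacement.
    """
    cols = traj.shapes[0].points[:, 0]
    if not np.allclose(cols, standing.points[:, 0]):
        raise ValueError("standing reference columns do not match the trajectory")
    rows = traj.rows()  # (n_frames, 19)
    d = -(rows - standing.points[:, 1][None, :]) * mm_per_px_y
    return DisplacementSet(d.T, traj.frame_rate_hz, standing.points[:, 1].copy(),
                           condition, stride_frequency_hz)


def highpass_stride(
    displ: DisplacementSet, stride_frequency_hz: float, order: int = 4
) -> DisplacementSet:
    """Zero-phase high-pass at the stride frequency, per landmark series.

    Removes gross movement-related displacement of the deformable tissue so
    that the spectrum reflects the oscillatory content.  The per-condition
    stride frequencies used as cutoffs in the reference protocol are
    1.3, 1.8, 2.4, 2.6, 2.7, 2.9 and 3.1 Hz.
    """
    fs = displ.frame_rate_hz
    if stride_frequency_hz >= fs / 2:
        raise ValueError("stride frequency must be below the Nyquist frequency")
    sos = butter(order, stride_frequency_hz, btype="highpass", fs=fs, output="sos")
    # sosfiltfilt default pad length per section group
    padlen = 3 * (2 * sos.shape[0] + 1)
    n = displ.displacement_mm.shape[1]
    if n <= padlen:
        raise ValueError(
            f"series of length {n} is too short to filter; "
            f"at least {padlen + 1} samples are required"
        )
    filtered = sosfiltfilt(sos, displ.displacement_mm, axis=1)
    return DisplacementSet(filtered, fs, displ.reference_rows,
                           displ.condition, stride_frequency_hz)


def power_spectrum(
    series: np.ndarray,
    fs: float,
    f_max: float = 40.0,
    landmark_index: int = -1,
) -> SpectrumSummary:
    """One-sided FFT power spectrum of a displacement series, 0..f_max Hz.

    Power is ``P(f) = 2*|X(f)|^2 / N^2`` on the unwindowed series, a
    convention under which a unit-amplitude sinusoid carries ~0.5 mm^2 at its
    bin.  The cumulative frequency is the smallest f* at which the
    trapezoidal area of P from 0 to f* reaches half the total area over
    [0, f_max], linearly interpolated inside the crossing bin.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValueError("series must be 1-D with at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    power = 2.0 * np.abs(X) ** 2 / n**2
    keep = freqs <= f_max
    freqs, power = freqs[keep], power[keep]

    if np.allclose(power, 0.0):
        return SpectrumSummary(freqs, power, 0.0, 0.0, landmark_index,
                               all_zero=True)

    cum = cumulative_trapezoid(power, freqs, initial=0.0)
    total = cum[-1]
    half = 0.5 * total
    idx = int(np.searchsorted(cum, half))
    if idx == 0:
        cf = freqs[0]
    else:
        c0, c1 = cum[idx - 1], cum[idx]
        f0, f1 = freqs[idx - 1], freqs[idx]
        cf = f0 if c1 == c0 else f0 + (half - c0) / (c1 - c0) * (f1 - f0)
    return SpectrumSummary(freqs, power, float(power.max()), float(cf),
                           landmark_index)


def assign_regions(summaries: list[SpectrumSummary]) -> list[SpectrumSummary]:
    """Label 19 per-landmark summaries with their image region.

    Landmarks 1-5 (0-based) form the distal region, 7-11 the mid region and
    13-17 the proximal region; the remaining four landmarks are labelled
    ``none``.
    """
    if len(summaries) != 19:
        raise ValueError("exactly 19 landmark summaries required")
    lookup = {i: name for name, idxs in REGIONS.items() for i in idxs}
    out = []
    for i, s in enumerate(summaries):
        out.append(SpectrumSummary(
            s.frequencies_hz, s.power_mm2, s.peak_power_mm2,
            s.cumulative_frequency_hz, landmark_index=i,
            region=lookup.get(i, "none"), all_zero=s.all_zero,
        ))
    return out


def region_summary(summaries: list[SpectrumSummary]) -> pd.DataFrame:
    """Region-level metrics: mean peak power and CF50 over each region's landmarks."""
    rows = []
    for name, idxs in REGIONS.items():
        sel = [s for s in summaries if s.landmark_index in idxs]
        if len(sel) != len(idxs):
            raise ValueError("summaries are missing landmarks; run assign_regions "
                             "on a full 19-landmark set")
        rows.append({
            "region": name,
            "peak_power_mm2": float(np.mean([s.peak_power_mm2 for s in sel])),
            "cumulative_frequency_hz": float(
                np.mean([s.cumulative_frequency_hz for s in sel])
            ),
        })
    return pd.DataFrame(rows)


def resample_stance(displ: DisplacementSet, n: int = 100) -> np.ndarray:
    """Resample each landmark series to ``n`` evenly spaced stance points.

    Linear interpolation over the stance interval; intended for trace
    reporting (e.g. group-mean displacement curves), never as spectral input.
    Returns an ``(19, n)`` array.
    """
    m = displ.displacement_mm.shape[1]
    if m < 2:
        raise ValueError("at least two samples required")
    t_old = np.arange(m) / displ.frame_rate_hz
    t_new = np.linspace(t_old[0], t_old[-1], n)
    return np.vstack([
        np.interp(t_new, t_old, displ.displacement_mm[j]) for j in range(19)
    ])


def summarize_displacement(
    displ: DisplacementSet,
    stride_frequency_hz: float | None = None,
    f_max: float = 40.0,
) -> list[SpectrumSummary]:
    """High-pass, per-landmark spectra and region labels in one call."""
    fc = stride_frequency_hz or displ.stride_frequency_hz
    if fc is None:
        raise ValueError("a stride frequency cutoff is required")
    hp = highpass_stride(displ, fc)
    summaries = [
        power_spectrum(hp.displacement_mm[j], displ.frame_rate_hz, f_max, j)
        for j in range(19)
    ]
    return assign_regions(summaries)
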