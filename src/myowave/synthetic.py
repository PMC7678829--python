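"""Synthetic ultrasound, ground-reaction-force and EMG generators with known truth.

Every generator in this module produces a data object *and* a ground-truth
record, so that each downstream stage of the pipeline (segmentation, spectral
statistics, impact-frequency estimation, EMG intensity) has a recoverable
answer.  The image generator emulates B-mode ultrasound of the soleus region:
two bright curvilinear aponeurosis bands over multiplicative speckle, moving
with a prescribed low-frequency gait trajectory plus higher-frequency
transverse oscillations.  The force generator builds walking (double-hump) or
running (active peak + impact transient) vertical ground reaction forces whose
impact timing is exact by construction.  The EMG generator produces
amplitude-modulated band-limited noise with an optional low-frequency motion
artifact.

All randomness flows from one explicit integer seed per generator call; the
same seed yields bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageSequence",
    "BoundarySpec",
    "GroundTruthScene",
    "ForceTruth",
    "ForceTrace",
    "EmgTruth",
    "EmgTrace",
    "generate_image_sequence",
    "generate_force_trace",
    "generate_emg_trace",
    "LANDMARK_COLUMNS",
]

# 19 evenly-spaced landmark columns, 32 px apart, spanning a 608 px image width.
LANDMARK_COLUMNS = 16 + 32 * np.arange(19)

#: Physical probe geometry: 60 mm scanning width, 50 mm depth.
DEFAULT_WIDTH_PX = 608
DEFAULT_HEIGHT_PX = 512
DEFAULT_MM_PER_PX_X = 60.0 / DEFAULT_WIDTH_PX   # ~0.0987 mm
DEFAULT_MM_PER_PX_Y = 50.0 / DEFAULT_HEIGHT_PX  # ~0.0977 mm


@dataclass
class ImageSequence:
    """A stack of grayscale B-mode frames with physical scale and frame rate.

    frames
        ``(n_frames, height, width)`` uint8 array.
    frame_rate_hz
        Imaging rate (the study hardware samples at ~80 Hz).
    mm_per_px_x, mm_per_px_y
        Physical pixel pitch along image width (proximo-distal) and depth.
    timestamps
        Acquisition time of each frame in seconds, strictly increasing.
    """

    frames: np.ndarray
    frame_rate_hz: float
    mm_per_px_x: float
    mm_per_px_y: float
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, column) array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.mm_per_px_x <= 0 or self.mm_per_px_y <= 0:
            raise ValueError("pixel scales must be positive")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class BoundarySpec:
    """Quadratic aponeurosis boundary ``row = c0 + c1*col + c2*col**2``.

    ``components`` lists transverse oscillation components ``(frequency_hz,
    amplitude_mm, phase_rad)`` added to ``c0`` over time; this covers both the
    low-frequency gait trajectory and the higher-frequency oscillations of
    interest.
    """

    c0: float
    c1: float = 0.0
    c2: float = 0.0
    components: list[tuple[float, float, float]] = field(default_factory=list)

    def offset_px(self, t: np.ndarray, mm_per_px_y: float) -> np.ndarray:
        """Transverse offset (px, positive = deeper rows) at times ``t``."""
        off = np.zeros_like(np.asarray(t, dtype=float))
        for f_hz, amp_mm, phase in self.components:
            off = off + (amp_mm / mm_per_px_y) * np.sin(2 * np.pi * f_hz * t + phase)
        return off

    def rows(self, cols: np.ndarray, t: np.ndarray, mm_per_px_y: float) -> np.ndarray:
        """Boundary rows, shape ``(len(t), len(cols))``."""
        cols = np.asarray(cols, dtype=float)
        base = self.c0 + self.c1 * cols + self.c2 * cols**2
        return base[None, :] + self.offset_px(t, mm_per_px_y)[:, None]


@dataclass
class GroundTruthScene:
    """True boundary geometry of a generated ultrasound sequence.

    ``landmark_truth`` maps boundary name (``"superficial"``/``"deep"``) to an
    ``(n_frames, 19)`` array of true landmark rows at the standard columns.
    """

    superficial: BoundarySpec
    deep: BoundarySpec
    landmark_truth: dict[str, np.ndarray]
    oscillation_components: dict[str, list[tuple[float, float, float]]]
    landmark_columns: np.ndarray = field(default_factory=lambda: LANDMARK_COLUMNS.copy())

    def standing_rows(self, boundary: str) -> np.ndarray:
        """Landmark rows of the static (zero-oscillation) boundary."""
        spec = {"superficial": self.superficial, "deep": self.deep}[boundary]
        cols = self.landmark_columns.astype(float)
        return spec.c0 + spec.c1 * cols + spec.c2 * cols**2


@dataclass
class ForceTruth:
    """Construction record of a synthetic vertical GRF trace."""

    impact_frequency_hz: float | None
    max_rfd_times_s: list[float]
    impact_peak_times_s: list[float]
    stance_intervals: list[tuple[float, float]]


@dataclass
class ForceTrace:
    """Uniformly sampled vertical ground reaction force in newtons."""

    values: np.ndarray
    sampling_rate_hz: float = 2000.0
    truth: ForceTruth | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("force values must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate_hz


@dataclass
class EmgTruth:
    """Envelope and artifact description of a synthetic EMG trace."""

    envelope: np.ndarray
    burst_windows: list[tuple[float, float]]
    artifact_hz: float | None


@dataclass
class EmgTrace:
    """Uniformly sampled surface EMG (arbitrary voltage units)."""

    values: np.ndarray
    sampling_rate_hz: float = 2000.0
    truth: EmgTruth | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EMG values must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate_hz


def generate_image_sequence(
    superficial: BoundarySpec,
    deep: BoundarySpec,
    n_frames: int,
    frame_rate_hz: float = 80.0,
    width: int = DEFAULT_WIDTH_PX,
    height: int = DEFAULT_HEIGHT_PX,
    mm_per_px_x: float = DEFAULT_MM_PER_PX_X,
    mm_per_px_y: float = DEFAULT_MM_PER_PX_Y,
    band_sigma_px: float = 3.0,
    band_amplitude: float = 0.8,
    background_level: float = 0.12,
    speckle_sigma_px: float = 1.1,
    min_gap_px: float = 20.0,
    seed: int = 0,
) -> tuple[ImageSequence, GroundTruthScene]:
    """Render a synthetic B-mode sequence of two moving aponeurosis bands.

    Each boundary is drawn as a bright band with a Gaussian cross-section
    (``band_sigma_px`` standard deviation, ``band_amplitude`` relative
    brightness) over a multiplicative speckle field (Rayleigh noise convolved
    with a small Gaussian kernel, scaled onto a low-intensity background).

    Returns the rendered 8-bit sequence together with a
    :class:`GroundTruthScene` whose ``landmark_truth`` holds the exact
    boundary rows at the 19 standard landmark columns for every frame.

    Raises
    ------
    ValueError
        If the image is too narrow for the 19-landmark grid, an oscillation
        component exceeds the Nyquist frequency of the frame rate, or a
        boundary exits the image or crosses the other boundary.
    """
    if width < LANDMARK_COLUMNS[-1] + 16:
        raise ValueError(
            f"image width {width} px cannot hold 19 landmarks at 32 px spacing"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    for name, spec in (("superficial", superficial), ("deep", deep)):
        for f_hz, _, _ in spec.components:
            if f_hz >= frame_rate_hz / 2:
                raise ValueError(
                    f"{name} component at {f_hz} Hz is at/above the Nyquist "
                    f"frequency {frame_rate_hz / 2} Hz"
                )

    t = np.arange(n_frames) / frame_rate_hz
    cols = np.arange(width, dtype=float)
    sup_rows = superficial.rows(cols, t, mm_per_px_y)   # (n_frames, width)
    deep_rows = deep.rows(cols, t, mm_per_px_y)

    margin = 2.0 * band_sigma_px
    for name, rows in (("superficial", sup_rows), ("deep", deep_rows)):
        if rows.min() < margin or rows.max() > height - 1 - margin:
            raise ValueError(f"{name} boundary exits the image (rows "
                             f"{rows.min():.1f}..{rows.max():.1f})")
    if np.any(deep_rows - sup_rows < min_gap_px):
        raise ValueError("boundaries cross or come closer than the minimum gap")

    rng = np.random.default_rng(seed)
    row_grid = np.arange(height, dtype=float)[:, None]
    frames = np.empty((n_frames, height, width), dtype=np.uint8)
    inv_two_sigma2 = 1.0 / (2.0 * band_sigma_px**2)
    for i in range(n_frames):
        speckle = gaussian_filter(
            rng.rayleigh(scale=1.0, size=(height, width)), speckle_sigma_px
        )
        speckle /= speckle.mean()
        bands = band_amplitude * (
            np.exp(-((row_grid - sup_rows[i][None, :]) ** 2) * inv_two_sigma2)
            + np.exp(-((row_grid - deep_rows[i][None, :]) ** 2) * inv_two_sigma2)
        )
        img = (background_level + bands) * speckle
        frames[i] = np.clip(np.round(255.0 * img), 0, 255).astype(np.uint8)

    lm_cols = LANDMARK_COLUMNS.astype(float)
    truth = {
        "superficial": superficial.rows(lm_cols, t, mm_per_px_y),
        "deep": deep.rows(lm_cols, t, mm_per_px_y),
    }
    seq = ImageSequence(frames, frame_rate_hz, mm_per_px_x, mm_per_px_y, t)
    scene = GroundTruthScene(
        superficial=superficial,
        deep=deep,
        landmark_truth=truth,
        oscillation_components={
            "superficial": list(superficial.components),
            "deep": list(deep.components),
        },
    )
    return seq, scene


def _running_stance(
    t: np.ndarray,
    stance_duration_s: float,
    impact_frequency_hz: float,
    impact_amplitude_N: float,
    active_peak_N: float,
) -> np.ndarray:
    """Running stance: damped impact transient + delayed active half-hump.

    During the first quarter-period of the impact oscillation the force is the
    rising quarter sine of the transient alone, so the interval from maximal
    rate of force development (at foot contact) to the first force maximum is
    exactly ``1/(4*impact_frequency_hz)``.  The active component starts at the
    impact peak with zero slope (a sin^2 hump), which keeps that timing exact.
    """
    T = stance_duration_s
    f = impact_frequency_hz
    t_q = 1.0 / (4.0 * f)
    force = np.zeros_like(t)
    in_stance = (t >= 0) & (t <= T)
    s = t[in_stance]
    out = np.zeros_like(s)

    if impact_amplitude_N > 0:
        rise = s <= t_q
        out[rise] += impact_amplitude_N * np.sin(2 * np.pi * f * s[rise])
        tail = s > t_q
        u = s[tail] - t_q
        # decaying oscillation after the peak, negative lobes clipped so the
        # total vertical force stays non-negative throughout stance
        out[tail] += (impact_amplitude_N
                      * np.maximum(np.cos(2 * np.pi * f * u), 0.0)
                      * np.exp(-2.0 * f * u))

    t0 = t_q if impact_amplitude_N > 0 else 0.0
    act = s >= t0
    u = (s[act] - t0) / (T - t0)
    out[act] += active_peak_N * np.sin(np.pi * u) ** 2
    force[in_stance] = out
    return force


def _walking_stance(
    t: np.ndarray,
    stance_duration_s: float,
    impact_frequency_hz: float,
    active_peak_N: float,
) -> np.ndarray:
    """Walking stance: two raised-cosine humps plus a mid-stance bridge.

    The first hump has width ``w = 1/impact_frequency_hz`` so its maximal rate
    of force development (at w/4) and its peak (at w/2) are separated by a
    quarter period of the nominal impact oscillation.  The bridge spans the
    two hump peaks with zero value and slope at both, so it disturbs neither
    the first hump's timing nor the second hump's peak, while keeping the
    force well above zero throughout stance.
    """
    T = stance_duration_s
    w = 1.0 / impact_frequency_hz
    force = np.zeros_like(t)
    in_stance = (t >= 0) & (t <= T)
    s = t[in_stance]
    out = np.zeros_like(s)

    h1 = s <= w
    out[h1] += active_peak_N * 0.5 * (1 - np.cos(2 * np.pi * s[h1] / w))
    h2 = s >= T - w
    out[h2] += 0.95 * active_peak_N * 0.5 * (
        1 - np.cos(2 * np.pi * (s[h2] - (T - w)) / w)
    )
    br = (s >= w / 2) & (s <= T - w / 2)
    out[br] += 0.6 * active_peak_N * np.sin(
        np.pi * (s[br] - w / 2) / (T - w)
    ) ** 2
    force[in_stance] = out
    return force


def generate_force_trace(
    gait: str = "running",
    stance_duration_s: float = 0.30,
    impact_frequency_hz: float = 15.0,
    impact_amplitude_N: float = 400.0,
    active_peak_N: float = 1500.0,
    sampling_rate_hz: float = 2000.0,
    n_stances: int = 4,
    swing_duration_s: float = 0.25,
    lead_in_s: float = 0.10,
    noise_sd_N: float = 0.0,
    seed: int = 0,
) -> ForceTrace:
    """Generate a vertical GRF trace with exactly known impact timing.

    ``truth`` records, per stance, the time of maximal rate of force
    development and of the impact force peak; their separation equals
    ``1/(4*impact_frequency_hz)`` by construction, so the quarter-wave
    input-frequency estimator should recover ``impact_frequency_hz`` up to
    sample quantisation.
    """
    if gait not in ("walking", "running"):
        raise ValueError("gait must be 'walking' or 'running'")
    if not (2.0 < impact_frequency_hz < 100.0):
        raise ValueError("impact_frequency_hz must lie in (2, 100) Hz")
    if stance_duration_s <= 4.0 / impact_frequency_hz and gait == "walking":
        raise ValueError("stance_duration_s must exceed 4/impact_frequency_hz for walking")
    t_q = 1.0 / (4.0 * impact_frequency_hz)
    if gait == "running" and t_q >= stance_duration_s:
        raise ValueError("impact transient peak would exceed stance duration")

    dt = 1.0 / sampling_rate_hz
    period = stance_duration_s + swing_duration_s
    total_s = lead_in_s + n_stances * period
    n = int(round(total_s * sampling_rate_hz)) + 1
    times = np.arange(n) * dt
    force = np.zeros(n)

    rfd_times, peak_times, intervals = [], [], []
    for k in range(n_stances):
        start = lead_in_s + k * period
        rel = times - start
        if gait == "running":
            force += _running_stance(
                rel, stance_duration_s, impact_frequency_hz,
                impact_amplitude_N, active_peak_N,
            )
            if impact_amplitude_N > 0:
                rfd_times.append(start)
                peak_times.append(start + t_q)
        else:
            force += _walking_stance(
                rel, stance_duration_s, impact_frequency_hz, active_peak_N
            )
            w = 1.0 / impact_frequency_hz
            rfd_times.append(start + w / 4.0)
            peak_times.append(start + w / 2.0)
        intervals.append((start, start + stance_duration_s))

    if noise_sd_N > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd_N, size=n)

    truth = ForceTruth(
        impact_frequency_hz=(
            impact_frequency_hz
            if (gait == "walking" or impact_amplitude_N > 0)
            else None
        ),
        max_rfd_times_s=rfd_times,
        impact_peak_times_s=peak_times,
        stance_intervals=intervals,
    )
    return ForceTrace(force, sampling_rate_hz, truth)


def generate_emg_trace(
    burst_windows: list[tuple[float, float]],
    duration_s: float = 2.0,
    band_hz: tuple[float, float] = (20.0, 450.0),
    artifact_hz: float | None = None,
    artifact_amplitude: float = 0.0,
    burst_amplitude: float = 1.0,
    edge_s: float = 0.02,
    sampling_rate_hz: float = 2000.0,
    seed: int = 0,
) -> EmgTrace:
    """Generate amplitude-modulated band-limited noise emulating surface EMG.

    White Gaussian noise is band-pass filtered to ``band_hz`` (zero-phase
    Butterworth) and multiplied by a smooth envelope built from the burst
    windows (cosine-tapered edges of ``edge_s`` seconds).  An optional
    sinusoidal motion artifact below 10 Hz can be added.  The trace is
    mean-removed after generation.
    """
    from scipy.signal import butter, sosfiltfilt

    lo, hi = band_hz
    nyq = sampling_rate_hz / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band_hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
    if artifact_hz is not None and artifact_hz >= 10.0:
        raise ValueError("motion artifact must lie below 10 Hz")
    if not burst_windows:
        warnings.warn("no burst windows given; generating a silent trace")

    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    envelope = np.zeros(n)
    for t0, t1 in burst_windows:
        win = np.zeros(n)
        inside = (t >= t0) & (t <= t1)
        win[inside] = 1.0
        if edge_s > 0:
            rise = (t >= t0) & (t < t0 + edge_s)
            fall = (t > t1 - edge_s) & (t <= t1)
            win[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / edge_s))
            win[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - t[fall]) / edge_s))
        envelope = np.maximum(envelope, win)
    envelope *= burst_amplitude

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    sos = butter(4, [lo, hi], btype="bandpass", fs=sampling_rate_hz, output="sos")
    carrier = sosfiltfilt(sos, noise)
    values = envelope * carrier
    if artifact_hz is not None and artifact_amplitude > 0:
        values = values + artifact_amplitude * np.sin(2 * np.pi * artifact_hz * t)
    values = values - values.mean()

    truth = EmgTruth(envelope=envelope, burst_windows=list(burst_windows),
                     artifact_hz=artifact_hz)
    return EmgTrace(values, sampling_rate_hz, truth)
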