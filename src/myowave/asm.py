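"""Active shape model segmentation of aponeurosis landmarks.

The aponeurosis is represented by 19 evenly-spaced landmarks, 32 pixels
apart, spanning the image width.  A point distribution model (PDM) captures
the variability of the training shapes (mean + principal modes of the
stacked coordinate vectors); per-landmark Gaussian models of the normalised
intensity-gradient profile along the boundary normal, built at multiple image
resolutions, drive a coarse-to-fine search.  Each iteration moves every
landmark to the candidate position minimising the Mahalanobis distance to its
intensity model, then projects the shape onto the PDM with each mode
coefficient clamped to +/-3 standard deviations, which keeps the result a
plausible aponeurosis shape.

Pose is deliberately left inside the shape space (no Procrustes alignment
before the PDM): the measurand downstream is absolute transverse displacement
relative to the probe, so translation must remain a modelled degree of
freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .synthetic import LANDMARK_COLUMNS, ImageSequence

__all__ = [
    "LandmarkShape",
    "PointDistributionModel",
    "IntensityProfileModel",
    "ShapeModel",
    "FitDiagnostics",
    "LandmarkTrajectory",
    "build_pdm",
    "build_intensity_models",
    "train_shape_model",
    "fit_shape",
    "segment_sequence",
    "image_pyramid",
]

N_LANDMARKS = 19
LANDMARK_SPACING_PX = 32


@dataclass
class LandmarkShape:
    """One aponeurosis shape: 19 (x, y) pixel points at the standard columns."""

    points: np.ndarray  # (19, 2) float, columns fixed at LANDMARK_COLUMNS
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError("shape must have exactly 19 (x, y) points")
        if not np.allclose(self.points[:, 0], LANDMARK_COLUMNS, atol=1e-6):
            raise ValueError(
                "x-coordinates must sit on the 19 standard columns "
                "(16 + 32*j pixels)"
            )

    @classmethod
    def from_rows(cls, rows: np.ndarray, frame_index: int = 0) -> "LandmarkShape":
        """Build a shape from 19 row (y) coordinates at the standard columns."""
        rows = np.asarray(rows, dtype=float)
        if rows.shape != (N_LANDMARKS,):
            raise ValueError("rows must be a length-19 vector")
        pts = np.column_stack([LANDMARK_COLUMNS.astype(float), rows])
        return cls(pts, frame_index)

    def vector(self) -> np.ndarray:
        """Pack as the 38-vector (x_0..x_18, y_0..y_18)."""
        return np.concatenate([self.points[:, 0], self.points[:, 1]])


def _unpack(vec: np.ndarray) -> np.ndarray:
    return np.column_stack([vec[:N_LANDMARKS], vec[N_LANDMARKS:]])


@dataclass
class PointDistributionModel:
    """Mean shape plus orthonormal variation modes with their variances."""

    mean_shape: np.ndarray  # (38,)
    modes: np.ndarray       # (38, n_modes), orthonormal columns
    variances: np.ndarray   # (n_modes,), descending
    n_modes: int

    def project(self, vec: np.ndarray) -> np.ndarray:
        """Mode coefficients b = P^T (x - mean)."""
        return self.modes.T @ (vec - self.mean_shape)

    def reconstruct(self, b: np.ndarray) -> np.ndarray:
        return self.mean_shape + self.modes @ b

    def clamp(self, b: np.ndarray, n_sd: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        """Clamp each coefficient to ``+/- n_sd * sqrt(lambda_i)``.

        Returns the clamped coefficients and a boolean mask of which modes
        were clamped.
        """
        lim = n_sd * np.sqrt(self.variances)
        clamped = np.clip(b, -lim, lim)
        return clamped, ~np.isclose(clamped, b)


def build_pdm(
    training_shapes: list[LandmarkShape], variance_fraction: float = 0.98
) -> PointDistributionModel:
    """Eigendecompose the covariance of stacked training-shape vectors.

    Retains the smallest number of modes whose cumulative variance reaches
    ``variance_fraction`` of the total.  No Procrustes alignment is applied:
    absolute position in the image is part of the modelled variation.  A set
    of identical shapes yields a valid model with zero modes.
    """
    if len(training_shapes) < 2:
        raise ValueError("at least two training shapes required")
    X = np.vstack([s.vector() for s in training_shapes])
    mean = X.mean(axis=0)
    C = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        return PointDistributionModel(mean, np.zeros((mean.size, 0)),
                                      np.zeros(0), 0)
    cum = np.cumsum(evals) / total
    n_modes = int(np.searchsorted(cum, variance_fraction) + 1)
    return PointDistributionModel(mean, evecs[:, :n_modes],
                                  evals[:n_modes], n_modes)


@dataclass
class IntensityProfileModel:
    """Per-landmark, per-level Gaussian models of normal intensity-gradient profiles.

    ``means[level]`` is ``(19, 2k+1)``; ``inv_covariances[level]`` is
    ``(19, 2k+1, 2k+1)`` (covariance regularised by ``eps`` on the diagonal
    before inversion).  ``clamped_landmarks`` flags landmarks whose profile
    had to be clamped at an image edge during training.
    """

    k: int
    n_levels: int
    means: list[np.ndarray]
    covariances: list[np.ndarray]
    inv_covariances: list[np.ndarray]
    eps: float
    clamped_landmarks: np.ndarray = field(
        default_factory=lambda: np.zeros(N_LANDMARKS, dtype=bool)
    )


def image_pyramid(image: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Gaussian pyramid: smooth (sigma=1) and downsample by 2 per level."""
    levels = [np.asarray(image, dtype=float)]
    for _ in range(n_levels - 1):
        levels.append(gaussian_filter(levels[-1], 1.0)[::2, ::2])
    return levels


def _normals(points: np.ndarray) -> np.ndarray:
    """Unit boundary normals per landmark, oriented toward larger rows.

    The normal at landmark j is perpendicular to the chord joining its
    neighbours (one-sided at the ends).  For near-horizontal aponeuroses it is
    close to the image column direction.
    """
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    n = np.column_stack([-t[:, 1], t[:, 0]])
    norms = np.linalg.norm(n, axis=1)
    norms[norms == 0] = 1.0
    n = n / norms[:, None]
    flip = n[:, 1] < 0
    n[flip] *= -1
    return n


def _sample_along_normals(
    image: np.ndarray,
    centers: np.ndarray,
    normals: np.ndarray,
    offsets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples at ``centers + offset*normal`` for every offset.

    Returns ``(samples, clamped)`` where samples is ``(n_points, n_offsets)``
    and clamped flags points whose sample positions left the image (values
    are clamped to the nearest edge pixel).
    """
    xs = centers[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    ys = centers[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]
    h, w = image.shape
    clamped = (
        (xs < 0).any(axis=1) | (xs > w - 1).any(axis=1)
        | (ys < 0).any(axis=1) | (ys > h - 1).any(axis=1)
    )
    vals = map_coordinates(image, [ys.ravel(), xs.ravel()], order=1,
                           mode="nearest")
    return vals.reshape(xs.shape), clamped


def _gradient_profiles(samples: np.ndarray) -> np.ndarray:
    """Normalised central-difference gradient of sampled intensity profiles.

    Input ``(..., m)`` intensity samples yield ``(..., m-2)`` gradient values,
    each profile normalised by the sum of absolute values (zero profiles are
    returned as zero vectors, no division by zero).
    """
    g = 0.5 * (samples[..., 2:] - samples[..., :-2])
    norm = np.abs(g).sum(axis=-1, keepdims=True)
    safe = np.where(norm > 0, norm, 1.0)
    return g / safe


def build_intensity_models(
    images: ImageSequence | list[ImageSequence],
    labels: list[LandmarkShape] | list[list[LandmarkShape]],
    k: int = 6,
    n_levels: int = 5,
    eps_frac: float = 1e-6,
) -> IntensityProfileModel:
    """Train the per-landmark intensity-gradient models at every pyramid level.

    For each level the image is smoothed and downsampled by two; at each
    labelled landmark the intensity-gradient profile along the local boundary
    normal is sampled (2k+1 values, normalised by the sum of absolute
    values).  Mean and covariance accumulate over the labelled frames; the
    covariance is regularised by adding ``eps_frac * mean(diagonal)`` to the
    diagonal before inversion.

    ``images``/``labels`` may be a single sequence with its labelled shapes
    or parallel lists of sequences and label lists (per-source training over
    several trials).
    """
    if k < 3:
        raise ValueError("profile half-length k must be >= 3")
    if isinstance(images, ImageSequence):
        pairs = [(images, labels)]
    else:
        pairs = list(zip(images, labels))
    if not pairs or any(len(lab) == 0 for _, lab in pairs):
        raise ValueError("labelled frames are required")

    offsets = np.arange(-(k + 1), k + 2, dtype=float)  # 2k+3 samples
    per_level_feats: list[list[np.ndarray]] = [[] for _ in range(n_levels)]
    clamped_any = np.zeros(N_LANDMARKS, dtype=bool)
    for seq, labs in pairs:
        for shape in labs:
            frame = seq.frames[shape.frame_index]
            pyr = image_pyramid(frame, n_levels)
            normals = _normals(shape.points)
            for lvl in range(n_levels):
                centers = shape.points / (2**lvl)
                samples, clamped = _sample_along_normals(
                    pyr[lvl], centers, normals, offsets
                )
                clamped_any |= clamped
                per_level_feats[lvl].append(_gradient_profiles(samples))

    means, covs, invs = [], [], []
    for lvl in range(n_levels):
        feats = np.stack(per_level_feats[lvl])  # (n_frames, 19, 2k+1)
        mean = feats.mean(axis=0)
        d = feats - mean[None]
        nf = feats.shape[0]
        if nf > 1:
            cov = np.einsum("fjp,fjq->jpq", d, d) / (nf - 1)
        else:
            cov = np.zeros((N_LANDMARKS, 2 * k + 1, 2 * k + 1))
        diag_mean = np.einsum("jpp->j", cov) / (2 * k + 1)
        eps = eps_frac * np.where(diag_mean > 0, diag_mean, 1.0)
        cov = cov + eps[:, None, None] * np.eye(2 * k + 1)[None]
        means.append(mean)
        covs.append(cov)
        invs.append(np.linalg.inv(cov))
    return IntensityProfileModel(k=k, n_levels=n_levels, means=means,
                                 covariances=covs, inv_covariances=invs,
                                 eps=eps_frac, clamped_landmarks=clamped_any)


@dataclass
class ShapeModel:
    """A trained active shape model bound to one image source."""

    pdm: PointDistributionModel
    intensity: IntensityProfileModel
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Persist as a structured .npz archive (versioned layout)."""
        path = Path(path)
        arrays = {
            "mean_shape": self.pdm.mean_shape,
            "modes": self.pdm.modes,
            "variances": self.pdm.variances,
            "clamped_landmarks": self.intensity.clamped_landmarks,
        }
        for lvl in range(self.intensity.n_levels):
            arrays[f"profile_mean_{lvl}"] = self.intensity.means[lvl]
            arrays[f"profile_cov_{lvl}"] = self.intensity.covariances[lvl]
        meta = dict(self.metadata)
        meta.update({
            "format_version": 1,
            "k": self.intensity.k,
            "n_levels": self.intensity.n_levels,
            "eps": self.intensity.eps,
        })
        arrays["metadata_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["metadata_json"]).decode())
            pdm = PointDistributionModel(
                z["mean_shape"], z["modes"], z["variances"],
                z["modes"].shape[1],
            )
            n_levels, k = meta["n_levels"], meta["k"]
            means = [z[f"profile_mean_{lvl}"] for lvl in range(n_levels)]
            covs = [z[f"profile_cov_{lvl}"] for lvl in range(n_levels)]
            invs = [np.linalg.inv(c) for c in covs]
            intensity = IntensityProfileModel(
                k=k, n_levels=n_levels, means=means, covariances=covs,
                inv_covariances=invs, eps=meta["eps"],
                clamped_landmarks=z["clamped_landmarks"],
            )
        info = {k_: v for k_, v in meta.items()
                if k_ not in ("format_version", "k", "n_levels", "eps")}
        return cls(pdm, intensity, info)


@dataclass
class FitDiagnostics:
    """Convergence record of one frame's shape fit."""

    iterations: int
    converged: bool
    mean_mahalanobis: float
    b: np.ndarray
    clamped_modes: np.ndarray
    max_last_move_px: float


def _choose_candidates(
    mahal: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """Per landmark, the candidate step minimising the Mahalanobis distance.

    Ties (within relative 1e-12) break toward the smallest displacement from
    the current position, for stability.
    """
    chosen = np.empty(mahal.shape[0], dtype=int)
    for j in range(mahal.shape[0]):
        m = mahal[j]
        tol = 1e-12 * max(1.0, abs(m.min()))
        tied = np.flatnonzero(m <= m.min() + tol)
        chosen[j] = tied[np.argmin(np.abs(candidates[tied]))]
    return candidates[chosen]


def fit_shape(
    model: ShapeModel,
    image: np.ndarray | list[np.ndarray],
    init: LandmarkShape,
    search_range: int = 4,
    max_iter: int = 20,
    n_levels: int = 3,
) -> tuple[LandmarkShape, FitDiagnostics]:
    """Fit the ASM to one frame by coarse-to-fine Mahalanobis search.

    At each pyramid level, every landmark evaluates candidate positions at
    ``+/- search_range`` unit steps along its boundary normal (one step = one
    pixel at that level) and moves to the candidate whose normalised
    intensity-gradient profile minimises the Mahalanobis distance to the
    trained model.  The updated points are then projected onto the PDM with
    each mode coefficient clamped to +/-3 SD and the x-coordinates re-pinned
    to the standard columns.  Iteration at a level stops when fewer than 10%
    of landmarks move more than one pixel, or after ``max_iter`` iterations.

    ``image`` may be a single frame or a precomputed pyramid (finest first).
    Non-convergence never raises; the best shape is returned with
    ``converged=False``.
    """
    intensity = model.intensity
    pdm = model.pdm
    k = intensity.k
    n_levels = min(n_levels, intensity.n_levels)
    if isinstance(image, list):
        pyr = image
        if len(pyr) < n_levels:
            raise ValueError("pyramid has fewer levels than requested")
    else:
        pyr = image_pyramid(image, n_levels)

    h, w = pyr[0].shape
    pts = init.points.copy()
    if (pts[:, 1].min() < 0) or (pts[:, 1].max() > h - 1):
        raise ValueError("initial shape lies outside the image")

    candidates = np.arange(-search_range, search_range + 1, dtype=float)
    win = 2 * k + 1
    total_iters = 0
    converged = True
    mean_mahal = np.nan
    b = np.zeros(pdm.n_modes)
    clamped = np.zeros(pdm.n_modes, dtype=bool)
    max_move = np.inf

    for lvl in range(n_levels - 1, -1, -1):
        scale = 2.0**lvl
        img_l = pyr[lvl]
        mean_l = intensity.means[lvl]
        inv_l = intensity.inv_covariances[lvl]
        level_converged = False
        for _ in range(max_iter):
            total_iters += 1
            prev = pts.copy()
            normals = _normals(pts)
            centers = pts / scale
            offsets = np.arange(-(search_range + k + 1),
                                search_range + k + 2, dtype=float)
            samples, _ = _sample_along_normals(img_l, centers, normals, offsets)
            grads = _gradient_profiles_raw(samples)
            # windows: candidate c covers grads[:, c+r : c+r+win]
            g_win = np.stack([
                grads[:, c:c + win] for c in range(2 * search_range + 1)
            ], axis=1)  # (19, n_cand, win)
            norm = np.abs(g_win).sum(axis=-1, keepdims=True)
            g_win = g_win / np.where(norm > 0, norm, 1.0)
            d = g_win - mean_l[:, None, :]
            mahal = np.einsum("jcp,jpq,jcq->jc", d, inv_l, d)
            steps = _choose_candidates(mahal, candidates)
            mean_mahal = float(
                mahal[np.arange(N_LANDMARKS),
                      np.searchsorted(candidates, steps)].mean()
            )
            moved = pts + (steps[:, None] * scale) * normals
            vec = np.concatenate([LANDMARK_COLUMNS.astype(float), moved[:, 1]])
            b = pdm.project(vec)
            b, clamped = pdm.clamp(b)
            rec = _unpack(pdm.reconstruct(b))
            pts = np.column_stack([LANDMARK_COLUMNS.astype(float), rec[:, 1]])
            np.clip(pts[:, 1], 0, h - 1, out=pts[:, 1])
            move = np.linalg.norm(pts - prev, axis=1)
            max_move = float(move.max())
            if (move > 1.0).sum() < 0.1 * N_LANDMARKS:
                level_converged = True
                break
        if not level_converged:
            converged = False

    shape = LandmarkShape(pts, init.frame_index)
    diag = FitDiagnostics(total_iters, converged, mean_mahal, b, clamped,
                          max_move)
    return shape, diag


def _gradient_profiles_raw(samples: np.ndarray) -> np.ndarray:
    """Central-difference gradient without normalisation (windows are
    normalised individually during the candidate search)."""
    return 0.5 * (samples[..., 2:] - samples[..., :-2])


@dataclass
class LandmarkTrajectory:
    """Per-frame segmented shapes with convergence diagnostics."""

    shapes: list[LandmarkShape]
    diagnostics: list[FitDiagnostics]
    frame_rate_hz: float
    flagged_frames: list[int] = field(default_factory=list)

    def rows(self) -> np.ndarray:
        """Landmark rows as an ``(n_frames, 19)`` array."""
        return np.vstack([s.points[:, 1] for s in self.shapes])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format landmark table: frame, point_index, x_px, y_px."""
        rows = []
        for s in self.shapes:
            for j, (x, y) in enumerate(s.points):
                rows.append({"frame": s.frame_index, "point_index": j,
                             "x_px": x, "y_px": y})
        return pd.DataFrame(rows)


def train_shape_model(
    data: list[tuple[ImageSequence, list[LandmarkShape]]],
    variance_fraction: float = 0.98,
    k: int = 6,
    n_levels: int = 5,
    eps_frac: float = 1e-6,
    metadata: dict | None = None,
) -> ShapeModel:
    """Train PDM and intensity models from labelled frames of one source.

    Training data stay isolated to one participant/source: the model records
    its source in ``metadata`` and downstream tooling can refuse cross-source
    application.
    """
    all_shapes = [s for _, labs in data for s in labs]
    pdm = build_pdm(all_shapes, variance_fraction)
    intensity = build_intensity_models(
        [seq for seq, _ in data], [labs for _, labs in data],
        k=k, n_levels=n_levels, eps_frac=eps_frac,
    )
    return ShapeModel(pdm, intensity, metadata or {})


def segment_sequence(
    model: ShapeModel,
    images: ImageSequence,
    init: LandmarkShape | None = None,
    search_range: int = 4,
    max_iter: int = 20,
    first_frame_levels: int = 5,
    later_frame_levels: int = 3,
    pyramids: list[list[np.ndarray]] | None = None,
) -> LandmarkTrajectory:
    """Segment every frame, propagating each solution to the next frame.

    The first frame starts from ``init`` (or the PDM mean shape) and is
    searched over five pyramid levels; each subsequent frame starts from the
    previous frame's solution with a three-level search.  A frame whose fit
    raises is flagged and carries the previous shape forward.
    """
    n_levels_model = model.intensity.n_levels
    first_levels = min(first_frame_levels, n_levels_model)
    later_levels = min(later_frame_levels, n_levels_model)
    if init is None:
        init = LandmarkShape(_unpack(model.pdm.mean_shape))

    shapes: list[LandmarkShape] = []
    diags: list[FitDiagnostics] = []
    flagged: list[int] = []
    current = init
    for i in range(images.n_frames):
        levels = first_levels if i == 0 else later_levels
        pyr = (pyramids[i] if pyramids is not None
               else image_pyramid(images.frames[i], levels))
        try:
            fitted, diag = fit_shape(
                model, pyr, LandmarkShape(current.points.copy(), i),
                search_range=search_range, max_iter=max_iter, n_levels=levels,
            )
        except Exception:
            flagged.append(i)
            fitted = LandmarkShape(current.points.copy(), i)
            diag = FitDiagnostics(0, False, np.nan, np.zeros(model.pdm.n_modes),
                                  np.zeros(model.pdm.n_modes, dtype=bool), np.nan)
        shapes.append(fitted)
        diags.append(diag)
        current = fitted
    return LandmarkTrajectory(shapes, diags, images.frame_rate_hz, flagged)
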