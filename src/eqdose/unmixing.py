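"""Fluorescence image processing: illumination correction, spectral
unmixing and doxorubicin signal calibration.

Raw images follow the multiplicative model ``I = L * (C + b)`` where ``L``
is a smooth vignetting (illumination) field, ``C`` the signal from cells
and ``b`` the background.  The pipeline:

1. suppress cell signal with a median disc filter, average the background
   over timepoints, fit a low-order smooth surface and normalise it to a
   maximum of 1 (:func:`estimate_illumination`);
2. divide each frame by the field (:func:`correct_illumination`);
3. build the fluorophore x channel mixing matrix ``T`` from single-
   fluorophore control images, each spectrum scaled so its brightest
   channel is 1 (:func:`build_mixing_matrix`);
4. solve the overdetermined linear system ``S T = I`` by QR for the
   per-fluorophore signals, per region (default) or per pixel
   (:func:`unmix`);
5. convert the doxorubicin signal to concentration through the linear
   calibration ``S_Dox = a [Dox] + b`` (:func:`calibrate`,
   :func:`signal_to_concentration`).

Pixel convention: row-major arrays, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.ndimage import median_filter
from skimage.measure import label as _label
from skimage.morphology import disk

__all__ = [
    "SpectralStack",
    "IlluminationField",
    "MixingMatrix",
    "CalibrationLine",
    "estimate_illumination",
    "correct_illumination",
    "build_mixing_matrix",
    "unmix",
    "calibrate",
    "signal_to_concentration",
    "segment_cells",
    "compartment_masks",
    "FLUOROPHORES",
    "N_CHANNELS",
]

FLUOROPHORES = ("H2B", "MDR", "Dox", "background")
N_CHANNELS = 5


@dataclass(frozen=True)
class SpectralStack:
    """One timepoint of multi-channel imaging: ``images`` is (5, H, W)."""

    images: np.ndarray
    timepoint: int = 0

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        if images.ndim != 3 or images.shape[0] != N_CHANNELS:
            raise ValueError(f"images must have shape ({N_CHANNELS}, H, W)")
        if np.any(images < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "images", images)

    @property
    def shape(self) -> tuple:
        return self.images.shape[1:]


@dataclass(frozen=True)
class IlluminationField:
    """Smooth multiplicative vignetting surface, max 1, positive."""

    L: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        if L.ndim != 2:
            raise ValueError("L must be a 2-D field")
        if not np.isclose(L.max(), 1.0):
            raise ValueError("L must be normalised to a maximum of 1")
        if np.any(L <= 0):
            raise ValueError("L must be positive everywhere")
        object.__setattr__(self, "L", L)


@dataclass(frozen=True)
class MixingMatrix:
    """Fluorophore x channel matrix of relative emission intensities."""

    T: np.ndarray
    labels: tuple = FLUOROPHORES

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.shape != (len(FLUOROPHORES), N_CHANNELS):
            raise ValueError(f"T must be {len(FLUOROPHORES)}x{N_CHANNELS}")
        if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(T.max(axis=1), 1.0):
            raise ValueError("each row must contain a 1 in its brightest channel")
        if np.linalg.matrix_rank(T, tol=1e-10) < len(FLUOROPHORES):
            raise ValueError("mixing matrix is rank-deficient: spectra are not separable")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class CalibrationLine:
    """Linear doxorubicin calibration: signal = a * [Dox] + b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError("calibration slope must be positive")


def _poly2d_design(shape: tuple, degree: int) -> np.ndarray:
    ny, nx = shape
    y = np.linspace(-1.0, 1.0, ny)
    x = np.linspace(-1.0, 1.0, nx)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [xx.ravel() ** i * yy.ravel() ** j
            for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.stack(cols, axis=1)


def estimate_illumination(
    images: Sequence[np.ndarray], radius: int = 50, degree: int = 2
) -> IlluminationField:
    """Estimate the vignetting field from a time series of one channel.

    Cell signal is suppressed per frame by a median disc filter of the
    given pixel radius, the background frames are averaged over timepoints,
    and a smooth 2-D polynomial surface (default degree 2) is fitted and
    normalised to a maximum of 1.
    """
    frames = [np.asarray(im, dtype=float) for im in images]
    if not frames:
        raise ValueError("at least one timepoint is required")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share a shape")
    if all(np.all(f == 0) for f in frames):
        raise ValueError("all-zero images carry no illumination information")
    footprint = disk(radius)
    background = np.mean([median_filter(f, footprint=footprint) for f in frames], axis=0)
    X = _poly2d_design(shape, degree)
    coef, *_ = np.linalg.lstsq(X, background.ravel(), rcond=None)
    surface = (X @ coef).reshape(shape)
    peak = surface.max()
    if peak <= 0:
        raise ValueError("fitted surface is non-positive; cannot normalise")
    L = surface / peak
    if np.any(L <= 0):
        raise ValueError("fitted illumination surface is not positive everywhere")
    return IlluminationField(L=L)


def correct_illumination(image: np.ndarray, L) -> np.ndarray:
    """Divide an image by the illumination surface, elementwise."""
    field = L.L if isinstance(L, IlluminationField) else np.asarray(L, dtype=float)
    image = np.asarray(image, dtype=float)
    if image.shape != field.shape:
        raise ValueError("image and illumination field shapes differ")
    if np.any(field <= 0):
        raise ValueError("illumination field must be positive everywhere")
    return image / field


def build_mixing_matrix(controls: Mapping[str, np.ndarray]) -> MixingMatrix:
    """Assemble T from single-fluorophore control acquisitions.

    ``controls`` maps each fluorophore name to either its five per-channel
    mean intensities or a full (5, H, W) control stack (averaged here).
    The brightest channel of each spectrum is taken as the true image and
    scaled to 1.  Raises if a control is all zero or the assembled matrix
    is rank-deficient (inseparable spectra).
    """
    missing = set(FLUOROPHORES) - set(controls)
    if missing:
        raise ValueError(f"missing control acquisitions for: {sorted(missing)}")
    rows = []
    for name in FLUOROPHORES:
        data = np.asarray(controls[name], dtype=float)
        means = data.reshape(N_CHANNELS, -1).mean(axis=1) if data.ndim == 3 else data
        if means.shape != (N_CHANNELS,):
            raise ValueError(f"control {name!r} must provide {N_CHANNELS} channel intensities")
        peak = means.max()
        if peak <= 0:
            raise ValueError(f"control {name!r} has no signal in any channel")
        rows.append(means / peak)
    return MixingMatrix(T=np.vstack(rows))


def unmix(intensities: np.ndarray, T) -> tuple:
    """Solve ``S T = I`` for the fluorophore signals by QR least squares.

    ``intensities`` has channel as its last axis: a 5-vector of region
    means, a batch (..., 5), or a full image (H, W, 5) for per-pixel
    unmixing.  Returns ``(S, residual_norm)`` with shapes (..., 4) and
    (...,).
    """
    M = T.T if isinstance(T, MixingMatrix) else np.asarray(T, dtype=float)
    if M.shape != (len(FLUOROPHORES), N_CHANNELS):
        raise ValueError("mixing matrix must be 4x5")
    if np.linalg.matrix_rank(M, tol=1e-10) < len(FLUOROPHORES):
        raise ValueError("mixing matrix is rank-deficient")
    I = np.asarray(intensities, dtype=float)
    if I.shape[-1] != N_CHANNELS:
        raise ValueError(f"last axis must hold the {N_CHANNELS} channel intensities")
    if not np.all(np.isfinite(I)):
        raise ValueError("intensities must be finite")
    flat = I.reshape(-1, N_CHANNELS).T  # (5, m)
    Q, R = np.linalg.qr(M.T)  # M.T is (5, 4)
    S = solve_triangular(R, Q.T @ flat)  # (4, m)
    resid = np.linalg.norm(M.T @ S - flat, axis=0)
    out_shape = I.shape[:-1]
    return S.T.reshape(out_shape + (len(FLUOROPHORES),)), resid.reshape(out_shape)


def calibrate(concentrations_nM: Sequence[float], signals: Sequence[float]) -> CalibrationLine:
    """Fit the linear signal model to doxorubicin standards."""
    conc = np.asarray(concentrations_nM, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.shape != sig.shape or conc.size < 2:
        raise ValueError("at least two (concentration, signal) standards are required")
    if np.unique(conc).size < 2:
        raise ValueError("standards must span at least two distinct concentrations")
    a, b = np.polyfit(conc, sig, 1)
    return CalibrationLine(a=float(a), b=float(b))


def signal_to_concentration(s_dox, cal: CalibrationLine) -> tuple:
    """Invert the calibration; negatives are clipped to 0 and flagged."""
    s = np.asarray(s_dox, dtype=float)
    conc = (s - cal.b) / cal.a
    clipped = conc < 0
    return np.clip(conc, 0.0, None), clipped


def segment_cells(image: np.ndarray, threshold: float) -> tuple:
    """Threshold segmentation with 8-connected component counting.

    Returns ``(mask, count)``; apply to illumination-corrected images.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    image = np.asarray(image, dtype=float)
    mask = image > threshold
    labels = _label(mask, connectivity=2)
    return mask, int(labels.max())


def compartment_masks(cell_mask: np.ndarray, guard_px: int = 2) -> tuple:
    """Split a field into intracellular and extracellular regions.

    Intracellular is the segmented cell mask; extracellular is its
    complement minus a guard band (default 2 px of dilation) so that edge
    bleed from cells does not contaminate the extracellular means.
    """
    from scipy.ndimage import binary_dilation

    cell_mask = np.asarray(cell_mask, dtype=bool)
    if guard_px < 0:
        raise ValueError("guard_px must be nonnegative")
    guarded = binary_dilation(cell_mask, structure=disk(1), iterations=guard_px) \
        if guard_px else cell_mask
    return cell_mask, ~guarded
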