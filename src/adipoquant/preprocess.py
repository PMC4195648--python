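"""Per-slice pre-processing: normalization, background removal, denoising,
edge enhancement and foreground extraction.

All stages operate on 2-D slices in normalized [0, 1] intensity units and are
applied slice-by-slice by the pipeline, matching the 2-D character of the
acquisition (thick transverse slices, thin in-plane pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import NoBodyDetected, ValidationError


@dataclass
class DiffusionParams:
    """Parameters of Perona–Malik anisotropic diffusion.

    ``kappa`` is the edge-stopping conductance scale in normalized intensity
    units: gradients well below kappa are smoothed, gradients well above it
    are preserved. ``step_size`` must satisfy the 2-D explicit-scheme
    stability bound (<= 0.25).
    """

    n_iterations: int = 15
    kappa: float = 0.1
    step_size: float = 0.2
    conductance_form: str = "exponential"  # or "rational"

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValidationError("n_iterations must be >= 0")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if not (0 < self.step_size <= 0.25):
            raise ValidationError(
                "step_size must be in (0, 0.25] for 2-D stability"
            )
        if self.conductance_form not in ("exponential", "rational"):
            raise ValidationError(
                "conductance_form must be 'exponential' or 'rational'"
            )


def normalize_intensity(
    pixels: np.ndarray,
    low_percentile: float = 0.5,
    high_percentile: float = 99.5,
) -> np.ndarray:
    """Robust min–max normalization to [0, 1].

    Intensities are clipped at the given percentiles before the affine map,
    so isolated hot pixels do not compress the body contrast. Constant
    slices map to all zeros. The map is monotone in the input intensities.
    """
    pixels = np.asarray(pixels, dtype=float)
    finite = np.isfinite(pixels)
    if not finite.any():
        raise ValidationError("slice contains no finite values")
    vals = pixels[finite]
    lo = np.percentile(vals, low_percentile)
    hi = np.percentile(vals, high_percentile)
    if hi <= lo:
        return np.zeros_like(pixels)
    out = np.clip(pixels, lo, hi)
    return (out - lo) / (hi - lo)


def remove_background(pixels: np.ndarray, bg_threshold: float = 0.05) -> np.ndarray:
    """Zero out pixels strictly below ``bg_threshold`` (fraction of the
    normalized range); everything else is unchanged."""
    if not (0.0 <= bg_threshold <= 1.0):
        raise ValidationError("bg_threshold must lie in [0, 1]")
    pixels = np.asarray(pixels, dtype=float)
    out = pixels.copy()
    out[pixels < bg_threshold] = 0.0
    return out


def _conductance(grad: np.ndarray, kappa: float, form: str) -> np.ndarray:
    if form == "exponential":
        return np.exp(-((grad / kappa) ** 2))
    return 1.0 / (1.0 + (grad / kappa) ** 2)


def anisotropic_diffuse(
    pixels: np.ndarray, params: DiffusionParams | None = None
) -> np.ndarray:
    """Perona–Malik anisotropic diffusion with zero-flux boundaries.

    Each iteration adds ``step_size`` times the sum over the four nearest
    neighbours of ``g(dI) * dI``, where ``dI`` is the neighbour difference
    and ``g`` the chosen conductance. The antisymmetric flux form conserves
    the global mean; the flow never increases total variation.
    """
    if params is None:
        params = DiffusionParams()
    out = np.asarray(pixels, dtype=float).copy()
    k, dt, form = params.kappa, params.step_size, params.conductance_form
    for _ in range(params.n_iterations):
        # neighbour differences with edge replication = zero-flux boundaries
        padded = np.pad(out, 1, mode="edge")
        d_n = padded[:-2, 1:-1] - out
        d_s = padded[2:, 1:-1] - out
        d_w = padded[1:-1, :-2] - out
        d_e = padded[1:-1, 2:] - out
        flux = (
            _conductance(np.abs(d_n), k, form) * d_n
            + _conductance(np.abs(d_s), k, form) * d_s
            + _conductance(np.abs(d_w), k, form) * d_w
            + _conductance(np.abs(d_e), k, form) * d_e
        )
        out = out + dt * flux
    return out


def enhance_edges(
    pixels: np.ndarray, amount: float = 1.0, sigma: float = 1.0
) -> np.ndarray:
    """Unsharp masking: ``I + amount * (I - G_sigma * I)``, clipped to [0, 1].

    ``amount = 0`` is the identity; constant slices are fixed points.
    """
    if amount < 0:
        raise ValidationError("edge-enhancement gain must be >= 0")
    pixels = np.asarray(pixels, dtype=float)
    if amount == 0:
        return pixels.copy()
    blurred = ndimage.gaussian_filter(pixels, sigma=sigma, mode="nearest")
    return np.clip(pixels + amount * (pixels - blurred), 0.0, 1.0)


def bright_foreground(pixels: np.ndarray) -> np.ndarray:
    """Largest connected bright component of a normalized slice.

    Otsu's threshold over the nonzero pixels separates the bright fat/skin
    shell from darker tissue; small disjoint bright artifacts are dropped
    by the largest-component rule. This is the unfilled foreground — on an
    abdominal slice, the subcutaneous shell ring.
    """
    pixels = np.asarray(pixels, dtype=float)
    nonzero = pixels[pixels > 0]
    if nonzero.size == 0:
        raise NoBodyDetected("no body detected: slice is entirely background")
    if np.ptp(nonzero) == 0:
        bright = pixels > 0
    else:
        thr = threshold_otsu(nonzero)
        bright = pixels > thr
    if not bright.any():
        raise NoBodyDetected("no body detected: nothing above Otsu threshold")
    labeled, n = ndimage.label(bright)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def adaptive_threshold(pixels: np.ndarray) -> np.ndarray:
    """Foreground (body) mask from a normalized, background-suppressed slice.

    The largest bright component (:func:`bright_foreground`) is hole-filled,
    so iso/hypo-intense organs enclosed by the fat shell become part of the
    foreground. Returns a boolean mask.
    """
    return ndimage.binary_fill_holes(bright_foreground(pixels))
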