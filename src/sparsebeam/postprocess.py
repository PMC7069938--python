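"""Display post-processing and reconstruction-quality metrics.

The raw l1 estimate is point-like, so for display (and for the quality
metric) it is smoothed by an isotropic Gaussian (default σ = 12.5 µm, the
coarse grid step), interpolated to a four-times finer grid (3.125 µm) and
normalized to unit maximum.  The quality metric is the normalized,
non-mean-subtracted inner product

    C = Σᵢ T̂(i)·T_true(i) / √(Σᵢ T̂²(i) · Σᵢ T_true²(i)) ∈ [0, 1]

between the post-processed reconstruction and the identically post-processed
ideal object (value 1 in the grid cell of each true source, 0 elsewhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks

from .exceptions import MetricError, UnderResolvedError
from .geometry import ReconGrid
from .signals import SourceSet

__all__ = [
    "DisplayImage",
    "smooth_and_upsample",
    "correlation",
    "make_ideal_object",
    "peak_spacing",
]


@dataclass(frozen=True)
class DisplayImage:
    """Nonnegative, max-normalized image on a fine display grid."""

    pixels: np.ndarray  # (nz_fine, nx_fine)
    x_coords: np.ndarray
    z_coords: np.ndarray
    fine_step: float
    is_zero: bool = False


def smooth_and_upsample(
    image: np.ndarray,
    grid: ReconGrid,
    sigma: float = 12.5e-6,
    fine_step: float = 3.125e-6,
) -> DisplayImage:
    """Gaussian-smooth (physical σ, kernel truncated at 4σ, zero padding),
    bicubically interpolate onto a ``fine_step`` grid spanning the same
    window, and normalize the maximum to 1.

    ``image`` is a (nz, nx) map on ``grid``; the coarse step must be an
    integer multiple of ``fine_step``.  An identically-zero image is
    returned unnormalized with ``is_zero`` set.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (grid.nz, grid.nx):
        raise ValueError("image shape does not match grid")
    if sigma < 0 or fine_step <= 0:
        raise ValueError("sigma must be >= 0 and fine_step > 0")
    factor = grid.step / fine_step
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fine_step must divide the coarse step evenly "
            f"(step {grid.step:g} / fine {fine_step:g} = {factor:g})"
        )
    factor = int(round(factor))

    if sigma > 0:
        image = gaussian_filter(
            image, sigma=sigma / grid.step, mode="constant", truncate=4.0
        )

    fx = grid.x_coords[0] + np.arange((grid.nx - 1) * factor + 1) * fine_step
    fz = grid.z_coords[0] + np.arange((grid.nz - 1) * factor + 1) * fine_step
    # bicubic where the grid allows it; thin grids degrade gracefully
    z_nodes, img_nodes = grid.z_coords, image
    if grid.nz == 1:  # duplicate the single depth line so the spline exists
        z_nodes = np.array([grid.z_coords[0], grid.z_coords[0] + grid.step])
        img_nodes = np.vstack([image, image])
    kz = min(3, len(z_nodes) - 1)
    kx = min(3, grid.nx - 1)
    if kx < 1:
        raise ValueError("grid needs at least 2 lateral points")
    spl = RectBivariateSpline(z_nodes, grid.x_coords, img_nodes, kx=kz, ky=kx)
    fine = spl(fz, fx)
    fine = np.maximum(fine, 0.0)  # clip spline undershoot

    peak = fine.max()
    if peak == 0.0:
        return DisplayImage(
            pixels=fine, x_coords=fx, z_coords=fz,
            fine_step=float(fine_step), is_zero=True,
        )
    return DisplayImage(
        pixels=fine / peak, x_coords=fx, z_coords=fz,
        fine_step=float(fine_step),
    )


def correlation(recon, truth) -> float:
    """Normalized inner-product correlation between two images on the same
    display grid (no mean subtraction); 1 for proportional images, 0 for
    disjoint support."""
    a = recon.pixels if isinstance(recon, DisplayImage) else np.asarray(recon, float)
    b = truth.pixels if isinstance(truth, DisplayImage) else np.asarray(truth, float)
    if a.shape != b.shape:
        raise MetricError("images must share the display grid")
    na = float(np.sum(a * a))
    nb = float(np.sum(b * b))
    if na == 0.0 or nb == 0.0:
        raise MetricError("correlation undefined for an identically-zero image")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def make_ideal_object(sources: SourceSet, grid: ReconGrid) -> np.ndarray:
    """Ideal object: value 1 in the grid cell nearest each source, 0
    elsewhere; returns a (nz, nx) map.  Exact midpoints break to the lower
    cell index; two sources mapping to one cell trigger a collision
    warning (the cell stays at 1)."""
    img = np.zeros((grid.nz, grid.nx))
    for x, z in sources.positions:
        if not (grid.x_coords[0] - grid.step / 2 <= x
                <= grid.x_coords[-1] + grid.step / 2) or not (
                grid.z_coords[0] - grid.step / 2 <= z
                <= grid.z_coords[-1] + grid.step / 2):
            raise ValueError(f"source ({x:g}, {z:g}) m falls outside the grid")
        ix, iz = grid.nearest_cell(x, z)
        if img[iz, ix] == 1.0:
            warnings.warn(
                f"two sources map to the same grid cell ({ix}, {iz})",
                stacklevel=2,
            )
        img[iz, ix] = 1.0
    return img


def peak_spacing(
    display: DisplayImage,
    expected_peaks: int,
    prominence_fraction: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Detect ``expected_peaks`` lateral maxima and return their
    consecutive centre-to-centre spacings (m) and the mean spacing.

    The lateral profile through the global maximum is scanned for local
    maxima with prominence at least ``prominence_fraction`` of the global
    peak; the ``expected_peaks`` most prominent are kept, ordered by
    position.  Raises :class:`UnderResolvedError` when fewer maxima exist —
    the programmatic definition of "not resolved".
    """
    if expected_peaks < 2:
        raise ValueError("expected_peaks must be at least 2")
    img = display.pixels
    iz, _ = np.unravel_index(np.argmax(img), img.shape)
    profile = img[iz]
    peaks, props = find_peaks(
        profile, prominence=prominence_fraction * img.max()
    )
    if peaks.size < expected_peaks:
        raise UnderResolvedError(
            f"found {peaks.size} distinct lateral peaks, expected "
            f"{expected_peaks}: structure not resolved"
        )
    order = np.argsort(props["prominences"])[::-1][:expected_peaks]
    kept = np.sort(peaks[order])
    positions = display.x_coords[kept]
    spacings = np.diff(positions)
    return spacings, float(spacings.mean())
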