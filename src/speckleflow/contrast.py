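"""Spatial speckle contrast estimators.

The spatial speckle contrast is the local ratio of the standard deviation to
the mean of the pixel gray levels, Ks = sigma / <I>, evaluated over a small
sliding window (square side or disc diameter of 5 or 7 pixels in common
practice).  This module provides a slow reference estimator (explicit
summation over every window, the ``direct`` engine) and the fast
convolution-based "sums algorithm" variants found in the wild, which differ
in kernel shape, border padding and variance divisor and therefore disagree
near edges (and, for some published implementations, beyond them).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Tuple

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "KernelSpec",
    "ContrastMap",
    "disc_offsets",
    "contrast_direct",
    "contrast_sums",
    "contrast_variant",
    "crop_edges",
    "relative_error_map",
    "mean_ks",
]

_SHAPES = ("square", "disc")
_PADDINGS = ("none_crop", "reflect", "constant_zero", "symmetric")
_DIVISORS = ("population_n", "sample_n_minus_1")
_ENGINES = ("direct", "sums_uniform", "sums_correlate_pad", "sums_disc")

# scipy.ndimage naming crosses numpy.pad conventions: ndimage 'reflect'
# repeats the edge sample (numpy 'symmetric'), ndimage 'mirror' does not
# (numpy 'reflect').  Our 'reflect' follows scipy.ndimage.uniform_filter's
# default; 'symmetric' maps to ndimage 'mirror'.
_NDIMAGE_MODE = {"reflect": "reflect", "symmetric": "mirror", "constant_zero": "constant", "none_crop": "reflect"}

# Variances below this fraction of E[I^2] are double-precision cancellation
# noise (the sums algorithm subtracts two nearly equal O(E[I^2]) quantities);
# they are treated as exactly zero so constant regions report Ks = 0.
_VAR_EPS = 1e-12


_DISC_RULES = ("imagej", "euclidean")


def disc_offsets(size: int, rule: str = "imagej") -> Tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of the member pixels of a discrete disc kernel.

    ``imagej`` (default) is the circular-mask convention of ImageJ's rank
    filters, dy^2 + dx^2 <= r^2 + 1 with r = (size - 1) / 2: 21 members for
    diameter 5, 37 for diameter 7.  ``euclidean`` is the plain center-distance
    rule dy^2 + dx^2 <= r^2: 13 and 29 members.  The fatter ImageJ mask
    tracks the square kernel of equal nominal size much more closely.
    """
    if rule not in _DISC_RULES:
        raise ValueError(f"disc rule must be one of {_DISC_RULES}")
    radius = (size - 1) / 2.0
    slack = 1.0 if rule == "imagej" else 1e-9
    span = np.arange(-(size // 2), size // 2 + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    inside = dy ** 2 + dx ** 2 <= radius ** 2 + slack
    return dy[inside], dx[inside]


@dataclass(frozen=True)
class KernelSpec:
    """One numerically distinct Ks implementation variant."""

    shape: str = "square"
    size: int = 7
    padding: str = "none_crop"
    divisor: str = "population_n"
    engine: str = "direct"
    disc_rule: str = "imagej"

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.disc_rule not in _DISC_RULES:
            raise ValueError(f"disc_rule must be one of {_DISC_RULES}")
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 3, got {self.size}")
        if self.padding not in _PADDINGS:
            raise ValueError(f"padding must be one of {_PADDINGS}")
        if self.divisor not in _DIVISORS:
            raise ValueError(f"divisor must be one of {_DIVISORS}")
        if self.engine not in _ENGINES:
            raise ValueError(f"engine must be one of {_ENGINES}")

    @property
    def n_pixels(self) -> int:
        """Member-pixel count N of the window."""
        if self.shape == "square":
            return self.size * self.size
        return disc_offsets(self.size, self.disc_rule)[0].size

    @property
    def margin(self) -> int:
        return self.size // 2


@dataclass
class ContrastMap:
    """2D Ks image with kernel provenance and valid-region bounds.

    Undefined pixels (cropped margins, zero-mean windows) are NaN, never
    infinite.  ``valid_margin`` is the per-side width of the border region
    that is either undefined or influenced by padding.
    """

    values: np.ndarray
    exposure_time: float
    kernel: KernelSpec
    valid_margin: int
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("contrast map must be 2D")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("contrast values must be >= 0 where defined")


def _check_image(image: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    if min(image.shape) < kernel.size:
        raise ValueError(f"image {image.shape} smaller than kernel size {kernel.size}")
    return image


def _divisor_factor(kernel: KernelSpec) -> float:
    """Multiplier converting population variance to the configured divisor."""
    n = kernel.n_pixels
    return n / (n - 1.0) if kernel.divisor == "sample_n_minus_1" else 1.0


def contrast_direct(image: np.ndarray, kernel: KernelSpec, exposure_time: float = float("nan")) -> ContrastMap:
    """Reference Ks by explicit per-window summation (slow, edge-cropping).

    For every interior pixel the window mean and variance are accumulated
    directly from the member pixels, with the configured divisor; no padding
    is ever applied (border pixels are undefined).
    """
    image = _check_image(image, kernel)
    m = kernel.margin
    rows, cols = image.shape
    out = np.full(image.shape, np.nan)
    fac = _divisor_factor(kernel)
    n_clamped = 0
    if kernel.shape == "square":
        npix = kernel.size * kernel.size
        for i in range(m, rows - m):
            for j in range(m, cols - m):
                win = image[i - m : i + m + 1, j - m : j + m + 1]
                s = win.sum()
                s2 = (win * win).sum()
                mean = s / npix
                if mean == 0:
                    continue
                var = (s2 / npix - mean * mean) * fac
                if var < 0:
                    var = 0.0
                    n_clamped += 1
                elif var < _VAR_EPS * (s2 / npix):
                    var = 0.0
                out[i, j] = np.sqrt(var) / mean
    else:
        dy, dx = disc_offsets(kernel.size, kernel.disc_rule)
        npix = dy.size
        for i in range(m, rows - m):
            for j in range(m, cols - m):
                vals = image[i + dy, j + dx]
                s = vals.sum()
                mean = s / npix
                if mean == 0:
                    continue
                s2n = (vals * vals).sum() / npix
                var = (s2n - mean * mean) * fac
                if var < 0:
                    var = 0.0
                    n_clamped += 1
                elif var < _VAR_EPS * s2n:
                    var = 0.0
                out[i, j] = np.sqrt(var) / mean
    return ContrastMap(out, exposure_time, kernel, valid_margin=m, n_clamped=n_clamped)


def _local_means(image: np.ndarray, kernel: KernelSpec):
    """Local means of I and I*I by a single-pass box or disc convolution."""
    mode = _NDIMAGE_MODE[kernel.padding]
    if kernel.engine == "sums_correlate_pad":
        boundary = {"constant_zero": "fill", "none_crop": "fill", "reflect": "symm", "symmetric": "symm"}[
            kernel.padding
        ]
        w = np.ones((kernel.size, kernel.size)) / kernel.n_pixels
        m1 = signal.correlate2d(image, w, mode="same", boundary=boundary)
        m2 = signal.correlate2d(image * image, w, mode="same", boundary=boundary)
    elif kernel.shape == "square":
        m1 = ndimage.uniform_filter(image, kernel.size, mode=mode, cval=0.0)
        m2 = ndimage.uniform_filter(image * image, kernel.size, mode=mode, cval=0.0)
    else:
        dy, dx = disc_offsets(kernel.size, kernel.disc_rule)
        w = np.zeros((kernel.size, kernel.size))
        w[dy + kernel.margin, dx + kernel.margin] = 1.0 / dy.size
        m1 = ndimage.correlate(image, w, mode=mode, cval=0.0)
        m2 = ndimage.correlate(image * image, w, mode=mode, cval=0.0)
    return m1, m2


def contrast_sums(image: np.ndarray, kernel: KernelSpec, exposure_time: float = float("nan")) -> ContrastMap:
    """Vectorized Ks via the sums algorithm: Var = E[I^2] - E[I]^2.

    Equals :func:`contrast_direct` on the valid interior to floating-point
    tolerance; padding affects only pixels within ``size // 2`` of the
    border.  Negative variances produced by cancellation are clamped to zero
    and counted in ``n_clamped``.
    """
    image = _check_image(image, kernel)
    m1, m2 = _local_means(image, kernel)
    var = (m2 - m1 * m1) * _divisor_factor(kernel)
    neg = var < 0
    n_clamped = int(neg.sum())
    var = np.where(neg | (var < _VAR_EPS * m2), 0.0, var)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(m1 > 0, np.sqrt(var) / np.where(m1 > 0, m1, 1.0), np.nan)
    m = kernel.margin
    if kernel.padding == "none_crop":
        mask = np.full(image.shape, np.nan)
        mask[m:-m or None, m:-m or None] = 1.0
        out = out * mask
    return ContrastMap(out, exposure_time, kernel, valid_margin=m, n_clamped=n_clamped)


def contrast_variant(image: np.ndarray, kernel: KernelSpec, exposure_time: float = float("nan")) -> ContrastMap:
    """Dispatch a Ks computation on the kernel's engine.

    * ``direct`` — explicit summation reference.
    * ``sums_uniform`` — square kernel box filter (reflect padding by
      default, the scipy ``uniform_filter`` convention).
    * ``sums_correlate_pad`` — square kernel 2D correlation with constant
      zero padding (the ``correlate2d`` convention).
    * ``sums_disc`` — disc kernel convolution (zero or reflect padding).
    """
    if kernel.engine == "direct":
        return contrast_direct(image, kernel, exposure_time)
    if kernel.engine == "sums_uniform" and kernel.shape != "square":
        raise ValueError("sums_uniform implements square kernels")
    if kernel.engine == "sums_correlate_pad" and kernel.shape != "square":
        raise ValueError("sums_correlate_pad implements square kernels")
    if kernel.engine == "sums_disc" and kernel.shape != "disc":
        raise ValueError("sums_disc implements disc kernels")
    return contrast_sums(image, kernel, exposure_time)


def crop_edges(cmap: ContrastMap) -> ContrastMap:
    """Remove the ``size // 2`` border pixels affected by edge handling."""
    m = cmap.kernel.margin
    rows, cols = cmap.values.shape
    if rows <= 2 * m or cols <= 2 * m:
        raise ValueError(f"map {cmap.values.shape} too small to crop margin {m} per side")
    if cmap.valid_margin == 0:
        return replace(cmap, values=cmap.values.copy())
    return ContrastMap(
        cmap.values[m:-m, m:-m].copy(),
        cmap.exposure_time,
        cmap.kernel,
        valid_margin=0,
        n_clamped=cmap.n_clamped,
    )


def mean_ks(cmap: ContrastMap) -> float:
    """Spatial mean Ks over the cropped valid region."""
    values = crop_edges(cmap).values if cmap.valid_margin > 0 else cmap.values
    return float(np.nanmean(values))


class RelErrStats(NamedTuple):
    mean: float
    min: float
    max: float


def relative_error_map(test: ContrastMap, reference: ContrastMap):
    """Elementwise percent error 100 * (test - reference) / reference.

    Undefined (NaN) where the reference is undefined or zero.  Returns the
    error map and its spatial mean and extreme values over defined pixels.
    """
    if test.values.shape != reference.values.shape:
        raise ValueError(
            f"shape mismatch: {test.values.shape} vs {reference.values.shape}"
        )
    t_exp, r_exp = test.exposure_time, reference.exposure_time
    if np.isfinite(t_exp) and np.isfinite(r_exp) and t_exp != r_exp:
        raise ValueError(f"exposure mismatch: {t_exp} vs {r_exp}")
    ref = reference.values
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.where(ref != 0, 100.0 * (test.values - ref) / np.where(ref != 0, ref, 1.0), np.nan)
    defined = np.isfinite(err)
    if defined.any():
        stats = RelErrStats(float(np.nanmean(err)), float(np.nanmin(err)), float(np.nanmax(err)))
    else:
        stats = RelErrStats(float("nan"), float("nan"), float("nan"))
    return err, stats
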