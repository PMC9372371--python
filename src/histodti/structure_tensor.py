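"""2D structure-tensor analysis and the ROI anisotropy index (AI).

The image is convolved with directional derivatives of a 2D Gaussian
(truncated kernel, default size 11 px and sigma 3 px) in the two axis
directions; the per-pixel outer product of the gradients is then summed
over a Gaussian integration window, giving the pixelwise structure tensor
J = [[Jxx, Jxy], [Jxy, Jyy]].  With eigenvalues mu1 >= mu2 >= 0, the
per-pixel anisotropy index is the normalised eigenvalue difference

    AI = (mu1 - mu2) / (mu1 + mu2)   in [0, 1],

and the ROI AI is the mean per-pixel AI over ROI pixels whose tensor trace
exceeds a small floor (flat pixels carry no orientation and are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .images import Micrograph

__all__ = ["StConfig", "StructureTensorField", "AnisotropyResult",
           "structure_tensor_field", "anisotropy_index", "roi_anisotropy"]


@dataclass(frozen=True)
class StConfig:
    derivative_sigma: float = 3.0   # px
    kernel_size: int = 11           # px, odd
    integration_sigma: float = 3.0  # px; window of the tensor summation
    trace_floor: float = 1e-6       # fraction of the max trace
    aggregation: str = "mean_pixel_ai"  # or "roi_tensor"

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.derivative_sigma <= 0 or self.integration_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if self.aggregation not in ("mean_pixel_ai", "roi_tensor"):
            raise ValueError("aggregation must be 'mean_pixel_ai' or 'roi_tensor'")


@dataclass
class StructureTensorField:
    Jxx: np.ndarray
    Jxy: np.ndarray
    Jyy: np.ndarray

    @property
    def trace(self) -> np.ndarray:
        return self.Jxx + self.Jyy

    def eigenvalues(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (mu1, mu2) with mu1 >= mu2 >= 0."""
        half_trace = 0.5 * (self.Jxx + self.Jyy)
        gap = np.sqrt((0.5 * (self.Jxx - self.Jyy)) ** 2 + self.Jxy ** 2)
        mu1 = half_trace + gap
        mu2 = np.clip(half_trace - gap, 0.0, None)  # PSD up to rounding
        return mu1, mu2


@dataclass
class AnisotropyResult:
    AI: float
    per_pixel_AI: np.ndarray  # NaN where the tensor is below the trace floor
    n_valid_pixels: int


def _gaussian_derivative_kernels(sigma: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.arange(size) - size // 2
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    dg = -(x / sigma ** 2) * g
    return g, dg


def structure_tensor_field(img: Micrograph | np.ndarray,
                           cfg: StConfig = StConfig()) -> StructureTensorField:
    """Gaussian-derivative gradients, tensor formation, window integration."""
    pixels = img.pixels if isinstance(img, Micrograph) else np.asarray(img)
    f = pixels.astype(float)
    if min(f.shape) < cfg.kernel_size:
        raise ValueError(
            f"image {f.shape} smaller than kernel_size {cfg.kernel_size}")

    g, dg = _gaussian_derivative_kernels(cfg.derivative_sigma, cfg.kernel_size)
    # Ix: derivative along columns (x), smoothing along rows (y); reflect padding
    ix = ndi.correlate1d(ndi.correlate1d(f, dg, axis=1, mode="reflect"),
                         g, axis=0, mode="reflect")
    iy = ndi.correlate1d(ndi.correlate1d(f, dg, axis=0, mode="reflect"),
                         g, axis=1, mode="reflect")

    jxx = ndi.gaussian_filter(ix * ix, cfg.integration_sigma, mode="reflect")
    jxy = ndi.gaussian_filter(ix * iy, cfg.integration_sigma, mode="reflect")
    jyy = ndi.gaussian_filter(iy * iy, cfg.integration_sigma, mode="reflect")
    return StructureTensorField(Jxx=jxx, Jxy=jxy, Jyy=jyy)


def anisotropy_index(field: StructureTensorField, roi: np.ndarray | None = None,
                     cfg: StConfig = StConfig()) -> AnisotropyResult:
    """ROI anisotropy index from an integrated structure-tensor field."""
    if roi is None:
        roi = np.ones(field.Jxx.shape, dtype=bool)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != field.Jxx.shape:
        raise ValueError("ROI shape must match the tensor field")

    trace = field.trace
    floor = cfg.trace_floor * float(trace.max()) if trace.max() > 0 else np.inf
    valid = trace > floor

    mu1, mu2 = field.eigenvalues()
    per_pixel = np.full(trace.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_pixel[valid] = (mu1[valid] - mu2[valid]) / (mu1[valid] + mu2[valid])

    sel = valid & roi
    n_valid = int(sel.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels in ROI: region is flat below the trace floor")

    if cfg.aggregation == "mean_pixel_ai":
        ai = float(np.mean(per_pixel[sel]))
    else:  # AI of the ROI-summed tensor
        summed = StructureTensorField(
            Jxx=np.array([[field.Jxx[sel].sum()]]),
            Jxy=np.array([[field.Jxy[sel].sum()]]),
            Jyy=np.array([[field.Jyy[sel].sum()]]))
        m1, m2 = summed.eigenvalues()
        ai = float(((m1 - m2) / (m1 + m2)).item())

    return AnisotropyResult(AI=ai, per_pixel_AI=per_pixel, n_valid_pixels=n_valid)


def roi_anisotropy(img: Micrograph, roi: np.ndarray | None = None,
                   cfg: StConfig = StConfig()) -> AnisotropyResult:
    """Convenience: tensor field then ROI anisotropy index in one call."""
    return anisotropy_index(structure_tensor_field(img, cfg), roi, cfg)
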