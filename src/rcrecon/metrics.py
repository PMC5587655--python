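"""Image-quality metrics: PSNR, CoC, ENL, CNR, and point-target FWHM."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RegionSpec",
    "MetricsReport",
    "mse",
    "psnr",
    "coc",
    "enl",
    "cnr",
    "fwhm",
    "circle_region",
    "box_region",
]

# 4-neighbour discrete Laplacian, reflect boundary
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class RegionSpec:
    """A labeled region of interest given as a boolean voxel mask."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            raise ValueError("region mask must be boolean")
        if not m.any():
            raise ValueError(f"region '{self.label}' is empty")

    def values(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.mask.shape:
            raise ValueError("region mask does not match image shape")
        return np.asarray(image, dtype=float)[self.mask]


def circle_region(label: str, shape, pitch, origin, center_x: float,
                  center_z: float, diameter: float) -> RegionSpec:
    z = origin[0] + np.arange(shape[0]) * pitch[0]
    x = origin[1] + np.arange(shape[1]) * pitch[1]
    zz, xx = z[:, None], x[None, :]
    m = (xx - center_x) ** 2 + (zz - center_z) ** 2 <= (diameter / 2) ** 2
    return RegionSpec(label=label, mask=m)


def box_region(label: str, shape, pitch, origin, corner_x: float, corner_z: float,
               extent_x: float, extent_z: float) -> RegionSpec:
    z = origin[0] + np.arange(shape[0]) * pitch[0]
    x = origin[1] + np.arange(shape[1]) * pitch[1]
    zz, xx = z[:, None], x[None, :]
    m = ((xx >= corner_x) & (xx <= corner_x + extent_x)
         & (zz >= corner_z) & (zz <= corner_z + extent_z))
    return RegionSpec(label=label, mask=m)


@dataclass(frozen=True)
class MetricsReport:
    psnr: float
    mse: float
    coc: float
    enl: dict = field(default_factory=dict)
    cnr: float | None = None
    fwhm_mm: float | None = None

    def to_dict(self) -> dict:
        return {
            "psnr": self.psnr,
            "mse": self.mse,
            "coc": self.coc,
            "enl": dict(self.enl),
            "cnr": self.cnr,
            "fwhm_mm": self.fwhm_mm,
        }


def mse(f_p: np.ndarray, f_r: np.ndarray) -> float:
    a = np.asarray(f_p, dtype=float)
    b = np.asarray(f_r, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    return float(np.mean((a - b) ** 2))


def psnr(f_p: np.ndarray, f_r: np.ndarray) -> float:
    """10 log10(max(f_p)^2 / MSE); +inf when the images are identical."""
    m = mse(f_p, f_r)
    if m == 0.0:
        return float("inf")
    peak = float(np.max(f_p))
    return float(10.0 * np.log10(peak ** 2 / m))


def _laplacian(img: np.ndarray) -> np.ndarray:
    return ndimage.convolve(np.asarray(img, dtype=float), _LAPLACIAN,
                            mode="reflect")


def coc(f_p: np.ndarray, f_r: np.ndarray) -> float:
    """Pearson correlation of the discrete Laplacians of the two images.

    1 for identical images, -1 for negated ones; NaN when either Laplacian
    has zero variance.
    """
    a = _laplacian(f_p).ravel()
    b = _laplacian(f_r).ravel()
    if a.size != b.size:
        raise ValueError("images must share a shape")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(da * db) / denom)


def enl(image: np.ndarray, region: RegionSpec | np.ndarray, ddof: int = 0) -> float:
    """mu^2 / sigma^2 of a region; +inf for a perfectly smooth region."""
    if isinstance(region, RegionSpec):
        v = region.values(image)
    else:
        v = np.asarray(image, dtype=float)[np.asarray(region, dtype=bool)]
    if v.size < 2:
        raise ValueError("region must have at least 2 voxels")
    var = float(np.var(v, ddof=ddof))
    if var == 0.0:
        return float("inf")
    return float(np.mean(v) ** 2 / var)


def cnr(image: np.ndarray, features: Sequence[RegionSpec],
        background: RegionSpec, corrected: bool = False,
        ddof: int = 0) -> float:
    """Mean feature-background contrast over noise.

    By default the denominator mixes the feature variance with the
    background *standard deviation* (sigma_r^2 + sigma_b), the form common
    in the despeckling literature; pass ``corrected=True`` for the
    dimensionally consistent sigma_r^2 + sigma_b^2 variant.  Returns NaN
    when a denominator is nonpositive.
    """
    if len(features) < 1:
        raise ValueError("need at least one feature region")
    img = np.asarray(image, dtype=float)
    vb = background.values(img)
    mu_b = float(np.mean(vb))
    sd_b = float(np.std(vb, ddof=ddof))
    acc = 0.0
    for reg in features:
        v = reg.values(img)
        var_r = float(np.var(v, ddof=ddof))
        denom = var_r + (sd_b ** 2 if corrected else sd_b)
        if denom <= 0.0:
            return float("nan")
        acc += (float(np.mean(v)) - mu_b) / np.sqrt(denom)
    return acc / len(features)


def fwhm(profile: np.ndarray, pitch: float) -> float:
    """Full width at half maximum of a 1-D profile, in mm.

    Half level is min + (max - min) / 2; crossings are linearly
    interpolated on each side of the global maximum.  NaN when the half
    level is never crossed on either side.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        return float("nan")
    lo, hi = float(p.min()), float(p.max())
    if hi <= lo:
        return float("nan")
    half = lo + (hi - lo) / 2.0
    i = int(np.argmax(p))
    left = right = None
    for j in range(i, 0, -1):
        if p[j - 1] < half <= p[j]:
            left = (j - 1) + (half - p[j - 1]) / (p[j] - p[j - 1])
            break
    for j in range(i, p.size - 1):
        if p[j + 1] < half <= p[j]:
            right = (j + 1) - (half - p[j + 1]) / (p[j] - p[j + 1])
            break
    if left is None or right is None:
        return float("nan")
    return float((right - left) * pitch)
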