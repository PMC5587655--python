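"""Edge-guided stochastic clique structure.

Each lattice node is notionally connected to every other node; a pair (i, j)
is realized when the product of three Gaussian affinities — spatial
proximity, intensity similarity, and edge-value similarity — clears a
sparsity threshold gamma (deterministically, or against a uniform draw in
stochastic mode).  Full connectivity is truncated to a square window since
the spatial affinity is numerically zero beyond a few bandwidths.

Pairs are stored canonically per offset in the lexicographic half-space, so
(i, j) is realized iff (j, i) is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters

__all__ = [
    "edge_map",
    "IndicatorParams",
    "NeighborSampler",
    "spatial_affinity",
    "data_affinity",
    "edge_affinity",
    "indicator",
    "build_sampler",
    "half_space_offsets",
]


def edge_map(image: np.ndarray, presmooth_sigma: float = 0.0) -> np.ndarray:
    """Sobel gradient magnitude normalized to [0, 1] (zero map if constant).

    ``presmooth_sigma`` optionally Gaussian-smooths the image first (voxel
    units) so speckle granulation does not read as edges; the default keeps
    the plain Sobel response.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("edge_map expects a 2-D slice")
    if presmooth_sigma > 0:
        img = ndimage.gaussian_filter(img, presmooth_sigma)
    e = filters.sobel(img)
    mx = e.max()
    return e / mx if mx > 0 else np.zeros_like(e)


@dataclass(frozen=True)
class IndicatorParams:
    """Affinity bandwidths and sparsity control for clique realization.

    ``sigma_q=None`` resolves at build time to 0.1 of the guide image's
    intensity range.
    """

    sigma_p: float = 3.0
    sigma_q: float | None = None
    sigma_r: float = 0.1
    gamma: float = 0.02
    window_radius: int = 9
    mode: str = "deterministic"  # or "stochastic"
    seed: int | None = None
    edge_presmooth: float = 0.0  # Gaussian sigma (voxels) before the Sobel

    def __post_init__(self) -> None:
        if self.sigma_p <= 0 or self.sigma_r <= 0:
            raise ValueError("affinity bandwidths must be positive")
        if self.sigma_q is not None and self.sigma_q <= 0:
            raise ValueError("affinity bandwidths must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")

    def resolve_sigma_q(self, image: np.ndarray) -> float:
        if self.sigma_q is not None:
            return self.sigma_q
        rng_ = float(np.ptp(image))
        return 0.1 * rng_ if rng_ > 0 else 1.0


def spatial_affinity(i, j, sigma_p: float):
    """Gaussian affinity on inter-node Euclidean distance (voxel units).

    The neighbourhood is centered on node i, so its own center distance is
    zero and the affinity collapses to exp(-||i - j||^2 / (2 sigma_p^2)).
    """
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    d2 = np.sum((np.asarray(i, dtype=float) - np.asarray(j, dtype=float)) ** 2,
                axis=-1)
    return np.exp(-d2 / (2.0 * sigma_p ** 2))


def data_affinity(intensity_i, intensity_j, sigma_q: float):
    """exp(-(I_i - I_j)^2 / (2 sigma_q^2)), in (0, 1]."""
    if sigma_q <= 0:
        raise ValueError("sigma_q must be positive")
    d = np.asarray(intensity_i, dtype=float) - np.asarray(intensity_j, dtype=float)
    return np.exp(-d * d / (2.0 * sigma_q ** 2))


def edge_affinity(edge_i, edge_j, sigma_r: float):
    """exp(-(B_i - B_j)^2 / (2 sigma_r^2)), in (0, 1]."""
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    d = np.asarray(edge_i, dtype=float) - np.asarray(edge_j, dtype=float)
    return np.exp(-d * d / (2.0 * sigma_r ** 2))


def indicator(i, j, image: np.ndarray, edges: np.ndarray,
              params: IndicatorParams, rng=None) -> int:
    """Single-pair stochastic indicator: 1 iff P^s * Q^d * R^e clears gamma.

    Deterministic mode thresholds the triple product at gamma; stochastic
    mode compares it to gamma times a uniform draw.
    """
    sq = params.resolve_sigma_q(image)
    p = spatial_affinity(i, j, params.sigma_p)
    q = data_affinity(image[tuple(i)], image[tuple(j)], sq)
    r = edge_affinity(edges[tuple(i)], edges[tuple(j)], params.sigma_r)
    prod = p * q * r
    if params.mode == "deterministic":
        return int(prod >= params.gamma)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return int(prod >= params.gamma * rng.uniform())


def half_space_offsets(radius: int) -> list[tuple[int, int]]:
    """Canonical (dz, dx) offsets: dz > 0, or dz == 0 and dx > 0."""
    offs = []
    for dz in range(0, radius + 1):
        for dx in range(-radius, radius + 1):
            if dz == 0 and dx <= 0:
                continue
            offs.append((dz, dx))
    return offs


def offset_slices(shape: tuple[int, int], off: tuple[int, int]):
    """Index slices (sa, sb) pairing base voxels with their +off partners.

    Offsets at least as large as the image yield empty (zero-length) slices.
    """
    nz, nx = shape
    dz, dx = off
    za, zb = (slice(0, max(nz - dz, 0)), slice(min(dz, nz), nz))
    if dx >= 0:
        xa, xb = (slice(0, max(nx - dx, 0)), slice(min(dx, nx), nx))
    else:
        xa, xb = (slice(min(-dx, nx), nx), slice(0, max(nx + dx, 0)))
    return (za, xa), (zb, xb)


@dataclass(frozen=True)
class NeighborSampler:
    """Realized pairwise clique structure over one slice.

    ``realized[k][z, x]`` is True iff the pair between voxel (z, x) and
    voxel (z, x) + ``offsets[k]`` is in the clique set.  Offsets live in the
    lexicographic half-space, so every unordered pair appears exactly once.
    """

    shape: tuple[int, int]
    offsets: tuple[tuple[int, int], ...]
    realized: tuple[np.ndarray, ...]
    params: IndicatorParams

    @property
    def n_pairs(self) -> int:
        return int(sum(r.sum() for r in self.realized))

    def degrees(self) -> np.ndarray:
        """Per-node realized degree (each pair counts for both endpoints)."""
        deg = np.zeros(self.shape, dtype=int)
        for off, r in zip(self.offsets, self.realized):
            sa, sb = offset_slices(self.shape, off)
            deg[sa] += r[sa]
            deg[sb] += r[sa]
        return deg

    def pairs(self) -> np.ndarray:
        """(m, 2) array of flat (i, j) indices, i the base voxel."""
        nz, nx = self.shape
        flat = np.arange(nz * nx).reshape(self.shape)
        out = []
        for off, r in zip(self.offsets, self.realized):
            sa, sb = offset_slices(self.shape, off)
            sel = r[sa]
            out.append(np.column_stack([flat[sa][sel], flat[sb][sel]]))
        if not out:
            return np.empty((0, 2), dtype=int)
        return np.concatenate(out, axis=0)


def build_sampler(image: np.ndarray, edges: np.ndarray,
                  params: IndicatorParams) -> NeighborSampler:
    """Realize the clique structure over a slice.

    Vectorized per window offset; deterministic under a fixed seed in
    stochastic mode (uniform draws are made in fixed offset order).
    """
    img = np.asarray(image, dtype=float)
    edg = np.asarray(edges, dtype=float)
    if img.shape != edg.shape or img.ndim != 2:
        raise ValueError("image and edges must be 2-D with the same shape")
    sq = params.resolve_sigma_q(img)
    rng = np.random.default_rng(params.seed)
    offsets = half_space_offsets(params.window_radius)
    realized = []
    for off in offsets:
        sa, sb = offset_slices(img.shape, off)
        p = spatial_affinity((0.0, 0.0), off, params.sigma_p)
        q = data_affinity(img[sa], img[sb], sq)
        r = edge_affinity(edg[sa], edg[sb], params.sigma_r)
        prod = p * q * r
        if params.mode == "deterministic":
            hit = prod >= params.gamma
        else:
            u = rng.uniform(size=prod.shape)
            hit = prod >= params.gamma * u
        full = np.zeros(img.shape, dtype=bool)
        full[sa] = hit
        realized.append(full)
    return NeighborSampler(shape=img.shape, offsets=tuple(offsets),
                           realized=tuple(realized), params=params)
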