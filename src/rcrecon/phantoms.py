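"""Synthetic reflectivity phantoms and scatterer fields.

Phantoms are defined per 2-D slice in the lateral/axial (x-z) plane; a 3-D
volume is a stack of identical slices along the elevation (y) axis.  Arrays
are indexed ``[z, x]`` (axial, lateral); physical positions refer to voxel
centers in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = [
    "GeometryError",
    "ResolutionError",
    "Sphere",
    "Box",
    "Point",
    "PhantomSpec",
    "ReflectivityImage",
    "ScattererSet",
    "make_cyst_phantom",
    "make_lshape_phantom",
    "make_point_phantom",
    "rasterize",
    "scatter_field",
    "DEFAULT_PITCH",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_ORIGIN",
]

# Default slice grid: 0.05 mm axial x 0.1 mm lateral pitch, z in [0, 50] mm,
# x in [-10, 10] mm (voxel centers at the interval ends included).
DEFAULT_PITCH = (0.05, 0.1)  # (pitch_z, pitch_x) mm
DEFAULT_GRID_SHAPE = (1001, 201)  # (nz, nx)
DEFAULT_ORIGIN = (0.0, -10.0)  # (z0, x0) mm, voxel [0, 0] center


class GeometryError(ValueError):
    """A feature does not fit inside the phantom grid."""


class ResolutionError(ValueError):
    """The grid pitch is too coarse to represent a feature."""


@dataclass(frozen=True)
class Sphere:
    """Spherical (cyst) inclusion; the slice sees its great circle."""

    center_x: float
    center_z: float
    diameter: float
    amplitude_ratio: float = 10.0

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        # closed boundary with an ulp-scale tolerance so voxel centers that
        # land exactly on the rim classify identically on both sides
        r = self.diameter / 2.0
        return ((x - self.center_x) ** 2 + (z - self.center_z) ** 2
                <= r * r + 1e-9)

    def bounds(self) -> tuple[float, float, float, float]:
        r = self.diameter / 2.0
        return (self.center_x - r, self.center_x + r, self.center_z - r, self.center_z + r)


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangular inclusion (corner + extents, mm)."""

    corner_x: float
    corner_z: float
    extent_x: float
    extent_z: float
    amplitude_ratio: float = 10.0

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        tol = 1e-9
        return (
            (x >= self.corner_x - tol)
            & (x <= self.corner_x + self.extent_x + tol)
            & (z >= self.corner_z - tol)
            & (z <= self.corner_z + self.extent_z + tol)
        )

    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.corner_x,
            self.corner_x + self.extent_x,
            self.corner_z,
            self.corner_z + self.extent_z,
        )


@dataclass(frozen=True)
class Point:
    """Single-voxel point target."""

    x: float
    z: float
    amplitude_ratio: float = 10.0

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x, self.x, self.z, self.z)


Feature = Sphere | Box | Point


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a phantom slice.

    ``background`` is the reflectivity outside every feature; features carry
    an ``amplitude_ratio`` relative to it.  Overlapping features resolve to
    the maximum ratio.
    """

    grid_shape: tuple[int, int]
    voxel_pitch: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    features: tuple[Feature, ...] = ()
    background: float = 1.0

    def __post_init__(self) -> None:
        if min(self.voxel_pitch) <= 0:
            raise ValueError("voxel_pitch must be positive")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")
        for f in self.features:
            if f.amplitude_ratio <= 0:
                raise ValueError(f"amplitude_ratio must be > 0 for {f!r}")
            x0, x1, z0, z1 = f.bounds()
            gx0, gx1 = self.x_extent
            gz0, gz1 = self.z_extent
            if x0 < gx0 or x1 > gx1 or z0 < gz0 or z1 > gz1:
                raise GeometryError(f"feature {f!r} extends outside grid "
                                    f"x=[{gx0}, {gx1}] z=[{gz0}, {gz1}] mm")

    @property
    def z_extent(self) -> tuple[float, float]:
        z0 = self.origin[0]
        return (z0, z0 + (self.grid_shape[0] - 1) * self.voxel_pitch[0])

    @property
    def x_extent(self) -> tuple[float, float]:
        x0 = self.origin[1]
        return (x0, x0 + (self.grid_shape[1] - 1) * self.voxel_pitch[1])

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center physical coordinates as broadcastable (z, x) arrays."""
        z = self.origin[0] + np.arange(self.grid_shape[0]) * self.voxel_pitch[0]
        x = self.origin[1] + np.arange(self.grid_shape[1]) * self.voxel_pitch[1]
        return z[:, None], x[None, :]


@dataclass(frozen=True)
class ReflectivityImage:
    """Ground-truth tissue reflectivity on a regular lattice."""

    values: np.ndarray  # (nz, nx) nonnegative
    pitch: tuple[float, float]
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("reflectivity values must be finite and nonnegative")


@dataclass(frozen=True)
class ScattererSet:
    """Point scatterers with Gaussian amplitudes (speckle generators)."""

    positions: np.ndarray  # (n, 3) mm: columns x, y, z
    amplitudes: np.ndarray  # (n,) signed


def rasterize(spec: PhantomSpec) -> ReflectivityImage:
    """Render a :class:`PhantomSpec` onto its lattice.

    Closed-boundary convention: a voxel belongs to a sphere/box iff its
    center lies at distance <= radius (inside the box closure).  Point
    features claim the single nearest voxel.
    """
    zc, xc = spec.coords()
    ratio = np.ones(spec.grid_shape)
    for f in spec.features:
        if isinstance(f, Point):
            iz = int(round((f.z - spec.origin[0]) / spec.voxel_pitch[0]))
            ix = int(round((f.x - spec.origin[1]) / spec.voxel_pitch[1]))
            ratio[iz, ix] = max(ratio[iz, ix], f.amplitude_ratio)
        else:
            inside = f.contains(xc, zc)
            ratio = np.where(inside, np.maximum(ratio, f.amplitude_ratio), ratio)
    # ratios scale the background; for an anechoic (zero) background the
    # ratio is read against a unit reference so features do not vanish
    ref = spec.background if spec.background > 0 else 1.0
    out = np.where(ratio > 1.0, ratio * ref, float(spec.background))
    return ReflectivityImage(values=out, pitch=spec.voxel_pitch, origin=spec.origin)


def _default_grid(grid_shape, voxel_pitch, origin):
    if grid_shape is None:
        grid_shape = DEFAULT_GRID_SHAPE
    if voxel_pitch is None:
        voxel_pitch = DEFAULT_PITCH
    if origin is None:
        origin = DEFAULT_ORIGIN
    return tuple(grid_shape), tuple(voxel_pitch), tuple(origin)


def make_cyst_phantom(grid_shape=None, voxel_pitch=None, origin=None) -> PhantomSpec:
    """Four cysts at 10/20/30/40 mm depth, laterally offset 0/0/2.5/5 mm,
    diameters 6/4/2/2 mm, ten times the background reflectivity."""
    grid_shape, voxel_pitch, origin = _default_grid(grid_shape, voxel_pitch, origin)
    cysts = tuple(
        Sphere(center_x=x, center_z=z, diameter=d, amplitude_ratio=10.0)
        for x, z, d in [(0.0, 10.0, 6.0), (0.0, 20.0, 4.0), (2.5, 30.0, 2.0), (5.0, 40.0, 2.0)]
    )
    return PhantomSpec(grid_shape=grid_shape, voxel_pitch=voxel_pitch,
                       origin=origin, features=cysts)


def make_lshape_phantom(grid_shape=None, voxel_pitch=None, origin=None,
                        center_depth: float = 25.0, center_x: float = 0.0) -> PhantomSpec:
    """Three adjoining 6 x 6 mm squares forming an "L".

    The L's 12 x 12 mm bounding box is
    centered at ``(center_x, center_depth)`` with the empty quadrant at the
    top right.
    """
    grid_shape, voxel_pitch, origin = _default_grid(grid_shape, voxel_pitch, origin)
    squares = tuple(
        Box(corner_x=cx, corner_z=cz, extent_x=6.0, extent_z=6.0, amplitude_ratio=10.0)
        for cx, cz in [
            (center_x - 6.0, center_depth - 6.0),  # top left
            (center_x - 6.0, center_depth),        # bottom left
            (center_x, center_depth),              # bottom right
        ]
    )
    return PhantomSpec(grid_shape=grid_shape, voxel_pitch=voxel_pitch,
                       origin=origin, features=squares)


def make_point_phantom(grid_shape=None, voxel_pitch=None, origin=None,
                       background: float = 0.0) -> PhantomSpec:
    """Three on-axis point targets at z = 39.5, 40 and 40.25 mm.

    The background defaults to anechoic (0) so that the targets stand alone.
    """
    grid_shape, voxel_pitch, origin = _default_grid(grid_shape, voxel_pitch, origin)
    if voxel_pitch[0] > 0.25:
        raise ResolutionError(
            f"axial pitch {voxel_pitch[0]} mm cannot separate points 0.25 mm apart")
    points = tuple(Point(x=0.0, z=z, amplitude_ratio=10.0) for z in (39.5, 40.0, 40.25))
    spec = PhantomSpec(grid_shape=grid_shape, voxel_pitch=voxel_pitch, origin=origin,
                       features=points, background=background)
    # points must land on distinct voxels
    idx = {
        (int(round((p.z - origin[0]) / voxel_pitch[0])),
         int(round((p.x - origin[1]) / voxel_pitch[1])))
        for p in points
    }
    if len(idx) != len(points):
        raise ResolutionError(
            f"voxel pitch {voxel_pitch} mm collapses distinct point targets")
    return spec


def scatter_field(spec: PhantomSpec, n: int, seed=None,
                  y_extent: tuple[float, float] = (-0.5, 0.5)) -> ScattererSet:
    """Uniformly place ``n`` scatterers in the grid extent with Gaussian(0, 1)
    amplitudes scaled by the local feature amplitude ratio."""
    if n <= 0:
        raise ValueError("scatterer count must be >= 1")
    rng = np.random.default_rng(seed)
    gx0, gx1 = spec.x_extent
    gz0, gz1 = spec.z_extent
    x = rng.uniform(gx0, gx1, size=n)
    y = rng.uniform(y_extent[0], y_extent[1], size=n)
    z = rng.uniform(gz0, gz1, size=n)
    amp = rng.standard_normal(n)
    ratio = np.ones(n)
    for f in spec.features:
        if isinstance(f, Point):
            continue
        inside = f.contains(x, z)
        ratio = np.where(inside, np.maximum(ratio, f.amplitude_ratio), ratio)
    return ScattererSet(positions=np.column_stack([x, y, z]),
                        amplitudes=amp * ratio)
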