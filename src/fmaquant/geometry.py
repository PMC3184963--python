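"""Voxel geometry and ellipsoid primitives.

All 3D arrays in this package use axis order ``(z, y, x)``; physical
coordinates are micrometres. A voxel with index ``(k, j, i)`` has its centre
at ``(k*dz, j*dy, i*dx)`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Axial step of the confocal z-stacks this pipeline was designed around, µm.
DEFAULT_DZ_UM = 0.8141

#: Default lateral pixel pitch, µm/pixel (20x objective, zoom 2; the lateral
#: pitch is instrument-dependent and must always be recorded explicitly).
DEFAULT_DXY_UM = 0.73


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of a voxel in micrometres.

    Parameters
    ----------
    dx, dy : float
        Lateral pixel pitch, µm/pixel.
    dz : float
        Axial step between optical sections, µm (default 0.8141).
    """

    dx: float = DEFAULT_DXY_UM
    dy: float = DEFAULT_DXY_UM
    dz: float = DEFAULT_DZ_UM

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel geometry {name} must be > 0, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, µm³ (= dx·dy·dz)."""
        return self.dx * self.dy * self.dz

    @property
    def spacing_zyx(self) -> np.ndarray:
        """Spacing as an array in axis order (z, y, x)."""
        return np.array([self.dz, self.dy, self.dx], dtype=float)

    def to_dict(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "dz": self.dz, "units": "um"}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        units = d.get("units", "um")
        if units not in ("um", "µm", "micron", "micrometre", "micrometer"):
            raise ValueError(f"unsupported geometry units {units!r}")
        return cls(dx=float(d["dx"]), dy=float(d["dy"]), dz=float(d["dz"]))


@dataclass(frozen=True)
class Ellipsoid:
    """Solid ellipsoid with semi-axes ``a >= b >= c`` (µm).

    ``axes`` holds the unit principal directions as columns, expressed in
    (z, y, x) physical coordinates; column ``i`` corresponds to semi-axis
    ``(a, b, c)[i]``. ``center`` is in (z, y, x) µm.
    """

    a: float
    b: float
    c: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if not (self.a >= self.b >= self.c > 0):
            raise ValueError(
                f"ellipsoid semi-axes must satisfy a >= b >= c > 0, "
                f"got ({self.a}, {self.b}, {self.c})"
            )

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def volume(self) -> float:
        """Ellipsoid volume V = 4πabc/3, µm³."""
        return ellipsoid_volume(self.a, self.b, self.c)

    def scaled(self, factor: float) -> "Ellipsoid":
        """Return an ellipsoid with all semi-axes multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return Ellipsoid(
            self.a * factor, self.b * factor, self.c * factor,
            center=self.center, axes=self.axes,
        )

    def contains(self, points_zyx: np.ndarray) -> np.ndarray:
        """Boolean membership test for an (n, 3) array of (z, y, x) µm points."""
        rel = np.atleast_2d(points_zyx) - np.asarray(self.center, dtype=float)
        # coordinates along principal directions, normalised by semi-axes
        u = rel @ self.axes / self.semi_axes
        return (u * u).sum(axis=1) <= 1.0

    def rasterize(self, shape: tuple[int, int, int], geometry: VoxelGeometry) -> np.ndarray:
        """Binary mask of voxels whose centres lie inside the ellipsoid."""
        # principal-axis quadratic form, evaluated slice-wise to bound memory
        M = (self.axes / self.semi_axes) @ (self.axes / self.semi_axes).T
        cz, cy, cx = self.center
        y = np.arange(shape[1]) * geometry.dy - cy
        x = np.arange(shape[2]) * geometry.dx - cx
        yy, xx = np.meshgrid(y, x, indexing="ij")
        qyy = M[1, 1] * yy * yy + 2 * M[1, 2] * yy * xx + M[2, 2] * xx * xx
        mask = np.empty(shape, dtype=bool)
        for k in range(shape[0]):
            z = k * geometry.dz - cz
            q = M[0, 0] * z * z + 2 * z * (M[0, 1] * yy + M[0, 2] * xx) + qyy
            mask[k] = q <= 1.0
        return mask


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of an ellipsoid with semi-axes a, b, c: V = 4πabc/3 (µm³)."""
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    return 4.0 * np.pi * a * b * c / 3.0
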