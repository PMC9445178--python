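"""Core geometric containers: observation windows, point patterns, ellipsoidal cells.

Conventions
-----------
* All lengths are micrometres (µm). Voxel pitches arrive in nanometres and are
  converted once at ingestion (see :mod:`stereocol.morph3d`).
* The window is an axis-aligned box with one corner at the origin. The x-axis
  is the direction perpendicular to the pial surface, so cortical minicolumns
  run along x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Window3D", "PointPattern3D", "EllipsoidCell"]


@dataclass(frozen=True)
class Window3D:
    """Axis-aligned box ``[0, lx] x [0, ly] x [0, lz]`` in µm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"window side lengths must be positive, got {self.sides}")

    @property
    def sides(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        """Window volume in µm³."""
        return float(self.lx * self.ly * self.lz)

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the (closed) box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= -atol) & (pts <= self.sides + atol), axis=1)


@dataclass
class PointPattern3D:
    """A finite 3D point pattern observed in a box window.

    ``points`` is an (n, 3) float array of cell-centroid coordinates in µm.
    """

    points: np.ndarray
    window: Window3D

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if pts.shape[0] and not np.all(self.window.contains(pts, atol=1e-9)):
            raise ValueError("all points must lie inside the window")
        self.points = pts

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def intensity(self) -> float:
        """Empirical intensity n / |W| in µm⁻³."""
        return self.n / self.window.volume


def _check_rotation(rotation: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    r = np.asarray(rotation, dtype=float).reshape(3, 3)
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("rotation matrix must be orthonormal (RᵀR = I)")
    return r


@dataclass
class EllipsoidCell:
    """A solid triaxial ellipsoid with a nucleolus reference point.

    The ellipsoid is the set ``{c + R y : sum((y/s)^2) <= 1}`` where ``s`` are
    the semi-axes, ``c`` the centre and ``R`` the rotation. The nucleolus is
    the reference point about which volume tensors are taken; it must lie
    inside the cell.
    """

    semi_axes: np.ndarray
    center: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    nucleolus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        if not np.all(self.semi_axes > 0):
            raise ValueError(f"semi-axes must be strictly positive, got {self.semi_axes}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.rotation = _check_rotation(self.rotation)
        if self.nucleolus is None:
            self.nucleolus = self.center.copy()
        else:
            self.nucleolus = np.asarray(self.nucleolus, dtype=float).reshape(3)
            if not bool(self.contains(self.nucleolus)[0]):
                raise ValueError("nucleolus reference point must lie inside the ellipsoid")

    @property
    def volume(self) -> float:
        """Exact volume (4/3)π·a·b·c in µm³."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    @property
    def bounding_radius(self) -> float:
        return float(np.max(self.semi_axes))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie inside (closed) the ellipsoid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        y = (pts - self.center) @ self.rotation  # body coordinates
        return np.sum((y / self.semi_axes) ** 2, axis=1) <= 1.0

    def ray_lengths(self, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distance from ``origin`` (inside the cell) to the boundary along unit rays.

        Solves the quadratic |A(origin + t·ω − c)|² = 1 for the positive root,
        with A mapping to the unit ball. Used by the rotator probe.
        """
        origin = np.asarray(origin, dtype=float).reshape(3)
        if not bool(self.contains(origin)[0]):
            raise ValueError("ray origin must lie inside the ellipsoid")
        dirs = np.atleast_2d(np.asarray(directions, dtype=float))
        # body-frame, axis-scaled coordinates
        p = ((origin - self.center) @ self.rotation) / self.semi_axes
        d = (dirs @ self.rotation) / self.semi_axes
        a = np.sum(d * d, axis=1)
        b = d @ p
        c = float(p @ p) - 1.0  # <= 0 since origin inside
        disc = b * b - a * c
        return (-b + np.sqrt(disc)) / a
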