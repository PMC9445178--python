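"""Per-cell 3D morphometry from labelled anisotropic voxel stacks.

A :class:`CellLabelVolume` holds an integer label grid indexed ``[i, j, k]``
along (x, y, z) with an anisotropic voxel pitch given in nanometres (the
native pitch of serial-section light microscopy, e.g. 272x272x900 nm) and
converted to µm internally. The voxel with index ``(i, j, k)`` has its centre
at ``((i+0.5)·vx, (j+0.5)·vy, (k+0.5)·vz)`` µm.

Anisotropy is handled by scaling coordinates to physical units before any
covariance or meshing computation; the grid itself is never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import PointPattern3D, Window3D

__all__ = [
    "CellLabelVolume",
    "CellMorphology",
    "label_components",
    "cell_metrics",
    "extract_centroids",
    "sphericity_from_mesh",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class CellLabelVolume:
    """Labelled 3D voxel grid; 0 is background, each positive label one cell."""

    labels: np.ndarray
    voxel_pitch_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.labels = lab.astype(np.int32, copy=False)
        pitch = tuple(float(p) for p in self.voxel_pitch_nm)
        if len(pitch) != 3 or any(p <= 0 for p in pitch):
            raise ValueError("voxel pitch must be three positive lengths in nm")
        self.voxel_pitch_nm = pitch

    @property
    def pitch_um(self) -> np.ndarray:
        return np.array(self.voxel_pitch_nm, dtype=float) / 1000.0

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.pitch_um))


@dataclass
class CellMorphology:
    """Morphometric summary of one labelled cell.

    orientation is the angle (degrees, folded to [0, 90]) between the
    principal axis of the cell and the x-axis (the pial-surface normal);
    it is NaN (and ``reliable`` False) when fewer than 4 voxels support it.
    """

    label: int
    volume: float
    equivalent_diameter: float
    sphericity: float
    orientation: float
    centroid: np.ndarray
    n_voxels: int
    reliable: bool = True


def label_components(binary: np.ndarray, connectivity: int = 26,
                     voxel_pitch_nm: tuple[float, float, float] = (1000.0, 1000.0, 1000.0)) -> CellLabelVolume:
    """Label connected foreground components of a boolean grid.

    ``connectivity`` counts the neighbours of a voxel: 6 (faces),
    18 (faces+edges) or 26 (faces+edges+corners). Labels are assigned in
    scan order of each component's first voxel, so the labelling is
    deterministic.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    lab = measure.label(np.asarray(binary).astype(bool), connectivity=_CONNECTIVITY[connectivity])
    return CellLabelVolume(labels=lab, voxel_pitch_nm=voxel_pitch_nm)


def sphericity_from_mesh(volume_um3: float, area_um2: float) -> float:
    """Sphericity π^(1/3)·(6V)^(2/3)/A — 1 for a ball, < 1 for elongated shapes."""
    if volume_um3 <= 0 or area_um2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0) / area_um2)


def _surface_area(mask: np.ndarray, pitch_um: np.ndarray, smooth_sigma_um: float | None) -> float:
    # pad so the iso-surface is closed; marching cubes honours the anisotropic
    # spacing, avoiding the up-to-50% overestimate of voxel-face counting.
    # A Gaussian regularisation at the physical pitch scale removes the
    # staircase of strongly anisotropic grids (z-pitch ~3x the in-plane
    # pitch), whose meshed area otherwise exceeds the true area by ~17%
    # regardless of object size; with it the area error vanishes as
    # size/pitch grows.
    if smooth_sigma_um is None:
        smooth_sigma_um = float(np.max(pitch_um))
    padded = np.pad(mask, 4).astype(np.float64)
    if smooth_sigma_um > 0:
        padded = ndimage.gaussian_filter(padded, sigma=smooth_sigma_um / pitch_um)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(pitch_um))
    return float(measure.mesh_surface_area(verts, faces))


def cell_metrics(volume: CellLabelVolume, min_volume: float = 0.0,
                 smooth_sigma_um: float | None = None) -> list[CellMorphology]:
    """Compute volume, equivalent diameter, sphericity, orientation and centroid per label.

    Volume is voxel count x voxel volume; the equivalent diameter is that of
    the ball of equal volume; surface area comes from an iso-surface mesh at
    the physical voxel pitch; orientation is the angle between the principal
    eigenvector of the physical-coordinate covariance and the x-axis, folded
    to [0, 90] degrees. Labels with volume below ``min_volume`` (µm³) are
    dropped; labels with fewer than 4 voxels are kept but flagged unreliable
    with undefined orientation.

    ``smooth_sigma_um`` is the physical scale (µm) of the Gaussian
    regularisation applied to the binary mask before iso-surface meshing,
    defaulting to the largest voxel pitch; it trades the staircase area
    overestimate of anisotropic grids against a small curvature loss, so
    digitized-ball sphericity can slightly exceed 1 (bounded by ~1.1) at
    small radius and converges to 1 as radius/pitch grows. Set 0 for the raw
    binary mesh.
    """
    pitch = volume.pitch_um
    vvol = volume.voxel_volume_um3
    slices = ndimage.find_objects(volume.labels)
    out: list[CellMorphology] = []
    for lbl, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = volume.labels[sl] == lbl
        idx = np.argwhere(sub) + [s.start for s in sl]
        nvox = idx.shape[0]
        vol = nvox * vvol
        if vol < min_volume:
            continue
        coords = (idx + 0.5) * pitch
        centroid = coords.mean(axis=0)
        eqd = float((6.0 * vol / np.pi) ** (1.0 / 3.0))
        reliable = nvox >= 4
        if reliable:
            area = _surface_area(sub, pitch, smooth_sigma_um)
            spher = sphericity_from_mesh(vol, area)
            cov = np.cov(coords.T) if nvox > 1 else np.zeros((3, 3))
            _, vecs = np.linalg.eigh(cov)
            principal = vecs[:, -1]
            cosang = np.clip(abs(principal[0]), 0.0, 1.0)
            orient = float(np.degrees(np.arccos(cosang)))
        else:
            spher = np.nan
            orient = np.nan
        out.append(
            CellMorphology(
                label=int(lbl), volume=float(vol), equivalent_diameter=eqd,
                sphericity=spher, orientation=orient, centroid=centroid,
                n_voxels=int(nvox), reliable=reliable,
            )
        )
    return out


def extract_centroids(volume: CellLabelVolume, window: Window3D,
                      min_volume: float = 0.0) -> PointPattern3D:
    """Export per-cell centroids (µm) as a point pattern in ``window``.

    Ordering matches :func:`cell_metrics`. A centroid outside the window
    signals a window/volume mismatch and raises.
    """
    metrics = cell_metrics(volume, min_volume=min_volume)
    pts = np.array([m.centroid for m in metrics], dtype=float).reshape(-1, 3)
    if pts.shape[0] and not np.all(window.contains(pts)):
        raise ValueError("a centroid falls outside the window; window/volume mismatch")
    return PointPattern3D(points=pts, window=window)
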