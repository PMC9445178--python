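"""Synthetic ground-truth generators for point patterns, cells and counting studies.

Every estimator in the package is validated against data produced here:
completely spatially random (CSR) centroid patterns, Poisson-line-cluster
patterns emulating cortical minicolumns (parent lines run along the x-axis,
the pial-surface normal), Matérn type-II hard-core patterns for repulsion
between somata, ellipsoidal cell populations with a nucleolus reference
point, voxelizations at anisotropic microscope pitch, and simulated
fractionator / Cavalieri counting studies whose sampling designs have known
inclusion probabilities.

All generators draw their randomness from a single integer seed through the
package's counter-based stream splitting, so results are reproducible and
independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from ._rng import split_rng
from .geometry import EllipsoidCell, PointPattern3D, Window3D
from .morph3d import CellLabelVolume
from .stereology import CavalieriCounts, FractionatorCounts

__all__ = [
    "ColumnarParams",
    "CellTemplate",
    "PopulationSpec",
    "simulate_csr",
    "simulate_columnar",
    "simulate_hardcore",
    "place_population",
    "voxelize_cells",
    "simulate_fractionator_study",
    "simulate_cavalieri_sections",
]


@dataclass(frozen=True)
class ColumnarParams:
    """Parameters of the Poisson-line-cluster (columnar) pattern.

    line_intensity : parent lines per µm² of (y, z) cross-section.
    points_per_line : mean daughters per line (Poisson).
    column_sd : isotropic Gaussian radial dispersion of daughters, µm.
    background_fraction : fraction of points drawn CSR instead of on a line;
        cluster daughters are thinned by (1 − f) and a CSR component with the
        complementary expected count is added, so the total expected count is
        independent of f.
    """

    line_intensity: float
    points_per_line: float
    column_sd: float
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.line_intensity < 0 or self.points_per_line < 0 or self.column_sd < 0:
            raise ValueError("rates and dispersions must be nonnegative")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CellTemplate:
    """Sampling ranges for ellipsoidal cell shapes (µm).

    Semi-axes are drawn uniformly in the given ranges (the long axis first),
    the orientation is uniform on SO(3), and the nucleolus is placed uniformly
    in the ellipsoid shrunk by ``nucleolus_extent`` about the centre.
    Defaults approximate layer-III pyramidal somata (longest diameter
    ~15–25 µm).
    """

    long_axis_range: tuple[float, float] = (7.0, 12.0)
    short_axis_range: tuple[float, float] = (4.0, 7.0)
    nucleolus_extent: float = 0.3

    def __post_init__(self) -> None:
        for lo, hi in (self.long_axis_range, self.short_axis_range):
            if not (0 < lo <= hi):
                raise ValueError("axis ranges must be positive and ordered")
        if not (0.0 <= self.nucleolus_extent < 1.0):
            raise ValueError("nucleolus_extent must be in [0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a disjoint ellipsoidal cell population."""

    n_cells: int
    window: Window3D
    template: CellTemplate = field(default_factory=CellTemplate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")


# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------


def simulate_csr(
    window: Window3D,
    n_points: int | None = None,
    intensity: float | None = None,
    seed: int = 0,
) -> PointPattern3D:
    """Simulate complete spatial randomness in ``window``.

    Exactly one of ``n_points`` (binomial process: that many i.i.d. uniform
    points) or ``intensity`` (homogeneous Poisson process, points per µm³)
    must be given.
    """
    if (n_points is None) == (intensity is None):
        raise ValueError("give exactly one of n_points or intensity")
    rng = split_rng(seed, "csr")
    if n_points is None:
        if intensity < 0:
            raise ValueError("intensity must be nonnegative")
        n = int(rng.poisson(intensity * window.volume))
    else:
        if n_points < 0:
            raise ValueError("n_points must be nonnegative")
        n = int(n_points)
    pts = rng.uniform(0.0, 1.0, size=(n, 3)) * window.sides
    return PointPattern3D(points=pts, window=window)


def simulate_columnar(window: Window3D, params: ColumnarParams, seed: int = 0) -> PointPattern3D:
    """Simulate a Poisson-line-cluster pattern with columns along the x-axis.

    Parent lines parallel to x sit at Poisson-distributed (y, z) positions and
    span the window; each receives a Poisson number of daughters, uniform in x
    and displaced radially in (y, z) by an isotropic Gaussian of standard
    deviation ``column_sd``. Daughters landing outside the window are
    discarded (minus-sampling). A CSR admixture replaces the stated fraction
    of the points.
    """
    rng = split_rng(seed, "columnar")
    n_lines = int(rng.poisson(params.line_intensity * window.ly * window.lz))
    keep_frac = 1.0 - params.background_fraction
    daughters = []
    for _ in range(n_lines):
        yz = rng.uniform(0.0, 1.0, size=2) * (window.ly, window.lz)
        n_d = int(rng.poisson(params.points_per_line * keep_frac))
        if n_d == 0:
            continue
        x = rng.uniform(0.0, window.lx, size=n_d)
        off = rng.normal(0.0, params.column_sd, size=(n_d, 2)) if params.column_sd > 0 else 0.0
        pts = np.column_stack([x, np.broadcast_to(yz, (n_d, 2)) + off])
        daughters.append(pts)
    pts = np.concatenate(daughters, axis=0) if daughters else np.empty((0, 3))
    pts = pts[window.contains(pts)] if len(pts) else pts

    mu_bg = params.line_intensity * window.ly * window.lz * params.points_per_line \
        * params.background_fraction
    n_bg = int(rng.poisson(mu_bg))
    bg = rng.uniform(0.0, 1.0, size=(n_bg, 3)) * window.sides
    return PointPattern3D(points=np.concatenate([pts, bg], axis=0), window=window)


def simulate_hardcore(
    window: Window3D, proposal_intensity: float, hardcore_r: float, seed: int = 0
) -> PointPattern3D:
    """Simulate a Matérn type-II hard-core pattern.

    Poisson proposals receive i.i.d. uniform marks; a point survives iff no
    proposal with an earlier mark lies within ``hardcore_r``. Proposals are
    drawn in the window dilated by the hard-core radius and clipped back
    after thinning, so the returned pattern is the stationary process
    restricted to the window and the retained intensity has the closed form
    (1 − exp(−λ_p v)) / v with v the volume of the hard-core ball.
    """
    if hardcore_r < 0:
        raise ValueError("hardcore_r must be nonnegative")
    rng = split_rng(seed, "hardcore")
    r = float(hardcore_r)
    ext = window.sides + 2 * r
    n = int(rng.poisson(proposal_intensity * np.prod(ext)))
    pts = rng.uniform(0.0, 1.0, size=(n, 3)) * ext - r
    keep = np.ones(n, dtype=bool)
    if r > 0 and n >= 2:
        marks = rng.uniform(size=n)
        pairs = cKDTree(pts).query_pairs(r, output_type="ndarray")
        for i, j in pairs:
            if marks[i] < marks[j]:
                keep[j] = False
            else:
                keep[i] = False
    kept = pts[keep]
    kept = kept[window.contains(kept)]
    return PointPattern3D(points=kept, window=window)


# ---------------------------------------------------------------------------
# cell populations
# ---------------------------------------------------------------------------


def _sample_cell(rng: np.random.Generator, template: CellTemplate, center: np.ndarray) -> EllipsoidCell:
    a = rng.uniform(*template.long_axis_range)
    b, c = np.sort(rng.uniform(*template.short_axis_range, size=2))[::-1]
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    semi = np.array([a, b, c])
    # uniform point in the ellipsoid shrunk by nucleolus_extent
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    r = template.nucleolus_extent * rng.uniform() ** (1.0 / 3.0)
    nucleolus = center + rot @ (semi * r * u)
    return EllipsoidCell(semi_axes=semi, center=center, rotation=rot, nucleolus=nucleolus)


def place_population(spec: PopulationSpec, max_tries_per_cell: int = 1000) -> list[EllipsoidCell]:
    """Place ``n_cells`` pairwise-disjoint ellipsoids fully inside the window.

    Disjointness is enforced conservatively through bounding spheres
    (centre distance > sum of the bounding radii); candidate placements are
    rejected and retried up to a bounded budget.
    """
    rng = split_rng(spec.seed, "population")
    cells: list[EllipsoidCell] = []
    centers = np.empty((0, 3))
    radii = np.empty(0)
    budget = max_tries_per_cell * max(spec.n_cells, 1)
    sides = spec.window.sides
    while len(cells) < spec.n_cells:
        if budget <= 0:
            raise RuntimeError(
                f"placement retry budget exhausted after placing {len(cells)} of "
                f"{spec.n_cells} cells; enlarge the window or reduce n_cells"
            )
        budget -= 1
        rmax = spec.template.long_axis_range[1]
        lo, hi = rmax, sides - rmax
        if np.any(hi <= lo):
            raise RuntimeError("window too small to contain a single cell")
        center = rng.uniform(lo, hi)
        cell = _sample_cell(rng, spec.template, center)
        r = cell.bounding_radius
        if len(cells):
            d = np.linalg.norm(centers - center, axis=1)
            if np.any(d <= radii + r):
                continue
        cells.append(cell)
        centers = np.vstack([centers, center])
        radii = np.append(radii, r)
    return cells


def voxelize_cells(
    cells: list[EllipsoidCell],
    voxel_pitch_nm: tuple[float, float, float],
    window: Window3D,
) -> CellLabelVolume:
    """Rasterize disjoint cells onto an anisotropic voxel grid.

    A voxel gets label ``i`` (1-based, order of ``cells``) iff its centre lies
    inside cell ``i``; 0 is background. Overlapping cells raise, since the
    downstream estimators assume identifiable cells.
    """
    pitch_um = np.asarray(voxel_pitch_nm, dtype=float) / 1000.0
    if np.any(pitch_um <= 0):
        raise ValueError("voxel pitch must be positive")
    shape = np.maximum(np.floor(window.sides / pitch_um).astype(int), 1)
    labels = np.zeros(shape, dtype=np.int32)
    for i, cell in enumerate(cells, start=1):
        r = cell.bounding_radius
        lo = np.maximum(np.floor((cell.center - r) / pitch_um - 1).astype(int), 0)
        hi = np.minimum(np.ceil((cell.center + r) / pitch_um + 1).astype(int), shape)
        if np.any(hi <= lo):
            continue
        axes = [np.arange(lo[d], hi[d]) for d in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        centers = (grid + 0.5) * pitch_um
        inside = cell.contains(centers.reshape(-1, 3)).reshape(centers.shape[:3])
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if np.any(sub[inside] != 0):
            raise ValueError(f"cell {i} overlaps a previously voxelized cell")
        sub[inside] = i
    return CellLabelVolume(labels=labels, voxel_pitch_nm=tuple(float(p) for p in voxel_pitch_nm))


# ---------------------------------------------------------------------------
# counting studies
# ---------------------------------------------------------------------------


def simulate_fractionator_study(
    true_N: int,
    fractions: tuple[float, float, float, float],
    seed: int = 0,
) -> FractionatorCounts:
    """Simulate an optical fractionator study over a known population.

    Each of ``true_N`` cells is sampled independently with probability
    ssf·bsf·asf·hsf, so ΣQ⁻ is binomial and the fractionator estimate is
    unbiased for ``true_N``.
    """
    ssf, bsf, asf, hsf = fractions
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError("sampling fractions must be in (0, 1]")
    if true_N < 0:
        raise ValueError("true_N must be nonnegative")
    rng = split_rng(seed, "fractionator")
    q = int(rng.binomial(true_N, ssf * bsf * asf * hsf)) if true_N else 0
    return FractionatorCounts(Q=q, ssf=ssf, bsf=bsf, asf=asf, hsf=hsf)


def simulate_cavalieri_sections(
    shape: EllipsoidCell | list[EllipsoidCell] | None,
    section_spacing_T: float,
    area_per_point: float,
    seed: int = 0,
    axis: int = 2,
) -> CavalieriCounts:
    """Simulate Cavalieri point counting of a shape (ellipsoid or union).

    Parallel sections perpendicular to ``axis`` are placed with uniformly
    random phase and spacing ``T``; each section carries a square point grid
    of area ``area_per_point`` per point with a uniformly random in-plane
    offset. Returns the per-section counts of grid points falling inside the
    shape, from which ``cavalieri_volume`` is unbiased for the true volume.
    """
    if section_spacing_T <= 0 or area_per_point <= 0:
        raise ValueError("T and area per point must be positive")
    cells = [] if shape is None else ([shape] if isinstance(shape, EllipsoidCell) else list(shape))
    rng = split_rng(seed, "cavalieri")
    T = float(section_spacing_T)
    step = float(np.sqrt(area_per_point))
    phase = rng.uniform(0.0, T)
    offsets = rng.uniform(0.0, step, size=2)
    if not cells:
        return CavalieriCounts(T=T, area_per_point=area_per_point, counts=np.zeros(1, dtype=int))

    in_plane = [d for d in range(3) if d != axis]
    lo = np.min([c.center - c.bounding_radius for c in cells], axis=0)
    hi = np.max([c.center + c.bounding_radius for c in cells], axis=0)
    # sections at phase + kT covering [lo, hi] along the section axis
    k0 = int(np.ceil((lo[axis] - phase) / T))
    k1 = int(np.floor((hi[axis] - phase) / T))
    counts = []
    for k in range(k0, k1 + 1):
        z = phase + k * T
        u = offsets[0] + step * np.arange(np.floor((lo[in_plane[0]] - offsets[0]) / step) - 1,
                                          np.ceil((hi[in_plane[0]] - offsets[0]) / step) + 1)
        v = offsets[1] + step * np.arange(np.floor((lo[in_plane[1]] - offsets[1]) / step) - 1,
                                          np.ceil((hi[in_plane[1]] - offsets[1]) / step) + 1)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        pts = np.empty((uu.size, 3))
        pts[:, in_plane[0]] = uu.ravel()
        pts[:, in_plane[1]] = vv.ravel()
        pts[:, axis] = z
        inside = np.zeros(uu.size, dtype=bool)
        for c in cells:
            inside |= c.contains(pts)
        counts.append(int(inside.sum()))
    if not counts:
        counts = [0]
    return CavalieriCounts(T=T, area_per_point=area_per_point, counts=np.array(counts, dtype=int))
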