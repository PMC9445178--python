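"""Design-based stereology: Cavalieri volume, optical fractionator, volume tensors.

The three estimators implemented here are the classical unbiased design-based
probes used for quantifying a cell population in thick sectioned tissue:

* **Cavalieri estimator** — volume from systematic parallel sections with
  point counting: ``V = T · (a/p) · ΣP`` where ``T`` is the mean distance
  between the analysed sections, ``a/p`` the grid area per point and ``ΣP``
  the total number of grid points hitting the region.
* **Optical fractionator** — total cell number from counts in a known
  fraction of the tissue: ``N = (1/ssf)(1/bsf)(1/asf)(1/hsf) · ΣQ⁻``, the
  product of the inverse slab, block (section), area and height sampling
  fractions with the number of cells sampled by optical disectors. The
  equivalent component form is ``N = 2 · (T/MA) · (A/a) · (t_Q⁻/h) · ΣQ⁻``
  where the leading factor 2 is the inverse slab sampling fraction for
  every-second-slab sampling.
* **Volume tensors** — moments of a cell ``X`` about a reference point
  (here the nucleolus): ``T_k(X) = (1/k!) ∫_X x⊗…⊗x dx``. Rank 0 is the
  volume, rank 1 / rank 0 the centre of mass relative to the reference, and
  the centred rank 2 yields a moment-matched ellipsoid whose semi-axes give
  an elongation index. The rotator probe estimates these tensors from
  boundary distances along sine-weighted half-lines in isotropically rotated
  planes through the reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import split_rng
from .geometry import EllipsoidCell

__all__ = [
    "CavalieriCounts",
    "FractionatorCounts",
    "VolumeTensors",
    "TensorSummaries",
    "cavalieri_volume",
    "fractionator_number",
    "number_density",
    "effective_section_spacing",
    "exact_volume_tensors",
    "ellipsoid_volume_tensors",
    "rotator_tensor_estimate",
    "tensor_summaries",
]


# ---------------------------------------------------------------------------
# counting-design records
# ---------------------------------------------------------------------------


@dataclass
class CavalieriCounts:
    """Record of a Cavalieri point-counting design.

    T : mean distance between analysed sections, µm.
    area_per_point : grid area associated with each test point, µm².
    counts : per-section tallies of grid points hitting the region.
    """

    T: float
    area_per_point: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("section spacing T must be positive")
        if self.area_per_point <= 0:
            raise ValueError("area per point must be positive")
        c = np.asarray(self.counts)
        if c.size and (np.any(c < 0) or not np.issubdtype(c.dtype, np.integer)):
            c = c.astype(float)
            if np.any(c < 0) or np.any(c != np.round(c)):
                raise ValueError("counts must be nonnegative integers")
        self.counts = np.asarray(c, dtype=int).reshape(-1)


@dataclass
class FractionatorCounts:
    """Record of an optical fractionator design, in fraction and/or component form.

    Fraction form: ``ssf, bsf, asf, hsf`` each in (0, 1].
    Component form: slab spacing ``T`` (µm), microtome advance ``MA`` (µm),
    grid step area ``A`` (µm²), counting-frame area ``a`` (µm²), disector
    height ``h`` (µm) and number-weighted mean section thickness ``t_Q`` (µm);
    the slab sampling (every second slab) contributes a fixed factor 2.
    ``Q`` is the total number of sampled cells ΣQ⁻.
    """

    Q: int
    ssf: float | None = None
    bsf: float | None = None
    asf: float | None = None
    hsf: float | None = None
    T: float | None = None
    MA: float | None = None
    A: float | None = None
    a: float | None = None
    h: float | None = None
    t_Q: float | None = None

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be nonnegative")
        if self.has_fractions:
            for name in ("ssf", "bsf", "asf", "hsf"):
                f = getattr(self, name)
                if not (0 < f <= 1):
                    raise ValueError(f"sampling fraction {name}={f} must be in (0, 1]")
        if self.has_components:
            for name in ("T", "MA", "A", "a", "h", "t_Q"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"component {name} must be positive")
            if self.h > self.t_Q:
                raise ValueError("disector height h cannot exceed section thickness t_Q")
            if self.a > self.A:
                raise ValueError("counting frame area a cannot exceed grid area A")
            if self.MA > self.T:
                raise ValueError("microtome advance MA cannot exceed slab spacing T")
        if not self.has_fractions and not self.has_components:
            raise ValueError("either the fraction form or the component form must be given")

    @property
    def has_fractions(self) -> bool:
        return all(getattr(self, n) is not None for n in ("ssf", "bsf", "asf", "hsf"))

    @property
    def has_components(self) -> bool:
        return all(getattr(self, n) is not None for n in ("T", "MA", "A", "a", "h", "t_Q"))


# ---------------------------------------------------------------------------
# scalar estimators
# ---------------------------------------------------------------------------


def cavalieri_volume(counts: CavalieriCounts) -> float:
    """Cavalieri volume estimate ``V = T · (a/p) · ΣP`` in µm³."""
    return float(counts.T * counts.area_per_point * int(np.sum(counts.counts)))


def fractionator_number(counts: FractionatorCounts) -> float:
    """Optical fractionator estimate of the total cell number.

    Uses the fraction form when available; when both forms are supplied they
    must agree to 1e-9 relative.
    """
    n_frac = n_comp = None
    if counts.has_fractions:
        inv = 1.0 / (counts.ssf * counts.bsf * counts.asf * counts.hsf)
        n_frac = inv * counts.Q
    if counts.has_components:
        n_comp = 2.0 * (counts.T / counts.MA) * (counts.A / counts.a) * (counts.t_Q / counts.h) * counts.Q
    if n_frac is not None and n_comp is not None:
        ref = max(abs(n_frac), abs(n_comp), 1.0)
        if abs(n_frac - n_comp) > 1e-9 * ref:
            raise ValueError(
                f"fraction form ({n_frac:.12g}) and component form ({n_comp:.12g}) disagree"
            )
    return float(n_frac if n_frac is not None else n_comp)


def number_density(N: float, V: float) -> float:
    """Number density in cells per mm³ from a count and a volume in µm³."""
    if V <= 0:
        raise ValueError("volume must be positive")
    return float(N / V * 1e9)


def effective_section_spacing(cut_thickness_nm: float, sampling_period: int) -> float:
    """Effective spacing (nm) of analysed sections cut at ``cut_thickness_nm``
    when every ``sampling_period``-th section is kept."""
    if cut_thickness_nm <= 0 or sampling_period < 1:
        raise ValueError("cut thickness must be positive and period >= 1")
    return float(cut_thickness_nm * sampling_period)


# ---------------------------------------------------------------------------
# volume tensors
# ---------------------------------------------------------------------------


@dataclass
class VolumeTensors:
    """Volume tensors of rank 0–2 about a reference point.

    rank0 : µm³ (the volume).
    rank1 : µm⁴ 3-vector, (1/1!)∫x dx with x relative to the reference.
    rank2 : µm⁵ symmetric 3×3 matrix, (1/2!)∫ x xᵀ dx.
    """

    rank0: float
    rank1: np.ndarray
    rank2: np.ndarray
    reference: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rank1 = np.asarray(self.rank1, dtype=float).reshape(3)
        self.rank2 = np.asarray(self.rank2, dtype=float).reshape(3, 3)
        self.reference = np.asarray(self.reference, dtype=float).reshape(3)
        if self.rank0 < 0:
            raise ValueError("rank-0 tensor (volume) must be nonnegative")
        if not np.allclose(self.rank2, self.rank2.T, atol=1e-9 * max(1.0, abs(self.rank0))):
            raise ValueError("rank-2 tensor must be symmetric")
        self.rank2 = 0.5 * (self.rank2 + self.rank2.T)


@dataclass
class TensorSummaries:
    """Scalar summaries derived from rank 0–2 volume tensors.

    volume in µm³; centroid relative to the reference point, µm;
    displacement = |centroid|, µm; semi_axes (a ≥ b ≥ c) of the
    moment-matched ellipsoid, µm; elongation_index = a/c; axes as rows of an
    orthonormal matrix (principal directions, same order as semi_axes).
    """

    volume: float
    centroid: np.ndarray
    displacement: float
    semi_axes: np.ndarray
    elongation_index: float
    axes: np.ndarray


def ellipsoid_volume_tensors(cell: EllipsoidCell, reference: np.ndarray | None = None) -> VolumeTensors:
    """Closed-form volume tensors of an ellipsoid about ``reference``.

    With m the ellipsoid centre relative to the reference and
    C = R·diag(a²,b²,c²)/5·Rᵀ the ellipsoid's covariance of the uniform
    distribution on it, the moments are V, V·m and (V/2)(m mᵀ + C).
    """
    ref = np.asarray(cell.nucleolus if reference is None else reference, dtype=float).reshape(3)
    V = cell.volume
    m = cell.center - ref
    cov = cell.rotation @ np.diag(cell.semi_axes**2 / 5.0) @ cell.rotation.T
    return VolumeTensors(
        rank0=V,
        rank1=V * m,
        rank2=0.5 * V * (np.outer(m, m) + cov),
        reference=ref,
    )


def _label_region_tensors(volume, reference: np.ndarray, label: int) -> VolumeTensors:
    """Voxel-sum volume tensors of one labelled region (midpoint rule)."""
    ref = np.asarray(reference, dtype=float).reshape(3)
    idx = np.argwhere(volume.labels == label)
    if idx.size == 0:
        raise ValueError(f"label {label} selects an empty region")
    pitch = volume.pitch_um
    coords = (idx + 0.5) * pitch - ref
    vvol = float(np.prod(pitch))
    rank0 = vvol * idx.shape[0]
    rank1 = vvol * coords.sum(axis=0)
    rank2 = 0.5 * vvol * (coords.T @ coords)
    return VolumeTensors(rank0=rank0, rank1=rank1, rank2=rank2, reference=ref)


def exact_volume_tensors(obj, reference: np.ndarray | None = None, *, label: int | None = None,
                         max_rank: int = 2) -> VolumeTensors:
    """Volume tensors of rank 0..2 by exact/numerical integration.

    ``obj`` is an :class:`EllipsoidCell` (closed forms) or a
    ``CellLabelVolume`` (midpoint-rule voxel sums for one label, the sole
    nonzero label by default). Serves as the oracle for
    :func:`rotator_tensor_estimate`.
    """
    if max_rank != 2:
        raise NotImplementedError("ranks 0..2 are supported")
    if obj is None:
        return VolumeTensors(0.0, np.zeros(3), np.zeros((3, 3)))
    if isinstance(obj, EllipsoidCell):
        return ellipsoid_volume_tensors(obj, reference)
    # duck-typed CellLabelVolume (avoids a circular import with morph3d)
    if reference is None:
        raise ValueError("a reference point is required for a label volume")
    if label is None:
        present = np.unique(obj.labels)
        present = present[present > 0]
        if present.size != 1:
            raise ValueError("label volume holds several cells; pass label=")
        label = int(present[0])
    return _label_region_tensors(obj, reference, label)


def _orthonormal_frame(vertical_axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = np.asarray(vertical_axis, dtype=float).reshape(3)
    nrm = np.linalg.norm(v)
    if not np.isclose(nrm, 1.0, atol=1e-8):
        raise ValueError("vertical_axis must be a unit vector")
    v = v / nrm
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u1 = np.cross(v, helper)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(v, u1)
    return v, u1, u2


def _sine_weighted_angles(u: np.ndarray) -> np.ndarray:
    """Inverse CDF of the density |sin ψ|/4 on [0, 2π)."""
    q = np.asarray(u, dtype=float)
    out = np.where(
        q <= 0.5,
        np.arccos(np.clip(1.0 - 4.0 * q, -1.0, 1.0)),
        np.pi + np.arccos(np.clip(3.0 - 4.0 * q, -1.0, 1.0)),
    )
    return out


def rotator_tensor_estimate(
    cell: EllipsoidCell | None,
    reference: np.ndarray | None = None,
    vertical_axis: np.ndarray = (1.0, 0.0, 0.0),
    n_halflines: int = 4,
    n_planes: int = 1,
    seed: int = 0,
) -> VolumeTensors:
    """Rotator-design Monte-Carlo estimate of the volume tensors.

    For each of ``n_planes`` planes containing the vertical axis through the
    reference point (plane azimuth uniform on [0, π)), boundary distances
    ρ(ω) are measured along ``n_halflines`` systematically placed
    sine-weighted half-lines. The in-plane half-line angles are drawn by
    systematic inverse-CDF sampling of the density |sin ψ|/4, which makes the
    rank-0 estimate exact on a ball from a single plane and the estimator
    unbiased for all ranks: with ψ so distributed and azimuth φ uniform,

        E[ 4π · ω⊗k · ρ(ω)^{k+3} / ((k+3) k!) ] = T_k(X).

    Requires the cell to be star-shaped about the reference (true for any
    ellipsoid containing it). For shapes where a half-line crosses the
    boundary several times the contract would be the total intercept moment;
    ellipsoids have a single crossing.
    """
    if cell is None:
        return VolumeTensors(0.0, np.zeros(3), np.zeros((3, 3)))
    ref = np.asarray(cell.nucleolus if reference is None else reference, dtype=float).reshape(3)
    if not bool(cell.contains(ref)[0]):
        raise ValueError("reference point must lie inside the cell")
    if n_halflines < 1 or n_planes < 1:
        raise ValueError("n_halflines and n_planes must be >= 1")
    v, u1, u2 = _orthonormal_frame(np.asarray(vertical_axis, dtype=float))
    rng = split_rng(seed, "rotator")

    phi = rng.uniform(0.0, np.pi, size=n_planes)
    u0 = rng.uniform(0.0, 1.0, size=n_planes)
    j = np.arange(n_halflines)
    psi = _sine_weighted_angles(((u0[:, None] + j[None, :]) % n_halflines) / n_halflines)

    horiz = np.cos(phi)[:, None, None] * u1 + np.sin(phi)[:, None, None] * u2  # (P,1,3)
    omega = np.cos(psi)[..., None] * v + np.sin(psi)[..., None] * horiz  # (P,H,3)
    rho = cell.ray_lengths(ref, omega.reshape(-1, 3)).reshape(n_planes, n_halflines)

    w = 4.0 * np.pi / (n_planes * n_halflines)  # MC weight per half-line
    rank0 = w * np.sum(rho**3) / 3.0
    rank1 = w * np.einsum("ph,phd->d", rho**4, omega) / 4.0
    rank2 = 0.5 * w * np.einsum("ph,phd,phe->de", rho**5, omega, omega) / 5.0
    return VolumeTensors(rank0=rank0, rank1=rank1, rank2=rank2, reference=ref)


def tensor_summaries(tensors: VolumeTensors) -> TensorSummaries:
    """Volume, centroid, nucleus displacement and moment-matched ellipsoid shape.

    The shape summary is the ellipsoid whose uniform-distribution covariance
    has the same principal axes and anisotropy as the centred rank-2 moment
    (semi-axes ∝ √(5λᵢ)), rescaled so its volume equals the rank-0 tensor
    exactly; for data that are themselves ellipsoidal the rescale factor
    is 1. The elongation index is the longest over the shortest semi-axis.
    """
    if tensors.rank0 <= 0:
        raise ValueError("rank-0 tensor (volume) must be positive to summarise")
    V = tensors.rank0
    centroid = tensors.rank1 / V
    # centred second moment of the uniform distribution on X
    cov = 2.0 * tensors.rank2 / V - np.outer(centroid, centroid)
    eigval, eigvec = np.linalg.eigh(cov)
    tol = 1e-9 * max(float(np.max(np.abs(eigval))), 1e-300)
    if np.any(eigval < -tol):
        raise ValueError(
            f"centred rank-2 tensor is not positive semidefinite (eigenvalues {eigval})"
        )
    eigval = np.clip(eigval, 0.0, None)
    semi = np.sqrt(5.0 * eigval)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    axes = eigvec[:, order].T
    if np.any(semi <= 0):
        raise ValueError("degenerate (flat) second moment; shape summary undefined")
    v_fit = 4.0 / 3.0 * np.pi * np.prod(semi)
    semi = semi * (V / v_fit) ** (1.0 / 3.0)
    return TensorSummaries(
        volume=float(V),
        centroid=centroid,
        displacement=float(np.linalg.norm(centroid)),
        semi_axes=semi,
        elongation_index=float(semi[0] / semi[2]),
        axes=axes,
    )
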