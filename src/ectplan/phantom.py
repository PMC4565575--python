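"""Synthetic voxel anatomy (phantoms) and safety-margin masks.

A phantom is a labelled 3-D voxel grid standing in for a segmented CT volume:
tumor lesions as spheres, a blood vessel as a cylinder and bone as a slab,
embedded in homogeneous normal soft tissue.  Voxel membership in a solid is
decided by voxel-center inclusion, which keeps every geometric quantity
checkable against a brute-force loop over voxel centers.

Coordinate convention: 0-based indices, axis-aligned grid, and the world
position (mm) of voxel center ``(i, j, k)`` is ``origin + (index + 0.5) *
spacing``.  No orientation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# Label codes. One code per voxel; background doubles as normal soft tissue.
BACKGROUND = 0
TUMOR = 1
VESSEL = 2
BONE = 3

LABEL_NAMES = {BACKGROUND: "normal", TUMOR: "tumor", VESSEL: "vessel", BONE: "bone"}


class PhantomConfigError(ValueError):
    """Raised for inconsistent phantom configurations (overlap, out of grid)."""


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue type.

    Parameters
    ----------
    sigma0 : float
        Baseline (non-electroporated) conductivity, S/m.
    sigma_factor : float
        Multiplicative conductivity increase when fully electroporated
        (dimensionless, >= 1).
    e_rev : float
        Reversible electroporation threshold, V/cm.
    e_irrev : float
        Irreversible electroporation threshold, V/cm.
    """

    sigma0: float
    sigma_factor: float
    e_rev: float
    e_irrev: float

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.sigma_factor < 1:
            raise ValueError("sigma_factor must be >= 1")
        if not (0 < self.e_rev < self.e_irrev):
            raise ValueError("thresholds must satisfy 0 < e_rev < e_irrev")


def default_tissue_table() -> dict[int, TissueProperties]:
    """Default electrical properties per tissue code.

    The numbers are literature-typical assumptions, not measured values:
    soft tissues around 0.2-0.3 S/m, blood markedly more conductive, cortical
    bone nearly insulating.  Electroporation raises soft-tissue conductivity
    by a factor of 3.5 between the reversible and irreversible thresholds;
    bone is treated as non-electroporating.  Thresholds follow the display
    convention of 400 V/cm for tumor and 350 V/cm for normal tissue, with
    800 V/cm as the irreversible threshold for soft tissues.
    """
    return {
        BACKGROUND: TissueProperties(0.2, 3.5, 350.0, 800.0),
        TUMOR: TissueProperties(0.3, 3.5, 400.0, 800.0),
        VESSEL: TissueProperties(0.7, 3.5, 350.0, 800.0),
        BONE: TissueProperties(0.02, 1.0, 350.0, 800.0),
    }


@dataclass
class VoxelPhantom:
    """Labelled 3-D voxel grid: the simulation domain.

    Attributes
    ----------
    labels : ndarray of int
        Shape ``(nx, ny, nz)``; values drawn from the declared code set.
    spacing : ndarray of float
        mm per voxel along each axis, all > 0.
    origin : ndarray of float
        World coordinate (mm) of the corner of voxel (0, 0, 0).
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0 on all axes")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        known = set(LABEL_NAMES)
        found = set(np.unique(self.labels).tolist())
        if not found <= known:
            raise ValueError(f"unknown label codes: {sorted(found - known)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.mask(TUMOR)

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.mask(VESSEL)

    @property
    def bone_mask(self) -> np.ndarray:
        return self.mask(BONE)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates (mm)."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def world_to_index(self, point) -> tuple[int, int, int]:
        """Voxel containing a world point: floor((world - origin) / spacing)."""
        idx = np.floor((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        return tuple(int(v) for v in idx)  # type: ignore[return-value]

    def index_to_center(self, index) -> np.ndarray:
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.spacing

    def contains_point(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        upper = self.origin + np.asarray(self.shape) * self.spacing
        return bool(np.all(p >= self.origin) and np.all(p < upper))

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid per axis, mm."""
        return np.asarray(self.shape) * self.spacing


@dataclass(frozen=True)
class Sphere:
    """Tumor lesion: center (world mm) and diameter (mm)."""

    center: tuple[float, float, float]
    diameter: float


@dataclass(frozen=True)
class Cylinder:
    """Vessel: a point on the axis, axis direction, radius (mm).

    ``length`` limits the cylinder to a segment centered on ``point``;
    ``None`` means the vessel runs through the whole grid.
    """

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float
    length: float | None = None


@dataclass(frozen=True)
class Slab:
    """Bone: half-space slab with unit normal, signed offset of the mid-plane
    from the world origin along the normal (mm), and thickness (mm)."""

    normal: tuple[float, float, float]
    offset: float
    thickness: float


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (80, 80, 80)
    spacing: tuple[float, float, float] | float = 0.57
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tumors: list[Sphere] = field(default_factory=list)
    vessel: Cylinder | None = None
    bone: Slab | None = None


def _center_grids(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    spacing = np.broadcast_to(np.asarray(config.spacing, dtype=float), (3,))
    origin = np.asarray(config.origin, dtype=float)
    axes = [origin[a] + (np.arange(config.shape[a]) + 0.5) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")  # type: ignore[return-value]


def _sphere_mask(xx, yy, zz, sphere: Sphere) -> np.ndarray:
    c = np.asarray(sphere.center, dtype=float)
    r = sphere.diameter / 2.0
    return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r * r


def _cylinder_mask(xx, yy, zz, cyl: Cylinder) -> np.ndarray:
    p = np.asarray(cyl.point, dtype=float)
    d = np.asarray(cyl.direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise PhantomConfigError("cylinder direction must be nonzero")
    d = d / nrm
    rx, ry, rz = xx - p[0], yy - p[1], zz - p[2]
    t = rx * d[0] + ry * d[1] + rz * d[2]  # axial coordinate
    per2 = rx * rx + ry * ry + rz * rz - t * t
    mask = per2 <= cyl.radius**2
    if cyl.length is not None:
        mask &= np.abs(t) <= cyl.length / 2.0
    return mask


def _slab_mask(xx, yy, zz, slab: Slab) -> np.ndarray:
    n = np.asarray(slab.normal, dtype=float)
    nrm = np.linalg.norm(n)
    if nrm == 0:
        raise PhantomConfigError("slab normal must be nonzero")
    n = n / nrm
    s = xx * n[0] + yy * n[1] + zz * n[2]
    return np.abs(s - slab.offset) <= slab.thickness / 2.0


def make_phantom(config: PhantomConfig) -> VoxelPhantom:
    """Build a labelled phantom from geometric solids.

    Tumor spheres must lie entirely inside the grid, and no two solids may
    overlap — overlap is a configuration error, not resolved by precedence,
    because an ECT plan needs an unambiguous tissue at every voxel.
    """
    spacing = np.broadcast_to(np.asarray(config.spacing, dtype=float), (3,))
    origin = np.asarray(config.origin, dtype=float)
    upper = origin + np.asarray(config.shape) * spacing

    for sph in config.tumors:
        c = np.asarray(sph.center, dtype=float)
        r = sph.diameter / 2.0
        if np.any(c - r < origin) or np.any(c + r > upper):
            raise PhantomConfigError(f"tumor sphere at {sph.center} extends outside the grid")

    xx, yy, zz = _center_grids(config)
    labels = np.zeros(config.shape, dtype=np.int16)
    solids: list[tuple[int, np.ndarray, str]] = []
    for i, sph in enumerate(config.tumors):
        solids.append((TUMOR, _sphere_mask(xx, yy, zz, sph), f"tumor[{i}]"))
    if config.vessel is not None:
        solids.append((VESSEL, _cylinder_mask(xx, yy, zz, config.vessel), "vessel"))
    if config.bone is not None:
        solids.append((BONE, _slab_mask(xx, yy, zz, config.bone), "bone"))

    for i, (_, mask_i, name_i) in enumerate(solids):
        for _, mask_j, name_j in solids[i + 1 :]:
            if np.any(mask_i & mask_j):
                raise PhantomConfigError(f"solids overlap: {name_i} and {name_j}")

    for code, mask, _ in solids:
        labels[mask] = code
    return VoxelPhantom(labels=labels, spacing=spacing.copy(), origin=origin)


def safety_margin(phantom: VoxelPhantom, width: float) -> np.ndarray:
    """Safety-margin mask: the belt of normal tissue around the tumor.

    A voxel belongs to the margin when its center lies within ``width`` mm
    (Euclidean, spacing-aware) of the tumor, it is not itself tumor, and it
    is normal soft tissue (vessel and bone are excluded — they are not a
    treatment target).

    Parameters
    ----------
    width : float
        Margin width in mm, >= 0.  The clinical convention is a belt of up
        to 5 mm.
    """
    if width < 0:
        raise ValueError("margin width must be >= 0")
    tumor = phantom.tumor_mask
    if width == 0 or not tumor.any():
        return np.zeros(phantom.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~tumor, sampling=phantom.spacing)
    return (dist <= width) & (phantom.labels == BACKGROUND)
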