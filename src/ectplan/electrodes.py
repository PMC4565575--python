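"""Single long-needle electrodes, the 5-electrode star array, pulse schedules.

ECT of deep-seated tumors uses individually placed long needle electrodes
with an uninsulated (active) distal tip; only that segment imposes boundary
potential.  The canonical configuration is a star: one needle through the
tumor center and four peripheral needles in surrounding normal tissue at
1 cm from the center, which puts adjacent peripheral needles ~1.4 cm apart
(a square).  Pulses are delivered pairwise: adjacent outer-outer pairs at a
higher voltage, then each outer against the central needle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ectplan.phantom import LABEL_NAMES, VESSEL, BONE, VoxelPhantom

#: Angular tolerance (degrees) for the "needles are parallel" invariant.
PARALLEL_TOL_DEG = 1.0

#: Default needle radius, mm.  Not a protocol parameter; typical long-needle
#: hardware has shaft diameters slightly over 1 mm.
DEFAULT_RADIUS_MM = 0.6


def _unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be nonzero")
    return v / n


@dataclass(frozen=True)
class NeedleElectrode:
    """One long needle electrode.

    ``entry`` and ``tip`` are world points in mm; ``active_tip_length`` is
    the conductive, uninsulated distal segment measured back from the tip.
    """

    id: int
    entry: tuple[float, float, float]
    tip: tuple[float, float, float]
    active_tip_length: float
    radius: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if np.allclose(self.entry, self.tip):
            raise ValueError("entry and tip must differ")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.active_tip_length > self.length + 1e-9:
            raise ValueError("active tip cannot be longer than the needle")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.tip) - np.asarray(self.entry)))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry to tip."""
        return _unit(np.asarray(self.tip) - np.asarray(self.entry))

    @property
    def active_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints (proximal, distal) of the active tip, world mm."""
        tip = np.asarray(self.tip, dtype=float)
        return tip - self.active_tip_length * self.direction, tip


@dataclass
class ElectrodeArray:
    """Ordered collection of parallel needles sharing an insertion direction."""

    electrodes: list[NeedleElectrode]
    insertion_direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = _unit(self.insertion_direction, "insertion_direction")
        self.insertion_direction = tuple(d)
        ids = [e.id for e in self.electrodes]
        if len(ids) != len(set(ids)):
            raise ValueError("electrode ids must be unique")
        tol = np.cos(np.deg2rad(PARALLEL_TOL_DEG))
        for e in self.electrodes:
            if abs(float(np.dot(e.direction, d))) < tol:
                raise ValueError(
                    f"electrode {e.id} is not parallel to the insertion direction "
                    f"(tolerance {PARALLEL_TOL_DEG} deg)"
                )

    def __iter__(self):
        return iter(self.electrodes)

    def __len__(self) -> int:
        return len(self.electrodes)

    def get(self, electrode_id: int) -> NeedleElectrode:
        for e in self.electrodes:
            if e.id == electrode_id:
                return e
        raise KeyError(f"no electrode with id {electrode_id}")

    def ids(self) -> list[int]:
        return [e.id for e in self.electrodes]

    def pair_distance(self, id_a: int, id_b: int) -> float:
        """Center-to-center distance (mm) between two parallel needle axes."""
        a, b = self.get(id_a), self.get(id_b)
        d = np.asarray(self.insertion_direction)
        delta = np.asarray(b.tip, dtype=float) - np.asarray(a.tip, dtype=float)
        perp = delta - np.dot(delta, d) * d
        return float(np.linalg.norm(perp))

    def translated(self, offset) -> "ElectrodeArray":
        """Rigidly shifted copy of the array."""
        off = np.asarray(offset, dtype=float)
        return ElectrodeArray(
            electrodes=[
                NeedleElectrode(
                    id=e.id,
                    entry=tuple(np.asarray(e.entry) + off),
                    tip=tuple(np.asarray(e.tip) + off),
                    active_tip_length=e.active_tip_length,
                    radius=e.radius,
                )
                for e in self.electrodes
            ],
            insertion_direction=self.insertion_direction,
        )


@dataclass(frozen=True)
class ScheduleEntry:
    pair: tuple[int, int]
    voltage: float
    n_pulses: int = 8
    pulse_duration_us: float = 100.0

    def __post_init__(self) -> None:
        if self.voltage < 0:
            raise ValueError("voltage must be >= 0")
        if self.n_pulses <= 0:
            raise ValueError("n_pulses must be > 0")


@dataclass
class PulseSchedule:
    """Ordered electrode-pair / voltage / pulse protocol."""

    entries: list[ScheduleEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_pulses(self) -> int:
        return sum(e.n_pulses for e in self.entries)

    def validate_against(self, array: ElectrodeArray) -> None:
        known = set(array.ids())
        for e in self.entries:
            missing = set(e.pair) - known
            if missing:
                raise ValueError(f"schedule references unknown electrode ids {sorted(missing)}")

    def with_voltages(self, voltages: dict[float, float]) -> "PulseSchedule":
        """Copy with each distinct nominal voltage level remapped."""
        return PulseSchedule(
            entries=[
                ScheduleEntry(
                    pair=e.pair,
                    voltage=voltages.get(e.voltage, e.voltage),
                    n_pulses=e.n_pulses,
                    pulse_duration_us=e.pulse_duration_us,
                )
                for e in self.entries
            ]
        )


# Delivery order of the star protocol: outer-outer pairs first, then
# center-outer pairs, the central needle being id 5.
STAR_PAIR_ORDER: list[tuple[int, int]] = [
    (1, 2), (1, 4), (2, 3), (3, 4),  # adjacent peripheral pairs
    (2, 5), (1, 5), (3, 5), (4, 5),  # center-outer pairs
]


def _orthonormal_frame(direction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = _unit(direction, "insertion_direction")
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(helper, d))
    v = np.cross(d, u)
    return u, v, d


def star_array(
    center,
    insertion_direction,
    center_to_outer: float = 10.0,
    active_tip: float = 30.0,
    radius: float = DEFAULT_RADIUS_MM,
    needle_length: float = 100.0,
) -> ElectrodeArray:
    """Five parallel needles in the star pattern.

    One needle runs through ``center`` (the tumor center) and four
    peripheral needles sit at ``center_to_outer`` mm from it, at 90 deg
    angular spacing (counter-clockwise, ids 1-4) in the plane normal to the
    insertion direction; the central needle carries id 5.  Tips are at equal
    depth, with the active tip centered on ``center`` along the insertion
    direction.
    """
    u, v, d = _orthonormal_frame(insertion_direction)
    center = np.asarray(center, dtype=float)
    tip_depth = center + (active_tip / 2.0) * d
    offsets = {5: np.zeros(3)}
    for i in range(4):
        ang = np.pi / 2 * i
        offsets[i + 1] = center_to_outer * (np.cos(ang) * u + np.sin(ang) * v)
    electrodes = []
    for eid in (1, 2, 3, 4, 5):
        tip = tip_depth + offsets[eid]
        entry = tip - needle_length * d
        electrodes.append(
            NeedleElectrode(
                id=eid, entry=tuple(entry), tip=tuple(tip),
                active_tip_length=active_tip, radius=radius,
            )
        )
    return ElectrodeArray(electrodes=electrodes, insertion_direction=tuple(d))


def _is_star(array: ElectrodeArray, rtol: float = 0.05) -> bool:
    if len(array) != 5 or set(array.ids()) != {1, 2, 3, 4, 5}:
        return False
    spokes = [array.pair_distance(i, 5) for i in (1, 2, 3, 4)]
    r = np.mean(spokes)
    if r <= 0 or np.max(np.abs(np.asarray(spokes) - r)) > rtol * r:
        return False
    for a, b in ((1, 2), (2, 3), (3, 4), (1, 4)):
        if abs(array.pair_distance(a, b) - np.sqrt(2) * r) > rtol * np.sqrt(2) * r:
            return False
    return True


def star_schedule(
    array: ElectrodeArray,
    v_center_outer: float = 1000.0,
    v_outer_outer: float = 1200.0,
    n_pulses: int = 8,
    pulse_duration_us: float = 100.0,
) -> PulseSchedule:
    """Standard star protocol: 8 pairs, outer-outer pairs first.

    Defaults give the clinical protocol: 1200 V between adjacent outer
    electrodes, 1000 V between the center and each outer electrode, 8 pulses
    of 100 us per pair — 64 pulses in total.
    """
    if not _is_star(array):
        raise ValueError(
            "array does not have the 5-needle star topology; build a "
            "PulseSchedule from explicit ScheduleEntry pairs instead"
        )
    entries = []
    for pair in STAR_PAIR_ORDER:
        voltage = v_center_outer if 5 in pair else v_outer_outer
        entries.append(
            ScheduleEntry(pair=pair, voltage=voltage, n_pulses=n_pulses,
                          pulse_duration_us=pulse_duration_us)
        )
    return PulseSchedule(entries=entries)


def voltage_to_distance_ratio(entry: ScheduleEntry, array: ElectrodeArray) -> float:
    """Applied voltage over center-to-center distance, in V/cm.

    The rule-of-thumb field estimate for needle pairs (~1000 V/cm for the
    clinical protocol).
    """
    d_mm = array.pair_distance(*entry.pair)
    if d_mm == 0:
        raise ValueError(f"electrodes {entry.pair} are coincident")
    return entry.voltage / (d_mm / 10.0)


def _segment_mask(phantom: VoxelPhantom, p0, p1, radius: float) -> np.ndarray:
    """Voxels whose centers lie within ``radius`` of the segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    # bounding box in index space, padded by radius + one voxel
    lo_w = np.minimum(p0, p1) - radius - phantom.spacing
    hi_w = np.maximum(p0, p1) + radius + phantom.spacing
    lo = np.maximum(np.floor((lo_w - phantom.origin) / phantom.spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((hi_w - phantom.origin) / phantom.spacing).astype(int) + 1,
        np.asarray(phantom.shape),
    )
    mask = np.zeros(phantom.shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    axes = [
        phantom.origin[a] + (np.arange(lo[a], hi[a]) + 0.5) * phantom.spacing[a]
        for a in range(3)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    seg = p1 - p0
    seg_len2 = float(np.dot(seg, seg))
    rx, ry, rz = xx - p0[0], yy - p0[1], zz - p0[2]
    if seg_len2 == 0:
        d2 = rx * rx + ry * ry + rz * rz
    else:
        t = np.clip((rx * seg[0] + ry * seg[1] + rz * seg[2]) / seg_len2, 0.0, 1.0)
        dx = rx - t * seg[0]
        dy = ry - t * seg[1]
        dz = rz - t * seg[2]
        d2 = dx * dx + dy * dy + dz * dz
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius * radius
    return mask


def rasterize(
    array: ElectrodeArray, phantom: VoxelPhantom, min_radius: float | None = None
) -> dict[int, np.ndarray]:
    """Active-tip voxel masks per electrode.

    Each mask holds the voxels whose centers lie within the needle radius of
    the active-tip segment.  Masks must be pairwise disjoint — overlap means
    the electrodes are too close together for the grid resolution.

    ``min_radius`` (mm) optionally inflates the rasterization radius; coarse
    grids cannot represent a sub-voxel needle, and callers that coarsen for
    speed (optimizer, robustness sweeps) pass a floor on the order of the
    voxel size so the needle always occupies a voxel column.
    """
    masks: dict[int, np.ndarray] = {}
    for e in array:
        a0, a1 = e.active_segment
        for pt, role in ((a0, "active-tip start"), (a1, "tip")):
            if not phantom.contains_point(pt):
                raise ValueError(f"electrode {e.id}: {role} lies outside the grid")
        radius = e.radius if min_radius is None else max(e.radius, min_radius)
        mask = _segment_mask(phantom, a0, a1, radius)
        if not mask.any():
            raise ValueError(
                f"electrode {e.id}: active tip rasterizes to no voxels "
                "(radius too small for this spacing)"
            )
        masks[e.id] = mask
    ids = list(masks)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(
                    f"electrodes {a} and {b} overlap after rasterization; "
                    "they are too close for this grid spacing"
                )
    return masks


@dataclass(frozen=True)
class CollisionViolation:
    electrode_id: int
    tissue_code: int

    @property
    def tissue(self) -> str:
        return LABEL_NAMES[self.tissue_code]


def check_collisions(array: ElectrodeArray, phantom: VoxelPhantom) -> list[CollisionViolation]:
    """Needle-shaft collisions with vessel or bone.

    The full shaft (entry to tip, inflated by the needle radius) is tested;
    one violation is reported per (electrode, tissue) combination.  An empty
    list means the plan is anatomically admissible.

    The test radius is never smaller than half the voxel diagonal: a safety
    check must not let a thin shaft thread between voxel centers, so on
    coarse grids the check is deliberately conservative.
    """
    violations = []
    r_floor = 0.5 * float(np.linalg.norm(phantom.spacing))
    for e in array:
        shaft = _segment_mask(phantom, e.entry, e.tip, max(e.radius, r_floor))
        for code in (VESSEL, BONE):
            if np.any(shaft & phantom.mask(code)):
                violations.append(CollisionViolation(electrode_id=e.id, tissue_code=code))
    return violations
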