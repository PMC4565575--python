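"""Trajectory export for image-guided navigation and placement-error metrics.

A navigation system registers preoperative images to the patient and guides
each needle along its planned trajectory.  The planning side of that
workflow is simple and fully reproducible: the tip and entry point of every
needle is marked directly on the image volume by setting the corresponding
voxel intensity to a sentinel value (3000 by default, well above soft-tissue
CT numbers), and the planned insertion length is reported per electrode
because insertion depth is not tracked by the navigation system and is
measured with a ruler instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ectplan.phantom import VoxelPhantom
from ectplan.electrodes import ElectrodeArray, NeedleElectrode

DEFAULT_MARKER_VALUE = 3000


@dataclass(frozen=True)
class Marker:
    electrode_id: int
    role: str  # "entry" or "tip"
    index: tuple[int, int, int]
    world_mm: tuple[float, float, float]


@dataclass
class TrajectoryExport:
    """Marked volume plus the marker list and planned insertion lengths."""

    volume: np.ndarray
    markers: list[Marker]
    marker_value: int = DEFAULT_MARKER_VALUE
    insertion_length_mm: dict[int, float] = field(default_factory=dict)


def mark_trajectories(
    phantom: VoxelPhantom,
    array: ElectrodeArray,
    marker_value: int = DEFAULT_MARKER_VALUE,
    volume: np.ndarray | None = None,
) -> TrajectoryExport:
    """Mark needle entry and tip voxels on a copy of the image volume.

    ``volume`` defaults to the phantom's label volume; any array with the
    phantom's grid shape can be marked (e.g. a CT intensity volume).  The
    marker voxel is the voxel *containing* the world point
    (``floor((world - origin) / spacing)``); single voxels are set, no
    marker spheres.  Two markers landing in the same voxel raise a warning
    and both are listed.
    """
    base = phantom.labels if volume is None else volume
    if base.shape != phantom.shape:
        raise ValueError("volume shape does not match the phantom grid")
    out = np.array(base, copy=True)
    markers: list[Marker] = []
    lengths: dict[int, float] = {}
    seen: dict[tuple[int, int, int], Marker] = {}
    for e in array:
        for role, point in (("entry", e.entry), ("tip", e.tip)):
            if not phantom.contains_point(point):
                raise ValueError(f"electrode {e.id}: {role} point lies outside the grid")
            idx = phantom.world_to_index(point)
            marker = Marker(electrode_id=e.id, role=role, index=idx,
                            world_mm=tuple(float(v) for v in point))
            if idx in seen:
                other = seen[idx]
                warnings.warn(
                    f"markers collide in voxel {idx}: electrode {other.electrode_id} "
                    f"{other.role} and electrode {e.id} {role}"
                )
            seen[idx] = marker
            markers.append(marker)
            out[idx] = marker_value
        lengths[e.id] = e.length
    return TrajectoryExport(volume=out, markers=markers, marker_value=marker_value,
                            insertion_length_mm=lengths)


def placement_error(
    planned: NeedleElectrode, achieved_entry, pixel_size: float
) -> tuple[float, float]:
    """Distance from an achieved entry point to the planned trajectory line.

    Returns ``(error_mm, error_pixels)`` where the error is the 3-D
    point-to-line distance from ``achieved_entry`` to the infinite line
    through the planned entry and tip, and the pixel error divides by the
    (isotropic in-plane) pixel size.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    entry = np.asarray(planned.entry, dtype=float)
    tip = np.asarray(planned.tip, dtype=float)
    axis = tip - entry
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate trajectory: entry equals tip")
    axis /= norm
    rel = np.asarray(achieved_entry, dtype=float) - entry
    perp = rel - np.dot(rel, axis) * axis
    error_mm = float(np.linalg.norm(perp))
    return error_mm, error_mm / pixel_size
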