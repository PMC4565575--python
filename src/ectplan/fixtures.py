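"""Deterministic generators for the study geometries used in tests and demos.

Two families:

* ``clinical_case_fixture`` — a phantom with the reference clinical-case geometry: a
  near-spherical lymph-node metastasis of 20.3 mm (case 1) or 20.6 mm
  (case 2) diameter in soft tissue, a 4 mm-radius vessel 8 mm from the tumor
  surface, a bone slab at the far grid face, the 5-needle star array
  centered on the tumor and the standard 1000/1200 V pulse schedule.  The
  vessel and bone placement is synthetic (the patient anatomy is not
  available); it is chosen so that a lateral approach would collide with the
  vessel, exercising the collision check.
* ``two_needle_fixture`` — a homogeneous block with two parallel needles,
  the geometry for which the two-cylinder closed-form conductance is an
  analytic oracle.

Everything is reproducible bit-exactly from the parameters; a manifest with
a parameter hash is provided for provenance.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from ectplan.phantom import (
    PhantomConfig,
    Sphere,
    Cylinder,
    Slab,
    VoxelPhantom,
    make_phantom,
)
from ectplan.electrodes import (
    ElectrodeArray,
    NeedleElectrode,
    PulseSchedule,
    star_array,
    star_schedule,
)

#: Printed lesion diameters (mm) for the two metastases.
LESION_DIAMETERS = {1: 20.3, 2: 20.6}


def fixture_manifest(name: str, params: dict) -> dict:
    """Manifest with a stable hash of the generating parameters."""
    blob = json.dumps(params, sort_keys=True, default=float).encode()
    return {"fixture": name, "params": params, "sha256": hashlib.sha256(blob).hexdigest()}


def clinical_case_fixture(
    metastasis: int = 1,
    spacing: float = 0.57,
    pad_factor: float = 1.5,
    electrode_radius: float = 0.6,
) -> tuple[VoxelPhantom, ElectrodeArray, PulseSchedule]:
    """Phantom + star array + schedule for one of the two treated lesions.

    ``spacing`` defaults to the CT pixel size of 0.57 mm; coarser spacings
    (e.g. 1 mm) give the same geometry on a faster grid.  The grid is padded
    so the outer boundary is at least ``pad_factor`` array diameters from
    any electrode, per the insulated-boundary solve policy.
    """
    if metastasis not in LESION_DIAMETERS:
        raise ValueError("metastasis must be 1 or 2")
    diameter = LESION_DIAMETERS[metastasis]
    center_to_outer = 10.0
    active_tip = 30.0
    array_diameter = 2 * center_to_outer
    pad = pad_factor * array_diameter  # distance from electrodes to the boundary

    # lateral half-extent: electrode ring + padding; axial: active tip + padding
    half_xy = center_to_outer + pad
    half_z = active_tip / 2 + pad
    extent = np.array([2 * half_xy, 2 * half_xy, 2 * half_z])
    shape = tuple(int(np.ceil(e / spacing)) for e in extent)
    origin = -np.asarray(shape) * spacing / 2.0  # grid centered on the tumor
    center = (0.0, 0.0, 0.0)

    vessel_radius = 4.0
    vessel_offset = diameter / 2 + 8.0 + vessel_radius  # 8 mm from tumor surface
    bone_thickness = 6.0
    zmax = origin[2] + shape[2] * spacing

    config = PhantomConfig(
        shape=shape,
        spacing=spacing,
        origin=tuple(origin),
        tumors=[Sphere(center=center, diameter=diameter)],
        vessel=Cylinder(point=(vessel_offset, 0.0, 0.0), direction=(0.0, 1.0, 0.0),
                        radius=vessel_radius),
        bone=Slab(normal=(0.0, 0.0, 1.0), offset=zmax - bone_thickness / 2.0,
                  thickness=bone_thickness),
    )
    phantom = make_phantom(config)
    array = star_array(
        center=center, insertion_direction=(0.0, 0.0, 1.0),
        center_to_outer=center_to_outer, active_tip=active_tip,
        radius=electrode_radius,
        needle_length=active_tip / 2 - origin[2] - spacing,  # entry just inside the grid
    )
    schedule = star_schedule(array)
    return phantom, array, schedule


def two_needle_fixture(
    spacing: float = 0.5,
    separation: float = 10.0,
    radius: float = 0.5,
    active_tip: float = 30.0,
    pad_factor: float = 1.5,
) -> tuple[VoxelPhantom, ElectrodeArray]:
    """Homogeneous block with two parallel needles for the analytic oracle.

    The grid origin is chosen so the needle axes pass exactly through
    voxel-center columns, making the rasterized cross-sections identical for
    the two electrodes and symmetric about the midplane.
    """
    if spacing > 1.0:
        raise ValueError("two-needle fixture requires spacing <= 1 mm")
    pad = pad_factor * separation
    half = separation / 2.0

    def axis_coords(lo: float, hi: float) -> tuple[float, int]:
        # origin = -(n*spacing)/2 shifted so that 0 is a voxel center
        n = int(np.ceil((hi - lo) / spacing))
        if n % 2 == 0:
            n += 1  # odd count puts a voxel center at 0
        return -n * spacing / 2.0, n

    ox, nx = axis_coords(-(half + pad), half + pad)
    oy, ny = axis_coords(-(radius + pad), radius + pad)
    oz, nz = axis_coords(-(active_tip / 2 + pad), active_tip / 2 + pad)
    # shift x origin so +/- half are voxel centers: centers are ox+(i+.5)s,
    # with ox = -(nx*s)/2 and nx odd, centers include 0; half must be a
    # multiple of s for +/-half to be centers
    if abs(half / spacing - round(half / spacing)) > 1e-9:
        raise ValueError("separation/2 must be a multiple of the spacing")

    phantom = VoxelPhantom(
        labels=np.zeros((nx, ny, nz), dtype=np.int16),
        spacing=(spacing, spacing, spacing),
        origin=(ox, oy, oz),
    )
    z_tip = active_tip / 2.0
    z_entry = oz + spacing  # just inside the grid
    electrodes = [
        NeedleElectrode(id=1, entry=(-half, 0.0, z_entry), tip=(-half, 0.0, z_tip),
                        active_tip_length=active_tip, radius=radius),
        NeedleElectrode(id=2, entry=(half, 0.0, z_entry), tip=(half, 0.0, z_tip),
                        active_tip_length=active_tip, radius=radius),
    ]
    array = ElectrodeArray(electrodes=electrodes, insertion_direction=(0.0, 0.0, 1.0))
    return phantom, array


def toy_slab_fixture(spacing: float = 2.0) -> tuple[VoxelPhantom, ElectrodeArray, PulseSchedule]:
    """Small two-electrode fixture with a central tumor for fast optimizer tests."""
    from ectplan.electrodes import ScheduleEntry

    separation, radius, active_tip, pad = 12.0, 0.8, 16.0, 12.0
    half = separation / 2.0

    def axis_n(ext: float) -> int:
        n = int(np.ceil(2 * ext / spacing))
        return n + 1 if n % 2 == 0 else n

    nx, ny, nz = axis_n(half + pad), axis_n(radius + pad), axis_n(active_tip / 2 + pad)
    origin = (-nx * spacing / 2, -ny * spacing / 2, -nz * spacing / 2)
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    phantom = VoxelPhantom(labels=labels, spacing=(spacing,) * 3, origin=origin)
    # small tumor sphere between the needles
    xx, yy, zz = np.meshgrid(*phantom.voxel_centers(), indexing="ij")
    labels[xx**2 + yy**2 + zz**2 <= 4.0**2] = 1

    z_tip, z_entry = active_tip / 2.0, origin[2] + spacing
    electrodes = [
        NeedleElectrode(id=1, entry=(-half, 0.0, z_entry), tip=(-half, 0.0, z_tip),
                        active_tip_length=active_tip, radius=radius),
        NeedleElectrode(id=2, entry=(half, 0.0, z_entry), tip=(half, 0.0, z_tip),
                        active_tip_length=active_tip, radius=radius),
    ]
    array = ElectrodeArray(electrodes=electrodes, insertion_direction=(0.0, 0.0, 1.0))
    schedule = PulseSchedule(entries=[ScheduleEntry(pair=(1, 2), voltage=1000.0)])
    return phantom, array, schedule
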