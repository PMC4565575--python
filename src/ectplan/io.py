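"""Volume I/O: NIfTI (via nibabel) and NRRD (via SimpleITK).

Label volumes are written as integers, field/potential grids as floating
point.  The grid geometry round-trips exactly: spacing on the diagonal of
the affine and the corner origin encoded so that the world position of a
voxel center is ``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from ectplan.phantom import VoxelPhantom


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def save_volume(path, data: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a 3-D array with grid geometry to .nii/.nii.gz or .nrrd."""
    path = Path(path)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)
    center0 = origin + 0.5 * spacing  # world position of voxel (0,0,0) center
    if _is_nifti(path):
        affine = np.diag([*spacing, 1.0])
        affine[:3, 3] = center0
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    elif path.suffix == ".nrrd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in center0))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a volume; returns (data, spacing, origin) in the package convention."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        center0 = affine[:3, 3]
    elif path.suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = np.asarray(img.GetSpacing())
        center0 = np.asarray(img.GetOrigin())
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    origin = np.asarray(center0, dtype=float) - 0.5 * spacing
    return data, spacing, origin


def save_phantom(path, phantom: VoxelPhantom) -> None:
    save_volume(path, phantom.labels.astype(np.int16), phantom.spacing, phantom.origin)


def load_phantom(path) -> VoxelPhantom:
    data, spacing, origin = load_volume(path)
    return VoxelPhantom(labels=np.asarray(data).astype(np.int16), spacing=spacing,
                        origin=origin)
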