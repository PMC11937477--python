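"""Minimal 3D image container with world geometry.

Volumes are stored as float arrays in (i, j, k) index order with a 4x4
world affine mapping voxel indices to millimetres, mirroring the NIfTI
convention used by nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing, world affine and modality tag.

    Parameters
    ----------
    data:
        3D array of intensities.
    affine:
        4x4 voxel-to-world (mm) affine.
    modality:
        Free-text modality tag, e.g. ``"CT-like"``, ``"UTE-like"``,
        ``"T2w-like"``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size along each axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy_with(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return ImageVolume(data, self.affine.copy(), modality if modality is not None else self.modality)

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        if self.modality:
            img.header["descrip"] = self.modality.encode()[:79]
        nib.save(img, str(path))


def load_volume(path, modality: str = "") -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume`."""
    img = nib.load(str(path))
    if not modality:
        modality = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    return ImageVolume(np.asanyarray(img.dataobj, dtype=np.float32), img.affine, modality)
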