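"""Volume containers and I/O.

Arrays are indexed ``[z, y, x]`` with the z axis vertical (loading axis).
Physical coordinates are ``(x, y, z)`` in millimetres with isotropic voxel
spacing; densities are calibrated bone mineral densities in mgHA/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "DensityVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "write_labels",
]


@dataclass
class DensityVolume:
    """3D calibrated bone-mineral-density grid (mgHA/cm^3)."""

    data: np.ndarray  # (nz, ny, nx), float
    spacing: float  # mm per voxel, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) mm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("DensityVolume requires a 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def height_mm(self) -> float:
        """Physical extent along the vertical (z) axis."""
        return self.data.shape[0] * self.spacing

    def voxel_volume_cm3(self) -> float:
        return (self.spacing / 10.0) ** 3

    def copy_with(self, data: np.ndarray) -> "DensityVolume":
        return DensityVolume(data, self.spacing, self.origin, dict(self.metadata))


@dataclass
class LabelVolume:
    """Three-phase segmentation: 0 no bone, 1 trabecular bone, 2 cortical bone."""

    labels: np.ndarray  # (nz, ny, nx), uint8 in {0, 1, 2}
    periosteal_mask: np.ndarray  # bool, section interior incl. cortex
    cortical_mask: np.ndarray  # bool
    trabecular_mask: np.ndarray  # bool
    spacing: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        for name in ("periosteal_mask", "cortical_mask", "trabecular_mask"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not set(np.unique(self.labels)) <= {0, 1, 2}:
            raise ValueError("labels must be within {0, 1, 2}")
        if np.any(self.cortical_mask & self.trabecular_mask):
            raise ValueError("cortical and trabecular masks must be disjoint")
        if np.any((self.labels == 1) & ~self.trabecular_mask):
            raise ValueError("label 1 must lie inside the trabecular mask")
        if np.any((self.labels == 2) & ~self.cortical_mask):
            raise ValueError("label 2 must lie inside the cortical mask")

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels > 0


def _to_sitk(data: np.ndarray, spacing: float, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing((spacing,) * 3)
    img.SetOrigin(tuple(float(v) for v in origin))
    return img


def write_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write a density volume as MHA/NIfTI (by file extension)."""
    sitk.WriteImage(_to_sitk(vol.data.astype(np.float32), vol.spacing, vol.origin), str(path))


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    sitk.WriteImage(
        _to_sitk(labels.labels.astype(np.uint8), labels.spacing, (0.0, 0.0, 0.0)), str(path)
    )


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MHA/NIfTI volume; requires isotropic spacing."""
    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError("only isotropic volumes are supported")
    return DensityVolume(
        sitk.GetArrayFromImage(img).astype(float), float(spacing[0]), tuple(img.GetOrigin())
    )
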