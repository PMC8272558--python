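"""Shared containers, constants, and validation primitives.

All times are seconds internally; interfaces that mirror scanner protocol
cards accept milliseconds and convert once at parse time.  CBF is carried in
mL/100 g/min at every public surface and converted to s^-1 (f = CBF/6000)
inside the kinetic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA_H = 2.0 * np.pi * 42.577478518e6

#: Conversion between CBF in mL/100 g/min and perfusion rate f in s^-1
#: (unit tissue density assumed): f = CBF / CBF_UNIT_SCALE.
CBF_UNIT_SCALE = 6000.0


class ValidationError(ValueError):
    """Raised when a physical or geometric precondition is violated."""


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass
class ImageVolume:
    """A 3-D scalar map with its brain mask and voxel geometry.

    Carrier for ASL difference images, M0 calibration images, and fitted
    CBF/ATT/CVR maps.  Masked-out voxels are excluded from all statistics.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_mask: np.ndarray | None = None
    units: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        require(self.values.ndim == 3, "ImageVolume expects a 3-D array")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            require(
                self.brain_mask.shape == self.values.shape,
                "mask and values must share dimensions",
            )
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def masked(self) -> np.ndarray:
        """Values inside the brain mask as a flat array."""
        return self.values[self.brain_mask]

    def like(self, values: np.ndarray, units: str | None = None) -> "ImageVolume":
        """A new volume on the same grid/mask carrying ``values``."""
        return ImageVolume(
            values=np.asarray(values, dtype=float),
            voxel_size=self.voxel_size,
            brain_mask=self.brain_mask.copy(),
            units=self.units if units is None else units,
            affine=None if self.affine is None else self.affine.copy(),
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(
        cls, path: str | Path, brain_mask: np.ndarray | None = None, units: str = ""
    ) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            values=data,
            voxel_size=zooms,
            brain_mask=brain_mask,
            units=units,
            affine=np.asarray(img.affine),
        )


def save_nifti_4d(
    frames: np.ndarray, voxel_size: tuple[float, float, float], path: str | Path
) -> Path:
    """Write a (x, y, z, t) array as a 4-D NIfTI volume."""
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(frames, dtype=np.float32), affine)
    nib.save(img, str(path))
    return Path(path)


def load_nifti_4d(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms
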