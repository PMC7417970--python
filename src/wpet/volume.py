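"""3-D scalar volumes on a shared analysis grid.

``Volume`` is the unit of all image math in this package: a dense float (or
integer label) array together with its isotropic voxel size in millimetres
and an identifier of the analysis space it lives in.  Undefined voxels (for
example grey-matter voxels excluded by partial-volume correction) are carried
as NaN, never silently zero-filled, so downstream masks stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: full width at half maximum of a gaussian = FWHM_TO_SIGMA**-1 * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3-D scalar grid with voxel size (mm) and a shared-space identifier."""

    data: np.ndarray
    voxel_mm: float = 3.0
    space: str = "phantom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on this grid holding ``data``."""
        return Volume(np.asarray(data), voxel_mm=self.voxel_mm, space=self.space)

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and self.voxel_mm == other.voxel_mm \
            and self.space == other.space

    # -- I/O ---------------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0]).astype(float)
        # centre the grid at world origin so reported peak coordinates are mm
        aff[:3, 3] = -self.voxel_mm * (np.array(self.shape) - 1) / 2.0
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, space: str = "phantom") -> "Volume":
        img = nib.load(str(path))
        vox = float(img.header.get_zooms()[0])
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), voxel_mm=vox,
                   space=space)


def check_same_grid(*vols: Volume) -> None:
    first = vols[0]
    for v in vols[1:]:
        if not first.same_grid(v):
            raise ValueError(
                f"volumes are not on a shared grid: {first.shape}@{first.voxel_mm}mm"
                f"/{first.space} vs {v.shape}@{v.voxel_mm}mm/{v.space}")


def gaussian_blur(vol: Volume, fwhm_mm: float) -> Volume:
    """Isotropic gaussian blur; ``fwhm_mm = 0`` is the identity.

    sigma (mm) = fwhm / (2 * sqrt(2 * ln 2)); reflect boundary handling.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.like(vol.data.astype(float, copy=True))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_mm
    return vol.like(ndimage.gaussian_filter(vol.data.astype(float), sigma_vox,
                                            mode="reflect"))
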