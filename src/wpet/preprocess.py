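"""Analysis masks, intensity normalisation and smoothing.

The group analyses run inside a grey-matter analysis mask (mean GM
probability strictly above an absolute threshold, default 0.1, with the
occipital lobe excluded).  Uptake images are proportionally normalised to
the mean activity in that mask — so all downstream statistics are invariant
to global scanner scaling — or scaled to a cerebellar reference (SUVR).
Smoothing is gaussian; inside a mask it is normalised (mask-weighted)
convolution, so constants are preserved and values never leak across the
mask boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import Atlas
from .volume import FWHM_TO_SIGMA, Volume, check_same_grid


@dataclass
class AnalysisMask:
    """Boolean analysis mask with the provenance of its construction."""

    mask: Volume
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask.data = self.mask.data.astype(bool)
        if not self.mask.data.any():
            raise ValueError("analysis mask is empty")

    @property
    def array(self) -> np.ndarray:
        return self.mask.data

    @property
    def n_voxels(self) -> int:
        return int(self.mask.data.sum())


def make_analysis_mask(mean_gm_prob: Volume, atlas: Atlas,
                       threshold: float = 0.1,
                       excluded_labels: set[str] = frozenset({"occipital"}),
                       ) -> AnalysisMask:
    """GM analysis mask: mean GM probability strictly > threshold, minus the
    excluded atlas regions (a voxel at exactly the threshold is excluded)."""
    check_same_grid(mean_gm_prob, atlas.volume)
    m = mean_gm_prob.data > threshold
    excluded = sorted(excluded_labels)
    if excluded:
        m &= ~atlas.mask(*excluded)
    if not m.any():
        raise ValueError(
            f"analysis mask is empty at threshold {threshold} "
            f"(excluded: {excluded})")
    return AnalysisMask(
        mask=mean_gm_prob.like(m),
        provenance={"threshold": threshold, "excluded_labels": excluded})


def proportional_normalize(vol: Volume, mask: AnalysisMask) -> Volume:
    """Divide by the mean activity within the mask (undefined voxels
    ignored); the in-mask mean of the output is exactly 1."""
    check_same_grid(vol, mask.mask)
    vals = vol.data[mask.array]
    mean = float(np.nanmean(vals))
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"mask mean must be positive, got {mean}")
    return vol.like(vol.data / mean)


def suvr(vol: Volume, atlas: Atlas,
         reference_labels: set[str] = frozenset({"cerebellum"})) -> Volume:
    """Standardised uptake value ratio: divide by the mean uptake over the
    reference regions (cerebellum by default)."""
    check_same_grid(vol, atlas.volume)
    ref = atlas.mask(*sorted(reference_labels))
    if not ref.any():
        raise ValueError(f"reference region {sorted(reference_labels)} is "
                         "empty on this grid")
    mean = float(np.nanmean(vol.data[ref]))
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"reference mean must be positive, got {mean}")
    return vol.like(vol.data / mean)


def smooth(vol: Volume, fwhm_mm: float = 8.0,
           mask: AnalysisMask | None = None) -> Volume:
    """Isotropic gaussian smoothing; fwhm 0 is the identity.

    With a mask, normalised convolution is used: the image (zero-filled at
    undefined or out-of-mask voxels) and the indicator of valid voxels are
    blurred separately and divided, so constants are preserved inside the
    mask and nothing propagates in from outside it.  Out-of-mask voxels are
    undefined in the output.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.like(vol.data.astype(float, copy=True))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_mm
    if mask is None:
        data = vol.data.astype(float)
        if np.isnan(data).any():
            valid = np.isfinite(data)
            num = ndimage.gaussian_filter(np.where(valid, data, 0.0),
                                          sigma_vox, mode="reflect")
            den = ndimage.gaussian_filter(valid.astype(float), sigma_vox,
                                          mode="reflect")
            out = np.full(vol.shape, np.nan)
            out[valid] = num[valid] / den[valid]
            return vol.like(out)
        return vol.like(ndimage.gaussian_filter(data, sigma_vox,
                                                mode="reflect"))
    check_same_grid(vol, mask.mask)
    valid = mask.array & np.isfinite(vol.data)
    num = ndimage.gaussian_filter(np.where(valid, vol.data, 0.0), sigma_vox,
                                  mode="reflect")
    den = ndimage.gaussian_filter(valid.astype(float), sigma_vox,
                                  mode="reflect")
    out = np.full(vol.shape, np.nan)
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return vol.like(out)
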