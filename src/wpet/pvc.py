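"""Partial-volume correction of PET uptake images.

Scanner blur mixes activity across tissue compartments.  Two corrections are
provided:

* :func:`muller_gartner` — voxelwise correction of grey-matter voxels for WM
  spill-in and GM spill-out, with the WM activity estimated by an
  origin-constrained regression over high-probability WM voxels;
* :func:`region_based_correct` — geometric-transfer-matrix (GTM) correction
  for region-of-interest analysis: the matrix of blurred region-indicator
  overlaps is solved for the true regional means.

The point-spread function is modelled as an isotropic gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import Atlas
from .volume import Volume, check_same_grid, gaussian_blur


@dataclass
class PSFModel:
    """Isotropic gaussian point-spread function; fwhm 0 is the identity."""

    fwhm_mm: float = 5.5

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")

    def blur(self, vol: Volume) -> Volume:
        return gaussian_blur(vol, self.fwhm_mm)


def estimate_wm_activity(pet: Volume, wm_prob: Volume, psf: PSFModel,
                         wm_threshold: float = 0.95) -> float:
    """White-matter tracer activity via origin-constrained least squares.

    Regresses the observed PET values on the PSF-blurred WM probability over
    voxels whose (unblurred) WM probability exceeds ``wm_threshold``; the
    slope is the homogeneous WM activity.
    """
    check_same_grid(pet, wm_prob)
    sel = wm_prob.data > wm_threshold
    if not sel.any():
        raise ValueError(
            f"no voxel has WM probability > {wm_threshold}; cannot estimate "
            "WM activity")
    bw = psf.blur(wm_prob).data[sel]
    y = pet.data[sel]
    denom = float(np.dot(bw, bw))
    if denom == 0:
        raise ValueError("blurred WM probability vanishes on the WM voxel set")
    return float(np.dot(bw, y) / denom)


def muller_gartner(pet: Volume, gm_prob: Volume, wm_prob: Volume,
                   wm_activity: float, psf: PSFModel,
                   gm_threshold: float = 0.3,
                   eps: float = 1e-6) -> Volume:
    """Müller-Gärtner voxelwise PVC.

    For voxels with GM probability >= ``gm_threshold``::

        corrected = (pet - wm_activity * blur(wm_prob)) / blur(gm_prob)

    All other voxels are undefined (NaN), never zero-filled.  Included voxels
    whose blurred GM probability is <= ``eps`` are also marked undefined and
    counted in the returned volume's ``meta`` report.
    """
    if not 0 < gm_threshold < 1:
        raise ValueError("gm_threshold must be in (0, 1)")
    check_same_grid(pet, gm_prob, wm_prob)
    bgm = psf.blur(gm_prob).data
    bwm = psf.blur(wm_prob).data
    include = gm_prob.data >= gm_threshold
    degenerate = include & (bgm <= eps)
    valid = include & ~degenerate
    out = np.full(pet.shape, np.nan)
    out[valid] = (pet.data[valid] - wm_activity * bwm[valid]) / bgm[valid]
    res = pet.like(out)
    res.meta.update({
        "wm_activity": wm_activity,
        "n_included": int(include.sum()),
        "n_undefined_low_gm": int(degenerate.sum()),
        "gm_threshold": gm_threshold,
        "fwhm_mm": psf.fwhm_mm,
    })
    return res


def pvc_report(corrected: Volume) -> pd.DataFrame:
    """One-row TSV-ready report of a Müller-Gärtner correction."""
    m = corrected.meta
    return pd.DataFrame([{
        "wm_activity": m.get("wm_activity", np.nan),
        "n_included": m.get("n_included", 0),
        "n_undefined_low_gm": m.get("n_undefined_low_gm", 0),
        "gm_threshold": m.get("gm_threshold", np.nan),
        "fwhm_mm": m.get("fwhm_mm", np.nan),
    }])


def region_based_correct(pet: Volume, atlas: Atlas, gm_prob: Volume,
                         wm_prob: Volume, psf: PSFModel,
                         cond_limit: float = 1e8) -> pd.DataFrame:
    """Geometric-transfer-matrix regional PVC.

    Regions are the atlas labels plus a white-matter compartment (WM
    probability > 0.5 outside any label).  Entry (i, j) of the transfer
    matrix is the mean over region i of the blurred indicator of region j;
    solving ``W t = o`` for the observed regional means ``o`` gives the true
    means ``t``.  With fwhm 0 the matrix is the identity and corrected means
    equal raw means.
    """
    check_same_grid(pet, atlas.volume, gm_prob, wm_prob)
    label_of = {v: k for k, v in atlas.names.items()}
    regions: list[tuple[str, np.ndarray]] = []
    for lab in atlas.labels:
        regions.append((label_of.get(lab, f"label_{lab}"),
                        atlas.volume.data == lab))
    wm_extra = (wm_prob.data > 0.5) & (atlas.volume.data == 0)
    if wm_extra.any():
        regions.append(("white_matter", wm_extra))

    n = len(regions)
    if n == 0:
        raise ValueError("atlas contains no labels")
    blurred = [psf.blur(Volume(m.astype(float), pet.voxel_mm,
                               space=pet.space)).data
               for _, m in regions]
    W = np.empty((n, n))
    o = np.empty(n)
    sizes = np.empty(n, dtype=int)
    for i, (_, mi) in enumerate(regions):
        sizes[i] = mi.sum()
        o[i] = pet.data[mi].mean()
        for j in range(n):
            W[i, j] = blurred[j][mi].mean()
    cond = float(np.linalg.cond(W))
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"geometric transfer matrix is ill-conditioned "
            f"(condition number {cond:.3g} > {cond_limit:.3g})")
    t = np.linalg.solve(W, o)
    return pd.DataFrame({
        "region": [name for name, _ in regions],
        "size_voxels": sizes,
        "raw_mean": o,
        "corrected_mean": t,
    })
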