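"""Control-based normative modelling: W-score maps and their summaries.

A W-score is a covariate-adjusted z-score.  Per voxel, intensity is
regressed on age in the control group; a subject's W at that voxel is

    W = (raw - (intercept + slope * age)) / SD of the control residuals,

with the residual SD computed on n - 2 degrees of freedom.  Maps are
binarised at |W| >= 1.96 (boundary included; 1.96 bounds the central 95%
mass of a standard normal) separately for hypometabolism (W <= -1.96) and
hypermetabolism (W >= +1.96), then summed across subjects into frequency
maps giving the fraction of the cohort surpassing the threshold per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import AnalysisMask
from .volume import Volume, check_same_grid


@dataclass
class NormativeModel:
    """Per-voxel intercept, age slope and residual SD from controls."""

    intercept: Volume
    slope: Volume
    resid_sd: Volume
    n_controls: int
    mask: AnalysisMask

    def predict(self, age: float) -> Volume:
        return self.intercept.like(self.intercept.data
                                   + self.slope.data * age)


@dataclass
class WMap:
    """One subject's W-score map; defined only inside the analysis mask."""

    w: Volume
    subject_id: str
    threshold: float = 1.96


def fit_normative(control_images: list[Volume], control_ages,
                  mask: AnalysisMask,
                  on_zero_sd: str = "raise") -> NormativeModel:
    """Per-voxel OLS of intensity on age over the control group.

    Residual SD uses n - 2 degrees of freedom.  A voxel with zero residual
    SD makes W undefined; by default this is an error at fit time
    (``on_zero_sd="raise"``), or such voxels can be marked undefined
    (``"nan"``), e.g. to inspect coefficient recovery on noise-free data.
    """
    ages = np.asarray(control_ages, dtype=float)
    n = len(control_images)
    if n < 3:
        raise ValueError("need at least 3 controls to fit a normative model")
    if len(ages) != n:
        raise ValueError("one age per control image is required")
    if np.ptp(ages) == 0:
        raise ValueError("control ages are constant; age slope is not "
                         "identifiable")
    if on_zero_sd not in ("raise", "nan"):
        raise ValueError("on_zero_sd must be 'raise' or 'nan'")
    check_same_grid(mask.mask, *control_images)

    sel = mask.array
    Y = np.stack([img.data[sel] for img in control_images])  # n x V
    X = np.column_stack([np.ones(n), ages])
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    sd = np.sqrt(np.einsum("ij,ij->j", resid, resid) / (n - 2))
    sd[np.isnan(Y).any(axis=0)] = np.nan

    scale = float(np.nanmax(np.abs(Y))) if np.isfinite(Y).any() else 1.0
    zero = np.isfinite(sd) & (sd <= 1e-12 * max(scale, 1.0))
    if zero.any():
        if on_zero_sd == "raise":
            raise ValueError(
                f"{int(zero.sum())} in-mask voxels have zero residual SD; "
                "W-scores would be undefined there")
        sd[zero] = np.nan

    def grid(vals):
        out = np.full(mask.mask.shape, np.nan)
        out[sel] = vals
        return mask.mask.like(out)

    return NormativeModel(intercept=grid(beta[0]), slope=grid(beta[1]),
                          resid_sd=grid(sd), n_controls=n, mask=mask)


def wmap(subject_image: Volume, age: float, model: NormativeModel,
         subject_id: str = "") -> WMap:
    """W = (raw - predicted-for-age) / control residual SD, inside the mask."""
    if not subject_image.same_grid(model.mask.mask):
        raise ValueError("subject image is not on the model grid")
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (subject_image.data - model.predict(age).data) / model.resid_sd.data
    w[~model.mask.array] = np.nan
    return WMap(w=subject_image.like(w), subject_id=subject_id)


def binarize_w(w: WMap, direction: str, threshold: float = 1.96) -> Volume:
    """Binary abnormality map: ``hypo`` flags W <= -threshold, ``hyper``
    flags W >= +threshold; the boundary value is included."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    data = w.w.data
    with np.errstate(invalid="ignore"):
        if direction == "hypo":
            out = data <= -threshold
        elif direction == "hyper":
            out = data >= threshold
        else:
            raise ValueError("direction must be 'hypo' or 'hyper'")
    return w.w.like(np.where(np.isnan(data), False, out))


def frequency_map(binary_maps: list[Volume]) -> tuple[Volume, Volume, dict]:
    """Voxelwise count and fraction of subjects flagged, plus the maximal
    fraction and its location."""
    if not binary_maps:
        raise ValueError("at least one binary map is required")
    check_same_grid(*binary_maps)
    counts = np.sum([m.data.astype(float) for m in binary_maps], axis=0)
    frac = counts / len(binary_maps)
    peak = np.unravel_index(int(np.argmax(frac)), frac.shape)
    summary = {"max_fraction": float(frac[peak]),
               "max_count": int(counts[peak]),
               "n_subjects": len(binary_maps),
               "peak_ijk": tuple(int(i) for i in peak)}
    return binary_maps[0].like(counts), binary_maps[0].like(frac), summary


def mean_wmap(wmaps: list[WMap]) -> Volume:
    """Voxelwise arithmetic mean of W-score maps."""
    if not wmaps:
        raise ValueError("at least one W-map is required")
    check_same_grid(*[w.w for w in wmaps])
    return wmaps[0].w.like(np.mean([w.w.data for w in wmaps], axis=0))


def central_mass(z: float) -> float:
    """Standard-normal probability mass on [-z, +z] (0.95 at z = 1.96)."""
    if z < 0:
        raise ValueError("z must be >= 0")
    return float(stats.norm.cdf(z) - stats.norm.cdf(-z))


def region_flag_counts(wmaps: list[WMap], atlas, mask: AnalysisMask,
                       direction: str = "hypo",
                       threshold: float = 1.96):
    """Per-subject suprathreshold voxel counts by atlas region.

    A subject "shows abnormality" in a region if any in-mask voxel of that
    region surpasses the threshold (minimum count configurable downstream).
    """
    import pandas as pd

    rows = []
    for w in wmaps:
        flagged = binarize_w(w, direction, threshold).data & mask.array
        row = {"subject_id": w.subject_id}
        for name in sorted(atlas.names):
            region = atlas.mask(name) & mask.array
            row[name] = int(np.sum(flagged & region))
        rows.append(row)
    return pd.DataFrame(rows)
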