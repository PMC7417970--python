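"""Mass-univariate group inference on volumes.

Per-voxel ordinary least squares with nuisance covariates (age, optionally
total intracranial volume), one-sided t contrasts, height thresholding,
connected-component cluster formation with an extent filter, and
cluster-level familywise-error control by permutation.

Cluster-level FWE is controlled with a max-cluster-size permutation test
under Freedman-Lane residualisation: the data are residualised against the
nuisance columns, the residual rows are permuted, the full model is refit,
and the maximal suprathreshold cluster size per permutation forms the null
distribution.  The corrected p of an observed cluster is the proportion of
permutations whose maximal cluster is at least as large (with add-one
smoothing in numerator and denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import AnalysisMask
from .volume import Volume, check_same_grid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


# ---------------------------------------------------------------------------
# Design


@dataclass
class DesignMatrix:
    """Subjects x regressors design with a single contrast vector."""

    X: np.ndarray
    contrast: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal the column count")
        if not np.any(self.contrast):
            raise ValueError("contrast of all zeros is not a hypothesis")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if not self.names:
            self.names = [f"x{i}" for i in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


def make_group_design(groups, ages=None, tiv=None,
                      direction: str = "hypo") -> DesignMatrix:
    """Intercept + carrier indicator (+ centred age, + centred TIV).

    ``direction="hypo"`` tests carrier < control (t positive where carriers
    are lower); ``"hyper"`` tests carrier > control.
    """
    groups = np.asarray(groups)
    g = (groups == "carrier").astype(float)
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("both groups must be present in the design")
    cols = [np.ones(len(g)), g]
    names = ["intercept", "carrier"]
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        cols.append(ages - ages.mean())
        names.append("age")
    if tiv is not None:
        tiv = np.asarray(tiv, dtype=float)
        cols.append(tiv - tiv.mean())
        names.append("tiv")
    c = np.zeros(len(cols))
    if direction == "hypo":
        c[1] = -1.0
    elif direction == "hyper":
        c[1] = +1.0
    else:
        raise ValueError("direction must be 'hypo' or 'hyper'")
    return DesignMatrix(np.column_stack(cols), c, names)


# ---------------------------------------------------------------------------
# Voxel data plumbing


def stack_images(images: list[Volume], mask: AnalysisMask) -> np.ndarray:
    """Subjects x in-mask-voxels data matrix (NaN where undefined)."""
    check_same_grid(mask.mask, *images)
    sel = mask.array
    return np.stack([img.data[sel] for img in images])


def _contrast_t(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised per-voxel OLS t for one contrast; NaN where undefined."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    cvar = float(c @ xtx_inv @ c)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * cvar)
    return t


def fit_glm(images: list[Volume], design: DesignMatrix,
            mask: AnalysisMask) -> tuple[Volume, int]:
    """Per-voxel OLS t-map for the design's contrast, and the residual df.

    Voxels where any subject is undefined get a NaN t.  Out-of-mask voxels
    are NaN.
    """
    if len(images) != design.n:
        raise ValueError("one image per design row is required")
    if design.n <= design.X.shape[1] + 1:
        raise ValueError("need more subjects than regressors plus one")
    Y = stack_images(images, mask)
    t = _contrast_t(Y, design.X, design.contrast)
    t[np.isnan(Y).any(axis=0)] = np.nan
    out = np.full(mask.mask.shape, np.nan)
    out[mask.array] = t
    return mask.mask.like(out), design.df


def height_threshold(tmap: Volume, df: int, p: float = 0.001) -> Volume:
    """Upper-tail one-sided threshold: voxels with t above the t-quantile."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < p <= 0.5:
        raise ValueError("height p must be in (0, 0.5]")
    tcrit = float(stats.t.isf(p, df))
    with np.errstate(invalid="ignore"):
        binary = np.nan_to_num(tmap.data, nan=-np.inf) > tcrit
    return tmap.like(binary)


# ---------------------------------------------------------------------------
# Clusters


@dataclass
class Cluster:
    """Connected suprathreshold component."""

    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    size: int


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def clusterize(binary: Volume, connectivity: int = 18,
               extent: int = 150) -> list[Cluster]:
    """Connected components (default 18-connectivity: faces + edges) of a
    binary volume; components smaller than ``extent`` voxels are dropped."""
    struct = _structure(connectivity)
    labels, nlab = ndimage.label(binary.data.astype(bool), structure=struct)
    clusters = []
    for lab in range(1, nlab + 1):
        vox = np.nonzero(labels == lab)
        size = len(vox[0])
        if size >= extent:
            clusters.append(Cluster(voxels=vox, size=size))
    clusters.sort(key=lambda cl: -cl.size)
    return clusters


def percent_difference(images: list[Volume], groups,
                       cluster: Cluster) -> float:
    """Percent lower carrier mean over the cluster:
    100 * (control mean - carrier mean) / control mean."""
    if cluster.size == 0:
        raise ValueError("cluster is empty")
    groups = np.asarray(groups)
    vals = np.stack([img.data[cluster.voxels] for img in images])
    ctrl = float(np.nanmean(vals[groups == "control"]))
    carr = float(np.nanmean(vals[groups == "carrier"]))
    if ctrl == 0:
        raise ValueError("control mean over the cluster is zero")
    return 100.0 * (ctrl - carr) / ctrl


def _max_cluster_size(t: np.ndarray, tcrit: float, mask_idx, shape,
                      struct) -> int:
    grid = np.zeros(shape, dtype=bool)
    grid[mask_idx] = np.nan_to_num(t, nan=-np.inf) > tcrit
    labels, nlab = ndimage.label(grid, structure=struct)
    if nlab == 0:
        return 0
    return int(np.max(np.bincount(labels.ravel())[1:]))


def cluster_fwe(images: list[Volume], design: DesignMatrix,
                mask: AnalysisMask, n_perm: int = 1000,
                seed: int = 0, height_p: float = 0.001,
                extent: int = 150, cluster_p: float = 0.05,
                connectivity: int = 18,
                groups=None) -> pd.DataFrame:
    """Cluster table with permutation-based FWE-corrected p-values.

    Nuisance columns are those with a zero contrast weight; Freedman-Lane
    residualisation makes rows exchangeable under group relabelling.  If
    ``groups`` is given, each cluster also carries the percent difference of
    carrier vs control means over its voxels.
    """
    effect_cols = np.abs(design.contrast) > 0
    grp_col = design.X[:, np.flatnonzero(effect_cols)[0]]
    for val in np.unique(grp_col):
        if (grp_col == val).sum() < 3:
            raise ValueError("each group must have at least 3 subjects")
    if n_perm < 500:
        warnings.warn(f"n_perm={n_perm} < 500 gives a coarse FWE p-value",
                      stacklevel=2)
    if not 0 < height_p <= 0.5:
        raise ValueError("height p must be in (0, 0.5]")

    Y = stack_images(images, mask)
    undefined = np.isnan(Y).any(axis=0)
    Y = np.where(undefined, 0.0, Y)
    X, c = design.X, design.contrast
    df = design.df
    tcrit = float(stats.t.isf(height_p, df))
    struct = _structure(connectivity)
    mask_idx = np.nonzero(mask.array)
    shape = mask.mask.shape

    t_obs = _contrast_t(Y, X, c)
    t_obs[undefined] = np.nan
    tgrid = np.full(shape, np.nan)
    tgrid[mask_idx] = t_obs
    binary = mask.mask.like(np.nan_to_num(tgrid, nan=-np.inf) > tcrit)
    observed = clusterize(binary, connectivity=connectivity, extent=extent)

    # Freedman-Lane: residualise against nuisance columns, permute residuals
    Z = X[:, c == 0]
    if Z.size:
        hz = Z @ np.linalg.pinv(Z)
        fit_z = hz @ Y
        resid_z = Y - fit_z
    else:
        fit_z = np.zeros_like(Y)
        resid_z = Y
    rng = np.random.default_rng(seed)
    n = design.n
    max_sizes = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_b = _contrast_t(fit_z + resid_z[perm], X, c)
        t_b[undefined] = np.nan
        max_sizes[b] = _max_cluster_size(t_b, tcrit, mask_idx, shape, struct)

    rows = []
    for i, cl in enumerate(observed):
        p_fwe = (1 + int(np.sum(max_sizes >= cl.size))) / (1 + n_perm)
        peak_flat = np.argmax(np.nan_to_num(tgrid[cl.voxels], nan=-np.inf))
        peak = tuple(int(ax[peak_flat]) for ax in cl.voxels)
        row = {
            "cluster_id": i + 1,
            "size_voxels": cl.size,
            "peak_t": float(tgrid[peak]),
            "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
            "p_fwe": p_fwe,
            "significant": p_fwe < cluster_p,
        }
        if groups is not None:
            row["percent_difference"] = percent_difference(images, groups, cl)
        rows.append(row)
    cols = ["cluster_id", "size_voxels", "peak_t", "peak_i", "peak_j",
            "peak_k", "p_fwe", "significant"]
    if groups is not None:
        cols.append("percent_difference")
    table = pd.DataFrame(rows, columns=cols)
    table.attrs.update({"n_perm": n_perm, "seed": seed, "height_p": height_p,
                        "extent": extent, "connectivity": connectivity,
                        "df": df, "t_critical": tcrit})
    return table


def slope_interaction_test(images: list[Volume], ages, groups,
                           mask: AnalysisMask) -> tuple[Volume, int]:
    """t-map for the group x age interaction (difference in age slopes)."""
    ages = np.asarray(ages, dtype=float)
    groups = np.asarray(groups)
    for grp in ("control", "carrier"):
        sub = ages[groups == grp]
        if len(sub) < 3 or np.ptp(sub) == 0:
            raise ValueError(
                f"group {grp!r} has degenerate age variance; cannot test "
                "slope differences")
    g = (groups == "carrier").astype(float)
    a = ages - ages.mean()
    X = np.column_stack([np.ones(len(g)), g, a, g * a])
    design = DesignMatrix(X, np.array([0.0, 0.0, 0.0, 1.0]),
                          ["intercept", "carrier", "age", "carrier_x_age"])
    return fit_glm(images, design, mask)
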