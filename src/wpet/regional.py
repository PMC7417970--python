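"""Atlas volume-of-interest analysis with Benjamini-Hochberg control.

Confirms voxel-level findings region by region: per-subject regional means
(raw or partial-volume corrected), a one-sided age-adjusted group contrast
per region, and step-up false-discovery-rate control over regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import Atlas
from .preprocess import AnalysisMask
from .volume import Volume, check_same_grid


def voi_means(image: Volume, atlas: Atlas,
              mask: AnalysisMask | None = None) -> pd.DataFrame:
    """Mean image value over each atlas label (restricted to the analysis
    mask when given).  Labels with no in-mask voxels are dropped with a
    warning."""
    check_same_grid(image, atlas.volume)
    sel = mask.array if mask is not None else np.ones(image.shape, bool)
    name_of = {v: k for k, v in atlas.names.items()}
    rows = []
    for lab in atlas.labels:
        vox = (atlas.volume.data == lab) & sel
        if not vox.any():
            warnings.warn(f"region {name_of.get(lab, lab)!r} has no voxels "
                          "inside the analysis mask; dropped", stacklevel=2)
            continue
        rows.append({"region": name_of.get(lab, f"label_{lab}"),
                     "label": lab,
                     "size_voxels": int(vox.sum()),
                     "mean": float(np.nanmean(image.data[vox]))})
    return pd.DataFrame(rows, columns=["region", "label", "size_voxels",
                                       "mean"])


def region_table(images: list[Volume], subject_ids, atlas: Atlas,
                 mask: AnalysisMask | None = None) -> pd.DataFrame:
    """Long-format subject x region table of mean values."""
    frames = []
    for img, sid in zip(images, subject_ids):
        tab = voi_means(img, atlas, mask)
        tab.insert(0, "subject_id", sid)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def group_compare_regions(table: pd.DataFrame, groups: dict,
                          ages: dict, direction: str = "hypo",
                          value_col: str = "mean") -> pd.DataFrame:
    """Per-region one-sided age-adjusted group contrast.

    ``groups`` and ``ages`` map subject_id to group label and age.  The test
    is a linear-model contrast on the carrier indicator (intensity ~ group +
    age); ``direction="hypo"`` gives the upper-tail p for carrier < control,
    ``"hyper"`` the opposite side.  Returns per-region t, uncorrected p.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    out = []
    for region, sub in table.groupby("region", sort=True):
        sid = sub["subject_id"].to_numpy()
        y = sub[value_col].to_numpy(dtype=float)
        g = np.array([1.0 if groups[s] == "carrier" else 0.0 for s in sid])
        a = np.array([float(ages[s]) for s in sid])
        if (g == 1).sum() < 3 or (g == 0).sum() < 3:
            raise ValueError("both groups need >= 3 subjects per region")
        X = np.column_stack([np.ones(len(y)), g, a - a.mean()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = len(y) - X.shape[1]
        sigma2 = float(resid @ resid) / df
        if sigma2 <= 0:
            raise ValueError(f"degenerate variance in region {region!r}")
        cvar = float(np.linalg.inv(X.T @ X)[1, 1])
        sign = -1.0 if direction == "hypo" else 1.0
        t = sign * beta[1] / np.sqrt(sigma2 * cvar)
        out.append({"region": region, "t": float(t),
                    "p": float(stats.t.sf(t, df)), "df": df})
    return pd.DataFrame(out, columns=["region", "t", "p", "df"])


def benjamini_hochberg(pvals, q: float = 0.05) -> list[int]:
    """Step-up FDR control: indices of rejected hypotheses.

    Rejects all p at or below p_(k) with k = max{i : p_(i) <= i*q/m}.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return []
    k = int(np.max(np.nonzero(below)[0]))
    return sorted(int(i) for i in order[:k + 1])


def bh_report(stats_table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Region statistics table with a BH rejection column at level q."""
    rejected = set(benjamini_hochberg(stats_table["p"].to_numpy(), q))
    out = stats_table.copy()
    out["bh_rejected"] = [i in rejected for i in range(len(out))]
    out.attrs["q"] = q
    return out
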