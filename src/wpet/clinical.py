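"""Demographic, cognitive and fluid-biomarker statistics.

Group comparisons use a Pearson chi-square without continuity correction for
dichotomous variables and the Mann-Whitney U test for numeric ones.
Neurofilament concentrations are classified against predefined diagnostic
cutoffs (NfL 1227 pg/mL, pNfH 750 pg/mL; elevated means strictly above),
and ECAS cognitive subdomain scores against the 5th percentile of the
normative distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import SubjectRecord

#: 5th-percentile standard-normal quantile magnitude
_Z_P05 = float(stats.norm.ppf(0.95))  # 1.6449


@dataclass
class CutoffConfig:
    """Diagnostic cutoffs for fluid markers and the ECAS percentile rule."""

    nfl_cutoff: float = 1227.0     # pg/mL
    pnfh_cutoff: float = 750.0     # pg/mL
    ecas_percentile: float = 5.0

    def __post_init__(self) -> None:
        if self.nfl_cutoff <= 0 or self.pnfh_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.ecas_percentile < 50:
            raise ValueError("ecas_percentile must be in (0, 50)")


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    Equals N*(ad - bc)^2 / (r1*r2*c1*c2); p from the chi-square(1) upper
    tail.  All margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all table margins must be positive")
    n = t.sum()
    (a, b), (c, d) = t
    chi2 = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def _u_from_ranks(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    rx = ranks[:len(x)].sum()
    return float(rx - len(x) * (len(x) + 1) / 2)


def mann_whitney(x, y, side: str = "two-sided",
                 exact_max_n: int = 8) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` (with mid-rank ties) and its p-value.

    ``side`` is ``"less"``/``"greater"`` (one-sided alternatives about x) or
    ``"two-sided"``.  When both samples have at most ``exact_max_n``
    observations the null distribution of U is enumerated exactly over all
    group assignments (valid under ties); otherwise the normal approximation
    with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if side not in ("less", "greater", "two-sided"):
        raise ValueError("side must be 'less', 'greater' or 'two-sided'")
    nx, ny = len(x), len(y)
    u = _u_from_ranks(x, y)
    mean_u = nx * ny / 2

    if nx <= exact_max_n and ny <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        total = comb(nx + ny, nx)
        const = nx * (nx + 1) / 2
        us = np.fromiter(
            (ranks[list(idx)].sum() - const
             for idx in combinations(range(nx + ny), nx)),
            dtype=float, count=total)
        tol = 1e-9
        p_le = np.sum(us <= u + tol) / total
        p_ge = np.sum(us >= u - tol) / total
        if side == "less":
            p = p_le
        elif side == "greater":
            p = p_ge
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
        return u, float(p)

    n = nx + ny
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var_u = nx * ny / 12 * ((n + 1) - tie_term)
    if var_u <= 0:
        # all observations tied: U is degenerate at its mean
        return u, 1.0
    sd_u = np.sqrt(var_u)
    # continuity correction: U moves on a half-integer lattice
    if side == "less":
        p = stats.norm.cdf((u - mean_u + 0.5) / sd_u)
    elif side == "greater":
        p = stats.norm.sf((u - mean_u - 0.5) / sd_u)
    else:
        p = 2 * stats.norm.sf((abs(u - mean_u) - 0.5) / sd_u)
    return u, float(min(1.0, p))


def flag_nf(nfl: float, pnfh: float,
            cfg: CutoffConfig | None = None) -> dict[str, bool]:
    """Elevated iff strictly above the diagnostic cutoff."""
    cfg = cfg or CutoffConfig()
    if nfl <= 0 or pnfh <= 0:
        raise ValueError("neurofilament concentrations must be positive")
    return {"nfl_elevated": nfl > cfg.nfl_cutoff,
            "pnfh_elevated": pnfh > cfg.pnfh_cutoff}


def classify_ecas(scores: dict[str, float], norms: dict[str, dict],
                  cfg: CutoffConfig | None = None) -> tuple[dict[str, bool], int]:
    """Abnormal iff a subdomain score falls below the normative percentile
    threshold (normal-quantile rule: mean - z_p * SD, z_5% = 1.6449)."""
    cfg = cfg or CutoffConfig()
    z = float(stats.norm.ppf(1 - cfg.ecas_percentile / 100))
    flags = {}
    for dom, score in scores.items():
        if dom not in norms:
            raise KeyError(f"no normative mean/SD for ECAS subdomain {dom!r}")
        thr = norms[dom]["mean"] - z * norms[dom]["sd"]
        flags[dom] = bool(score < thr)
    return flags, sum(flags.values())


def _median_range(vals) -> str:
    v = np.asarray(vals, dtype=float)
    return f"{np.median(v):.1f} ({v.min():.1f}-{v.max():.1f})"


def cohort_summary(records: list[SubjectRecord],
                   cfg: CutoffConfig | None = None,
                   ecas_norms: dict | None = None) -> pd.DataFrame:
    """Demographics/biomarker table with group tests.

    Rows: age (median, range; Mann-Whitney), sex and UMN-sign counts
    (chi-square), NfL/pNfH (median, range; Mann-Whitney; elevated counts),
    ECAS abnormality counts when norms are given.
    """
    cfg = cfg or CutoffConfig()
    carriers = [r for r in records if r.group == "carrier"]
    controls = [r for r in records if r.group == "control"]
    if not carriers or not controls:
        raise ValueError("both groups must be nonempty")

    def count_row(name, pred):
        a = sum(pred(r) for r in carriers)
        b = sum(pred(r) for r in controls)
        table = [[a, len(carriers) - a], [b, len(controls) - b]]
        try:
            stat, _, p = chi_square_2x2(table)
            stat_s, p_s = f"chi2 = {stat:.2f}", p
        except ValueError:
            stat_s, p_s = "n/a", np.nan
        return {"variable": name,
                "carrier": f"{a} ({100 * a / len(carriers):.0f}%)",
                "control": f"{b} ({100 * b / len(controls):.0f}%)",
                "test": stat_s, "p": p_s}

    def numeric_row(name, get):
        xa = [get(r) for r in carriers]
        xb = [get(r) for r in controls]
        u, p = mann_whitney(xa, xb, side="two-sided")
        return {"variable": name, "carrier": _median_range(xa),
                "control": _median_range(xb), "test": f"U = {u:.1f}", "p": p}

    rows = [
        count_row("sex_female", lambda r: r.sex == "F"),
        numeric_row("age_years", lambda r: r.age),
        count_row("umn_sign", lambda r: r.umn_sign),
        numeric_row("nfl_pg_ml", lambda r: r.nfl),
        numeric_row("pnfh_pg_ml", lambda r: r.pnfh),
        count_row("nfl_elevated",
                  lambda r: flag_nf(r.nfl, r.pnfh, cfg)["nfl_elevated"]),
        count_row("pnfh_elevated",
                  lambda r: flag_nf(r.nfl, r.pnfh, cfg)["pnfh_elevated"]),
    ]
    if ecas_norms is not None:
        rows.append(count_row(
            "ecas_abnormal",
            lambda r: classify_ecas(r.ecas, ecas_norms, cfg)[1] > 0))
    return pd.DataFrame(rows, columns=["variable", "carrier", "control",
                                       "test", "p"])
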