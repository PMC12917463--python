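"""Major-axis (model II) regression of paired species-mean tissue densities.

Both tissue means carry sampling error, so the symmetric major-axis line —
the leading eigenvector of the 2x2 covariance matrix, minimising perpendicular
distances — is the appropriate fit for heartwood-vs-sapwood and
trunk-vs-branch comparisons.  Slopes below 1 signal variance attenuation in
the y tissue (densities regress toward the tissue mean); the confidence
interval is the classical angular interval of Jolicoeur & Mosimann.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MAFit", "species_tissue_means", "major_axis_fit"]

_TISSUE_COLUMNS = {
    "sapwood_vs_heartwood": ("type_tissue", "heartwood", "sapwood"),
    "branch_vs_trunk": ("location_sample", "trunk", "branch"),
}


@dataclass
class MAFit:
    """Major-axis slope and intercept with a 95% confidence interval."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "ci": [self.ci_low, self.ci_high], "r": self.r, "n": self.n}


def species_tissue_means(records: pd.DataFrame, contrast: str,
                         min_per_tissue: int = 1) -> pd.DataFrame:
    """Paired per-species means: x = reference tissue, y = contrasted tissue.

    For "branch_vs_trunk", x is the trunk mean and y the branch mean; species
    lacking either tissue (or below ``min_per_tissue`` records in one of them,
    for the robustness variant) are excluded.  Means are unweighted over
    records.
    """
    if contrast not in _TISSUE_COLUMNS:
        raise ValueError(f"unknown contrast {contrast!r}")
    col, x_level, y_level = _TISSUE_COLUMNS[contrast]
    sub = records.loc[records[col].isin([x_level, y_level])]
    stats_df = (sub.groupby(["species", col])["wsg"]
                .agg(["mean", "size"]).unstack(col))
    if stats_df.empty:
        return pd.DataFrame(columns=["x", "y", "n_x", "n_y"])
    means = stats_df["mean"]
    sizes = stats_df["size"].fillna(0)
    for lev in (x_level, y_level):
        if lev not in means.columns:
            means[lev] = np.nan
            sizes[lev] = 0
    ok = (sizes[x_level] >= min_per_tissue) & (sizes[y_level] >= min_per_tissue) \
        & means[x_level].notna() & means[y_level].notna()
    out = pd.DataFrame({
        "x": means.loc[ok, x_level],
        "y": means.loc[ok, y_level],
        "n_x": sizes.loc[ok, x_level].astype(int),
        "n_y": sizes.loc[ok, y_level].astype(int),
    })
    return out


def major_axis_fit(pairs: pd.DataFrame, alpha: float = 0.05) -> MAFit:
    """Major-axis regression of y on x through the centroid.

    slope = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy),
    identical to the slope of the leading eigenvector of the covariance
    matrix.  The confidence interval rotates the axis by
    phi = 0.5 * asin(2 sqrt(H l1 l2) / (l1 - l2)), H = t^2/(n-2); if the
    rotation reaches 90 degrees the interval is unbounded.
    """
    x = np.asarray(pairs["x"], dtype=float)
    y = np.asarray(pairs["y"], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("major-axis regression needs at least 3 pairs")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0.0:
        raise ValueError("zero covariance: major-axis slope undefined")
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    r = sxy / np.sqrt(sxx * syy)
    lam = np.linalg.eigvalsh(np.array([[sxx, sxy], [sxy, syy]]))
    l2, l1 = float(lam[0]), float(lam[1])
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    H = tcrit ** 2 / (n - 2)
    if l1 <= l2 or 2 * np.sqrt(H * l1 * l2) / (l1 - l2) >= 1:
        lo, hi = -np.inf, np.inf
    else:
        theta = np.arctan(slope)
        phi = 0.5 * np.arcsin(2 * np.sqrt(H * l1 * l2) / (l1 - l2))
        bounds = np.tan([theta - phi, theta + phi])
        lo, hi = float(np.min(bounds)), float(np.max(bounds))
    return MAFit(slope=float(slope), intercept=intercept, ci_low=lo,
                 ci_high=hi, r=float(r), n=n)
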