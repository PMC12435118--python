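"""ROI summaries and nonparametric group statistics for marker maps.

Workflow: extract per-region mean F_int / D_int from parameter maps,
apply the zero-F_int exclusion rule (an ROI whose measured F_int is
zero contributes neither marker to the statistics), compare groups with
the Kruskal–Wallis omnibus test followed by Dunn's rank-based pairwise
post-hoc test with Bonferroni adjustment over all pairs, and assess age
relationships with Spearman's rank correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .mapping import ParameterMaps

ALPHA = 0.05


def extract_roi(
    maps: ParameterMaps,
    labels: np.ndarray,
    names: "dict[int, str] | None" = None,
) -> pd.DataFrame:
    """Per-region marker means from parameter maps.

    F_int is averaged over voxels with a defined (finite) F_int; D_int
    over voxels with a valid intermediate component.  Regions with no
    labeled voxels produce a row of NaNs and a warning.

    Returns a table with columns region, label, n_voxels, n_f_int,
    f_int, n_d_int, d_int.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.f_int.shape:
        raise ValueError("label image must match the map grid")
    names = names or {}
    rows = []
    for label in np.unique(labels):
        if label == 0:
            continue
        vox = labels == label
        n_voxels = int(vox.sum())
        f_vals = maps.f_int[vox]
        f_vals = f_vals[np.isfinite(f_vals)]
        d_vals = maps.d_int[vox & maps.valid]
        if n_voxels == 0:
            warnings.warn(f"region {label} is empty", stacklevel=2)
        rows.append(
            {
                "region": names.get(int(label), str(int(label))),
                "label": int(label),
                "n_voxels": n_voxels,
                "n_f_int": int(f_vals.size),
                "f_int": float(f_vals.mean()) if f_vals.size else np.nan,
                "n_d_int": int(d_vals.size),
                "d_int": float(d_vals.mean()) if d_vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusion(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Flag zero-F_int rows as excluded for both markers.

    Adds (or overwrites) a boolean ``included`` column; rows with
    ``f_int == 0`` or missing F_int are excluded.  Idempotent.  Returns
    the annotated table and the number of newly-excluded non-missing
    rows.
    """
    out = table.copy()
    f = out["f_int"].to_numpy(dtype=float)
    included = np.isfinite(f) & (f != 0)
    n_excluded = int(np.sum(np.isfinite(f) & (f == 0)))
    out["included"] = included
    return out, n_excluded


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal–Wallis omnibus result plus Dunn pairwise table."""

    metric: str
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    group_sizes: dict[str, int]

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def dunn_posthoc(samples: "dict[str, np.ndarray]") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Bonferroni adjustment.

    For groups i, j with mean pooled ranks R̄_i, R̄_j over N total
    observations, the statistic is

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))

    with the tie correction T = Σ(t³ − t) over tie groups.  Two-sided
    p-values are Bonferroni-multiplied by the number of pairs and capped
    at 1.
    """
    names = list(samples)
    values = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    sizes = {g: len(samples[g]) for g in names}
    n_total = values.size
    ranks = scipy.stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance -= tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(variance * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": z,
                "p_unadjusted": p,
                "p_adjusted": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
) -> GroupComparison:
    """Kruskal–Wallis test across groups followed by Dunn post-hoc.

    Rows flagged ``included == False`` (see :func:`apply_exclusion`) and
    rows with a missing metric are dropped first.  Requires at least two
    groups with at least two analyzable rows each.
    """
    df = table
    if "included" in df.columns:
        df = df[df["included"]]
    df = df[np.isfinite(df[metric].to_numpy(dtype=float))]
    groups = {
        str(g): sub[metric].to_numpy(dtype=float)
        for g, sub in df.groupby(group_col, sort=False)
    }
    usable = {g: v for g, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError(
            "group comparison needs at least two groups with two or more "
            "analyzable observations each"
        )
    h, p = scipy.stats.kruskal(*usable.values())
    return GroupComparison(
        metric=metric,
        h_statistic=float(h),
        p_value=float(p),
        pairwise=dunn_posthoc(usable),
        group_sizes={g: int(v.size) for g, v in usable.items()},
    )


def age_correlation(
    table: pd.DataFrame,
    metric: str,
    age_col: str = "age",
    groups: "list[str] | None" = None,
    group_col: str = "group",
) -> tuple[float, float]:
    """Spearman rank correlation between a marker and age.

    ``groups`` restricts the rows to an inclusion scheme (e.g. healthy
    controls only, or controls plus patients outside hyperintense
    regions).  Ties are handled by average ranks.  Requires at least 3
    paired observations.
    """
    df = table
    if "included" in df.columns:
        df = df[df["included"]]
    if groups is not None:
        df = df[df[group_col].isin(groups)]
    x = df[age_col].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("Spearman correlation needs at least 3 paired values")
    rho, p = scipy.stats.spearmanr(x[keep], y[keep])
    return float(rho), float(p)
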