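"""Accuracy surfaces over the Monte-Carlo grid.

Estimator accuracy is summarized by the normalized root-mean-square
error

    nRMSE = RMSE(gt, est) / mean(gt),

computed per (compartment count, noise level) cell of the grid and per
marker (F_int or D_int).  For D_int, record pairs where either the
ground truth or the estimate lacks an intermediate component are
excluded from the cell, and the surviving count is tracked per cell.
Cells whose ground-truth mean is zero (or that are empty after
exclusion) are undefined, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class UndefinedNRMSEError(ValueError):
    """The nRMSE normalizer (the ground-truth mean) is zero."""


def nrmse(gt: np.ndarray, est: np.ndarray) -> float:
    """Root-mean-square error divided by the ground-truth mean.

    Scale-covariant: ``nrmse(c*gt, c*est) == nrmse(gt, est)`` for c > 0.
    Raises :class:`UndefinedNRMSEError` when ``mean(gt) == 0``.
    """
    gt = np.asarray(gt, dtype=float)
    est = np.asarray(est, dtype=float)
    if gt.shape != est.shape or gt.size == 0:
        raise ValueError("gt and est must be non-empty arrays of equal length")
    mean_gt = gt.mean()
    if mean_gt == 0:
        raise UndefinedNRMSEError("ground-truth mean is zero; nRMSE undefined")
    return float(np.sqrt(np.mean((gt - est) ** 2)) / mean_gt)


@dataclass(frozen=True)
class NRMSESurface:
    """nRMSE per (compartment count, noise level) cell for one marker.

    ``values[i, j]`` is the nRMSE at ``axis_n[i]`` compartments and
    noise SD ``axis_noise[j]``; undefined cells are NaN and carry
    ``n_used = 0`` or a zero-mean ground truth.
    """

    metric: str
    condition: str
    axis_n: np.ndarray
    axis_noise: np.ndarray
    values: np.ndarray
    n_used: np.ndarray

    def __post_init__(self) -> None:
        expected = (self.axis_n.size, self.axis_noise.size)
        if self.values.shape != expected or self.n_used.shape != expected:
            raise ValueError("surface arrays must match the axis lengths")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def grand_mean(self) -> float:
        """Mean nRMSE over the defined cells."""
        return float(np.nanmean(self.values))

    def mean_by_noise(self) -> np.ndarray:
        """nRMSE averaged over compartment counts, one value per noise level."""
        return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (n, noise_sd, metric, condition, nrmse, n_used)."""
        nn, ss = np.meshgrid(self.axis_n, self.axis_noise, indexing="ij")
        return pd.DataFrame(
            {
                "n": nn.ravel().astype(int),
                "noise_sd": ss.ravel(),
                "metric": self.metric,
                "condition": self.condition,
                "nrmse": self.values.ravel(),
                "n_used": self.n_used.ravel().astype(int),
            }
        )


def build_surface(
    records: pd.DataFrame, metric: str, condition: "str | None" = None
) -> NRMSESurface:
    """Aggregate grid records into an nRMSE surface for one marker.

    ``metric`` is ``"f_int"`` or ``"d_int"``.  ``records`` must cover a
    full grid for a single condition; pass ``condition`` to select one
    from a mixed table.
    """
    if metric not in ("f_int", "d_int"):
        raise ValueError("metric must be 'f_int' or 'd_int'")
    df = records
    if condition is not None:
        df = df[df["condition"] == condition]
    elif df["condition"].nunique() > 1:
        raise ValueError("records mix conditions; pass condition=")
    if df.empty:
        raise ValueError("no records for the requested condition")
    cond_name = str(df["condition"].iloc[0])
    if metric == "d_int":
        df = df[df["gt_valid"] & df["est_valid"]]
    gt_col, est_col = f"gt_{metric}", f"est_{metric}"

    axis_n = np.sort(records["n"].unique())
    axis_noise = np.sort(records["noise_sd"].unique())
    noise_pos = {sd: j for j, sd in enumerate(axis_noise)}
    n_pos = {n: i for i, n in enumerate(axis_n)}

    values = np.full((axis_n.size, axis_noise.size), np.nan)
    n_used = np.zeros((axis_n.size, axis_noise.size), dtype=int)
    for (n, sd), cell in df.groupby(["n", "noise_sd"], sort=False):
        i, j = n_pos[n], noise_pos[sd]
        n_used[i, j] = len(cell)
        try:
            values[i, j] = nrmse(
                cell[gt_col].to_numpy(), cell[est_col].to_numpy()
            )
        except UndefinedNRMSEError:
            pass  # flagged undefined via NaN
    return NRMSESurface(
        metric=metric,
        condition=cond_name,
        axis_n=axis_n,
        axis_noise=axis_noise,
        values=values,
        n_used=n_used,
    )


def compare_conditions(surfaces: "list[NRMSESurface]") -> pd.DataFrame:
    """Rank conditions by grand-mean nRMSE and per-cell wins.

    All surfaces must share the metric and the grid axes.  A condition
    "wins" a cell when its nRMSE is strictly the lowest there; cells
    where any condition is undefined, or where the minimum is tied, are
    counted in ``n_ties``.  The returned table is sorted best-first.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two surfaces to compare")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if s.metric != ref.metric:
            raise ValueError("surfaces mix metrics")
        if not (
            np.array_equal(s.axis_n, ref.axis_n)
            and np.allclose(s.axis_noise, ref.axis_noise)
        ):
            raise ValueError("surfaces are on mismatched grids")

    stack = np.stack([s.values for s in surfaces])  # (k, n, noise)
    finite = np.all(np.isfinite(stack), axis=0)
    wins = np.zeros(len(surfaces), dtype=int)
    ties = 0
    for idx in zip(*np.nonzero(finite)):
        cell = stack[(slice(None), *idx)]
        best = cell.min()
        winners = np.nonzero(cell == best)[0]
        if winners.size == 1:
            wins[winners[0]] += 1
        else:
            ties += 1
    out = pd.DataFrame(
        {
            "condition": [s.condition for s in surfaces],
            "metric": ref.metric,
            "grand_mean_nrmse": [s.grand_mean for s in surfaces],
            "cell_wins": wins,
            "n_cells_compared": int(finite.sum()),
            "n_ties": ties,
        }
    )
    return out.sort_values("grand_mean_nrmse", kind="stable").reset_index(
        drop=True
    )


def surfaces_to_csv(surfaces: "list[NRMSESurface]", path: "str | Path") -> None:
    pd.concat([s.to_frame() for s in surfaces], ignore_index=True).to_csv(
        path, index=False
    )


def plot_surface(surface: NRMSESurface, ax=None, vmax=None):
    """Heatmap of an nRMSE surface (noise on x, compartment count on y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        surface.values,
        origin="lower",
        aspect="auto",
        vmax=vmax,
        extent=(
            surface.axis_noise[0],
            surface.axis_noise[-1],
            surface.axis_n[0],
            surface.axis_n[-1],
        ),
    )
    ax.set_xlabel("noise SD (fraction of S0)")
    ax.set_ylabel("number of compartments")
    ax.set_title(f"{surface.metric} nRMSE — {surface.condition}")
    ax.figure.colorbar(im, ax=ax, label="nRMSE")
    return ax
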