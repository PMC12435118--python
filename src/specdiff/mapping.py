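"""Voxelwise F_int / D_int maps from 4D diffusion-weighted volumes.

Input is a 4D magnitude DWI (NIfTI), an FSL-style whitespace-separated
``.bval`` file and an optional brain mask.  Each masked voxel's decay is
normalized by the mean of its b = 0 volumes and decomposed by NNLS over
a diffusion-coefficient dictionary; the intermediate-component fraction
and peak diffusivity become the map values.  Preprocessing (denoising,
Gibbs-ringing removal, bias-field correction, spatial normalization) is
expected upstream; volumes acquired along several motion-probing
gradient directions should be trace-averaged, for which a helper is
provided.

Map conventions: F_int in percent, D_int on the 1e-3 mm²/s scale;
invalid or background voxels are NaN in the floating-point maps and 0
in the validity map, whose True voxels coincide exactly with the
defined D_int voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .dictionaries import DISPLAY_SCALE, get_dictionary
from .estimators import SpectralDiffusionAnalysis

logger = logging.getLogger(__name__)


def read_bvals(path: "str | Path") -> np.ndarray:
    """Read an FSL-style .bval file (whitespace-separated, one row)."""
    return np.loadtxt(path, dtype=float).reshape(-1)


def write_bvals(path: "str | Path", b_values) -> None:
    np.savetxt(path, np.asarray(b_values, dtype=float)[None, :], fmt="%g")


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition with per-volume b-values."""

    data: np.ndarray
    b_values: np.ndarray
    affine: np.ndarray
    mask: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float).reshape(-1)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, b-index)")
        if self.data.shape[3] != self.b_values.size:
            raise ValueError(
                "4th dimension must match the number of b-values"
            )
        if not np.any(self.b_values == 0):
            raise ValueError("at least one b = 0 volume is required")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask must match the spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @classmethod
    def from_files(
        cls,
        dwi_path: "str | Path",
        bval_path: "str | Path",
        mask_path: "str | Path | None" = None,
    ) -> "DWIVolume":
        img = nib.load(str(dwi_path))
        mask = None
        if mask_path is not None:
            mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
        return cls(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            b_values=read_bvals(bval_path),
            affine=np.asarray(img.affine),
            mask=mask,
        )

    def save(self, dwi_path: "str | Path", bval_path: "str | Path") -> None:
        nib.save(
            nib.Nifti1Image(self.data.astype(np.float32), self.affine),
            str(dwi_path),
        )
        write_bvals(bval_path, self.b_values)


def average_directions(dwi: DWIVolume, method: str = "geometric") -> DWIVolume:
    """Collapse repeated b-values (e.g. orthogonal gradient directions).

    ``method`` is ``"geometric"`` (trace-weighting of a diffusion tensor
    corresponds to the geometric mean of directional signals) or
    ``"arithmetic"``.  Volumes sharing a b-value are combined into one;
    the output b-values are the sorted unique input values.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    unique_b = np.unique(dwi.b_values)
    out = np.empty(dwi.shape + (unique_b.size,))
    for k, b in enumerate(unique_b):
        group = dwi.data[..., dwi.b_values == b]
        if method == "arithmetic":
            out[..., k] = group.mean(axis=-1)
        else:
            with np.errstate(divide="ignore"):
                out[..., k] = np.exp(np.log(np.maximum(group, 0)).mean(axis=-1))
    return DWIVolume(
        data=out, b_values=unique_b, affine=dwi.affine, mask=dwi.mask
    )


def normalize_volume(dwi: DWIVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """b0-normalize the masked voxels.

    Returns ``(signals, voxel_idx, b_positive)`` where ``signals`` is an
    (n_valid, M) array of S(b_i)/S(b_0) rows, ``voxel_idx`` the flat
    spatial indices of those rows, and ``b_positive`` the sorted b > 0
    values.  Voxels whose mean b0 intensity is <= 0 are dropped.
    """
    mask = (
        dwi.mask
        if dwi.mask is not None
        else np.ones(dwi.shape, dtype=bool)
    )
    flat = dwi.data.reshape(-1, dwi.b_values.size)[mask.reshape(-1)]
    voxel_idx = np.flatnonzero(mask.reshape(-1))
    b0_mask = dwi.b_values == 0
    denom = flat[:, b0_mask].mean(axis=1)
    valid = denom > 0
    order = np.argsort(dwi.b_values[~b0_mask], kind="stable")
    signals = flat[valid][:, ~b0_mask][:, order] / denom[valid, None]
    return signals, voxel_idx[valid], dwi.b_values[~b0_mask][order]


@dataclass
class ParameterMaps:
    """Voxelwise marker maps: F_int (%), D_int (1e-3 mm²/s), validity."""

    f_int: np.ndarray
    d_int: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if not (self.f_int.shape == self.d_int.shape == self.valid.shape):
            raise ValueError("map arrays must share one spatial grid")
        if np.any(np.isfinite(self.d_int) != self.valid):
            raise ValueError("defined D_int voxels must match the validity map")

    def save(self, out_dir: "str | Path") -> dict[str, Path]:
        """Write f_int.nii.gz, d_int.nii.gz and valid.nii.gz."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, arr, dtype in (
            ("f_int", self.f_int, np.float32),
            ("d_int", self.d_int, np.float32),
            ("valid", self.valid.astype(np.uint8), np.uint8),
        ):
            p = out_dir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr.astype(dtype), self.affine), str(p))
            paths[name] = p
        return paths

    @classmethod
    def load(cls, out_dir: "str | Path") -> "ParameterMaps":
        out_dir = Path(out_dir)

        def _read(name):
            img = nib.load(str(out_dir / f"{name}.nii.gz"))
            return np.asanyarray(img.dataobj), np.asarray(img.affine)

        f_int, affine = _read("f_int")
        d_int, _ = _read("d_int")
        valid, _ = _read("valid")
        return cls(
            f_int=np.asarray(f_int, dtype=float),
            d_int=np.asarray(d_int, dtype=float),
            valid=np.asarray(valid) > 0,
            affine=affine,
        )


def fit_volume(
    dwi: DWIVolume,
    dictionary="lin200",
    normalize_fractions: bool = True,
) -> ParameterMaps:
    """Fit the NNLS spectrum in every masked voxel and build marker maps.

    Voxels where the fit is impossible (non-positive b0, solver failure)
    are flagged invalid and skipped; the run continues and the skipped
    count is logged.
    """
    dictionary = get_dictionary(dictionary)
    signals, voxel_idx, b_pos = normalize_volume(dwi)
    est = SpectralDiffusionAnalysis(
        dictionary=dictionary,
        b_values=b_pos,
        normalize_fractions=normalize_fractions,
    )
    n_vox = int(np.prod(dwi.shape))
    f_int = np.full(n_vox, np.nan)
    d_int = np.full(n_vox, np.nan)
    if signals.shape[0]:
        feats = est.fit(signals).transform(signals)
        f_int[voxel_idx] = feats[:, 0] * 100.0
        d_int[voxel_idx] = feats[:, 1] * DISPLAY_SCALE
    n_failed = int(np.sum(~np.isfinite(f_int[voxel_idx]))) if len(voxel_idx) else 0
    if n_failed:
        logger.warning("fit failed in %d voxel(s); flagged invalid", n_failed)
    logger.info(
        "fitted %d voxels (%d with defined D_int)",
        len(voxel_idx),
        int(np.isfinite(d_int).sum()),
    )
    shape = dwi.shape
    return ParameterMaps(
        f_int=f_int.reshape(shape),
        d_int=d_int.reshape(shape),
        valid=np.isfinite(d_int).reshape(shape),
        affine=dwi.affine,
    )
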