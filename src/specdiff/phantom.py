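"""Synthetic DWI phantoms with known interstitial-fluid ground truth.

The default phantom is a small 3-D grid holding two tissue classes that
bracket the clinical contrast of interest:

* ``HC-WM`` — healthy-control white matter with component fractions
  0.80 / 0.15 / 0.05 (parenchymal / intermediate / microvascular);
* ``iNPH-PVH`` — periventricular-hyperintensity tissue with fractions
  0.45 / 0.50 / 0.05.

Each class decays as a three-compartment multi-exponential with one
representative diffusivity per component (defaults 0.7e-3, 2.5e-3 and
50e-3 mm²/s, near each component's center of mass), sampled at the
six-b scheme and corrupted with Rician noise.  Ground-truth markers
always accompany the generated volume.

A cohort generator additionally draws per-subject ROI-level marker
values around configurable group means, emulating the group structure
of an in-vivo study (healthy controls vs. hydrocephalus patients with
and without periventricular hyperintensity) for testing the ROI
statistics downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .dictionaries import DISPLAY_SCALE, ComponentRanges, DEFAULT_RANGES
from .mapping import DWIVolume
from .simulation import (
    CompartmentSet,
    add_rician_noise,
    ground_truth_sda,
    synthesize_signal,
)
from .spectral_fit import B_VALUES_CURRENT, SDAResult

#: Representative diffusivity per component (mm²/s).
DEFAULT_COMPONENT_DCS = (0.7e-3, 2.5e-3, 50e-3)

HC_WM_FRACTIONS = (0.80, 0.15, 0.05)
INPH_PVH_FRACTIONS = (0.45, 0.50, 0.05)


@dataclass(frozen=True)
class PhantomRegion:
    """One labeled tissue class with its generative compartments."""

    name: str
    label: int
    compartments: CompartmentSet


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic DWI phantom."""

    shape: tuple[int, int, int] = (32, 32, 32)
    regions: tuple[PhantomRegion, ...] = ()
    b_values: tuple[float, ...] = B_VALUES_CURRENT
    noise_sd: float = 0.0
    s0: float = 1000.0
    seed: int = 0
    margin: int = 4

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels) or 0 in labels:
            raise ValueError("region labels must be unique and non-zero")


def default_regions(
    component_dcs=DEFAULT_COMPONENT_DCS,
) -> tuple[PhantomRegion, PhantomRegion]:
    dcs = np.asarray(component_dcs, dtype=float)
    return (
        PhantomRegion(
            "HC-WM", 1, CompartmentSet(dcs=dcs, amps=np.array(HC_WM_FRACTIONS))
        ),
        PhantomRegion(
            "iNPH-PVH",
            2,
            CompartmentSet(dcs=dcs, amps=np.array(INPH_PVH_FRACTIONS)),
        ),
    )


def _slab_labels(spec: PhantomSpec) -> np.ndarray:
    """Split the interior (inside a background margin) into equal slabs."""
    labels = np.zeros(spec.shape, dtype=np.int16)
    m = spec.margin
    nx = spec.shape[0] - 2 * m
    if nx < len(spec.regions):
        raise ValueError("grid too small for the requested margin and regions")
    edges = np.linspace(m, spec.shape[0] - m, len(spec.regions) + 1).astype(int)
    for region, lo, hi in zip(spec.regions, edges[:-1], edges[1:]):
        labels[lo:hi, m:-m, m:-m] = region.label
    return labels


def build_phantom(
    spec: PhantomSpec,
    ranges: ComponentRanges = DEFAULT_RANGES,
) -> tuple[DWIVolume, np.ndarray, dict[str, SDAResult]]:
    """Realize a phantom: DWI volume, label image, per-region ground truth.

    Background voxels (label 0) carry zero signal and are excluded by
    the returned volume's mask.  Noise is drawn per voxel and per
    b-value from the seed, so identical specs give identical volumes.
    """
    labels = _slab_labels(spec)
    b = np.asarray(spec.b_values, dtype=float)
    data = np.zeros(spec.shape + (b.size,))
    rng = np.random.default_rng(spec.seed)
    ground_truth: dict[str, SDAResult] = {}
    for region in spec.regions:
        clean = spec.s0 * synthesize_signal(region.compartments, b)
        vox = labels == region.label
        block = np.broadcast_to(clean, (int(vox.sum()), b.size))
        data[vox] = add_rician_noise(block, spec.noise_sd * spec.s0, rng)
        ground_truth[region.name] = ground_truth_sda(
            region.compartments, ranges
        )
    dwi = DWIVolume(
        data=data, b_values=b, affine=np.eye(4), mask=labels > 0
    )
    return dwi, labels, ground_truth


def make_default_phantom(
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (32, 32, 32),
    component_dcs=DEFAULT_COMPONENT_DCS,
    b_values=B_VALUES_CURRENT,
    s0: float = 1000.0,
) -> tuple[DWIVolume, np.ndarray, dict[str, SDAResult]]:
    """The stock two-class phantom (HC-WM vs iNPH-PVH slabs)."""
    spec = PhantomSpec(
        shape=tuple(shape),
        regions=default_regions(component_dcs),
        b_values=tuple(float(x) for x in b_values),
        noise_sd=noise_sd,
        s0=s0,
        seed=seed,
    )
    return build_phantom(spec)


def save_phantom(
    dwi: DWIVolume,
    labels: np.ndarray,
    ground_truth: dict[str, SDAResult],
    out_dir: "str | Path",
) -> dict[str, Path]:
    """Write dwi.nii.gz + dwi.bval + labels.nii.gz + ground_truth.json."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": out_dir / "dwi.nii.gz",
        "bval": out_dir / "dwi.bval",
        "labels": out_dir / "labels.nii.gz",
        "ground_truth": out_dir / "ground_truth.json",
    }
    dwi.save(paths["dwi"], paths["bval"])
    nib.save(
        nib.Nifti1Image(labels.astype(np.int16), dwi.affine),
        str(paths["labels"]),
    )
    gt = {
        name: {
            "f_int_percent": res.f_int_percent,
            "d_int_e-3": None if not res.valid_d_int else res.d_int * DISPLAY_SCALE,
            "valid_d_int": res.valid_d_int,
        }
        for name, res in ground_truth.items()
    }
    paths["ground_truth"].write_text(json.dumps(gt, indent=2))
    return paths


#: Group-level generative parameters for the cohort generator:
#: mean and SD of F_int (%) and D_int (1e-3 mm²/s) per group, patterned
#: on centrum-semiovale-like values for healthy controls, hydrocephalus
#: outside periventricular hyperintensity, and within it.
DEFAULT_GROUP_SPECS: dict[str, dict[str, tuple[float, float]]] = {
    "HC": {"f_int": (12.7, 7.0), "d_int": (1.05, 0.45)},
    "iNPH": {"f_int": (12.6, 7.1), "d_int": (0.97, 0.48)},
    "iNPH_PVH": {"f_int": (40.3, 18.4), "d_int": (1.53, 0.63)},
}


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size: int, rng
) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return scipy.stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=size, random_state=rng
    )


def make_cohort(
    n_per_group: int = 30,
    group_specs: "dict | None" = None,
    region: str = "CSO",
    age_range: tuple[float, float] = (20.0, 90.0),
    age_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-subject ROI table emulating a group-structured study.

    Each subject contributes one row per group membership with F_int
    (%) and D_int (1e-3 mm²/s) drawn from truncated normals around the
    group means (F_int truncated to [0, 100], D_int to > 0).  Ages are
    uniform on ``age_range`` and independent of the markers unless
    ``age_effect`` (percentage points of F_int per year) is non-zero.

    Returns a tidy table with columns subject, group, region, age,
    f_int, d_int.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    specs = DEFAULT_GROUP_SPECS if group_specs is None else group_specs
    rng = np.random.default_rng(seed)
    rows = []
    subject = 0
    for group, params in specs.items():
        f_mean, f_sd = params["f_int"]
        d_mean, d_sd = params["d_int"]
        ages = rng.uniform(*age_range, size=n_per_group)
        f = _truncated_normal(f_mean, f_sd, 0.0, 100.0, n_per_group, rng)
        d = _truncated_normal(d_mean, d_sd, 1e-6, np.inf, n_per_group, rng)
        if age_effect:
            f = np.clip(f + age_effect * (ages - np.mean(age_range)), 0.0, 100.0)
        for k in range(n_per_group):
            rows.append(
                {
                    "subject": f"sub-{subject:04d}",
                    "group": group,
                    "region": region,
                    "age": ages[k],
                    "f_int": f[k],
                    "d_int": d[k],
                }
            )
            subject += 1
    return pd.DataFrame(rows)
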