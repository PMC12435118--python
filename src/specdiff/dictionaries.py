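"""Diffusion-coefficient dictionaries for spectral diffusion analysis.

Spectral diffusion analysis (SDA) represents a diffusion-weighted signal
decay as a non-negative combination of mono-exponential atoms
``exp(-b * D_j)``.  The candidate diffusion coefficients ``D_j`` form a
fixed *dictionary*, and every atom belongs to one of three physiological
components:

* **parenchymal diffusion** — hindered tissue water, ``D`` below
  1.5e-3 mm²/s;
* **intermediate diffusion** — interstitial-fluid-like water,
  ``1.5e-3 <= D <= 4.0e-3`` mm²/s (boundaries inclusive);
* **microvascular pseudo-diffusion** — capillary perfusion, ``D`` above
  4.0e-3 mm²/s.

Two stock designs are provided: ``log200`` (200 geometrically spaced
atoms spanning 0.1e-3 to 1000e-3 mm²/s) and ``lin200`` (66/68/66 atoms
linearly spaced within each component range).  All diffusivities are
stored internally in mm²/s so that ``b * D`` is dimensionless with ``b``
in s/mm²; display and CSV output use the conventional 1e-3 mm²/s scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PARENCHYMAL = "parenchymal"
INTERMEDIATE = "intermediate"
MICROVASCULAR = "microvascular"
COMPONENTS = (PARENCHYMAL, INTERMEDIATE, MICROVASCULAR)

#: Scale between internal units (mm²/s) and the conventional display
#: unit of 1e-3 mm²/s.
DISPLAY_SCALE = 1e3


@dataclass(frozen=True)
class ComponentRanges:
    """Boundaries of the three diffusion components, in mm²/s.

    The defaults are the standard SDA component limits: parenchymal
    diffusion on (0.1, 1.5)e-3, intermediate diffusion on [1.5, 4.0]e-3
    and microvascular pseudo-diffusion on (4.0, 1000)e-3 mm²/s.  The
    global minimum atom (0.1e-3) is classified as parenchymal.
    """

    parenchymal_upper: float = 1.5e-3
    intermediate_lower: float = 1.5e-3
    intermediate_upper: float = 4.0e-3
    global_min: float = 0.1e-3
    global_max: float = 1000e-3

    def __post_init__(self) -> None:
        if not (
            self.global_min
            < self.intermediate_lower
            <= self.parenchymal_upper
            < self.intermediate_upper
            < self.global_max
        ):
            raise ValueError(
                "component boundaries must satisfy global_min < "
                "intermediate_lower = parenchymal_upper < "
                "intermediate_upper < global_max"
            )
        if self.intermediate_lower != self.parenchymal_upper:
            raise ValueError(
                "parenchymal_upper and intermediate_lower must coincide"
            )

    def component_interval(self, component: str) -> tuple[float, float]:
        """Linear-scale interval spanned by one component."""
        if component == PARENCHYMAL:
            return self.global_min, self.parenchymal_upper
        if component == INTERMEDIATE:
            return self.intermediate_lower, self.intermediate_upper
        if component == MICROVASCULAR:
            return self.intermediate_upper, self.global_max
        raise ValueError(f"unknown component {component!r}")


DEFAULT_RANGES = ComponentRanges()


def classify_atoms(
    atoms: np.ndarray, ranges: ComponentRanges = DEFAULT_RANGES
) -> np.ndarray:
    """Assign each diffusivity to its component.

    An atom is parenchymal below ``intermediate_lower``, intermediate on
    the closed interval ``[intermediate_lower, intermediate_upper]`` and
    microvascular above it.  Atoms at the global limits belong to the
    outer components.

    Raises
    ------
    ValueError
        If any atom lies outside ``[global_min, global_max]``.
    """
    atoms = np.asarray(atoms, dtype=float)
    if atoms.size and (
        atoms.min() < ranges.global_min * (1 - 1e-12)
        or atoms.max() > ranges.global_max * (1 + 1e-12)
    ):
        raise ValueError("atom outside the global diffusivity range")
    labels = np.full(atoms.shape, MICROVASCULAR, dtype=object)
    labels[atoms <= ranges.intermediate_upper] = INTERMEDIATE
    labels[atoms < ranges.intermediate_lower] = PARENCHYMAL
    return labels.astype(str)


def component_counts(labels: np.ndarray) -> tuple[int, int, int]:
    """Number of atoms per component, in canonical component order."""
    labels = np.asarray(labels)
    return tuple(int(np.sum(labels == c)) for c in COMPONENTS)


@dataclass(frozen=True)
class DiffusionDictionary:
    """Ordered set of candidate diffusion coefficients with labels.

    Attributes
    ----------
    atoms : ndarray
        Strictly increasing diffusivities in mm²/s.
    labels : ndarray of str
        Per-atom component tag; forms three contiguous runs.
    scheme : str
        ``"logarithmic"`` or ``"component_linear"`` (or ``"custom"``).
    ranges : ComponentRanges
        The component boundaries used for labelling.
    """

    atoms: np.ndarray
    labels: np.ndarray
    scheme: str
    ranges: ComponentRanges = field(default=DEFAULT_RANGES)

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float)
        labels = np.asarray(self.labels).astype(str)
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "labels", labels)
        if atoms.ndim != 1 or atoms.size == 0:
            raise ValueError("atoms must be a non-empty 1-D array")
        if labels.shape != atoms.shape:
            raise ValueError("labels must align with atoms")
        if np.any(np.diff(atoms) <= 0):
            raise ValueError("atoms must be strictly increasing")
        unknown = set(labels) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown component labels: {unknown}")
        # labels must form three (or fewer) contiguous runs in canonical order
        order = {c: i for i, c in enumerate(COMPONENTS)}
        codes = np.array([order[l] for l in labels])
        if np.any(np.diff(codes) < 0):
            raise ValueError("component labels must be contiguous runs")

    @property
    def n_atoms(self) -> int:
        return int(self.atoms.size)

    @property
    def component_counts(self) -> tuple[int, int, int]:
        return component_counts(self.labels)

    def component_mask(self, component: str) -> np.ndarray:
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        return self.labels == component

    def atom(self, index: int) -> float:
        """Diffusivity of the 1-based atom ``index`` (D_1 .. D_N)."""
        if not 1 <= index <= self.n_atoms:
            raise IndexError(f"atom index {index} outside 1..{self.n_atoms}")
        return float(self.atoms[index - 1])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with 1-based indices and D in 1e-3 mm²/s."""
        return pd.DataFrame(
            {
                "index": np.arange(1, self.n_atoms + 1),
                "D_e-3_mm2_per_s": self.atoms * DISPLAY_SCALE,
                "component": self.labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        scheme: str = "custom",
        ranges: ComponentRanges = DEFAULT_RANGES,
    ) -> "DiffusionDictionary":
        frame = pd.read_csv(path)
        atoms = frame["D_e-3_mm2_per_s"].to_numpy(dtype=float) / DISPLAY_SCALE
        labels = frame["component"].to_numpy(dtype=str)
        return cls(atoms=atoms, labels=labels, scheme=scheme, ranges=ranges)


def build_log_dictionary(
    n_atoms: int = 200, ranges: ComponentRanges = DEFAULT_RANGES
) -> DiffusionDictionary:
    """Geometrically spaced dictionary from global_min to global_max.

    Atom j (1-based) is ``global_min * (global_max/global_min)**((j-1)/(n-1))``,
    so both global limits are included.  With the default ranges and
    n_atoms=200 this is the classical ``Log200`` design whose component
    census is 59/21/120.
    """
    if n_atoms < 2:
        raise ValueError("a logarithmic dictionary needs at least 2 atoms")
    atoms = np.geomspace(ranges.global_min, ranges.global_max, n_atoms)
    return DiffusionDictionary(
        atoms=atoms,
        labels=classify_atoms(atoms, ranges),
        scheme="logarithmic",
        ranges=ranges,
    )


def build_component_linear_dictionary(
    counts: tuple[int, int, int] = (66, 68, 66),
    ranges: ComponentRanges = DEFAULT_RANGES,
) -> DiffusionDictionary:
    """Per-component linearly spaced dictionary (the ``Lin200`` design).

    The intermediate run includes both of its boundaries (hence its two
    extra atoms in the stock 66/68/66 design).  The outer runs exclude
    the shared boundary: the parenchymal run starts at ``global_min``
    with step ``(parenchymal_upper - global_min)/counts[0]`` and stops
    one step short of 1.5e-3, while the microvascular run starts one
    step ``(global_max - intermediate_upper)/counts[2]`` above 4.0e-3
    and ends exactly at ``global_max``.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 2 for c in counts):
        raise ValueError("counts must be three integers, each at least 2")
    n_par, n_int, n_mic = counts
    par_step = (ranges.parenchymal_upper - ranges.global_min) / n_par
    par = ranges.global_min + par_step * np.arange(n_par)
    inter = np.linspace(ranges.intermediate_lower, ranges.intermediate_upper, n_int)
    mic_step = (ranges.global_max - ranges.intermediate_upper) / n_mic
    mic = ranges.intermediate_upper + mic_step * np.arange(1, n_mic + 1)
    atoms = np.concatenate([par, inter, mic])
    labels = np.concatenate(
        [
            np.full(n_par, PARENCHYMAL),
            np.full(n_int, INTERMEDIATE),
            np.full(n_mic, MICROVASCULAR),
        ]
    )
    return DiffusionDictionary(
        atoms=atoms, labels=labels, scheme="component_linear", ranges=ranges
    )


def log200() -> DiffusionDictionary:
    """The stock 200-atom geometric dictionary."""
    return build_log_dictionary(200)


def lin200() -> DiffusionDictionary:
    """The stock 66/68/66 component-linear dictionary."""
    return build_component_linear_dictionary((66, 68, 66))


_NAMED = {"log200": log200, "lin200": lin200}


def get_dictionary(name: "str | DiffusionDictionary") -> DiffusionDictionary:
    """Resolve a dictionary given by name ('lin200', 'log200') or instance."""
    if isinstance(name, DiffusionDictionary):
        return name
    try:
        return _NAMED[str(name).lower()]()
    except KeyError:
        raise ValueError(
            f"unknown dictionary {name!r}; choose from {sorted(_NAMED)}"
        ) from None
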