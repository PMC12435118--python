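"""Monte-Carlo study of b-value schemes and dictionary designs.

The study synthesizes multi-compartment decay signals with known ground
truth, corrupts them with Rician noise, fits each configured
(b-scheme, dictionary) condition, and records ground truth alongside
estimates.  The default grid enumerates compartment counts 1..50, 1000
random diffusion-coefficient combinations per count, and 50 noise
levels spanning 0%-5% of S0 — 2,500,000 decay patterns per condition.

Ground-truth diffusion coefficients are drawn by first choosing one of
the three diffusion components with equal probability and then sampling
uniformly (linear scale) within that component's continuous range; this
avoids the microvascular range (which spans almost the whole linear
axis) dominating a plain uniform draw.  Amplitudes are i.i.d.
uniform(0, 1) renormalized to sum to 1 (a symmetric Dirichlet draw is
available as an alternative law).

Noise is applied to the theoretical signals at every b-value including
b = 0, and the fitted signal is the ratio of noisy S(b_i) to noisy
S(b_0), matching how magnitude data are normalized in practice.  The
grid is a paired design along both comparison axes: one ground-truth
compartment set is shared across all noise levels and all conditions
of a (count, pattern) cell, and one standard complex-Gaussian draw per
(cell, b-scheme) is scaled by each noise level's SD, so neither
condition differences nor noise-level differences are confounded by
resampling (common random numbers along the noise ladder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dictionaries import (
    COMPONENTS,
    ComponentRanges,
    DEFAULT_RANGES,
    DiffusionDictionary,
    get_dictionary,
)
from .spectral_fit import (
    B_VALUES_CURRENT,
    B_VALUES_PREVIOUS,
    DecaySignal,
    SDAResult,
    fit_signal,
)

RECORD_COLUMNS = (
    "n",
    "pattern_id",
    "noise_idx",
    "noise_sd",
    "condition",
    "gt_f_int",
    "gt_d_int",
    "gt_valid",
    "est_f_int",
    "est_d_int",
    "est_valid",
)


@dataclass(frozen=True)
class CompartmentSet:
    """A simulation ground truth: continuous DCs with unit total amplitude."""

    dcs: np.ndarray
    amps: np.ndarray

    def __post_init__(self) -> None:
        dcs = np.asarray(self.dcs, dtype=float)
        amps = np.asarray(self.amps, dtype=float)
        object.__setattr__(self, "dcs", dcs)
        object.__setattr__(self, "amps", amps)
        if dcs.ndim != 1 or dcs.shape != amps.shape or dcs.size == 0:
            raise ValueError("dcs and amps must be matching non-empty 1-D arrays")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if abs(amps.sum() - 1.0) > 1e-12:
            raise ValueError("amplitudes must sum to 1 within 1e-12")

    @property
    def n(self) -> int:
        return int(self.dcs.size)


def sample_compartments(
    n: int,
    rng: np.random.Generator,
    ranges: ComponentRanges = DEFAULT_RANGES,
    amplitude_law: str = "uniform_normalized",
) -> CompartmentSet:
    """Draw a random multi-compartment ground truth.

    Each compartment's diffusivity comes from a component chosen with
    probability 1/3, then uniform on that component's linear interval.
    ``amplitude_law`` is ``"uniform_normalized"`` (default) or
    ``"dirichlet"`` (flat Dirichlet).
    """
    if n < 1:
        raise ValueError("need at least one compartment")
    comp_idx = rng.integers(0, 3, size=n)
    intervals = [ranges.component_interval(c) for c in COMPONENTS]
    lo = np.array([intervals[i][0] for i in comp_idx])
    hi = np.array([intervals[i][1] for i in comp_idx])
    dcs = rng.uniform(lo, hi)
    if amplitude_law == "uniform_normalized":
        raw = rng.uniform(0.0, 1.0, size=n)
        total = raw.sum()
        amps = raw / total if total > 0 else np.full(n, 1.0 / n)
    elif amplitude_law == "dirichlet":
        amps = rng.dirichlet(np.ones(n))
    else:
        raise ValueError(f"unknown amplitude law {amplitude_law!r}")
    return CompartmentSet(dcs=dcs, amps=amps)


def synthesize_signal(cs: CompartmentSet, b_values: Sequence[float]) -> np.ndarray:
    """Noise-free multi-exponential decay at the given b-values (incl. b0)."""
    b = np.asarray(b_values, dtype=float)
    return np.exp(-np.outer(b, cs.dcs)) @ cs.amps


def add_rician_noise(
    signal: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude of the signal plus complex Gaussian noise.

    Each element s becomes |s + g_re + i g_im| with g_re, g_im ~
    N(0, sd²) independent across elements; sd is expressed as a fraction
    of S0 for unit-normalized signals.  sd = 0 returns the input
    unchanged.
    """
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    s = np.asarray(signal, dtype=float)
    if sd == 0:
        return s.copy()
    g_re = rng.normal(0.0, sd, size=s.shape)
    g_im = rng.normal(0.0, sd, size=s.shape)
    return np.hypot(s + g_re, g_im)


def ground_truth_sda(
    cs: CompartmentSet, ranges: ComponentRanges = DEFAULT_RANGES
) -> SDAResult:
    """Ground-truth markers of a compartment set.

    F_int sums the amplitudes of compartments with diffusivity inside
    the closed intermediate range; D_int is the diffusivity of the
    maximum-amplitude compartment there (ties break toward the lower
    diffusivity, mirroring the estimator's rule).
    """
    in_int = (cs.dcs >= ranges.intermediate_lower) & (
        cs.dcs <= ranges.intermediate_upper
    )
    in_par = cs.dcs < ranges.intermediate_lower
    f_int = float(cs.amps[in_int].sum())
    if f_int > 0:
        dcs_int = cs.dcs[in_int]
        amps_int = cs.amps[in_int]
        best = amps_int.max()
        d_int = float(dcs_int[amps_int == best].min())
        valid = True
    else:
        d_int = math.nan
        valid = False
    return SDAResult(
        f_int=f_int,
        d_int=d_int,
        f_parenchymal=float(cs.amps[in_par].sum()),
        f_microvascular=float(cs.amps[~in_int & ~in_par].sum()),
        valid_d_int=valid,
    )


def default_noise_levels(n_levels: int = 50, max_sd: float = 0.05) -> np.ndarray:
    """Equally spaced noise SDs on [0, max_sd], endpoints included."""
    return np.linspace(0.0, max_sd, n_levels)


@dataclass(frozen=True)
class FitCondition:
    """One (b-scheme, dictionary) configuration to evaluate."""

    name: str
    b_values: tuple[float, ...]
    dictionary: DiffusionDictionary

    @classmethod
    def make(cls, name, b_values, dictionary) -> "FitCondition":
        return cls(
            name=name,
            b_values=tuple(float(b) for b in b_values),
            dictionary=get_dictionary(dictionary),
        )


def default_conditions() -> list[FitCondition]:
    """The three study conditions: Lin200/6b, Log200/6b, Log200/15b."""
    return [
        FitCondition.make("lin200_6b", B_VALUES_CURRENT, "lin200"),
        FitCondition.make("log200_6b", B_VALUES_CURRENT, "log200"),
        FitCondition.make("log200_15b", B_VALUES_PREVIOUS, "log200"),
    ]


@dataclass(frozen=True)
class SimulationGrid:
    """The Monte-Carlo grid: compartment counts x patterns x noise levels."""

    n_range: tuple[int, ...] = tuple(range(1, 51))
    patterns_per_n: int = 1000
    noise_levels: tuple[float, ...] = tuple(default_noise_levels())
    ranges: ComponentRanges = field(default=DEFAULT_RANGES)
    amplitude_law: str = "uniform_normalized"

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_range):
            raise ValueError("compartment counts must be >= 1")
        if self.patterns_per_n < 1:
            raise ValueError("patterns_per_n must be >= 1")
        if any(sd < 0 for sd in self.noise_levels):
            raise ValueError("noise levels must be non-negative")

    @property
    def total_patterns(self) -> int:
        """Decay patterns enumerated per condition (the grid product)."""
        return len(self.n_range) * self.patterns_per_n * len(self.noise_levels)

    def reduced(self, n_max=10, patterns=100, n_noise=10) -> "SimulationGrid":
        """A scaled-down grid for desk-scale replication runs."""
        return SimulationGrid(
            n_range=tuple(range(1, n_max + 1)),
            patterns_per_n=patterns,
            noise_levels=tuple(default_noise_levels(n_noise)),
            ranges=self.ranges,
            amplitude_law=self.amplitude_law,
        )


def iter_grid_records(
    grid: SimulationGrid,
    conditions: Sequence[FitCondition],
    seed: int,
) -> Iterable[dict]:
    """Yield one record per (n, pattern, noise level, condition).

    Deterministic given (grid, conditions, seed): compartment sets and
    noise realizations are drawn from seed sequences keyed by their grid
    coordinates, so the record stream is a pure function of the inputs.
    """
    if not conditions:
        raise ValueError("at least one fit condition is required")
    schemes: list[tuple[float, ...]] = []
    for cond in conditions:
        if cond.b_values not in schemes:
            schemes.append(cond.b_values)
    scheme_of = {s: i for i, s in enumerate(schemes)}

    for n in grid.n_range:
        for pattern in range(grid.patterns_per_n):
            rng_cs = np.random.default_rng([seed, 0, n, pattern])
            cs = sample_compartments(
                n, rng_cs, grid.ranges, grid.amplitude_law
            )
            gt = ground_truth_sda(cs, grid.ranges)
            clean = {s: synthesize_signal(cs, s) for s in schemes}
            # one base complex-Gaussian draw per scheme, scaled per level
            base = {}
            for s in schemes:
                rng_noise = np.random.default_rng(
                    [seed, 1, n, pattern, scheme_of[s]]
                )
                base[s] = (
                    rng_noise.normal(size=len(s)),
                    rng_noise.normal(size=len(s)),
                )
            for noise_idx, sd in enumerate(grid.noise_levels):
                noisy = {}
                for s in schemes:
                    if sd == 0:
                        noisy[s] = clean[s]
                    else:
                        z_re, z_im = base[s]
                        noisy[s] = np.hypot(clean[s] + sd * z_re, sd * z_im)
                for cond in conditions:
                    b = np.asarray(cond.b_values)
                    sig = DecaySignal.from_acquisition(b, noisy[cond.b_values])
                    est = fit_signal(
                        sig,
                        cond.dictionary,
                        identifier=(n, pattern, noise_idx, cond.name),
                    )
                    yield {
                        "n": n,
                        "pattern_id": pattern,
                        "noise_idx": noise_idx,
                        "noise_sd": sd,
                        "condition": cond.name,
                        "gt_f_int": gt.f_int,
                        "gt_d_int": gt.d_int,
                        "gt_valid": gt.valid_d_int,
                        "est_f_int": est.f_int,
                        "est_d_int": est.d_int,
                        "est_valid": est.valid_d_int,
                    }


def run_grid(
    grid: SimulationGrid,
    conditions: Sequence[FitCondition],
    seed: int,
    out: "str | Path | None" = None,
    chunk_size: int = 50_000,
) -> "pd.DataFrame | Path":
    """Run the Monte-Carlo grid over all conditions.

    Returns the record table as a DataFrame, or — when ``out`` is given
    — streams records to a CSV in chunks and returns its path (for
    grids too large to hold in memory).
    """
    records = iter_grid_records(grid, conditions, seed)
    if out is None:
        return pd.DataFrame.from_records(records, columns=RECORD_COLUMNS)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    first = True
    buffer: list[dict] = []

    def flush():
        nonlocal first
        if buffer:
            pd.DataFrame.from_records(buffer, columns=RECORD_COLUMNS).to_csv(
                out, mode="w" if first else "a", header=first, index=False
            )
            first = False
            buffer.clear()

    for rec in records:
        buffer.append(rec)
        if len(buffer) >= chunk_size:
            flush()
    flush()
    return out
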