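"""NNLS spectral decomposition of diffusion decay signals.

The signal model is a sum of mono-exponential compartments,

    S(b_i)/S(b_0) = sum_j A_j * exp(-b_i * D_j),   A_j >= 0,

where the D_j are the atoms of a :class:`~specdiff.dictionaries.DiffusionDictionary`.
Fitting amounts to non-negative least squares on the design matrix
``A[i, j] = exp(-b_i * D_j)`` against the b0-normalized signal vector.
From the fitted spectrum two interstitial-fluid surrogate markers are
read off:

* ``F_int`` — the summed amplitude inside the intermediate-diffusion
  range, optionally normalized by the total amplitude;
* ``D_int`` — the dictionary diffusivity at the maximum amplitude
  inside that range (undefined when the range carries no amplitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .dictionaries import (
    DISPLAY_SCALE,
    INTERMEDIATE,
    MICROVASCULAR,
    PARENCHYMAL,
    DiffusionDictionary,
)

#: The six-b acquisition scheme used for mapping (s/mm²).
B_VALUES_CURRENT = (0.0, 50.0, 100.0, 250.0, 500.0, 1000.0)

#: The legacy 15-b scheme (s/mm²).
B_VALUES_PREVIOUS = (
    0.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 40.0,
    50.0, 60.0, 100.0, 200.0, 400.0, 700.0, 1000.0,
)


class NNLSConvergenceError(RuntimeError):
    """The active-set NNLS solver failed to converge for one signal."""

    def __init__(self, identifier=None):
        self.identifier = identifier
        tag = "" if identifier is None else f" (signal {identifier!r})"
        super().__init__(f"NNLS did not converge{tag}")


@dataclass(frozen=True)
class DecaySignal:
    """A b0-normalized diffusion decay: b-values and S(b_i)/S(b_0).

    Only b > 0 rows enter the fit; the b = 0 measurement is consumed by
    the normalization.  Signals are magnitudes and must be >= 0.
    """

    b_values: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "signals", s)
        if b.ndim != 1 or s.shape != b.shape or b.size == 0:
            raise ValueError("b_values and signals must be matching 1-D arrays")
        if np.any(b <= 0):
            raise ValueError(
                "b_values must be strictly positive; normalize the b = 0 "
                "volume away first (see DecaySignal.from_acquisition)"
            )
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("signals must be finite and non-negative")

    @property
    def m(self) -> int:
        """Number of non-zero b-values entering the fit."""
        return int(self.b_values.size)

    @classmethod
    def from_acquisition(
        cls, b_values: np.ndarray, raw_signals: np.ndarray
    ) -> "DecaySignal":
        """Normalize a raw acquisition (including b = 0 volumes).

        All volumes with b = 0 are averaged to form the denominator; the
        remaining volumes are divided by it.  Raises if no b = 0 volume
        is present or the b0 mean is not positive.
        """
        b = np.asarray(b_values, dtype=float)
        s = np.asarray(raw_signals, dtype=float)
        b0_mask = b == 0
        if not b0_mask.any():
            raise ValueError("acquisition carries no b = 0 volume")
        denom = float(s[b0_mask].mean())
        if denom <= 0:
            raise ValueError("non-positive b0 signal; voxel is invalid")
        order = np.argsort(b[~b0_mask], kind="stable")
        return cls(b[~b0_mask][order], s[~b0_mask][order] / denom)


def build_design_matrix(
    b_values: np.ndarray, dictionary: "DiffusionDictionary | np.ndarray"
) -> np.ndarray:
    """The M x N exponential design matrix ``exp(-b_i * D_j)``."""
    atoms = (
        dictionary.atoms
        if isinstance(dictionary, DiffusionDictionary)
        else np.asarray(dictionary, dtype=float)
    )
    b = np.asarray(b_values, dtype=float)
    if b.size == 0 or atoms.size == 0:
        raise ValueError("empty b-value list or dictionary")
    return np.exp(-np.outer(b, atoms))


@dataclass(frozen=True)
class Spectrum:
    """A non-negative amplitude vector over a dictionary."""

    dictionary: DiffusionDictionary
    amplitudes: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if amps.shape != (self.dictionary.n_atoms,):
            raise ValueError("amplitude vector must match the dictionary size")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative")

    def component_sums(self) -> dict[str, float]:
        """Raw amplitude mass per component."""
        return {
            c: float(self.amplitudes[self.dictionary.component_mask(c)].sum())
            for c in (PARENCHYMAL, INTERMEDIATE, MICROVASCULAR)
        }

    def to_frame(self) -> pd.DataFrame:
        frame = self.dictionary.to_frame()
        frame["amplitude"] = self.amplitudes
        return frame

    def to_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False)


def nnls_solve(
    signal: DecaySignal,
    dictionary: DiffusionDictionary,
    identifier=None,
    b0_row: bool = True,
) -> Spectrum:
    """Solve the non-negative least-squares spectral fit.

    With ``b0_row=True`` (default) the linear system carries the b = 0
    measurement as its first row: the design row is all ones
    (``exp(0) = 1``) and the target entry is the unit ratio
    S(b_0)/S(b_0) = 1, which softly constrains the total amplitude to 1
    as the multi-exponential model implies.  Without it the fit sees
    only the b > 0 rows and the total amplitude is unconstrained.

    Uses the active-set NNLS algorithm, which is deterministic for a
    fixed input.  Raises :class:`NNLSConvergenceError` (carrying
    ``identifier``) if the solver fails.
    """
    design = build_design_matrix(signal.b_values, dictionary)
    target = signal.signals
    if b0_row:
        design = np.vstack([np.ones(dictionary.n_atoms), design])
        target = np.concatenate([[1.0], target])
    try:
        amplitudes, rnorm = scipy.optimize.nnls(design, target)
    except RuntimeError as exc:  # pragma: no cover - solver failure is rare
        raise NNLSConvergenceError(identifier) from exc
    return Spectrum(
        dictionary=dictionary, amplitudes=amplitudes, residual_norm=float(rnorm)
    )


@dataclass(frozen=True)
class SDAResult:
    """Interstitial-fluid surrogate markers extracted from one spectrum.

    Fractions are dimensionless in [0, 1]; ``f_int_percent`` gives the
    conventional percent scale.  ``d_int`` is NaN (and ``valid_d_int``
    False) exactly when the intermediate range carries zero amplitude.
    """

    f_int: float
    d_int: float
    f_parenchymal: float
    f_microvascular: float
    valid_d_int: bool

    @property
    def f_int_percent(self) -> float:
        return 100.0 * self.f_int

    @property
    def d_int_e3(self) -> float:
        """D_int on the conventional 1e-3 mm²/s display scale."""
        return self.d_int * DISPLAY_SCALE

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f_int, self.d_int, self.f_parenchymal, self.f_microvascular)


def extract_sda(spectrum: Spectrum, normalize: bool = True) -> SDAResult:
    """Read F_int / D_int (and the flanking fractions) off a spectrum.

    With ``normalize=True`` (default) each component fraction is the
    component amplitude sum divided by the total amplitude, so the three
    fractions sum to 1 whenever the spectrum is non-empty; this keeps
    fractions comparable across voxels whose fitted total deviates from
    1 under noise.  ``normalize=False`` reports raw amplitude sums.

    ``D_int`` is the dictionary diffusivity at the maximum amplitude
    within the intermediate range; equal maxima break toward the
    lower diffusivity.
    """
    sums = spectrum.component_sums()
    total = sum(sums.values())
    if normalize and total > 0:
        frac = {c: v / total for c, v in sums.items()}
    elif normalize:
        frac = {c: 0.0 for c in sums}
    else:
        frac = sums

    int_mask = spectrum.dictionary.component_mask(INTERMEDIATE)
    if sums[INTERMEDIATE] > 0:
        amps_int = spectrum.amplitudes[int_mask]
        # argmax returns the first (lowest-D) atom on ties
        d_int = float(spectrum.dictionary.atoms[int_mask][np.argmax(amps_int)])
        valid = True
    else:
        d_int = math.nan
        valid = False
    return SDAResult(
        f_int=frac[INTERMEDIATE],
        d_int=d_int,
        f_parenchymal=frac[PARENCHYMAL],
        f_microvascular=frac[MICROVASCULAR],
        valid_d_int=valid,
    )


def fit_signal(
    signal: DecaySignal,
    dictionary: DiffusionDictionary,
    normalize: bool = True,
    identifier=None,
    b0_row: bool = True,
) -> SDAResult:
    """Convenience wrapper: NNLS fit followed by marker extraction."""
    return extract_sda(
        nnls_solve(signal, dictionary, identifier, b0_row=b0_row), normalize
    )


def results_to_frame(results: dict) -> pd.DataFrame:
    """Tabulate SDAResults keyed by id, on the conventional scales."""
    rows = []
    for key, res in results.items():
        rows.append(
            {
                "id": key,
                "F_int_percent": res.f_int_percent,
                "D_int_e-3": res.d_int_e3,
                "valid_d_int": res.valid_d_int,
            }
        )
    return pd.DataFrame(rows)
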