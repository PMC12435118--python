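"""Scikit-learn style front end for the NNLS spectral fit.

:class:`SpectralDiffusionAnalysis` is a stateless-by-construction
transformer: ``fit`` resolves the dictionary and precomputes the
exponential design matrix, ``transform`` maps a matrix of decay signals
(one row per voxel or simulated pattern, one column per b-value) to the
four spectral features ``(F_int, D_int, F_parenchymal, F_microvascular)``.
It composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dictionaries import DiffusionDictionary, get_dictionary
from .spectral_fit import (
    B_VALUES_CURRENT,
    NNLSConvergenceError,
    Spectrum,
    build_design_matrix,
    extract_sda,
)

FEATURE_NAMES = ("f_int", "d_int", "f_parenchymal", "f_microvascular")


class SpectralDiffusionAnalysis(TransformerMixin, BaseEstimator):
    """Per-sample NNLS diffusion spectrum and interstitial-fluid markers.

    Parameters
    ----------
    dictionary : str or DiffusionDictionary, default="lin200"
        The diffusion-coefficient dictionary: ``"lin200"``, ``"log200"``
        or an explicit :class:`DiffusionDictionary`.
    b_values : sequence of float, optional
        b-values (s/mm²) matching the columns of ``X``.  Defaults to the
        six-b scheme 0/50/100/250/500/1000.  If a b = 0 column is
        present, each row is normalized by the mean of its b = 0
        columns before fitting; otherwise rows are assumed to be
        already-normalized ratios S(b_i)/S(b_0).
    normalize_fractions : bool, default=True
        Divide component fractions by the total fitted amplitude (so the
        three fractions sum to 1 for non-empty spectra).
    b0_row : bool, default=True
        Carry the b = 0 measurement into the linear system as a unit
        row (all-ones design row against the unit ratio), which softly
        constrains the total amplitude to 1 as the signal model
        implies.  When False the fit sees only the b > 0 rows.

    Attributes
    ----------
    dictionary_ : DiffusionDictionary
        The resolved dictionary.
    b_values_ : ndarray
        The b-values actually used, in column order.
    design_matrix_ : ndarray of shape (m, n_atoms)
        ``exp(-b_i D_j)`` over the b > 0 rows.
    n_features_in_ : int

    Notes
    -----
    ``transform`` returns an ``(n_samples, 4)`` array with columns
    ``f_int`` (fraction), ``d_int`` (mm²/s, NaN when the intermediate
    range is empty), ``f_parenchymal`` and ``f_microvascular``.  Rows
    whose b0 mean is non-positive, or that contain non-finite values,
    come back all-NaN rather than aborting the batch.
    """

    def __init__(
        self,
        dictionary="lin200",
        b_values=None,
        normalize_fractions: bool = True,
        b0_row: bool = True,
    ):
        self.dictionary = dictionary
        self.b_values = b_values
        self.normalize_fractions = normalize_fractions
        self.b0_row = b0_row

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=0, ensure_all_finite=False)
        b = np.asarray(
            B_VALUES_CURRENT if self.b_values is None else self.b_values,
            dtype=float,
        )
        if b.ndim != 1 or b.size != X.shape[1]:
            raise ValueError(
                f"b_values has {b.size} entries but X has {X.shape[1]} columns"
            )
        if np.any(b < 0):
            raise ValueError("b_values must be non-negative")
        self.b_values_ = b
        self._b0_mask = b == 0
        self._pos_order = np.argsort(b[~self._b0_mask], kind="stable")
        self.dictionary_ = get_dictionary(self.dictionary)
        b_pos = b[~self._b0_mask][self._pos_order]
        if b_pos.size == 0:
            raise ValueError("at least one b > 0 column is required")
        if np.unique(b_pos).size != b_pos.size:
            raise ValueError(
                "duplicate b > 0 values; average repeated directions upstream"
            )
        self.design_matrix_ = build_design_matrix(b_pos, self.dictionary_)
        if self.b0_row:
            self._solve_matrix = np.vstack(
                [np.ones(self.dictionary_.n_atoms), self.design_matrix_]
            )
        else:
            self._solve_matrix = self.design_matrix_
        return self

    def _normalized_rows(self, X: np.ndarray) -> np.ndarray:
        """b0-normalized (n_samples, m) signal rows; invalid rows -> NaN."""
        pos = X[:, ~self._b0_mask][:, self._pos_order]
        if self._b0_mask.any():
            denom = X[:, self._b0_mask].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                pos = pos / denom[:, None]
            pos[denom <= 0] = np.nan
        return pos

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(
            self, X, reset=False, ensure_min_samples=0, ensure_all_finite=False
        )
        rows = self._normalized_rows(np.asarray(X, dtype=float))
        out = np.full((rows.shape[0], 4), np.nan)
        for i, row in enumerate(rows):
            spectrum = self._solve_row(row, identifier=i)
            if spectrum is None:
                continue
            res = extract_sda(spectrum, normalize=self.normalize_fractions)
            out[i] = res.as_tuple()
        return out

    def spectra(self, X) -> np.ndarray:
        """Full amplitude matrix, shape (n_samples, n_atoms); invalid rows NaN."""
        check_is_fitted(self)
        X = validate_data(
            self, X, reset=False, ensure_min_samples=0, ensure_all_finite=False
        )
        rows = self._normalized_rows(np.asarray(X, dtype=float))
        out = np.full((rows.shape[0], self.dictionary_.n_atoms), np.nan)
        for i, row in enumerate(rows):
            spectrum = self._solve_row(row, identifier=i)
            if spectrum is not None:
                out[i] = spectrum.amplitudes
        return out

    def _solve_row(self, row: np.ndarray, identifier) -> "Spectrum | None":
        if not np.all(np.isfinite(row)) or np.any(row < 0):
            return None
        target = np.concatenate([[1.0], row]) if self.b0_row else row
        try:
            amps, rnorm = scipy.optimize.nnls(self._solve_matrix, target)
        except RuntimeError as exc:
            raise NNLSConvergenceError(identifier) from exc
        return Spectrum(
            dictionary=self.dictionary_,
            amplitudes=amps,
            residual_norm=float(rnorm),
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray(FEATURE_NAMES, dtype=object)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.requires_fit = True
        return tags
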