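"""NNLS spectral fitting and marker extraction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specdiff import (
    B_VALUES_CURRENT,
    DecaySignal,
    Spectrum,
    build_design_matrix,
    extract_sda,
    fit_signal,
    nnls_solve,
)
from specdiff.dictionaries import (
    DiffusionDictionary,
    INTERMEDIATE,
    MICROVASCULAR,
    PARENCHYMAL,
)

B6 = np.array(B_VALUES_CURRENT)


def tiny_dictionary(atoms):
    from specdiff.dictionaries import classify_atoms

    atoms = np.asarray(atoms, dtype=float)
    return DiffusionDictionary(
        atoms=atoms, labels=classify_atoms(atoms), scheme="custom"
    )


def enumerate_nnls_objective(design, target):
    """Independent oracle: best feasible objective over all column supports.

    Solves the unconstrained least-squares problem on every subset of
    columns and keeps solutions with all coefficients >= 0; the global
    NNLS optimum is attained on one of these supports.
    """
    n = design.shape[1]
    best = float(np.dot(target, target))  # empty support: x = 0
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sub = design[:, support]
            coef, *_ = np.linalg.lstsq(sub, target, rcond=None)
            if np.all(coef >= -1e-13):
                resid = target - sub @ np.clip(coef, 0, None)
                best = min(best, float(resid @ resid))
    return best


class TestDecaySignal:
    def test_normalization_consumes_b0(self):
        sig = DecaySignal.from_acquisition(
            np.array([0.0, 1000.0]), np.array([1000.0, 368.0])
        )
        assert sig.m == 1
        assert sig.signals[0] == pytest.approx(0.368)

    def test_multiple_b0_volumes_averaged(self):
        sig = DecaySignal.from_acquisition(
            np.array([0.0, 0.0, 1000.0]), np.array([990.0, 1010.0, 500.0])
        )
        assert sig.signals[0] == pytest.approx(0.5)

    def test_b0_required(self):
        with pytest.raises(ValueError):
            DecaySignal.from_acquisition(np.array([50.0]), np.array([1.0]))

    def test_nonpositive_b0_rejected(self):
        with pytest.raises(ValueError):
            DecaySignal.from_acquisition(
                np.array([0.0, 1000.0]), np.array([0.0, 1.0])
            )

    def test_zero_b_rejected_directly(self):
        with pytest.raises(ValueError):
            DecaySignal(np.array([0.0, 1000.0]), np.array([1.0, 0.4]))


class TestDesignMatrix:
    def test_closed_form_entry(self):
        m = build_design_matrix(np.array([1000.0]), np.array([1.0e-3]))
        assert m[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_extreme_entries(self):
        m = build_design_matrix(
            np.array([50.0, 1000.0]), np.array([0.1e-3, 1000e-3])
        )
        expected = np.exp(
            -np.outer([50.0, 1000.0], [0.1e-3, 1000e-3])
        )
        assert np.allclose(m, expected, rtol=1e-12)
        assert m[0, 0] == pytest.approx(np.exp(-0.005), rel=1e-12)
        assert m[1, 1] == 0.0  # exp(-1000) underflows to zero

    def test_entries_bounded_by_one(self, lin200_dict):
        m = build_design_matrix(B6[1:], lin200_dict)
        assert np.all(m > 0) or np.any(m == 0)
        assert np.all(m <= 1.0)


class TestNNLS:
    def test_single_atom_recovery(self, lin200_dict):
        atom = lin200_dict.atom(100)  # an intermediate atom
        sig = DecaySignal.from_acquisition(B6, np.exp(-B6 * atom))
        spectrum = nnls_solve(sig, lin200_dict)
        assert spectrum.residual_norm < 1e-8
        res = extract_sda(spectrum)
        assert res.f_int == pytest.approx(1.0, abs=1e-6)
        assert res.f_parenchymal == pytest.approx(0.0, abs=1e-6)

    def test_zero_signal_gives_empty_spectrum(self, lin200_dict):
        # without the b0 row the origin is the NNLS optimum
        sig = DecaySignal(B6[1:], np.zeros(5))
        spectrum = nnls_solve(sig, lin200_dict, b0_row=False)
        assert np.all(spectrum.amplitudes == 0)
        res = extract_sda(spectrum)
        assert res.f_int == 0.0
        assert not res.valid_d_int

    def test_zero_signal_with_b0_row_has_no_intermediate_mass(self, lin200_dict):
        # the unit row pushes all mass to the fastest-decaying atoms
        sig = DecaySignal(B6[1:], np.zeros(5))
        res = extract_sda(nnls_solve(sig, lin200_dict))
        assert res.f_int == pytest.approx(0.0, abs=1e-9)
        assert not res.valid_d_int

    def test_flat_signal_concentrates_at_smallest_atoms(self):
        d = tiny_dictionary(np.geomspace(0.1e-3, 1000e-3, 10))
        sig = DecaySignal(B6[1:], np.ones(5))
        spectrum = nnls_solve(sig, d)
        # a non-decaying signal is best explained by the slowest atom,
        # and matches the exhaustive-support oracle on the same system
        assert np.argmax(spectrum.amplitudes) == 0
        design = np.vstack(
            [np.ones(10), build_design_matrix(B6[1:], d)]
        )
        target = np.concatenate([[1.0], np.ones(5)])
        oracle = enumerate_nnls_objective(design, target)
        assert spectrum.residual_norm**2 == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_objective_matches_support_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        atoms = np.sort(rng.uniform(0.2e-3, 900e-3, size=7))
        d = tiny_dictionary(atoms)
        b = np.sort(rng.uniform(10, 1000, size=5))
        target = rng.uniform(0, 1, size=5)
        sig = DecaySignal(b, target)
        spectrum = nnls_solve(sig, d, b0_row=False)
        oracle = enumerate_nnls_objective(
            build_design_matrix(b, d), target
        )
        assert spectrum.residual_norm**2 == pytest.approx(oracle, abs=1e-9)

    def test_noise_free_multi_atom_residual(self, lin200_dict):
        # signals built from up to 3 dictionary atoms refit exactly
        rng = np.random.default_rng(7)
        for _ in range(10):
            idx = rng.choice(200, size=3, replace=False)
            amps = rng.dirichlet(np.ones(3))
            signal = np.exp(-np.outer(B6, lin200_dict.atoms[idx])) @ amps
            sig = DecaySignal.from_acquisition(B6, signal)
            spectrum = nnls_solve(sig, lin200_dict)
            assert spectrum.residual_norm < 1e-8

    def test_determinism(self, lin200_dict, rng):
        raw = np.exp(-B6 * 2e-3) + rng.normal(0, 0.02, B6.size)
        raw = np.abs(raw)
        sig = DecaySignal.from_acquisition(B6, raw)
        a = nnls_solve(sig, lin200_dict)
        b = nnls_solve(sig, lin200_dict)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestExtractSDA:
    def three_component_spectrum(self, lin200_dict, amps_by_component):
        amplitudes = np.zeros(200)
        for component, (target_d, amp) in amps_by_component.items():
            mask = lin200_dict.component_mask(component)
            j = np.argmin(np.abs(lin200_dict.atoms[mask] - target_d))
            amplitudes[np.flatnonzero(mask)[j]] = amp
        return Spectrum(
            dictionary=lin200_dict, amplitudes=amplitudes, residual_norm=0.0
        )

    def test_healthy_white_matter_fractions(self, lin200_dict):
        spectrum = self.three_component_spectrum(
            lin200_dict,
            {
                PARENCHYMAL: (0.7e-3, 0.80),
                INTERMEDIATE: (2.0e-3, 0.15),
                MICROVASCULAR: (50e-3, 0.05),
            },
        )
        res = extract_sda(spectrum)
        assert res.f_int == pytest.approx(0.15, rel=1e-12)
        assert res.f_int_percent == pytest.approx(15.0, rel=1e-12)
        assert res.d_int == pytest.approx(2.0e-3, abs=2e-5)
        assert res.valid_d_int

    def test_empty_intermediate_range(self, lin200_dict):
        spectrum = self.three_component_spectrum(
            lin200_dict, {PARENCHYMAL: (0.7e-3, 1.0)}
        )
        res = extract_sda(spectrum)
        assert res.f_int == 0.0
        assert not res.valid_d_int
        assert np.isnan(res.d_int)

    def test_tie_breaks_to_lower_diffusivity(self, lin200_dict):
        amplitudes = np.zeros(200)
        int_idx = np.flatnonzero(lin200_dict.component_mask(INTERMEDIATE))
        amplitudes[int_idx[10]] = 0.5
        amplitudes[int_idx[20]] = 0.5
        spectrum = Spectrum(lin200_dict, amplitudes, 0.0)
        res = extract_sda(spectrum)
        assert res.d_int == pytest.approx(
            lin200_dict.atoms[int_idx[10]], rel=1e-12
        )

    def test_unnormalized_fractions_are_raw_sums(self, lin200_dict):
        amplitudes = np.zeros(200)
        int_idx = np.flatnonzero(lin200_dict.component_mask(INTERMEDIATE))
        amplitudes[int_idx[0]] = 0.4  # total amplitude 0.4, not 1
        spectrum = Spectrum(lin200_dict, amplitudes, 0.0)
        assert extract_sda(spectrum, normalize=False).f_int == pytest.approx(0.4)
        assert extract_sda(spectrum, normalize=True).f_int == pytest.approx(1.0)


@settings(max_examples=30, deadline=None)
@given(data=st.data())
def test_fractions_sum_to_one_for_nonempty_spectra(data):
    from specdiff import lin200

    d = lin200()
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n = data.draw(st.integers(1, 6))
    dcs = rng.uniform(0.1e-3, 900e-3, size=n)
    amps = rng.dirichlet(np.ones(n))
    signal = np.exp(-np.outer(B6, dcs)) @ amps
    noisy = np.abs(signal + rng.normal(0, 0.02, B6.size))
    sig = DecaySignal.from_acquisition(B6, noisy)
    res = fit_signal(sig, d)
    total = res.f_int + res.f_parenchymal + res.f_microvascular
    assert total == pytest.approx(1.0, abs=1e-9) or total == 0.0
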