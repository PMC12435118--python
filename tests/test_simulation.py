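"""Monte-Carlo ground-truth generation, noise model and grid bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from specdiff import (
    CompartmentSet,
    FitCondition,
    SimulationGrid,
    add_rician_noise,
    default_conditions,
    ground_truth_sda,
    run_grid,
    sample_compartments,
    synthesize_signal,
)
from specdiff.dictionaries import DEFAULT_RANGES
from specdiff.simulation import default_noise_levels


class TestCompartmentSampling:
    def test_equal_component_probability(self, rng):
        r = DEFAULT_RANGES
        counts = {"par": 0, "int": 0, "mic": 0}
        draws = 30_000
        for _ in range(draws):
            dc = sample_compartments(1, rng).dcs[0]
            if dc < r.intermediate_lower:
                counts["par"] += 1
            elif dc <= r.intermediate_upper:
                counts["int"] += 1
            else:
                counts["mic"] += 1
        for share in counts.values():
            assert share / draws == pytest.approx(1 / 3, abs=0.01)

    def test_single_compartment_amplitude(self, rng):
        assert sample_compartments(1, rng).amps[0] == 1.0

    def test_dcs_within_global_range(self, rng):
        for n in (1, 5, 50):
            cs = sample_compartments(n, rng)
            assert cs.dcs.min() >= 0.1e-3 and cs.dcs.max() <= 1000e-3

    @pytest.mark.parametrize("law", ["uniform_normalized", "dirichlet"])
    def test_amplitudes_sum_to_one(self, rng, law):
        for n in (1, 3, 20, 50):
            cs = sample_compartments(n, rng, amplitude_law=law)
            assert abs(cs.amps.sum() - 1.0) <= 1e-12

    def test_unknown_law_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_compartments(3, rng, amplitude_law="exponential")


class TestSignalSynthesis:
    def test_single_compartment_closed_form(self):
        cs = CompartmentSet(dcs=np.array([1.0e-3]), amps=np.array([1.0]))
        assert synthesize_signal(cs, [1000.0])[0] == pytest.approx(
            np.exp(-1.0), rel=1e-12
        )

    def test_b0_signal_is_unity(self, rng):
        cs = sample_compartments(10, rng)
        assert synthesize_signal(cs, [0.0])[0] == pytest.approx(1.0, abs=1e-12)

    def test_three_compartment_value(self):
        # periventricular-hyperintensity-like fractions 0.45/0.50/0.05
        cs = CompartmentSet(
            dcs=np.array([0.7e-3, 2.5e-3, 50e-3]),
            amps=np.array([0.45, 0.50, 0.05]),
        )
        expected = (
            0.45 * np.exp(-0.35) + 0.50 * np.exp(-1.25) + 0.05 * np.exp(-25.0)
        )
        assert synthesize_signal(cs, [500.0])[0] == pytest.approx(
            expected, rel=1e-12
        )


class TestRicianNoise:
    def test_zero_sd_is_identity(self, rng):
        s = np.array([1.0, 0.5, 0.1])
        assert np.array_equal(add_rician_noise(s, 0.0, rng), s)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -0.01, rng)

    def test_rayleigh_mean_at_zero_signal(self, rng):
        sd = 0.04
        draws = add_rician_noise(np.zeros(100_000), sd, rng)
        assert draws.mean() == pytest.approx(sd * np.sqrt(np.pi / 2), rel=0.02)

    def test_rice_mean_at_high_snr(self, rng):
        # E|s + noise| ~ s + sd^2/(2 s) for s >> sd
        sd = 0.01
        draws = add_rician_noise(np.ones(100_000), sd, rng)
        assert draws.mean() == pytest.approx(1.0 + sd**2 / 2, abs=1e-3)

    def test_output_is_nonnegative(self, rng):
        assert np.all(add_rician_noise(np.zeros(1000), 0.5, rng) >= 0)


class TestGroundTruth:
    def test_healthy_white_matter_example(self):
        cs = CompartmentSet(
            dcs=np.array([0.7e-3, 2.5e-3, 50e-3]),
            amps=np.array([0.80, 0.15, 0.05]),
        )
        gt = ground_truth_sda(cs)
        assert gt.f_int == pytest.approx(0.15, rel=1e-12)
        assert gt.d_int == pytest.approx(2.5e-3, rel=1e-12)

    def test_all_parenchymal_has_no_d_int(self):
        cs = CompartmentSet(
            dcs=np.array([0.5e-3, 1.0e-3]), amps=np.array([0.5, 0.5])
        )
        gt = ground_truth_sda(cs)
        assert gt.f_int == 0.0
        assert not gt.valid_d_int

    def test_max_amplitude_rule(self):
        cs = CompartmentSet(
            dcs=np.array([2e-3, 3e-3]), amps=np.array([0.6, 0.4])
        )
        gt = ground_truth_sda(cs)
        assert gt.f_int == pytest.approx(1.0)
        assert gt.d_int == pytest.approx(2e-3)

    def test_boundaries_are_inclusive(self):
        cs = CompartmentSet(
            dcs=np.array([1.5e-3, 4.0e-3]), amps=np.array([0.3, 0.7])
        )
        assert ground_truth_sda(cs).f_int == pytest.approx(1.0)


class TestGrid:
    def test_default_grid_enumerates_full_study(self):
        grid = SimulationGrid()
        assert grid.total_patterns == 2_500_000
        assert len(grid.n_range) == 50
        assert grid.patterns_per_n == 1000
        assert len(grid.noise_levels) == 50
        assert grid.noise_levels[0] == 0.0
        assert grid.noise_levels[-1] == pytest.approx(0.05)

    def test_default_conditions_are_the_three_study_arms(self):
        conds = default_conditions()
        names = [c.name for c in conds]
        assert names == ["lin200_6b", "log200_6b", "log200_15b"]
        assert len(conds[0].b_values) == 6
        assert len(conds[2].b_values) == 15
        assert conds[2].b_values[:5] == (0.0, 5.0, 7.0, 10.0, 15.0)

    def small_grid(self):
        return SimulationGrid(
            n_range=(1, 2, 3),
            patterns_per_n=4,
            noise_levels=tuple(default_noise_levels(2)),
        )

    def test_record_count_is_grid_product(self, lin200_dict):
        grid = self.small_grid()
        cond = [FitCondition.make("lin", (0, 50, 100, 250, 500, 1000), lin200_dict)]
        records = run_grid(grid, cond, seed=5)
        assert len(records) == grid.total_patterns == 3 * 4 * 2

    def test_same_seed_reproduces_records(self, lin200_dict):
        grid = self.small_grid()
        cond = [FitCondition.make("lin", (0, 50, 100, 250, 500, 1000), lin200_dict)]
        a = run_grid(grid, cond, seed=11)
        b = run_grid(grid, cond, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_records(self, lin200_dict):
        grid = self.small_grid()
        cond = [FitCondition.make("lin", (0, 50, 100, 250, 500, 1000), lin200_dict)]
        a = run_grid(grid, cond, seed=11)
        b = run_grid(grid, cond, seed=12)
        assert not np.allclose(a["gt_f_int"], b["gt_f_int"])

    def test_ground_truth_shared_across_conditions(self, lin200_dict, log200_dict):
        grid = self.small_grid()
        conds = [
            FitCondition.make("lin", (0, 50, 100, 250, 500, 1000), lin200_dict),
            FitCondition.make("log", (0, 50, 100, 250, 500, 1000), log200_dict),
        ]
        rec = run_grid(grid, conds, seed=3)
        lin = rec[rec["condition"] == "lin"].reset_index(drop=True)
        log = rec[rec["condition"] == "log"].reset_index(drop=True)
        pd.testing.assert_series_equal(lin["gt_f_int"], log["gt_f_int"])

    def test_streaming_matches_in_memory(self, tmp_path, lin200_dict):
        grid = self.small_grid()
        cond = [FitCondition.make("lin", (0, 50, 100, 250, 500, 1000), lin200_dict)]
        in_mem = run_grid(grid, cond, seed=2)
        path = run_grid(grid, cond, seed=2, out=tmp_path / "records.csv")
        streamed = pd.read_csv(path)
        assert np.allclose(streamed["est_f_int"], in_mem["est_f_int"])

    def test_zero_noise_on_dictionary_truth_recovers_exactly(self, lin200_dict):
        # single-atom ground truth taken from the fitting dictionary
        atom = lin200_dict.atom(90)
        cs = CompartmentSet(dcs=np.array([atom]), amps=np.array([1.0]))
        b = np.array((0, 50, 100, 250, 500, 1000), dtype=float)
        from specdiff import DecaySignal, fit_signal

        sig = DecaySignal.from_acquisition(b, synthesize_signal(cs, b))
        est = fit_signal(sig, lin200_dict)
        gt = ground_truth_sda(cs)
        assert est.f_int == pytest.approx(gt.f_int, abs=1e-6)
        assert est.d_int == pytest.approx(gt.d_int, rel=1e-9)
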