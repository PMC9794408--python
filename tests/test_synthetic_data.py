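"""Generator contracts: ground-truth identities, seeding, preconditions."""

from dataclasses import replace

import numpy as np
import pytest

from phycoflux.kinetics import CompartmentModel, predict_surface
from phycoflux.optics import baseline_correct, reflectance_to_absorbance
from phycoflux.synthetic_data import (
    GroundTruth,
    default_treatment_grid,
    simulate_excitation_spectrum,
    simulate_reflectance,
    simulate_rlc,
    simulate_surface,
)


class TestGroundTruth:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(noise_scale=-0.1)
        with pytest.raises(ValueError):
            GroundTruth(pigment_bands=[(440.0, 0.0, 0.5)])
        with pytest.raises(ValueError):
            GroundTruth(rlc_truth=(-0.1, 6.0))
        with pytest.raises(ValueError):
            GroundTruth(treatment_grid=[(100.0, "shallow")])
        with pytest.raises(ValueError):
            GroundTruth(treatment_grid=[(350.0, "abyssal")])

    def test_default_grid_is_the_crossed_design(self):
        grid = default_treatment_grid()
        assert len(grid) == 9
        assert grid.count((350.0, "shallow+red")) == 1
        assert all(i in (350.0, 80.0, 20.0, 2.5) for i, _ in grid)


class TestSurface:
    def test_zero_noise_equals_forward_model(self, truth, grids):
        t, w = grids
        clean_truth = replace(truth, noise_scale=0.0)
        noisy, clean = simulate_surface(clean_truth, t, w)
        expected = predict_surface(truth.model, truth.amplitudes(w), t, w)
        np.testing.assert_array_equal(noisy.intensity, expected.intensity)
        np.testing.assert_array_equal(clean.intensity, expected.intensity)

    def test_decoupled_cascade_is_single_exponential(self, grids):
        t, w = grids
        # transfer switched off (huge tau_ab), only an A band: every trace
        # is the A natural decay convolved with the IRF, all proportional
        huge = 1e15
        truth = GroundTruth(
            model=CompartmentModel(tau_ab=huge, tau_bc=huge, tau_da=1000.0),
            compartment_bands={"A": [(585.0, 40.0, 1.0)], "B": [], "C": []},
            noise_scale=0.0,
        )
        _, clean = simulate_surface(truth, t, w)
        ref = clean.intensity[:, np.argmax(clean.intensity.max(axis=0))]
        late = t > 50.0
        for j in range(0, w.size, 10):
            col = clean.intensity[:, j]
            if col.max() > 1e-6:
                ratio = col[late] / ref[late]
                assert np.ptp(ratio) < 1e-9 * ratio.mean() + 1e-12
        decay = np.log(ref[late])
        slope = np.polyfit(t[late], decay, 1)[0]
        assert -1.0 / slope == pytest.approx(1000.0, rel=1e-3)

    def test_seed_reproducibility(self, truth, grids):
        t, w = grids
        a, _ = simulate_surface(truth, t, w)
        b, _ = simulate_surface(truth, t, w)
        c, _ = simulate_surface(replace(truth, seed=truth.seed + 1), t, w)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_substreams_differ_per_sample(self, truth, grids):
        t, w = grids
        a, _ = simulate_surface(truth, t, w, sample=0)
        b, _ = simulate_surface(truth, t, w, sample=1)
        assert not np.array_equal(a.intensity, b.intensity)

    def test_noise_scales_with_sqrt_signal(self, truth, grids):
        t, w = grids
        resid = []
        for s in range(12):
            noisy, clean = simulate_surface(replace(truth, seed=s), t, w)
            resid.append(noisy.intensity - clean.intensity)
        resid = np.stack(resid)
        _, clean = simulate_surface(truth, t, w)
        bright = clean.intensity > 0.5
        dim = np.abs(clean.intensity) < truth.noise_floor
        sd_bright = resid[:, bright].std()
        expected_bright = truth.noise_scale * np.sqrt(clean.intensity[bright].mean())
        assert sd_bright == pytest.approx(expected_bright, rel=0.1)
        assert resid[:, dim].std() == pytest.approx(
            truth.noise_scale * np.sqrt(truth.noise_floor), rel=0.1
        )

    def test_non_monotonic_grid_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_surface(truth, np.array([0.0, 2.0, 1.0]), np.arange(550.0, 761.0, 2.0))


class TestReflectance:
    def test_no_bands_no_offset_gives_unit_reflectance(self, grids):
        truth = GroundTruth(pigment_bands=[], pigment_offset=0.0)
        grid = np.arange(400.0, 801.0, 1.0)
        r = simulate_reflectance(truth, grid)
        np.testing.assert_array_equal(r.value, np.ones_like(grid))

    def test_single_band_survives_baseline_round_trip(self):
        truth = GroundTruth(pigment_bands=[(565.0, 20.0, 0.45)], pigment_offset=0.2)
        grid = np.arange(400.0, 801.0, 1.0)
        corrected = baseline_correct(reflectance_to_absorbance(simulate_reflectance(truth, grid)))
        assert corrected.at(565.0) == pytest.approx(0.45, abs=1e-9)

    def test_chlorophyll_band_peaks_at_680(self, truth):
        grid = np.arange(400.0, 801.0, 1.0)
        d = reflectance_to_absorbance(simulate_reflectance(truth, grid))
        window = (grid >= 650.0) & (grid <= 700.0)
        assert grid[window][np.argmax(d.value[window])] == 680.0


class TestRLC:
    def test_dark_step_finite_yield_zero_etr(self, truth):
        table = simulate_rlc(replace(truth, rlc_noise_sd=0.0))
        assert np.isfinite(table.yield_[0])
        assert table.etr_values()[0] == 0.0

    def test_noiseless_yields_invert_the_etr_formula(self, truth):
        table = simulate_rlc(replace(truth, rlc_noise_sd=0.0))
        alpha, etr_max = truth.rlc_truth
        e = table.irradiance[1:]
        expected = etr_max * np.tanh(alpha * e / etr_max)
        np.testing.assert_allclose(table.etr_values()[1:], expected, rtol=1e-12)

    def test_negative_steps_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_rlc(truth, steps=np.array([-10.0, 0.0, 60.0]))


class TestExcitationSpectrum:
    def test_normalised_at_570(self, truth):
        grid = np.arange(450.0, 651.0, 1.0)
        spec = simulate_excitation_spectrum(truth, grid)
        assert spec.at(570.0) == 1.0

    def test_zero_pcb_leaves_only_band_leakage_at_620(self, truth):
        grid = np.arange(450.0, 651.0, 1.0)
        weights = dict(truth.excitation_weights, pcb=0.0)
        spec = simulate_excitation_spectrum(replace(truth, excitation_weights=weights), grid)
        # the direct-chlorophyll term is 30/70 of the PCB term, so it
        # vanishes with it; what is left at 620 nm is the PEB band tail
        assert spec.at(620.0) < 0.02 * spec.at(565.0)

    def test_generated_tables_pass_consumer_preconditions(self, truth, grids):
        from phycoflux import eet, pam

        grid = np.arange(450.0, 651.0, 1.0)
        spec = simulate_excitation_spectrum(truth, grid)
        eet.eet_readout(eet.normalise_excitation(spec))  # should not raise
        pam.fit_rlc(simulate_rlc(truth))  # should not raise
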