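"""Optics, dispersion, detection and dataset generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mweauc.hydro import RotorProtocol, SolventModel, Species
from mweauc.instrument import (
    GRATINGS,
    CalibrationDisk,
    InstrumentModel,
    NoiseOptions,
    confocal_geometry,
    detect,
    disperse_spectrum,
    emission_escape,
    excitation_profile,
    rayleigh_length,
    simulate_calibration_scan,
    simulate_sv_dataset,
    simulate_zscan,
)


class TestConfocalGeometry:
    def test_spot_ratio_200_vs_50_is_exactly_four(self):
        spot200, _ = confocal_geometry(200.0)
        spot50, _ = confocal_geometry(50.0)
        assert spot200 / spot50 == 4.0
        assert spot200 == 135.0

    def test_depth_anchored_at_printed_pairs(self):
        assert confocal_geometry(50.0)[1] == pytest.approx(0.7)
        assert confocal_geometry(200.0)[1] == pytest.approx(1.5)
        # linear interpolation between the anchors (warns: uncharacterized)
        with pytest.warns(UserWarning):
            assert confocal_geometry(125.0)[1] == pytest.approx(1.1)

    def test_nonpositive_core_rejected_and_odd_core_warns(self):
        with pytest.raises(ValueError):
            confocal_geometry(0.0)
        with pytest.warns(UserWarning, match="characterized"):
            confocal_geometry(100.0)


class TestRayleighLength:
    def test_printed_beam_gives_about_two_mm(self):
        z = rayleigh_length(35.0, 520.0)
        assert z == pytest.approx(np.pi * 17.5e-3 ** 2 / 520e-6, rel=1e-12)
        assert 1.5 < z < 2.5  # the instrument quotes ~2 mm

    def test_quadratic_waist_and_inverse_wavelength_scaling(self):
        z = rayleigh_length(35.0, 520.0)
        assert rayleigh_length(70.0, 520.0) == pytest.approx(4 * z)
        assert rayleigh_length(35.0, 1040.0) == pytest.approx(z / 2)


class TestInnerFilter:
    def test_no_attenuation_when_eps_zero(self):
        z = np.linspace(0.0, 3.0, 31)
        assert np.allclose(excitation_profile(z, 1.0, 0.0), 1.0)
        assert np.allclose(emission_escape(z, 540.0, 1.0, 0.0), 1.0)

    def test_beer_lambert_closed_form(self):
        # uniform c with eps*c*(0.3 cm path) = 1 -> I(bottom) = 0.1
        z = np.linspace(0.0, 3.0, 601)  # mm
        eps, c = 1.0 / 0.3, 1.0
        prof = excitation_profile(z, c, eps)
        assert prof[0] == 1.0
        assert prof[-1] == pytest.approx(0.1, rel=1e-4)
        esc = emission_escape(z, 460.0, c, lambda lam: eps)
        assert esc[-1] == pytest.approx(0.1, rel=1e-4)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 5.0), min_size=5, max_size=30))
    def test_excitation_monotone_nonincreasing(self, conc):
        z = np.linspace(0.0, 3.0, len(conc))
        prof = excitation_profile(z, np.asarray(conc), 0.7)
        assert np.all(np.diff(prof) <= 1e-12)

    def test_negative_inputs_rejected(self):
        z = np.linspace(0.0, 3.0, 5)
        with pytest.raises(ValueError):
            excitation_profile(z, 1.0, -0.1)
        with pytest.raises(ValueError):
            excitation_profile(z, -1.0, 0.1)


class TestZScan:
    def make_dye(self, c0, eps_exc=0.0):
        return Species.gaussian_emitter("c153", s=0.05, lam_max=540.0,
                                        fwhm_nm=60.0, c0=c0, ff0=1.0,
                                        vbar=0.8, eps_exc=eps_exc)

    def test_dilute_profile_symmetric_about_cell_centre(self,
                                                        default_instrument):
        z = np.arange(9.5, 16.5, 0.05)
        zs = simulate_zscan(self.make_dye(1.0), default_instrument, z)
        y = zs.counts.astype(float).sum(axis=1)
        centre = default_instrument.cell_face_z_mm + \
            default_instrument.z_vacuum_shift_mm + 1.5
        top = np.nonzero(y >= 0.98 * y.max())[0]
        peak = 0.5 * (zs.z_mm[top[0]] + zs.z_mm[top[-1]])
        assert abs(peak - centre) < 0.2
        # asymmetry of the noiseless profile about its peak is tiny
        left = np.interp(peak - 1.0, zs.z_mm, y)
        right = np.interp(peak + 1.0, zs.z_mm, y)
        assert left == pytest.approx(right, rel=0.02)

    def test_concentrated_peak_shifts_toward_incident_face(
            self, default_instrument):
        z = np.arange(9.5, 16.5, 0.05)
        # eps_exc * c0 * cell depth (0.3 cm) >> 1: strong primary inner filter
        zs = simulate_zscan(self.make_dye(1.0, eps_exc=10.0),
                            default_instrument, z)
        y = zs.counts.astype(float).sum(axis=1)
        centre = default_instrument.cell_face_z_mm + \
            default_instrument.z_vacuum_shift_mm + 1.5
        peak = zs.z_mm[np.argmax(y)]
        assert peak < centre - 0.4  # displaced toward the incident window

    def test_zero_concentration_flat_offset_only(self, default_instrument):
        z = np.arange(10.0, 16.0, 0.1)
        zs = simulate_zscan(self.make_dye(0.0), default_instrument, z)
        assert np.all(zs.counts == default_instrument.adc_offset_counts)

    def test_vacuum_shift_moves_profile_by_two_mm(self, default_instrument):
        z = np.arange(8.0, 17.0, 0.05)
        dye = self.make_dye(1.0)
        air = simulate_zscan(dye, default_instrument, z, in_vacuum=False)
        vac = simulate_zscan(dye, default_instrument, z, in_vacuum=True)
        pa = air.z_mm[np.argmax(air.counts.sum(axis=1))]
        pv = vac.z_mm[np.argmax(vac.counts.sum(axis=1))]
        assert pv - pa == pytest.approx(
            default_instrument.z_vacuum_shift_mm, abs=0.1)


class TestDispersion:
    def test_delta_line_fwhm_matches_grating_resolution(self):
        for grating, (lo, hi, res) in GRATINGS.items():
            inst = InstrumentModel(grating_lmm=grating)
            centre = 0.5 * (lo + hi)
            lam = np.linspace(centre - 5, centre + 5, 4001)
            sigma_in = 0.005  # effectively a delta line
            dens = np.exp(-0.5 * ((lam - centre) / sigma_in) ** 2)
            dens /= np.trapezoid(dens, lam)
            px = disperse_spectrum(lam, dens, inst)
            grid = inst.wavelength_grid()
            half = px.max() / 2.0
            above = grid[px >= half]
            fwhm = above[-1] - above[0] + inst.nm_per_pixel
            assert fwhm == pytest.approx(res, rel=0.15)

    def test_total_signal_conserved_by_dispersion(self):
        inst = InstrumentModel()
        lam = np.linspace(500.0, 700.0, 1001)
        dens = np.exp(-0.5 * ((lam - 600.0) / 30.0) ** 2)
        total = np.trapezoid(dens, lam)
        px = disperse_spectrum(lam, dens, inst)
        assert px.sum() == pytest.approx(total, rel=1e-6)

    def test_grating_600_window_is_printed_span(self):
        inst = InstrumentModel(grating_lmm=600)
        assert inst.window_nm == (515.0, 643.0)
        assert inst.resolution_nm == 0.51

    def test_out_of_window_spectrum_truncated_with_warning(self):
        inst = InstrumentModel(grating_lmm=600)
        lam = np.linspace(300.0, 700.0, 2001)
        dens = np.ones_like(lam) / 400.0
        with pytest.warns(UserWarning, match="truncated"):
            px = disperse_spectrum(lam, dens, inst)
        assert px.sum() < 1.0


class TestDetect:
    def test_zero_signal_mean_offset_and_read_noise_sd(self, rng):
        inst = InstrumentModel()
        counts = detect(np.zeros(200_000), inst, rng).astype(float)
        assert counts.mean() == pytest.approx(inst.adc_offset_counts, abs=0.1)
        # quantization adds 1/12 variance to the read noise
        expected_sd = np.sqrt(inst.read_noise_e ** 2 + 1.0 / 12.0)
        assert counts.std() == pytest.approx(expected_sd, rel=0.02)

    def test_snr_at_1e4_electrons_matches_monte_carlo_oracle(self, rng):
        inst = InstrumentModel()
        counts = detect(np.full(100_000, 10_000.0), inst, rng).astype(float)
        sig = counts - inst.adc_offset_counts
        snr = sig.mean() / sig.std()
        assert snr == pytest.approx(10_000.0 / np.sqrt(10_049.0), rel=0.02)

    def test_saturation_clips_to_16_bit_ceiling(self, rng):
        inst = InstrumentModel()
        counts = detect(np.full(100, 1e7), inst, rng)
        assert np.all(counts == 65535)

    def test_noiseless_mode_returns_linear_mean(self):
        inst = InstrumentModel(adc_gain_e_per_count=4.0)
        out = detect(np.asarray([0.0, 400.0, 4000.0]), inst, None)
        assert np.allclose(out, [100.0, 200.0, 1100.0])

    @settings(deadline=None, max_examples=20)
    @given(st.floats(0.0, 1e6))
    def test_counts_always_in_adc_range(self, expected):
        inst = InstrumentModel()
        counts = detect(np.full(64, expected), inst,
                        np.random.default_rng(0))
        assert counts.min() >= 0 and counts.max() <= 65535


class TestSvDataset:
    def test_same_seed_bit_identical(self, analysis_solvent):
        sp = Species.gaussian_emitter("g", s=4.0, lam_max=550.0, fwhm_nm=40.0)
        protocol = RotorProtocol(n_scans=3, scan_interval_s=2000.0)
        inst = InstrumentModel(sensor_pixels=400)
        a = simulate_sv_dataset([sp], analysis_solvent, protocol, inst,
                                NoiseOptions(), seed=7)
        b = simulate_sv_dataset([sp], analysis_solvent, protocol, inst,
                                NoiseOptions(), seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_sv_dataset([sp], analysis_solvent, protocol, inst,
                                NoiseOptions(), seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_noise_free_counts_proportional_to_profile_times_spectrum(
            self, analysis_solvent):
        from mweauc.hydro import solve_lamm
        from mweauc.instrument import _apply_radial_psf

        sp = Species.gaussian_emitter("g", s=4.0, lam_max=550.0, fwhm_nm=40.0)
        protocol = RotorProtocol(n_scans=2, scan_interval_s=3000.0,
                                 bottom_cm=7.0)
        inst = InstrumentModel(sensor_pixels=400, adc_gain_e_per_count=4.0)
        ds = simulate_sv_dataset([sp], analysis_solvent, protocol, inst,
                                 NoiseOptions(detector=False), seed=0)
        sol = solve_lamm(sp, analysis_solvent, protocol, ds.times_s)
        spec = disperse_spectrum(sp.emission_nm, sp.emission_density, inst)
        k, j = 1, int(np.argmax(spec))
        prof = np.interp(ds.radius_cm, sol.radii,
                         _apply_radial_psf(sol.radii, sol.profiles[k], inst))
        expected = (inst.photon_budget * inst.exposure_ms * prof * spec[j]
                    / inst.adc_gain_e_per_count + inst.adc_offset_counts)
        inner = slice(5, 180)  # away from meniscus/bottom
        assert np.allclose(ds.counts[k, inner, j],
                           np.clip(np.rint(expected[inner]), 0, 65535),
                           atol=1.0)

    def test_injected_ti_ri_recorded_as_ground_truth(self, analysis_solvent):
        sp = Species.gaussian_emitter("g", s=4.0, lam_max=550.0, fwhm_nm=40.0)
        protocol = RotorProtocol(n_scans=4, scan_interval_s=2000.0)
        inst = InstrumentModel(sensor_pixels=200)
        noise = NoiseOptions(ti_amplitude=0.02, ri_amplitude=0.01)
        ds = simulate_sv_dataset([sp], analysis_solvent, protocol, inst,
                                 noise, seed=3)
        gt = ds.ground_truth
        assert gt["seed"] == 3
        assert np.asarray(gt["ti_profile"]).shape == ds.radius_cm.shape
        assert np.asarray(gt["ri_offsets"]).shape == ds.times_s.shape
        assert np.asarray(gt["ti_profile"]).any()

    def test_signal_invariant_under_speed_at_constant_duty_cycle(
            self, analysis_solvent):
        # signal amplitude depends on exposure, not rotor speed
        sp = Species.gaussian_emitter("g", s=0.05, lam_max=550.0, fwhm_nm=40.0)
        inst = InstrumentModel(sensor_pixels=200, adc_gain_e_per_count=4.0)
        out = []
        for rpm in (5_000.0, 40_000.0):
            protocol = RotorProtocol(speed_rpm=rpm, n_scans=1,
                                     scan_interval_s=10.0)
            ds = simulate_sv_dataset([sp], analysis_solvent, protocol, inst,
                                     NoiseOptions(detector=False), seed=0)
            out.append(ds.signal()[0, 50, :].sum())
        assert out[0] == pytest.approx(out[1], rel=1e-3)


class TestCalibrationScan:
    def test_edges_at_layout_positions_when_uncalibrated_error_zero(self):
        disk = CalibrationDisk()
        inst = InstrumentModel()
        scan = simulate_calibration_scan(disk, inst)
        prof = scan.counts[:, 0].astype(float)
        level = prof.min() + 0.5 * (prof.max() - prof.min())
        above = prof >= level
        crossings = np.nonzero(np.diff(above.astype(int)) != 0)[0]
        edges = disk.edges()
        assert crossings.size == edges.size
        for i, e in zip(crossings, edges):
            # crossing bracket contains the true edge within half a step
            assert abs(scan.radius_cm[i] - e) < 0.011

    def test_edge_blur_width_matches_convolution_oracle(self):
        from mweauc.qc import edge_response_width
        from scipy.special import ndtr

        inst = InstrumentModel()
        disk = CalibrationDisk(gaps_cm=((6.4, 7.0),))
        radii = np.arange(6.1, 6.75, 50e-4)
        scan = simulate_calibration_scan(disk, inst, radii_cm=radii)
        w = edge_response_width(scan.radius_cm, scan.counts[:, 0].astype(float))
        # oracle: 10-90 width of the step convolved with the excitation
        # Gaussian (FWHM = spot diameter), computed from the erf closed form
        sigma_um = inst.laser_spot_diameter_um / 2.354820045
        x = np.linspace(-200, 200, 20001)
        y = ndtr(x / sigma_um)
        w_oracle = (x[y >= 0.9][0] - x[y >= 0.1][0])
        assert w == pytest.approx(w_oracle, rel=0.05)
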