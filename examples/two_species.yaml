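# Reference two-species nanocluster run: 3.4 S / 3.9 S compact spheres with
# near-infrared emission at 800 / 705 nm, 405 nm excitation, 40 000 rpm.
# The scan schedule spans the same rotor time as a full run with fewer scans.
species:
  - {name: aunc-3.4S, s: 3.4, lambda_max_nm: 800, fwhm_nm: 70, ff0: 1.0,
     vbar: 0.547}
  - {name: aunc-3.9S, s: 3.9, lambda_max_nm: 705, fwhm_nm: 70, ff0: 1.0,
     vbar: 0.547}
solvent: {density: 1.0, viscosity: 1.002, temperature: 293.15}
protocol: {speed_rpm: 40000, meniscus_cm: 6.0, bottom_cm: 7.2,
           n_scans: 60, scan_interval_s: 450}
instrument: {laser_nm: 405, photon_budget: 100000, adc_gain_e_per_count: 4,
             exposure_ms: 100}
fit: {s_min: 1.0, s_max: 10.0, n_s: 150, ff0: 1.0, vbar: 0.547,
      regularization: second_derivative, wavelength_step_nm: 3.0,
      window_lo_nm: 640, window_hi_nm: 900, window_hi_cm: 7.0}
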