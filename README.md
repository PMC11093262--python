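# mweauc

Simulation and analysis of **multiwavelength fluorescence-emission
analytical ultracentrifugation** (MWE-AUC) data.

Sedimentation-velocity AUC measures how fast macromolecules and
nanoparticles move in a centrifugal field; a fluorescence-emission detector
with a spectrograph and EMCCD camera additionally resolves the *emission
spectrum* of everything that sediments.  The joint observable — a
2D distribution of sedimentation coefficient *s* against emission
wavelength λ — separates species that overlap in either dimension alone,
e.g. gold nanoclusters whose size-dependent photoluminescence shifts with
their sedimentation coefficient.

The package is aimed at developers and users of such instruments: it
provides a physics-based forward simulator of the detector (so analysis
software can be validated against known ground truth) and the matching
analysis chain.

## What is inside

* **`mweauc.hydro`** — species hydrodynamics and a conservative
  finite-volume Lamm-equation solver (Scharfetter–Gummel fluxes, implicit
  time stepping) for the sedimentation–diffusion transport
  `∂c/∂t = (1/r) ∂/∂r [ r (D ∂c/∂r − s ω² r² c) ]`
  in sector geometry, plus the closed forms used as oracles
  (Svedberg relation, `r(t) = r_m·exp(s ω² t)`, square-dilution rule).
* **`mweauc.instrument`** — the synthetic-data generator: confocal
  collection geometry (fibre core → spot size/confocal depth), primary and
  secondary inner-filter attenuation (Beer–Lambert along the optical
  axis), grating dispersion onto a 1600-pixel sensor, and EMCCD detection
  `counts = clip(round((Poisson(N_e) + N(0, σ_read))/gain) + offset, 0, 2¹⁶−1)`.
* **`mweauc.cs`** — per-wavelength regularized c(s) inversion,
  statsmodels-style: `CsModel(y, radii, times, …).fit()` returns a
  `CsDistribution` with nonnegative amplitudes on a 150-point log-spaced
  s grid, algebraically eliminated time-invariant (TI) and radial-invariant
  (RI) noise, and a penalty weight chosen by the one-sided F-statistic
  bound at confidence 0.683.  Second-derivative and maximum-entropy
  regularizers; meniscus, f/f₀ or v̄ can be floated.
* **`mweauc.mwl`** — `MultiWavelengthModel.fit()` assembles consecutive
  per-wavelength c(s) fits (default step 1.5 nm) into a `C2D`
  distribution; `extract_species` finds (s, λ_max) ridges;
  `global_species_fit` refines K discrete species shared across selected
  wavelengths by variable projection.
* **`mweauc.qc`** — instrument QC: radial calibration against a gap-disk
  layout, z-scan inner-filter assessment, SNR-regime characterization,
  linear dynamic range, edge-response (radial resolution) and
  spectral-band-integration gain.
* **`mweauc.io` / `mweauc.cli` / `mweauc.config`** — text scan files,
  HDF5 run containers with ground-truth sidecars, strict YAML
  configuration, and a `mweauc` command line
  (`simulate | calibrate | zscan | cs | mwl2d | species | snr | qc-report`).

## Worked example

Simulate the reference two-species nanocluster run (3.4 S and 3.9 S,
emission maxima 800 nm and 705 nm, 405 nm excitation, 40 000 rpm) and
recover both species from the 2D analysis:

```python
from mweauc.presets import aunc_two_species_run, aunc_fit_config
from mweauc.mwl import MultiWavelengthModel

ds, species, solvent, protocol, instrument = aunc_two_species_run(seed=2)
model = MultiWavelengthModel(ds, protocol, solvent, aunc_fit_config())
c2d = model.fit(wavelength_step_nm=3.0, window_nm=(640.0, 900.0))
print(c2d.summary())
```

prints

```
2D sedimentation-wavelength distribution
======================================================
  s grid      : 150 points, 1-10 S
  wavelengths : 87 steps, 641.5-899.5 nm
  shared vbar/ff0 : 0.5470 / 1.000
  median rmsd : 0.0013871 (rescaled units)
  species (>=5% of max, lambda-integrated):
    s =   3.421 S   lambda_max =  799.3 nm   abundance =  51.2%
    s =   3.890 S   lambda_max =  705.5 nm   abundance =  47.4%
```

Both generator truths are recovered within one s-grid interval
(3.421 vs 3.4 S; 3.890 vs 3.9 S) and well within one spectral resolution
element of the emission maxima (799.3 vs 800 nm; 705.5 vs 705 nm).  The
abundances reflect the equal loadings of the two species; the rmsd is in
the rescaled signal units used for fitting (raw counts divided by the
recorded `c2d.scale_factor`).

The same pipeline is available from the shell:

```bash
mweauc simulate --config examples/two_species.yaml --seed 1 --out run.h5
mweauc mwl2d run.h5 --config examples/two_species.yaml --plot c2d.png
```

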