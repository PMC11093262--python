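# Methods

This note documents the models implemented in `mweauc`, the numerical
choices behind them, and what the synthetic data generator does and does
not emulate.

## Sedimentation–diffusion transport

A species in a sector-shaped AUC cell obeys the Lamm equation

    ∂c/∂t = (1/r) ∂/∂r [ r ( D ∂c/∂r − s ω² r² c ) ],

with impermeable boundaries at the meniscus `r_m` and the cell bottom
`r_b`.  Units follow AUC convention: radii in cm, time in s, `s` in
Svedberg (1 S = 10⁻¹³ s) at the API surface, `D` in cm²/s, solvent density
in g/cm³ and viscosity in mPa·s; ω = 2π·rpm/60.

**Discretization.**  Conservative finite volumes on a uniform radial grid
(default cell size 8 µm for simulation, a few cells per data step for
inversion kernels).  Face fluxes use the Scharfetter–Gummel exponential
fitting `J = (D/h)(B(−Pe)·c_in − B(Pe)·c_out)` with `B(x) = x/(eˣ−1)` and
cell Péclet number `Pe = vh/D`; the scheme reduces to central differencing
at small `Pe` and to upwinding at large `Pe` and is monotone at any `Pe`,
which matters at 40 000 rpm where `Pe` spans orders of magnitude across a
run.  Time stepping is the implicit θ-scheme (θ = ½, i.e. Crank–Nicolson,
with two implicit-Euler startup steps to damp the initial discontinuity);
the tridiagonal systems are LU-factorized once per distinct step size.
Because fluxes telescope, sector mass `∫ c·r dr` is conserved to solver
precision (observed ≲10⁻¹² relative over a full run; the test bound is
10⁻⁶).  A grid coarser than 100 µm cells (or fewer than 50 cells) is
refused with a diagnostic rather than silently smeared by numerical
diffusion.

**Verification oracles.**  Three closed forms check the solver: the
diffusion-free boundary `r(t) = r_m·exp(s ω² t)` (boundary midpoints agree
within one grid cell at high Péclet), the square-dilution plateau rule
`c_p(t) = c₀·exp(−2 s ω² t)` (agreement ≲10⁻³; Scharfetter–Gummel fluxes
are exact for a uniform plateau, so the residual error is temporal), and
uniformization in the pure-diffusion limit.  The Svedberg relation
`M = sRT/(D(1 − v̄ρ))` and the compact-sphere construction
`R₀ = √(9 s η (f/f₀) v̄ / 2(1 − v̄ρ))` tie `D(s)` to a single frictional
ratio, which is the standard scaling assumption of c(s) analysis:
`D ∝ s^(−1/2) (η f/f₀)^(−3/2) ((1−v̄ρ)/v̄)^(1/2)`.

**Bottom accumulation** is physical and retained in the solver.  Back
diffusion forms an equilibrium layer of thickness `δ ≈ D/(s ω² r_b)`; for
small, fast-diffusing particles (nanoclusters, `D ≈ 1.6×10⁻⁶ cm²/s`)
δ ≈ 0.3 mm, so analyses of those species must exclude more than the 0.1 mm
default at the bottom of the window (the presets use 2 mm).  Inside the
exclusion zone the simulated signal can also saturate the ADC, which the
linear model cannot represent.

## Instrument forward model

The detector chain maps a concentration field to ADC counts:

1. **Radial response.**  Fluorescence is generated where the excitation
   beam hits and collected where that position falls inside the imaged
   fibre core (a flat-top of diameter `0.675 × core`), so the radial
   point-spread function is the *product* of the two profiles.  With the
   default geometry (135 µm collection, 40 µm beam) this is the excitation
   Gaussian essentially unchanged — the collection spot does not broaden
   the response — while a 50 µm core (35 µm spot, the older configuration)
   truncates it.  The excitation profile is a Gaussian whose **FWHM equals
   the nominal spot diameter**; this is the reading under which the quoted
   spot size and the quoted 10–90% radial resolution (both ≈40 µm) are
   mutually consistent, since the 10–90% edge width of a Gaussian response
   is 1.09×FWHM.
2. **Axial (z) response.**  Collection weight along the optical axis is a
   flat-top of width equal to the confocal depth, anchored at the two
   characterized cores (50 µm → 0.7 mm, 200 µm → 1.5 mm, linear in
   between; the true dependence between these anchors is not
   characterized).  z = 0 at the cell face nearest the optics; the
   commanded stage coordinate maps to the cell through an additive 2.0 mm
   vacuum shift (warping of the heat sink under vacuum), modelled as a
   constant offset rather than chamber mechanics.
3. **Inner-filter effects.**  Primary: excitation attenuation
   `I(z) = 10^(−ε_exc ∫₀ᶻ c dz′)`; secondary: emission escape
   `10^(−ε_em(λ) ∫₀ᶻ c dz′)`.  For radial scans the cell column at each
   radius is taken z-uniform and the Beer–Lambert factor is averaged
   analytically over the collection window.  Dilute samples give symmetric
   z-scan profiles peaked at the cell centre; optically thick samples
   shift the peak toward the incident face — the working QC criterion for
   "too concentrated".
4. **Dispersion.**  Each grating maps its window onto 1600 pixels
   (150 L/mm: 400–937 nm at 2.0 nm resolution; 600: 515–643 nm at
   0.51 nm; 1800: 525–558 nm at 0.14 nm).  Spectra are integrated over
   pixel bins via their CDF (area-exact) and convolved with a Gaussian of
   the grating's FWHM.  Light outside the window is truncated with a
   warning.
5. **Detection.**  `counts = clip(round((Poisson(N_e) + N(0, σ_read))/g) +
   offset, 0, 2¹⁶−1)` with σ_read = 7 e⁻ (1 MHz) or 4 e⁻ (100 kHz),
   gain g = 1 or 4 e⁻/count, fixed 100-count electronic offset
   (subtractable), exposures ≤ 500 ms (dark current neglected), and
   EM-multiplication excess noise out of scope.  The photon budget — total
   band photoelectrons per concentration unit per ms — is a single
   configurable calibration constant (default 2000; the reference
   nanocluster scenarios use 10⁵, giving peak amplitudes of order 10⁴
   counts as in real runs); absolute quantum yields are out of scope.

The generator is deterministic given its seed (recorded in the
ground-truth sidecar together with the species table and any injected
systematic noise).  Optional injections: a smooth fixed radial pattern
(TI), per-scan random offsets (RI), and a linear beam-drift ramp (off by
default).  Injection amplitudes are referenced to the usable-signal peak,
excluding the bottom accumulation zone.

**What the generator does not emulate:** photobleaching, Raman
scattering, rotor-phase gating electronics, EM excess noise,
concentration-dependent sedimentation or hydrodynamic non-ideality,
compressible solvents.  Tests passing on this generator therefore
establish the correctness of the analysis chain under the stated physics,
not robustness to these effects in real data.

## c(s) inversion

For one wavelength slice `y(r_j, t_k)` the model is

    y = Σ_i a_i L(r_j, t_k; s_i) + ti(r_j) + ri(t_k) + noise,  a_i ≥ 0,

with kernel columns `L` the unit-loading Lamm solutions on a 150-point
log-spaced s grid (log spacing matches the multiplicative resolution of
sedimentation analysis) and `D(s_i)` tied to one shared frictional ratio.
Signal amplitudes are rescaled to a maximum below 10 before fitting.

**Systematic noise.**  TI (per-radius constants) and RI (per-scan
constants) span a linear subspace; on the complete scans×radii grid the
orthogonal projection onto its complement is exact double centering, so
data and kernel are projected once and the noise parameters never appear
in the solve.  They are recovered afterwards from the residual, with the
TI/RI constant-exchange degeneracy resolved by the zero-mean-TI
convention.  The analysis window defaults to meniscus + 50 µm through
bottom − 100 µm.

**Solver.**  The projected design gets one economy QR factorization;
penalized solves stack `[R; √α L₂]` (L₂ the second-difference operator)
into an active-set NNLS of size ~(n_s + n_s) × n_s, so the per-α cost is
independent of the number of data points.  Normal equations were rejected:
forming the Gram matrix squares the kernel's condition number and visibly
(≈10⁻⁷) degraded agreement with the brute-force NNLS oracle.  The
maximum-entropy variant minimizes `½χ² + α Σ(a ln(a/m) − a + m)` with a
uniform prior by bounded L-BFGS.

**Regularization strength.**  α is the largest penalty whose χ² stays
within `χ²₀ · F⁻¹(P; n, n)` of the unregularized fit, with n the number of
data points and P the confidence level (default 0.683, the one-sigma
convention).  Higher P admits more χ² inflation and therefore smoother
distributions — the convention of the established c(s) implementations.
The exact F-statistic convention behind the printed "0.683" is not
published; this package's choice is stated here and asserted by its tests.
The bound is located by bisection on log α (relative tolerance 10⁻³,
within 50 iterations).

A practical consequence of χ²-bound smoothing: species ~15% apart in s
whose signals coexist at one wavelength are returned as one broad band at
that wavelength — a broad distribution fits two nearby boundaries almost
as well as two sharp peaks, at a χ² cost below the bound.  They remain
separable through the wavelength dimension (below).

**Nonlinear parameters.**  Meniscus, f/f₀ or v̄ (exactly one at a time)
are refined by bounded scalar minimization of the unregularized rmsd on a
coarsened s grid, then the full fit is repeated at the optimum.  Boundary
optima trigger a warning.  Recovery on synthetic data: v̄ to ±0.01 from a
0.4 start, meniscus to within half a radial step, f/f₀ to a few percent.

## Multiwavelength analysis

Per-wavelength fits share one kernel (computed once) and one rescaling
factor, and are pure functions of their slice — execution order cannot
change the result.  Sensor pixels are binned to the analysis step
(default 1.5 nm) before fitting.  TI/RI noise is estimated independently
per wavelength.  The shared v̄ is taken constant across wavelengths,
optimized (if desired) on the wavelength-integrated signal and frozen.

**Species extraction** operates on the wavelength-integrated c(s):
support regions are contiguous stretches above 5% of the maximum, *split
at interior local minima* between peaks of ≥20% relative prominence.  The
split is required because of the smoothing behaviour described above: two
nearby species produce a bimodal integrated profile bridged above the
threshold, and treating the bridge as one species would merge 3.4 S and
3.9 S into a fictitious 3.65 S ridge.  Each species' emission spectrum is
the amplitude slice summed over its s-support; λ_max comes from quadratic
interpolation around the spectral maximum, giving sub-resolution-element
accuracy.  Both thresholds are configurable.

**Global discrete-species fit.**  K species with shared s values across
selected wavelengths: the K sedimentation coefficients are optimized in
log space by Levenberg–Marquardt; per-wavelength amplitudes and TI/RI
noise are profiled out linearly at every trial (variable projection).
Initialization comes from species extraction on the selected wavelengths.
Near-coincident s estimates (<2% apart) are flagged as a sign that K
exceeds the identifiable number of species.

A known artefact is reproduced qualitatively: when species of genuinely
different v̄ are analysed with one shared v̄, the mismatched diffusion
model shifts apparent sedimentation coefficients in a wavelength-dependent
way; per-species parameters remove the shift.

## QC computations

* **Radial calibration** — edges of a known gap-disk layout located at the
  50% threshold and refined by a local integrated-Gaussian fit (plain
  linear interpolation of a blurred edge sampled at 50 µm carries a
  few-µm phase-dependent bias, too coarse for the 2×10⁻⁴ scale-accuracy
  target); a straight-line fit of detected against known positions yields
  absolute offset and step-size scale.  A 100 µm uniform offset changes a
  refit s by `≈ offset·(1/r_m − 1/r_b)/ln(r_b/r_m)` ≈ 0.16% for a boundary
  tracked from 6.0 to 6.5 cm — below the 0.2% tolerance.
* **z-scan assessment** — asymmetry index `2(z_peak − z_centre)/depth`
  with the peak taken as the midpoint of the ≥98%-of-maximum plateau (the
  dilute-limit axial response is a flat-topped trapezoid, so a bare argmax
  would return a plateau edge).  |index| ≤ 0.15 classifies "suitable"
  (threshold configurable; the underlying criterion is qualitative).
* **SNR characterization** — SNR = mean/sd of offset-subtracted replicate
  counts; log–log slopes fitted below 10 and above 100 counts approach 1
  (read-noise-limited) and ½ (shot-noise-limited); the crossover sits at
  σ_read² photoelectrons.
* **Dynamic range** — a 5-decade concentration grid × exposures up to
  500 ms; each amplitude is the mean of 8000 replicate detections
  (emulating the plateau average over ~240 radial points × ~34 band
  pixels that a real amplitude readout integrates), usable when that
  estimate has SNR ≥ 3 and stays 3σ clear of saturation; the span is the
  widest contiguous usable amplitude range with pooled log–log slope
  within 1 ± 0.02.  The default detector model yields ≳5.4 decades.
* **Edge response** — 10–90% width from a phase-independent
  integrated-Gaussian edge fit, floored at the 0.8-step sampling limit;
  direct spline interpolation (`method="interp"`) is retained but varies
  with the edge's phase relative to the 50 µm grid.  Default geometry:
  43.4 µm, set by the excitation spot alone.
* **Band-integration gain** — SNR(band sum)/SNR(peak pixel), bracketed by
  the read-limited bound `(S_band/S_peak)/√N_px` and the shot-limited
  bound `√(S_band/S_peak)`; of order 10 for a weak band filling
  485–650 nm.  The exact value depends on the (uncharacterized) band
  shape, so only the bracket and order of magnitude are asserted.

## Reference scenarios and problem sizes

`mweauc.presets` pins the study conditions used by tests and the
acceptance script: a single 4 S protein-like emitter; two nanocluster
species at 3.4/3.9 S with emission maxima 800/705 nm (equal loadings,
shared v̄ = 0.547 cm³/g, f/f₀ = 1); and three species at 3.35/3.97/4.82 S
with maxima 700/760/825 nm.  All run at 40 000 rpm in a 6.0–7.2 cm,
3 mm-path cell scanned at 50 µm steps.  Scan schedules are sub-sampled
(e.g. 60 scans × 450 s instead of 450 × 90 s) spanning the same rotor
time — the package's standard working size, chosen so a full 2D analysis
(150 s values × ~90 wavelength steps) completes in tens of seconds while
retaining enough statistical leverage to resolve the 3.4/3.9 S pair.

## Known limitations

* The χ²-bound regularization merges closely spaced species at a single
  wavelength (by design of the criterion); resolution of the 15%-spaced
  pair relies on the wavelength dimension and the region-splitting
  extraction rule.
* Confocal depth between the two characterized fibre cores is an
  interpolation, not a measurement.
* Fluorescence-specific signal corrections beyond TI/RI noise (e.g.
  intensity-dependent response corrections) are intentionally not
  applied, matching the analysis convention the package mirrors.
* The inner-filter model treats each radial column as z-uniform, which is
  exact for z-scans of uniform samples and a first-order approximation
  during sedimentation.
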