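# Methods

`barofold` analyses pressure-perturbation experiments on proteins: equilibrium
unfolding titrations followed by fluorescence, pressure-jump relaxation
kinetics, and size-exclusion chromatography (SEC) of the recovered material.
The reference system is bovine odorant-binding protein (bOBP), a domain-swapped
dimeric lipocalin studied at 25 °C in 1.5 M GdnHCl, both as the native dimer
and as an engineered monomer, with and without its substrate 1-octen-3-ol.

## Spectral observables

A spectrum is a sampled emission band F(λ). Two scalars summarize it:

* **Center of spectral mass.** csm = Σ νᵢFᵢ / ΣFᵢ with νᵢ = 10⁷/λᵢ — the
  intensity-weighted mean emission *wavenumber*. It tracks the mean solvent
  exposure of the tryptophans: folded bOBP sits near 344 nm, pressure-unfolded
  near 351 nm. We report both cm⁻¹ and nm; the nm value is defined as
  10⁷/csm(cm⁻¹) (the harmonic conversion of the wavenumber mean), not as a
  weighted mean over the nm axis. The two differ because 1/λ is convex; the
  wavenumber definition is primary.
* **Intensity at a fixed wavelength** (default 338 nm, the native emission
  maximum), linearly interpolated on the sampled grid, with no extrapolation,
  baseline subtraction or smoothing.

## Two-state pressure unfolding

Folded and unfolded states exchange with a pressure-linear free energy

    ΔG(p) = ΔG⁰ᵤ + p·ΔVᵤ ,   K(p) = exp(−ΔG(p)/RT),

with ΔG⁰ᵤ in kJ/mol, ΔVᵤ in ml/mol and p in MPa, so the p·ΔV product is in
J/mol with no conversion factor (1 MPa·ml/mol = 1 J/mol). The observed signal
is the Boltzmann mixture y(p) = (y_f + yᵤK)/(1+K). Negative ΔVᵤ means pressure
unfolds; the midpoint is p½ = −1000·ΔG⁰ᵤ/ΔVᵤ.

Fitting: unweighted nonlinear least squares (scipy `curve_fit`) in
(ΔG⁰ᵤ, ΔVᵤ, y_f, yᵤ); endpoints are fitted constants (pressure-linear
baselines are a switch, off by default); T defaults to 298.15 K; asymptotic
standard errors from the Jacobian; p½ and its propagated SE derived from the
fit. Initialization: endpoints from the outer 10% of points, p½ from the
observable's mid-crossing, ΔV seeded at −50 ml/mol. The parametrization has an
exact exchange symmetry (ΔG⁰, ΔV, y_f, yᵤ) ↔ (−ΔG⁰, −ΔV, yᵤ, y_f); p½ and the
predicted curve are invariant under it, and the identity p½ = −1000·ΔG⁰ᵤ/ΔVᵤ
is what downstream code consumes.

Hysteresis between compression and decompression branches is reported as
Δp½ with a propagated SE and flagged when |Δp½| exceeds twice that SE.
Each branch is treated as an *effective* two-state transition — dimer
dissociation is not modeled explicitly as 2N ⇌ N₂, and the monomer's minor
secondary transition near 350 MPa is not modeled.

A hyperbolic 1:1 binding fit, F = F_max·L/(K_d + L), covers
fluorescent-ligand titrations.

## Relaxation kinetics and activation volumes

After a pressure jump the signal relaxes as I(t) = I₀ + A·e^(−k_obs·t)
(optionally + B·e^(−k_slow·t); model choice by small-sample-corrected AIC with
ties going to the mono model; the fast phase is used as k_obs). Samples inside
the 5 ms instrument dead time are excluded. For a two-state system
k_obs = k_f + k_u, and with K(p) from an equilibrium fit,

    k_u = k_obs·K/(1+K),   k_f = k_obs/(1+K),

identities that hold to machine precision by construction. Which equilibrium
parameter set supplies K(p) is an explicit argument everywhere: the
experiments leave it ambiguous (the published second-cycle equilibrium
midpoint ≈132–150 MPa does not coincide with the published rate-line crossing
at 180 MPa), so the package never hard-codes the choice; synthetic scenarios
default to the self-consistent set implied by the rate laws themselves.

Log-linear rate laws ln k(p) = ln k(0) − p·ΔV‡/RT are fitted by OLS
(unweighted by default; optional weighting by propagated rate SEs), giving
activation volumes ΔV‡ = −slope·RT in ml/mol, the line-crossing pressure, and
the identity check ΔV‡ᵤ − ΔV‡_f = ΔVᵤ (flagged beyond 2σ). The reconstructed
k_obs(p) = k_f(p) + k_u(p) has a single interior minimum whenever the two
slopes have opposite signs, at

    p_min = p_cross + RT·ln(|s_f|/|sᵤ|)/(|s_f| + |sᵤ|)        (s = d ln k/dp).

Note a quantitative consequence: with the strongly asymmetric published
activation volumes (+95 vs −5.5 ml/mol) this offset is +70.3 MPa at 298.15 K,
i.e. the dip in k_obs(p) lies well *above* the crossing, not at it. Any
account that places the dip at or below the crossing is incompatible with
those slope magnitudes; the package reports both pressures so the discrepancy
is visible rather than hidden.

## SEC analysis

K_av = (Ve − V0)/(Vt − V0) with the column's void and total volumes
(defaults 8 and 20.8 ml). Calibration is an OLS line log₁₀(mass) = a + b·K_av
through ≥3 standards (inverted calibrations are flagged). A mass estimate is
10^(a + b·K_av) with a 95% Student-t confidence interval for the line response
at the query K_av — t rather than Gaussian because calibration sets are small
(6 standards → 4 degrees of freedom) and a ±2·SE band demonstrably
undercovers. Estimates outside the calibrated K_av range are flagged as
extrapolated.

Elution profiles are decomposed as sums of 1–3 Gaussians (zero baseline by
default, constant offset as an option). Initialization places centers at
prominence-filtered local maxima of a 5-point moving average (smoothing is
used for picking only) with widths at 2% of the volume span; when peaks
overlap into shoulders, the missing centers are multi-started from several
candidate placements (largest residual, ±0.8 and ±1.5 widths from the main
peak) and the restart with the lowest SSE wins — at ~2σ peak separation a
single start is prone to local minima. Area fractions are normalized to 1;
width-outlier, vanishing, or unresolved (closer than one peak width) peaks
trigger degeneracy warnings. Non-Gaussian peak shapes (tailing) and plate
theory are out of scope.

## Synthetic data

The generator produces all three input kinds with the statistical structure
the analysis assumes, so every stage is testable without instrument data.

* **Spectra.** Gaussian bands in wavelength (default σ = 25 nm on a
  300–400 nm, 1 nm grid); band centers are solved numerically at construction
  so the noiseless pure-state csm equals the configured endpoints
  (344/351 nm) on the configured grid — the center of a λ-Gaussian sits
  ~2 nm above its csm. Mixtures follow the two-state populations, with an
  unfolded/folded quantum-yield ratio q = 0.6 emulating the observed pressure
  quenching. Gaussian noise (default sd 1% of the folded amplitude) is added
  pointwise and clipped at zero.
* **Quenching bias, made explicit.** With q ≠ 1 the csm of a mixture is
  intensity-weighted, so csm(p) in wavenumber space is *exactly* two-state but
  with an effective constant K′ = qK — an apparent ΔG⁰ᵤ shift of −RT·ln q
  (≈ +1.27 kJ/mol at q = 0.6), with ΔVᵤ untouched. Intensity-at-λ profiles
  carry no such shift. Consequently ΔVᵤ round-trips exactly through the csm
  path while the apparent p½ of a csm fit is shifted by −RT·ln q·1000/|ΔVᵤ|
  (7–37 MPa depending on ΔVᵤ). This mirrors what quenching does to real csm
  fits. Recovery tests therefore use the intensity observable (or q = 1)
  where exactness is asserted.
* **Two-cycle scenario.** Cycle-1 compression uses the substrate-bound dimer
  truth (ΔG⁰ = 57.56 kJ/mol, ΔV = −172.6 ml/mol, p½ ≈ 333 MPa); the cycle-1
  decompression and the whole second cycle use the post-dissociation truth
  (12.63 kJ/mol, −95.71 ml/mol, p½ ≈ 132 MPa), emulating the irreversible
  substrate loss and dimer dissociation above ~350 MPa. Pressure ladder:
  0.1 MPa then 30 MPa steps to 600 MPa (21 points per branch).
* **Jump traces.** Rates from the log-linear laws with ΔV‡_f = +95,
  ΔV‡ᵤ = −5.5 ml/mol, lines crossing at 180 MPa with k = 0.005 s⁻¹ there
  (k_obs = 0.01 s⁻¹, τ = 100 s, matching the observed second-cycle
  relaxation). The implied equilibrium (ΔG⁰ᵤ = 18.09 kJ/mol,
  ΔVᵤ = −100.5 ml/mol) makes the scenario thermodynamically/kinetically
  self-consistent. Traces are mono-exponential toward the equilibrium
  intensity at the final pressure, 400 samples over 5/k_obs starting at the
  5 ms dead time, 40 MPa downward jumps at 8 final pressures (60–340 MPa);
  a bi-exponential mode adds a slow 30%-amplitude phase emulating the complex
  first-cycle upward jumps. Default noise: 2% of the jump amplitude in the
  recovery studies.
* **Chromatograms.** Species elute where the calibration-line truth
  (log₁₀ m = 5.6 − 2.0·K_av on the 8/20.8 ml column) puts their mass, as
  Gaussians of σ = 0.35 ml with areas proportional to the species fractions;
  signal noise 1% of the maximum. Standards' elution volumes carry *absolute*
  Gaussian noise of 0.1 ml (~1% of a typical Ve): FPLC volume error is
  instrumental, roughly constant in ml, which also keeps the calibration
  residuals homoscedastic as the interval estimator assumes.
* **Reproducibility.** Every draw descends from an explicit integer seed via
  `numpy.random.SeedSequence`; identical config + seed reproduces
  byte-identical arrays. No global random state is touched.

What the generator does *not* emulate: instrument response and inner-filter
effects, photobleaching, pressure-dependent quantum-yield curvature,
aggregation kinetics, non-exponential relaxations, peak tailing. Passing
recovery tests therefore demonstrate correctness of the estimators under the
assumed models, not robustness to these real-data complications.

## Study sizes and numerical choices

The bundled studies use: 50 seeds × 21-point profiles at 1% noise for
equilibrium recovery; 50 repetitions × 8 pressures × 3 replicates at 2% noise
for kinetics recovery; 50 seeds for the SEC round trip — sizes chosen to make
the success-rate estimates stable (binomial SE ≲ 6 points) while the whole
suite stays interactive. Exponent clamping at |x| = 700 guards K(p) overflow;
rate fits bound k > 0; curve_fit failures surface as typed fit-failure errors
with diagnostics, never as silent NaNs. Reports serialize as JSON with sorted
keys and embed sha256 digests of their input files.

## Known limitations

* Each branch is an effective two-state fit; protein-concentration dependence
  of dimer dissociation is not modeled.
* Asymptotic SEs from local curvature; the 68% coverage band (0.55–0.80)
  verified in the tests is what such SEs deliver at n = 21, not exact
  calibration.
* csm fits inherit the quenching-induced ΔG⁰ shift described above; compare
  csm- and intensity-derived parameters with that in mind.
* The equilibrium source for rate decomposition is a modeling choice the data
  do not fully determine; results downstream of K(p) (k_f, k_u, ΔV‡
  intercepts) depend on it, though the fitted slopes of ln k_obs regimes are
  insensitive.
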