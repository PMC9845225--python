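# Methods

This note documents the models implemented in `oxmembrane`, the
assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate. Units throughout:
distances in Å, times in ns, wavelengths in nm, scattering vectors in
Å⁻¹, viscosities in cP, temperatures in °C (Kelvin only where stated).

## TCSPC decay model and fitting

A measured decay is modelled as

    μ(t) = bg + A · [ IRF(t − s) ⊛ Σᵢ aᵢ e^(−t/τᵢ) ],  Σ aᵢ = 1,

with one or two exponential components. The instrument response is
taken from the trace itself (measured IRF channel counts, normalized);
the temporal shift s is a free parameter bounded at ±3 channels,
applied by linear interpolation of the IRF on the channel grid. The
background is a single fitted constant per decay. The fit window opens
10 channels before the count peak and runs to the last channel.

Two objectives are available. The default is the Poisson negative
log-likelihood Σ(μ − c·ln μ), correct at arbitrary count levels and
therefore used for per-pixel FLIM fitting, where peak counts of a few
hundred are routine. Weighted least squares (weights 1/max(c, 1)) is
provided for bright cuvette traces; both agree within the photon-noise
SD at ≥10⁴ peak counts (tested). Optimization is bound-constrained
L-BFGS-B; lifetimes are initialized from a log-linear regression of the
post-peak tail. Parameter covariances come from the inverse of a
central-finite-difference Hessian of the objective at the optimum
(doubled for the χ² objective); non-positive-definite curvature returns
no covariance rather than a fabricated one. Non-convergence and
parameters pinned at bounds are flagged on the result, never silent.

At 10⁴ peak counts and a 0.2 ns FWHM Gaussian IRF the estimator
recovers a 2.1 ns lifetime with |bias| ≪ 1% and SD ≈ 0.01 ns, and the
SD scales as 1/√counts over 10³–10⁵ (both covered by tests).

### Lifetime → microviscosity

Molecular rotors obey a power law τ = c·η^x over their working range,
so η = (τ/c)^(1/x), strictly increasing in τ. `calibrate_from_pairs`
fits the power law to (η, τ) pairs in log–log space (exact through two
points). The shipped `default_calibration()` passes exactly through
(159 cP, 1.8 ns) and (241 cP, 2.1 ns) — the measured end-member values
for pure POPC and fully peroxidized membranes — giving exponent
x ≈ 0.371. It is labelled as such in its `source` field: it is an
anchor calibration, not the constants of any instrument-specific
published curve, and users of a different rotor/instrument must supply
their own. Conversions outside the calibrated lifetime range warn.

### FLIM maps and heterogeneity

Binning b sums decays over the (2b+1)×(2b+1) neighbourhood of each
pixel before thresholding and fitting (the common TCSPC-software
convention); pixels below the minimum post-binning peak count (defaults:
200 for mono-exponential, 500 recommended for bi-exponential dyes) are
masked. Raising the threshold can only shrink the fitted set
(tested invariant). For bi-exponential dyes the longer lifetime
component is the viscosity reporter; ties are returned with a flag.

Heterogeneity of the per-pixel lifetime distribution is scored by the
BIC advantage ΔBIC = BIC₁ − BIC₂ of a two-component Gaussian mixture
(values ≳ 10 = strong evidence for two populations), with Sarle's
bimodality coefficient as a secondary, model-free readout. A dip-type
test was considered and not included; the mixture ΔBIC is more
sensitive at the ~10³-pixel scale of a single vesicle rim. Spatial
organization is scored separately by Moran's I over 4-neighbour
adjacency with a seeded permutation null: photon noise alone gives
I ≈ 0 regardless of histogram shape, while genuine lifetime domains
give I > 0 at small p.

## Laurdan spectroscopy

GP = (I_blue − I_red)/(I_blue + I_red) with band intensities integrated
(trapezoid) over 430–450 nm and 480–500 nm by default. The absolute GP
scale depends on this band convention, which is configurable and echoed
in every result; GP is exactly invariant to uniform intensity scaling.

Spectral decomposition uses three Siano–Metzler asymmetric lognormal
bands I(λ) = h·exp{−(ln2/ln²ρ)·ln²[1 + (λ−c)(ρ²−1)/(wρ)]} with peak
position c, FWHM w and asymmetry ρ. Centers are constrained to
[415, 435], [450, 470] and [480, 510] nm (configurable), widths to
20–80 nm, ρ to 1.05–1.8. Because the dominant noise on a bright
emission spectrum is multiplicative, residuals are taken relative to
the local intensity (floored at 2% of the peak); the fit is
Levenberg–Marquardt from ≥5 jittered starts, best residual kept. Band
areas are integrated numerically and reported as fractions; a
same-freedom single-band fit that matches the three-band residual marks
the decomposition as degenerate. Noiseless three-band spectra are
recovered to <1 nm in center and <2% in area fraction; at 1% noise the
centers of heavily overlapping bands are identifiable only to a few nm
— an information limit of the decomposition, not of the optimizer.

Thermotropic breakpoints use the continuous hinge model
y = b₀ + b₁T + b₂·max(T − T_b, 0), fitted exhaustively with T_b at
every interior data abscissa (two points reserved per edge). A
gradient change is declared only if the F-type variance ratio against
the single-line fit is significant (default α = 0.05); otherwise the
breakpoint is reported as absent. Confidence intervals come from a
seeded residual bootstrap. On a 17-point series with noise at 10% of
the signal range the per-replicate scatter of T̂_b is itself a few °C;
the estimator is unbiased, so averages across replicates converge on
the true breakpoint, and the CI width shrinks as ~1/√n (tested).

## X-ray scattering

Lamellar analysis detects local maxima above a noise floor estimated
from the median absolute second difference, then refines each peak with
a pseudo-Voigt plus linear background on a ±3×FWHM window. The repeat
distance is d = 2π/q₁ from the first order; orders n ≥ 2 are assigned
by proximity to 2πn/d and flagged if their implied d deviates by >2%.
The pseudo-Voigt is used because instrument smearing is generally
unknown; peak position is thereby recovered to well under a tenth of
the grid spacing on clean profiles. Full fluctuation-theory S(q)
lineshape fitting is deliberately out of scope: the slope of FWHM
versus n² is reported instead as the qualitative stack-softness
readout (fluctuation broadening grows as n², so a positive slope that
steepens across a composition series indicates softer stacks).

The wide-angle chain-packing peak is fitted as a Lorentzian on a
polynomial background of degree ≤ 2; the Lorentzian σ parameter is its
HWHM, and the chain spacing is 2π/center (≈4.5 Å in the fluid phase).
A same-freedom Gaussian comparison fit flags `lineshape_mismatch` when
it is markedly better (χ² ratio < 0.5), catching non-Lorentzian peaks.

`compare_series` tabulates d-spacing, widths and intensity ratios
across compositions; d-spacing uncertainties come from the fit
covariance, or — when raw profiles are passed — from a seeded residual
bootstrap of the first-order window refit.

## Bilayer trajectory metrics

Trajectories are frames of labelled particles (species; leaflet fixed
at construction — no flip-flop; role = phosphate anchor, chain site k,
or peroxide oxygen) in a box periodic in x and y only. All pairwise
computations use the in-plane minimum image and are invariant under
periodic translation (property-tested).

* **Density profiles** are midplane-centred histograms along z,
  normalized per unit area and bin width, so profile × area integrates
  to the group weight per frame. Weights default to 1 (number
  density); electron counts can be supplied per particle.
* **Thickness** is the frame-averaged difference of mean phosphate z
  between leaflets, with a frame-to-frame SE.
* **Order parameter**: successive chain sites define bond vectors;
  S_cd = ½⟨3cos²θ − 1⟩ against the z axis, per bond index, averaged
  over molecules and frames. Limits: +1 aligned, −0.5 in-plane, 0
  isotropic (all hit exactly or within sampling error in tests).
* **Area per lipid**: seeds are phosphate (x, y); the tessellation is
  made periodic by tiling the seeds with their 8 images and reading the
  primary-copy cell areas, which therefore sum to exactly Lx·Ly every
  frame. Coincident seeds are jittered by 1e-6 Å with a warning.
  Bimodality of the APL distribution is scored by the same
  two-component-GMM ΔBIC as the FLIM histograms.
* **Enrichment** E_ij = C_j,local/C_j,bulk: C_j,local is the mean
  concentration of species j within a 12 Å in-plane radius of a
  species-i lipid (central lipid excluded), C_j,bulk = N_j/(Lx·Ly),
  evaluated per leaflet, averaged leaflet-then-frame. SE by seeded
  block bootstrap over frames (default block = 10). With
  self-exclusion, ideal mixing gives E_ii = (N_i−1)/N_i ≈ 1 and
  E_ij = 1; the pipeline agrees with an O(n²) brute-force counter to
  1e-12. A 3-D mode (spherical neighbourhood across leaflets) exists
  but the in-plane per-leaflet definition is the primary one, matching
  how leaflet-resolved clustering maps are read.
* **Snorkelling**: a peroxide oxygen is "up" when |z| exceeds
  threshold × half-thickness, strictly; the default threshold 0.6 was
  chosen once as a round value separating the generator's up (0.85×)
  and down (0.15×) states with margin for jitter. Reported: time
  average, SE over frames, and mean dwell times per state.
* **Diffusion**: one phosphate anchor per molecule, unwrapped
  coordinates (stored by the generator, or reconstructed from wrapped
  ones via minimum-image steps, refusing wrap-ambiguous steps). The
  time- and ensemble-averaged 2-D MSD is fitted linearly on lags
  10–50% of the maximum (short lags are noise-dominated, long lags
  poorly sampled); D = slope/4. A log-log slope far from 1 (>±0.3)
  flags non-diffusive motion (ballistic test input gives slope 2).
  Because long-lag MSD values are few-sample averages, tight D recovery
  requires wide-and-short trajectories: ~10⁵ displacement samples with
  ≤100-frame spans give ~2% sampling SD, the regime the tests and the
  acceptance script use.
* **Saffman–Delbrück**: D = k_BT/(4πη_m h)·(ln(L_sd/r) − γ),
  L_sd = η_m h/(2η_w), with η_m the bulk-equivalent membrane viscosity
  (cP), h the hydrophobic thickness (nm), r the inclusion radius (nm).
  Valid only for r < L_sd (enforced). The inverse problem is solved by
  bracketed root finding on the strictly monotone forward map;
  roundtrips reproduce η to better than 1e-8 relative.
* **Contact maps**: for each role pair, the fraction of
  frame × molecule-pair combinations whose sites fall within the cutoff
  (in-plane minimum image, plain z), symmetrized over site assignment.
  Which site roles correspond to which chemical oxygens is left to the
  caller's labelling.

## The synthetic-data generator

The generator produces data *shaped like* the real modalities with
exactly known ground truth; it is a testbed, not a physics engine.

* **Decays**: μ(t) scaled so the expected peak equals the requested
  peak count (default 10,000, the usual acquisition stopping rule),
  plus uniform background, Poisson-sampled. The IRF is Gaussian
  (center 1 ns, FWHM 0.2 ns by default) — a modelling choice, since
  real IRFs are measured, not parametric. Expected total counts match
  the analytic integral (tested to 0.5% at 10⁶ counts).
* **FLIM stacks**: an annular vesicle-rim mask; populations assigned
  to angular sectors (validated disjoint) or at random by fraction;
  off-rim pixels hold background only. Per-pixel decays share one
  noiseless template per lifetime, Poisson-sampled independently.
* **Spectra**: sums of Siano–Metzler bands with multiplicative
  Gaussian noise; default bands at 425/460/495 nm mirror the three
  probe environments.
* **Scattering**: Gaussian Bragg orders at 2πn/d with heights ∝ 1/n²
  and FWHM(n) = FWHM₁·(1 + g·(n²−1)) — the n² growth mimics
  fluctuation broadening — plus one wide-angle Lorentzian and a
  polynomial background.
* **Trajectories**: per leaflet, overdamped Brownian motion of lipid
  anchors (step SD √(2D·dt)). With interactions on, each proposed step
  is Metropolis-accepted on ΔE with
  E = −ε_attr·n_same(<10 Å) + ε_core·n_all(<7 Å) in kT, evaluated
  against the other lipids' current positions. The soft core is
  essential physics for the clustered regime: same-species attraction
  alone condenses the leaflet into dense *mixed* aggregates (raising
  cross-enrichment above 1), whereas lipids are laterally almost
  incompressible; with the core term (2 kT in the standard clustered
  scenario, ε_attr = 0.8 kT) the system demixes, giving
  E_self ≈ 1.3–1.5 and E_cross ≈ 0.5–0.6 robustly across seeds. With
  all interactions off the dynamics are exactly Brownian, so MSD
  recovery and uniformity tests run against clean ground truth.
  Chain-site bond vectors are drawn i.i.d. each frame from a mixture
  of a pure-limit population (aligned, or in-plane for negative
  targets) and an isotropic one, making E[S_cd] exactly the target —
  there is no intramolecular dynamics. Snorkelling is a two-state
  Markov chain per oxidized lipid with exponential dwells; by default
  the rates are derived from the stationary fraction (default 0.40)
  with a 50 ns mean dwell timescale ("slow"), and explicitly supplied
  rates must be consistent with the stated fraction. Defaults — 200
  lipids/leaflet, box 115 Å (~66 Å²/lipid), thickness 39.2 Å,
  D = 1 Å²/ns, dt = 1 ns, 500 frames — emulate the simulated systems
  the analyses target; frame interval and span are free choices since
  no canonical values exist.

What the generator does **not** emulate: atomistic forces or torsions,
solvent, leaflet flip-flop, membrane undulations/curvature, correlated
chain conformations, instrument afterpulsing or detector nonlinearity,
SAXS form factors and smearing. Passing tests therefore demonstrate
estimator correctness on data satisfying the model assumptions — not
robustness to every artefact of real measurements.

## Numerical and design notes

* Seeding: every stochastic routine takes an explicit seed; identical
  spec + seed is bit-identical. No silent clock seeding anywhere.
* The uniformity invariant for non-interacting dynamics is checked by
  marginal KS tests on x/L and y/L (α = 0.01); a full 2-D KS test adds
  machinery without changing what is verified for uniform margins on a
  torus.
* Degenerate inputs: empty decays, all-zero spectra, flat scattering
  profiles, single-leaflet trajectories, sub-minimum pixel or point
  counts all raise explicit `ValueError`s naming the problem; duplicate
  Voronoi seeds are jittered with a warning rather than failing.
* The demo pipeline (`io.run_pipeline`) isolates stage failures: a
  failing stage is recorded and the remaining stages still run, with a
  non-zero exit from the CLI. Every output row carries the
  configuration hash.
* CLI: `oxmembrane synth|flim|spectra|scatter|bilayer|run`, a thin
  layer over the library; all analysis is importable without it.

## Known limitations

* The bi-exponential decay fit floats both components; if an
  instrument analysis fixes the short component, results can differ in
  the amplitude split (the long-lifetime reporter is robust to this).
* Enrichment's C_bulk = N_j/(Lx·Ly) with self-exclusion makes ideal
  mixing E_ii slightly below 1 (by 1/N); negligible at the simulated
  sizes but visible for very small systems.
* The hinge breakpoint model assumes a continuous change of slope; a
  genuine discontinuity (first-order transition in the observable)
  would be mislocated.
* The GRO reader is single-frame and minimal (residue → species,
  atom-name → role via maps); multi-frame trajectory formats should go
  through the extended-XYZ dialect.
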