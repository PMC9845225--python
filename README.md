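# oxmembrane

Quantitative analysis of peroxidized lipid membranes.

Peroxidation of unsaturated phospholipids (e.g. POPC → POPC-OOH by
singlet-oxygen attack on the oleoyl double bond) plants a polar –OOH
group inside the bilayer's hydrocarbon core. This single chemical change
reshapes the membrane: the peroxidized chain *snorkels* toward the
water interface, the bilayer thins, the area per lipid grows — and yet
the microviscosity *rises* while the bending rigidity falls, because the
oxidized lipids hydrogen-bond to each other and cluster into more
ordered lateral domains.

`oxmembrane` implements, as a single tested toolkit, the quantitative
pipeline used to characterize this behaviour across four experimental
and computational modalities, together with a synthetic-data generator
that produces every input modality with known ground truth so the whole
pipeline is verifiable end to end. It is aimed at membrane
biophysicists working with FLIM/TCSPC, Laurdan spectroscopy, lamellar
X-ray scattering, or bilayer simulation trajectories.

## What it computes

**FLIM / TCSPC (`oxmembrane.flim`)** — reconvolution fitting of
time-correlated single-photon-counting decays,

    counts(t) = bg + A · [ IRF(t − s) ⊛ Σᵢ aᵢ e^(−t/τᵢ) ],

by Poisson maximum likelihood (default) or weighted least squares;
per-pixel fitting of FLIM stacks with square-neighbourhood binning and a
minimum-peak-count mask; conversion of molecular-rotor lifetimes to
microviscosity through a power-law calibration τ = c·η^x (the shipped
default is anchored exactly at 1.8 ns ↔ 159 cP and 2.1 ns ↔ 241 cP, the
POPC / POPC-OOH end members); and heterogeneity statistics of the
lifetime histogram (SD, skewness, kurtosis, two-component
Gaussian-mixture ΔBIC, Moran's I spatial autocorrelation).

**Polarity spectroscopy (`oxmembrane.spectra`)** — Laurdan generalized
polarization GP = (I_blue − I_red)/(I_blue + I_red) over configurable
integration windows; decomposition of emission spectra into three
asymmetric lognormal (Siano–Metzler) bands assigned to apolar
(~425 nm), polar-aprotic (~450–470 nm) and polar-protic (~480–510 nm)
probe environments; and detection of a gradient change in GP- or
intensity-vs-temperature series with a continuous two-segment hinge fit
(F-test against a single line, bootstrap confidence interval).

**X-ray scattering (`oxmembrane.scattering`)** — lamellar d-spacing
d = 2π/q₁ from pseudo-Voigt-refined Bragg peaks, with higher orders
cross-checked and the growth of peak width with order² reported as a
stack-softness (Caillé-type) trend readout; Lorentzian fitting of the
wide-angle chain-packing peak (chain spacing 2π/q, width); composition
series tables with bootstrap uncertainties.

**Bilayer trajectories (`oxmembrane.bilayer`)** — density profiles
along the normal; phosphate–phosphate thickness; the chain order
parameter S_cd = ½⟨3cos²θ − 1⟩ per bond index; per-lipid areas from a
periodic 2-D Voronoi tessellation and their bimodality (GMM ΔBIC);
fractional enrichment E_ij = C_j,local/C_j,bulk within a 12 Å lateral
neighbourhood (the lipid-clustering readout: E_ii > 1 with E_ij < 1
means demixing); snorkelling fraction and dwell times of peroxide
oxygens; lateral diffusion from time-averaged MSD; the Saffman–Delbrück
bridge D = k_BT/(4πη_m h)·(ln(L_sd/r) − γ) between diffusion and
membrane viscosity (both directions); and site-to-site contact maps.

**Synthetic data (`oxmembrane.synthetic_data`)** — seeded generators
for every input: Poisson-noised IRF-convolved decays, vesicle-rim FLIM
stacks, lognormal-band spectra, lamellar + wide-angle scattering
profiles, and two-leaflet Brownian-dynamics trajectories with tunable
diffusion, chain order, same-species attraction (clustering) and slow
two-state snorkelling. Ground truth is recorded next to every dataset.

## Worked example

Simulate a TCSPC decay of a membrane-embedded molecular rotor with a
2.1 ns lifetime acquired to 10,000 peak counts, then fit it and convert
to microviscosity:

```
$ oxmembrane synth decay --seed 1 --out decay.csv
$ oxmembrane flim fit decay.csv
{
  "lifetimes_ns": [2.090327350013711],
  "amplitudes": [1.0],
  "background": 0.0010143238242586972,
  "shift_ns": -1.1535066889521613e-05,
  "reduced_chi2": 0.7665848827754108,
  "converged": true,
  "reported_lifetime_ns": 2.090327350013711,
  "viscosity_cP": 238.0168209003201,
  "flags": {}
}
```

The fitted lifetime (2.090 ns) recovers the planted 2.1 ns within the
photon-noise precision of a 10⁴-peak-count acquisition (~0.01 ns), and
the calibration maps it to 238 cP — the microviscosity of a fully
peroxidized bilayer, against ~159 cP for pure POPC. A reduced χ² near
1 and an IRF shift near zero indicate a clean reconvolution fit.

The same pattern works for the other modalities
(`oxmembrane synth scatter … && oxmembrane scatter saxs …` reports
`"d_spacing_A": 62.805…` for a planted 62.8 Å lamellar repeat), and
`oxmembrane run --config cfg.yaml --seed 1 --out results/` executes a
full multi-modal demo pipeline, writing a tidy metric table and a
manifest carrying the configuration hash.

Python API equivalent:

```python
from oxmembrane import synthetic_data as syn, flim

trace = syn.gen_decay(syn.DecaySimSpec(lifetimes=[2.1], amplitudes=[1.0], seed=1))
fit = flim.fit_decay(trace)                       # Poisson-MLE reconvolution
tau = flim.select_reported_lifetime(fit, "mono")  # 2.090 ns
eta = flim.lifetime_to_viscosity(tau, flim.default_calibration())  # 238 cP
```

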