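# Methods

This note documents the models behind `braindose`, the defaults they
use, and what the synthetic stand-ins do and do not capture.

## Energy grid and species

All spectra and response functions live on a common grid of kinetic
energy per nucleon. The default is 128 log-spaced bins from 1 MeV to
10 GeV; particles above 10 GeV are cut off (their flux falls as a power
law and the transport chain is not validated there). Supported species
are H, He, C, N and Fe — protons and helium dominate the GCR number
flux (≈87% and ≈12%), while the heavy ions matter through their high
linear energy transfer.

## GCR model

The modulated GCR flux is computed with the **force-field
approximation**: a single parameter, the solar modulation potential
Φ (MV), maps the local interstellar spectrum (LIS) to the flux at 1 AU,

    J(E, Φ) = J_LIS(E + ΔE) · E(E + 2m) / ((E + ΔE)(E + ΔE + 2m)),

with ΔE = (Z/A)·Φ in MeV per nucleon and m = 938.272 MeV. The proton
LIS is the Burger/Usoskin-style analytic form
J(P) = c1·P^(−2.78)/(1 + 0.4866·P^(−2.51)), P = √(T(T+2Tr)) in GeV;
its coefficients ship as package data (`data/lis_params.json`). The
documented validity range is Φ = 300 MV (solar minimum) to 1200 MV
(solar maximum); the 20 MeV proton flux ratio between those extremes is
≈35, consistent with the one-to-two-orders-of-magnitude modulation of
the low-energy GCR flux over the cycle.

Heavy-ion spectra are the proton LIS scaled by fixed abundances
(He 12/87 of H; C, N, Fe each one third of ~1%/87%), configurable via
`GCRParams.abundances`. This is a composition convenience, not a
species-resolved LIS fit; iron's Z²-weighted dose contribution is
therefore overweighted relative to measured GCR composition, which is
acceptable for the factor-band checks the stand-in chain is used for
but not for absolute heavy-ion dosimetry.

## Transport stand-in (CSDA slab)

Reference brain response functions come from 3-D Monte Carlo transport
through CT-derived head geometry and are loaded with `read_brf`. The
built-in generator replaces that with a deliberately simple 1-D model:

* **Range-energy relation:** R(E) = α·E^p with α = 2.2×10⁻³ g cm⁻²
  MeV⁻ᵖ and p = 1.77 for water/tissue; this tracks published proton
  CSDA ranges to a few percent over 10–250 MeV (7.63 vs 7.72 g/cm² at
  100 MeV). Aluminium shields and cranial bone are treated through
  their areal density as water-equivalent depth.
* **Geometry:** shield (areal density = thickness × 2.70 g/cm³ for Al)
  + cranium (6.5 mm at 1.6 g/cm³ ⇒ 1.04 g/cm²) + per-region tissue
  overburden. Each region is a weighted set of **contiguous 0.5 g/cm²
  scoring layers** (`data/region_depths.csv`): the whole head spans
  0–12 g/cm² uniformly; the lobes are 5-layer distributions with mean
  depths 2 (frontal), 3 (parietal/temporal/occipital) and 5 g/cm²
  (hippocampus), reproducing the observed ordering — frontal least
  shielded, hippocampus most. Contiguous layers make the weighted layer
  sum telescope, which guarantees the generated curve has a single
  interior (Bragg-region) maximum; isolated thin slabs spaced wider
  than their own thickness would instead produce spurious ripples.
* **Dose scoring:** per layer, dose/fluence = (E_in − E_out)·A / t,
  converted at 1 MeV/g = 1.602×10⁻⁴ µGy. Ions scale from protons at
  equal energy per nucleon by Z²/A in stopping (effective depth) and by
  A in deposited energy; no effective-charge correction.
* **Solid angle:** generated BRFs are dose per unit *per-steradian*
  fluence under isotropic exposure, i.e. planar-slab response × 4π sr.
  The convention is declared in every BRF file header; folding a
  per-steradian spectrum with such a BRF integrates the steradian away.

**What the stand-in does not model:** nuclear interactions, secondary
particles (including neutrons), straggling, 3-D geometry and the
minimum-ionizing plateau of the stopping power (the power law
undershoots dE/dx above ~1 GeV). It therefore underestimates the
high-energy response, and absolute doses from it are only order-of-
magnitude. Tests against it check thresholds, shapes, monotonicities
and the pivot mechanism — passing them says nothing quantitative about
doses in real heads; the packaged registry carries the quantitative
results.

## Folding

The fold is a trapezoid rule in log energy: ∫BRF·F dE is evaluated as
the trapezoid of BRF·F·E against ln E on the bin centers. On the default
grid this agrees with a 100×-refined Riemann sum to better than 0.1% for
smooth integrands (oracle-tested). Response functions are log-linearly
interpolated onto the spectrum grid when grids differ, with zero fill
outside their support (conservative), flagged in provenance and logged.
Flux-mode folds are converted to µGy/day with exactly 86 400 s/day;
event doses are reported in cGy (1 cGy = 10⁴ µGy).

## Synthetic SEP ensembles

`make_sep_ensemble` emulates the spectral diversity of large historical
SEP event catalogs: per event, fluence(E) = I₀·(E/30 MeV)^(−γ), with γ
uniform in [2, 4] (falling spectra; the sign is stored positive) and I₀
log-uniform over 10⁴–10⁸ particles cm⁻² sr⁻¹ MeV⁻¹ at the 30 MeV
reference energy — spanning the intensity spread of events that deposit
10–2000 cGy in an unshielded head. An optional exponential rollover
models spectra that steepen at high energy. The default ensemble size
is 53 events (catalog-sized; the analysis functions accept any n ≥ 3).
All draws come from one `numpy` generator with a mandatory seed; there
is no global random state. The generator does not model time profiles,
spectral breaks beyond one rollover, anisotropy, or heavy-ion content
of events (SEP doses are computed for protons).

## Pivot scan and fit

Correlations are computed in linear dose/fluence space with the Pearson
product-moment coefficient; candidate pivot energies default to the
grid restricted to 10–1000 MeV (bracketing all registry pivots,
20–300 MeV). Pivot selection is deterministic: maximum Pcc, ties within
10⁻⁹ broken by the smallest relative RMS residual of the OLS line, then
by the lowest energy (the residual rule matters for degenerate
ensembles — e.g. identical spectral slopes — where Pcc = 1 everywhere).

The dose-fluence law is fitted by unweighted ordinary least squares;
reported uncertainties are plain OLS standard errors from the residual
variance (the ± values in the registry are stored as published, their
exact estimator being unstated there). Calibration: with fluences drawn
uniformly over one intensity scale and 5% Gaussian relative noise,
2-SE intervals cover the true (a, b) in ≳90% of replicates. A known
limitation: when fluences spread over several decades, multiplicative
noise is strongly heteroscedastic and unweighted-OLS slope errors
undercover; a weighted fit would be needed there.

`analytic_pivot_oracle` provides an independent cross-check used in
tests: for pure power-law ensembles the dose factorizes as I₀·g(γ), so
log dose − log fluence(E) = log g(γ) + γ·log(E/E_ref), and the pivot is
the energy minimizing the spread of that quantity over a γ grid (brute
force). Scan and oracle agree within one grid bin on the stand-in BRFs.

## Packaged tables

The ready-function registry (11 scenarios) and the 35-event dose table
ship as plain-text CSV under `braindose/data/`, transcribed at printed
precision; SHA-256 checksums are frozen in the test suite. The event
table keeps printed rounding (including exact zeros behind thick
shields); reduction statistics average per-event fractions and exclude
zero-baseline events with a warning, and two typographically ambiguous
spots are annotated in the file header. SPEL flagging uses strict `>`
against 50 cGy per 30 days ("exceeds" means strictly above).

## Problem sizes

Default analyses use the 128-bin grid, 53-event ensembles, 200-replicate
fit calibration and four shield depths for the pivot sweep; the full
test suite and the acceptance script each complete in seconds on one
core.
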