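# braindose

Deep-space radiation dosimetry for the human brain.

Astronauts outside the magnetosphere are exposed to two radiation
sources: the quasi-steady galactic cosmic rays (GCRs), modulated over the
solar cycle, and sporadic solar energetic particle (SEP) events, which
can deposit tens to thousands of cGy in the head within hours. `braindose`
implements the dose-assessment chain used to quantify both for the brain
and its sub-regions (frontal, parietal, temporal and occipital lobes, and
the hippocampus), and the statistical machinery that turns 35+ historical
SEP events into a one-line operational dose forecaster.

It is aimed at space-weather and radiation-health researchers who need
desk-scale dose estimates, pivot-energy analyses, or a fast nowcast of
the brain dose of an ongoing SEP event.

## The method

**Folding.** A brain response function (BRF) `{D/f}(E)` gives the dose
per unit primary fluence as a function of particle energy, per region,
shield and species. Folding it with a particle spectrum `F` gives the
dose (rate):

    Ḋ = Σ_E  {D/f}(E) · F(E) · ΔE

A flux-mode GCR spectrum (particles cm⁻² sr⁻¹ MeV⁻¹ s⁻¹) yields µGy/s;
an event-integrated SEP fluence yields the event dose. Reference BRFs
come from full Monte Carlo transport through CT-derived head geometry
and can be loaded from files; the package also generates a documented
CSDA (continuous-slowing-down) slab stand-in so the entire chain runs
without external data.

**Pivot energy.** SEP events differ in intensity and spectral slope
(power-law index roughly −4…−2), but there is one energy — the *pivot
energy* — at which the event fluence alone predicts the dose: dose lost
below the pivot when the spectrum softens is exactly compensated above
it. Operationally, `pcc_scan` finds the energy maximizing the Pearson
correlation between per-event fluence and per-event dose across an
ensemble. At the pivot, dose vs. fluence is fitted with

    D_brain [cGy] = a · I_pivot + b

**Ready functions.** The package ships the fitted `(pivot, a, b, R²)`
registry for eleven scenarios — the whole head under 0/2 mm/5 mm/2 cm/
5 cm/10 cm of aluminium, and five brain regions behind 2 mm — plus the
35-event dose table used for shielding statistics and for flagging
events against the 50 cGy / 30-day short-term CNS exposure limit (SPEL).
Head pivots rise from 20 MeV (no shield) to 300 MeV (10 cm Al,
27 g/cm²); region pivots at 2 mm run from 75 MeV (frontal) to 120 MeV
(hippocampus, the most shielded structure).

## Worked example

Forecast the head dose of an event whose fluence at 40 MeV (the
head/2 mm pivot) is 10⁶ particles cm⁻² sr⁻¹ MeV⁻¹:

```sh
$ braindose predict --region head --shield 2mm --fluence 1e6
7.9380 cGy  [head/2mm: pivot=40 MeV, a=5.890e-06 cGy sr cm^2 MeV, b=2.048 cGy, R^2=0.998]
```

i.e. D = 5.89×10⁻⁶ · 10⁶ + 2.048 = 7.938 cGy — well below the 50 cGy
SPEL. The same fluence at the hippocampus pivot (120 MeV) would signal a
much harder event:

```sh
$ braindose predict --region hippocampus --shield 2mm --fluence 1e6
26.9800 cGy  [hippocampus/2mm: pivot=120 MeV, a=2.680e-05 cGy sr cm^2 MeV, b=0.18 cGy, R^2=0.99]
```

The full synthetic chain — 53 power-law events folded with the stand-in
BRF, correlation scan, pivot and linear fit:

```sh
$ braindose pivot-scan --n-events 53 --seed 7 --region head --shield 2mm
scenario,pivot_energy_MeV,max_pcc,a,a_se,b_cGy,b_se,r_squared,n_events
head/2mm,89.7687,0.999735,1.605199e-04,5.178e-07,-0.3831,0.640,0.999470,53
```

The maximum correlation is ≈0.9997 at ~90 MeV: the stand-in BRF is
thinner-bodied than the Monte Carlo one, so its pivot sits higher than
the published 40 MeV, but the pivot mechanism (and its increase with
shield depth) is reproduced. In Python:

```python
import braindose as bd

rf = bd.lookup("head", "2mm")
rf.predict(1e6)                      # 7.938 cGy

table = bd.table1_fixture()          # 35 events x 11 scenarios, cGy
_, mean_pct = bd.reduction_stats(table, "no_shield", "al_2mm")
bd.exceeds_limit(table)              # SPEL flags per cell
```

Other subcommands: `gcr-dose` (µGy/day per region/shield/Φ), `sep-dose`,
`make-brf`, `fixtures` (writes a complete synthetic workspace).

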