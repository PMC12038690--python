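# Methods

`pegsim` simulates arrays of paper-based electrical gas sensors (PEGS)
for breath-ammonia measurement and implements the complete analysis chain
that turns raw conductance traces into NH3 readouts: differential
humidity compensation, slope extraction, calibration with limit of
detection, and paired cohort statistics.  This note documents the model,
its assumptions, the parameters that matter, and what the synthetic data
do and do not establish.

## Sensor model

A PEGS is chromatography paper with printed carbon electrodes.  Water
adsorbs on the cellulose fibres; above roughly 40% relative humidity (RH)
the adsorbed layer behaves like bulk water and dissolved ions conduct.
The readout is the conductance

G = G_bg + k · w(t) · [ S_paper + Σ_i c_i |z_i| µ_i ],

with `w` the water-film filling fraction in [0, 1], `c_i = n_i / V` the
molar concentration of deposited/reacted ion species *i* in the 10 µL
deposit volume, `z_i` its charge, `µ_i` its mobility (cm² V⁻¹ s⁻¹),
`S_paper` the mobility-weighted strength of ions native to wet cellulose
(this is what gives untreated sensors their humidity response), `k` a
geometric cell factor and `G_bg` the dry-paper floor.  With the defaults
(`k = 0.8`, `G_bg = 1 nS`, `S_paper = 1.5e-4`), impedances across
20–100% RH and all functionalizations stay within the kΩ–GΩ operating
window of the physical readout.  The AC excitation of the real
electronics is reduced to this pure conductance; no reactive component is
modelled.

Mobilities: H3O⁺ 36.23e-4 and NH4⁺ 7.63e-4 (the contrast that makes acid
neutralization read as a conductance *drop*), plus standard
infinite-dilution values for Na⁺ (5.19e-4), OH⁻ (20.5e-4), HCO3⁻
(4.61e-4), SO4²⁻ (8.29e-4), CO3²⁻ (7.18e-4).

### Water film

`W_eq(RH)` is logistic with midpoint 60% RH and scale 10 (≈0 below 20%
RH, where paper sensing is known to fail; near saturation above 90%).
The film relaxes toward `W_eq` first-order, with `tau_adsorb = 120 s`
when rising and `tau_desorb = 360 s` when falling — desorption from
paper is thermodynamically less favorable.  The pair is calibrated so
that under 8 s/4 s humid/dry cycling the cycle-averaged film reaches 95%
of its stationary value at 7.0 minutes (dense-integration check),
matching the equilibration window observed on the bench.  Each update
uses the exact exponential solution, so results are step-size-exact for
piecewise-constant RH.

### Chemistry

* **Acid sensors (A)**: 10 µL of H2SO4 at 0.001–0.1 M deposits
  `2MV` mol H3O⁺ and `MV` mol SO4²⁻.  Absorbed NH3 converts H3O⁺ to
  NH4⁺ one-to-one (two NH3 per H2SO4); because NH4⁺ is ~4.7× slower than
  H3O⁺, conductance falls while acid remains.  `absorb_nh3` implements
  this reaction endpoint exactly (the stoichiometric claims in the tests
  are exact), while the simulator applies a kinetic *sticking factor*
  `n/(n+K)` per step (`K = nh3_half_saturation = 2.5e-8 mol`): as acid
  runs low, an increasing share of incoming NH3 follows the
  untreated-sensor route instead, so exhaustion is an exponential
  approach rather than a kink.  This matters for the human pipeline —
  with an abrupt cutoff, high-NH3 subjects complete neutralization in
  the first minutes and the endpoint-normalized differential loses its
  signal support.
* **Weak-base route**: NH3 arriving at a neutral film ionizes with
  fraction `weak_base_fraction = 0.15` to NH4⁺ + OH⁻; the rest pools
  un-ionized (nitrogen balance is exact: delivered = NH4⁺ + pool).  The
  value is chosen so an exhausted 0.001 M acid sensor nets a conductance
  *rise* under 5 ppm NH3 (it "becomes an untreated sensor"), while
  endpoint-normalized untreated traces at 0 vs 5 ppm still agree within
  ~4% — the humidity swing dominates their dynamic range, which is what
  licenses the differential analysis.
* **Base sensors (B) and CO2**: while OH⁻ remains, CO2 + OH⁻ → HCO3⁻
  (fast anion → slow anion: drop).  Afterwards CO2 dissolves with a
  pH-scaled ionization yield (`co2_ionization_fraction = 0.2` times a
  logistic in pH with midpoint 5): acidified films take up almost no
  CO2, reproducing the acid sensors' CO2 insensitivity, while neutral
  and sodium-bicarbonate films show a reversible rise.  The pH used here
  excludes CO2's self-generated hydronium (a bicarbonate-buffered film
  does not self-quench the way deposited mineral acid does).  Physically
  dissolved CO2 outgasses first-order (`tau_outgas = 120 s`), reverting
  its ion pairs — this is the reversibility of the untreated sensor.
  Where OH⁻ and HCO3⁻ coexist, carbonate forms slowly
  (`tau_carbonate = 600 s`); after exposure ends this continues and
  produces the delayed second conductance drop seen on strongly
  base-treated sensors.
* **Capture**: a sensor absorbs `eff · flow · ppm·1e-6 / 24.45 L/mol`
  mol/s.  `capture_efficiency = 0.06` for NH3 in the characterization
  chamber — calibrated so 5 ppm depletes a 0.01 M acid deposit over
  about 10 minutes of continuous exposure, with the trace still visibly
  declining at the end.  CO2 uses 1.5e-5 (far less soluble), so 5% v/v
  CO2 exhausts 0.01 M NaOH within ~2 minutes but not 0.1 M within 10.
  The wearable mask chamber ducts the full exhaled stream directly over
  the array, so cohort simulations use a larger efficiency (0.26, see
  below).

Integration is operator splitting at one step per sample (0.1 s at the
10 Hz default): film update → gas uptake → slow desorption chemistry →
readout.  All sub-steps are exactly integrated for constant conditions,
so the 0.1 s production step agrees with a 100× denser integration to
~1e-5 sup-norm.  Electroneutrality holds to 1e-18 mol after every
operation by construction (all reactions swap equal charge).

## Protocols and noise

Chamber runs: 2 min baseline, gas step, 5 min recovery, all at constant
RH (default 65%), starting pre-equilibrated at the chamber humidity.
Breathing runs: 8 s at 90% RH with NH3 in the stream ("exhale", 2,000
mL/min ≈ 267 mL tidal volume) alternating with 4 s at 50% RH
("inhale"), starting from 45% room RH; a 15-minute recording is exactly
75 cycles.

Measurement noise is multiplicative on the clean traces: a lognormal
per-channel baseline multiplier (CV 15%, the paper-to-paper
microstructural spread), per-sample white noise (0.5%), a random linear
drift per channel, and optionally a sinusoid at the 12-s breathing
period.  Bench recordings default to ±0.1% drift per 15 min (mass-flow
controlled rig); human recordings use ±5% drift and 2% oscillation
(mask fit, motion, condensation).

## Signal pipeline

Chamber analysis: per-channel ΔG/G₀ against the pre-exposure baseline,
then an ordinary least-squares line from the trace peak (+30 s) to the
end; slopes are reported per minute.  Breathing/human analysis: 1,000-
point centered moving average (100 s ≈ 8 breathing cycles; shrunken
windows at the edges keep the endpoint defined), division by the 15-min
endpoint, averaging of replicate channels per functionalization, and the
differential S_NH3 = S_A − S_U.  Humidity affects both arrays
identically and multiplicatively, so it cancels in the differential to
first order (verified: the 0-ppm differential slope is <1e-4 of the
5-ppm slope).  The slope is extracted either post-peak (bench runs; the
peak search is restricted to the first half of the recording, where the
physical neutralization peak always lies, so that blank runs do not fit
arbitrarily short windows around late noise excursions) or, for human
recordings, on the interval from 90% to 20% of peak height after
rescaling the differential to its own maximum, which makes subjects
comparable.

## Calibration and statistics

Calibration fits mean slope vs concentration by ordinary least squares
(R² = 1 − SS_res/SS_tot, defined as 0 for flat responses); inversion is
linear with clipping at zero.  The limit of detection is the lowest
tested concentration whose mean |slope| exceeds the blank mean + 3 SD of
|blank| (≥3 blank replicates required; ascending scan).  The cohort
comparison is the one-tailed (right) paired-samples t test with the
Student tail computed through the regularized incomplete beta function
(agreement with an independent high-precision implementation to 1e-10;
type-I error calibrated to 0.05 ± 0.01 under the null at 10⁴
replicates).

## Synthetic cohort

Each subject has a latent breath-NH3 level drawn from a lognormal
truncated to the published clinical range — healthy 425–1,800 ppb,
diseased 820–14,700 ppb — with the location solved so the truncated mean
is exactly 960 / 4,880 ppb and log-scale sigma set to one eighth of the
log-range (mass concentrated near the clinical mean; extremes reachable).
A full candy draws from the disease law; half/quarter candies scale a
disease draw by the dose fraction with 25% lognormal between-dose noise,
which makes neighbouring doses statistically inseparable, as observed.
Subjects keep their channel multipliers and room humidity (50 ± 1.5% RH)
across sessions, and their two sessions' latent levels share a
correlated normal score (ρ = 0.9), so within-subject slope pairs are
positively correlated — the structure the paired test exploits.
Recordings are 15 minutes on the human array (three 0.01 M acid + three
untreated sensors) at the mask capture efficiency of 0.26, calibrated so
the cohort fold-change distribution centers on the observed ~3-fold
control→candy slope increase (mean 3.06, SD ≈ 0.25 across cohort seeds
at n = 8 — the spread reflects genuine subject sampling at this cohort
size).

**What the synthetic data do not show.**  The generator reproduces the
statistical structure the analysis assumes — latent concentration
ranges, paired design, humidity dynamics, channel variability and
measurement noise — but not oral physiology (salivary urea, candy
dissolution, consumption style), inter-breath CO2, temperature effects,
sensor aging, or motion artifacts beyond multiplicative drift.  Passing
tests therefore demonstrate that the *analysis chain* recovers known
ground truth under realistic signal structure, not that the physical
sensor achieves these numbers.

## Numerical choices and edge cases

* Degenerate fits: all-identical x raises an error; flat y returns
  R² = 0 by convention.
* Zero-variance paired differences report p = 0 (positive mean) or 1
  (negative); identical samples give t = 0, p = 0.5.
* A trace whose maximum sits at the final sample has no decline and is
  an error for post-peak fitting; a peak at the first sample (decline
  from the start) is accepted.
* Peak-fraction intervals that never reach the 20% crossing fall back to
  the trace end; never reaching 90% is a degenerate-interval error.
* Recording CSVs round-trip losslessly to 1e-12 relative (17 significant
  digits); readers validate grid uniformity, positivity and channel
  metadata with row numbers in error messages.

## Problem sizes

Default experiment sizes used by the test suite and the acceptance
script: chamber calibrations use 7 concentrations × 3 replicates of
17-minute runs on a single acid channel; breathing calibrations 6 × 3
15-minute runs on the six-channel array; LOD 6 blanks + 5 × 3 runs;
cohorts 8 subjects × 2 conditions; integrator cross-checks run 1-minute
protocols at 10 Hz vs 1 kHz.  A full acceptance pass computes everything
from scratch in well under a minute per experiment family.

## Known limitations

* The conductance law is linear in ionic strength (no activity
  corrections, ion pairing, or percolation effects of partially wetted
  fibre networks).
* Film pH is a coarse classifier based on deposited acid/base, not a
  full speciation equilibrium; the CO2 rise magnitude on depleted base
  sensors is phenomenological.
* Capture efficiencies are lumped constants per rig geometry; no
  fluid-dynamic model of the chamber or mask.
* The 90%→20% fold-change at n = 8 is intrinsically noisy (SD ≈ 0.25 of
  a ~3.0 mean); single-cohort estimates can deviate 15% from the central
  value.
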