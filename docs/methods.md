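# Methods

## Scope and data model

The package analyses long-format screen tables with one row per
(particle, reporter line, dose, replicate) carrying viability (% intact
cells versus vehicle control), mean GFP fluorescence and, where relevant,
particle autofluorescence; plus a particle metadata table (diameter,
density, element mass fraction, dose basis). Five analysis stages —
synthesis, Hill fitting, dosimetry, dose-metric identification, reporter
calling — communicate exclusively through CSV contracts so each is
independently testable. The fitting stages are also exposed as
scikit-learn-style estimators (`HillCytotoxicityModel`,
`DoseMetricIdentifier`) with `fit`/`predict`/`get_params`, so they compose
with sklearn tooling; the module-level functions are thin wrappers.

## Hill cytotoxicity model

Viability is modelled as `V(C) = 100 / (1 + C/LD50)` — a Hill curve with
the slope fixed at 1, which is the convention for this screen's LD50
estimates. The single parameter is found by ordinary least squares on
viability percent, minimised over log(LD50) (bounded scalar minimisation):
optimising the logarithm keeps the parameter positive and makes the
conditioning independent of the dose scale, so the fit is exactly
equivariant under dose-unit changes. No replicate weighting is applied
(the screen reports mean ± SEM but no error model). Vehicle-control rows
are excluded: the model is anchored at 100 % by construction and dose-0
rows carry no information about LD50.

**Censoring.** A fit is reported as the bound `LD50 > max tested dose`
when either (a) the mean viability at the top dose exceeds 75 % — the
screen's own dose-finding rule treats 50–75 % top-dose cytotoxicity as the
informative regime, so above 75 % viability the curve's midpoint was never
approached — or (b) the least-squares optimum exceeds twice the top tested
dose, in which case the point estimate would be an extrapolation.
Censored fits have no equi-response doses; requesting one raises an error
rather than extrapolating.

**Equi-response doses.** With the slope fixed, inversion is closed-form:
`ED_x = LD50 · x/(100−x)`. The default response level for dose-metric
analysis is a 20 % viability decrease (ED20 = LD50/4), configurable.
Closed-form inversion of the fitted curve replaces external
benchmark-dose software here; this is a deliberate substitution — the
fixed-slope model makes the equi-response dose an analytic function of the
one fitted parameter.

## Particle dosimetry

All particles are treated as monodisperse spheres at their nominal
diameter; polydispersity, agglomeration and sedimentation (delivered-dose
modelling) are out of scope. Conversions, with d in cm and ρ in g/cm³:
per-particle mass `m_p = ρ(π/6)d³`, number `N = C/m_p`, surface area
`SA = Nπd² = 6C/(ρd)`. Interfaces use nm for diameters, µg/mL for mass
doses, cm²/mL for surface area. Element-mass doses (e.g. µg Cd/mL) are
divided by the element mass fraction before geometry. For the CdTe
worked example the defaults are bulk CdTe density 5.85 g/cm³ and Cd mass
fraction 112.414/(112.414+127.60) ≈ 0.468 from standard atomic masses;
both are assumptions (suppliers do not publish per-lot values) and both
cancel out of the log-log slope, affecting only the intercept.

## Dose-metric identification

Equi-response doses across a size series are converted to particle numbers
and fitted by unweighted OLS on (log10 d, log10 N); base-10 logarithms
throughout. Canonical slopes: −2 surface area, −3 volume/mass, 0 particle
number. Classification picks the canonical slope strictly nearest the
fitted slope when within a tolerance, default 0.75: the canonical slopes
are at least 1 apart, so 0.75 accepts moderately off-canonical series
(including the worked example's −1.44) while still rejecting nothing as a
forced choice — slopes equidistant between two canonical values (to 1e-9,
absorbing float error) and slopes farther than the tolerance from every
canonical value classify as *intermediate*, reported with the exponent
p = −m and the invariant constant `10^q = N·d^(−m)`. A flat series
(zero variance in log N) is a perfect number-metric line; its r² is
reported as 1 although the correlation coefficient is formally undefined.

## Reporter-activation calling

Fold induction is the ratio of replicate means: autofluorescence is
subtracted per well (before averaging — the alternative order is
indistinguishable for the mean but matters for the floor), corrected
values are floored at zero with a logged warning, replicates are averaged,
and the dose mean is divided by the vehicle-control mean. Verdicts per
(particle, reporter): maximum fold over doses with viability > 25 %;
strictly > 2 → positive, in (1.5, 2] → weak positive, otherwise negative.
Fold exactly 2.0 is assigned to the weak band so the bands are exhaustive
(the conventional inequalities ">1.5 but <2" and ">2" leave 2.0
unassigned). The viability gate applies per dose, not per particle; if
every dose is gated the verdict is *uninterpretable*. No statistical test
is applied to folds — the screen's rule is threshold-only.

**Dose selection.** The exposure ladder emulates the screen's dose-finding
rule: the top dose is the smallest tested dose with 50–75 % cytotoxicity;
with no cytotoxicity reaching 50 % anywhere, the top dose is the 100 µg/mL
cap; four two-fold dilutions complete the five-dose ladder. One edge the
rule leaves open: cytotoxicity can jump over the 50–75 % band between
consecutive tested doses, in which case the largest dose still under 50 %
cytotoxicity is used (staying below excessive toxicity rather than above).
A screen already above 75 % cytotoxicity at its lowest dose errors with
advice to re-screen lower.

## Synthetic-data generator

The generator emulates well-level flow-cytometry summaries, not raw event
data. Viability follows the unit-slope Hill curve around a configured true
LD50 (non-cytotoxic particles are flagged with no finite LD50); GFP is a
control level (default 200 AU) times a saturating induction curve
`fold(C) = 1 + (F_max−1)·C/(C+D_half)`; particle autofluorescence is
optional and dose-proportional, reported in its own column. Replicate
noise is multiplicative lognormal with configurable CV (default 0.1):
readouts are strictly positive and reported as mean ± SEM without a stated
distribution, so a mean-1 lognormal is the natural choice; viability is
truncated to [0, 100] after noise because it is a percentage of control.
The noise CV and fold-curve parameters are generator choices, not
literature values — real replicate variances for such screens are
unpublished. One integer seed drives the whole table through a
counter-based substream per (particle, reporter)
(`SeedSequence(seed, spawn_key=(particle_idx, reporter_idx))`), so
regeneration is byte-identical and independent of row order. Exposure
doses come from the dose-selection rule applied to the particle's own
noiseless cytotoxicity curve (geometric mean of its finite LD50s across
reporters), so generated panels obey the screen's design.

What passing tests on synthetic data do **not** show about real screens:
the generator has no dose-measurement error, no systematic plate or batch
effects, no particle settling (so nominal equals delivered dose), and
noise is homoscedastic on the log scale; real deviations from these
assumptions would widen, and could bias, slope and LD50 estimates.

## Verification problem sizes

The recovery suites run at sizes chosen to give stable rates at modest
cost: LD50 recovery over 200 simulated panels (true LD50 log-uniform on
[1, 100] µg/mL, CV 10 %, n = 3 replicates) requiring median absolute
relative error < 15 % and an unbiased sign test; end-to-end dose-metric
recovery over 200 seeded runs per canonical metric at three diameters
(10, 17, 30 nm — a factor-3 span keeps number-driven doses inside the
100 µg/mL cap, since mass scales with d³), requiring ≥ 95 % correct
classification. Noise-free identities (Hill round-trip, canonical slopes,
dosimetry consistency) are asserted at 1e-6 relative or tighter.

## Known limitations

- The unit-slope Hill model cannot represent steeper-than-unit viability
  curves; size series whose smallest particles act through additional
  mechanisms will show it as slope drift, not as a model-fit flag.
- Censoring is a hard rule, not an inference; bounds carry no confidence
  level.
- No uncertainty intervals on the log-log slope (bootstrap would be a
  natural extension but is not part of the analysis contract).
- Dosimetry assumes ideal spheres at nominal diameter; for rods,
  aggregates or broad size distributions the number and surface
  conversions are only nominal.
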