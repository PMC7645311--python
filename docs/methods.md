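# Methods

This note documents the model behind `piglca`: what is simulated, which
constants matter, what the synthetic cohorts do and do not emulate, and the
numerical choices a user should know before trusting (or extending) the
results.

## System and functional unit

The system is a cradle-to-farm-gate pig production chain: feed production,
the reproducing sow and her litter, the post-weaning phase, the individually
modelled fattening pig, manure management through housing, outside slurry
storage and field spreading, and on-farm water, energy and feed transport.
All flows are expressed per kg of live pig at the farm gate.  Each fattening
pig carries its own fattening-stage flows, its full post-weaning stage, and
an equal share (1/weaned piglets) of one sow reproductive cycle.  Burdens
are divided by *weaned* piglets because only weaned piglets enter fattening
and hence reach the functional unit.

## Growth model

Daily net-energy (NE) intake is a Gamma function of age in days,
`NEI(t) = A · t^k · exp(−t/θ)` (MJ/day).  The exact parametric form used in
commercial growth calibration tools is not public; any smooth unimodal
positive curve calibrated to the same mean daily intake and total intake
reproduces the NE flux the downstream chain consumes, so the Gamma family
with defaults k = 2, θ = 80 d (intake rising through most of fattening,
peaking near day 160) is used and both parameters are exposed in
`ModelConfig`.

The daily budget is

```
NEm = m · 0.75 · BW^0.60          maintenance, MJ/day
RE  = NEI − NEm                    retained energy
PD  = min(pd_max, ρ·RE/23.6)       protein deposition, g/day
LD  = (RE − 23.6·PD)/39.7          lipid deposition, g/day
```

with tissue energy densities 23.6 kJ/g protein and 39.7 kJ/g lipid, a
marginal partition fraction ρ ∈ (0,1), and an *individual maintenance
multiplier* m (see below).  `pd_max` defaults to "none": calibrated pigs on
this trajectory do not hit a deposition plateau between day 68 and
slaughter; the cap exists for stress tests.

Live weight closes through body composition: empty BW = BP + BL + water +
ash with water = 4.88·BP^0.855 kg and ash = 0.20·BP, and live BW =
empty/0.95 (5% gut fill).  These allometries are conventional defaults of
NE-based pig growth modelling, not measured values; all are config
constants.  Because each kg of protein gain carries roughly 3–4 kg of
water, protein-directed growth yields live weight much more cheaply per MJ
than lipid-directed growth — this single mechanism links feed efficiency,
body composition and the environmental results.

Integration is explicit daily Euler (step 1 d; any finer step is allowed),
stopping on the first step with BW ≥ target; slaughter age, BP, BL and
cumulative NE are linearly interpolated to the exact target BW.  The daily
identity NEI − NEm = (23.6·PD + 39.7·LD)/1000 holds to machine precision by
construction and is asserted in the tests.  A step of 1 d agrees with a
0.01 d integration to well within 0.5% on slaughter BP, BL and duration.

### The maintenance multiplier

Residual feed intake is, by definition, the part of intake that production
traits do not explain.  In a deterministic energy model with fixed start
and target weights, drawing ADFI, FCR and slaughter BP/BL independently
over-determines the energy balance; early versions that forced the balance
through initial body composition alone made ~30% of realistic trait
combinations infeasible.  The model therefore gives each pig a maintenance
multiplier m: after the intake curve is calibrated to the pig's ADFI and
FCR, (ρ, m) are solved jointly (nested Brent iterations) so the simulated
fattening duration and slaughter BP/BL hit their targets.  m absorbs
exactly the intake variation that growth and composition do not explain —
the accepted biological substrate of RFI (basal metabolism, activity,
protein turnover).  Consistently, the calibrated LRFI (efficient) mean pig
resolves to ~7% lower maintenance than the HRFI mean pig.

## Nutrient balance and emissions

Excretion per stage is intake − retention, exactly.  Retention: N =
0.16·ΔBP (the 6.25 protein convention); P, K, Cu, Zn at fixed per-kg-gain
coefficients (5.3 g, 2.2 g, 2.5 mg, 25 mg per kg live gain — literature-
style defaults, config-exposed); DM/OM retention is the body solids.  For
the elements this is the standard excretion estimate.  For DM and OM the
balance residual also contains respired carbon, so the storage-CH4 chain
does **not** use balance OM directly: volatile solids entering storage are
`vs_from_om` (default 0.25) of balance OM, approximating the faecal share.

The emission chain is linear in the excretion vector.  Housing: NH3-N as a
fraction (0.25) of the TAN pool (TAN = 0.70 of excreted N), N2O-N and NO-N
as fractions (0.002 each) of total N.  Storage: CH4 = VS·B0·MCF·0.67 with
B0 = 0.45 m³/kg VS and MCF = 0.10; NH3-N 0.05 and N2O-N 0.005 of stored N.
Spreading: NH3-N 0.25 of applied TAN, direct N2O-N 0.01 of applied N,
leaching 0.15 of applied N, P runoff 0.20 of applied P, indirect N2O from
volatilized (0.01) and leached (0.0075) N.  Gas masses are reported as the
gas species (17/14, 44/28, 30/14 stoichiometry) because characterization
factors are per kg gas.  Indirect N2O is emitted off-site from N already
booked as NH3 or leaching, so the farm N ledger counts NH3-N, NO-N, direct
N2O-N, leached N and net field N — and closes to 1e−9.

Field-applied manure nutrients displace mineral fertilizer at 75% (N) and
100% (P, K) equivalency.  The credit subtracts the *production-phase*
impacts of the avoided fertilizer only (the conservative convention); no
credit is taken for avoided field emissions.  Biogenic CO2 from animals and
manure is excluded from climate change; CH4 and N2O are included.

## Farm inputs

Drinking water is 4.5 / 4.0 / 2.5 / 2.7 L per kg feed for lactating,
gestating, post-weaning and fattening animals; cleaning water 2300 L per
sow-year and 30 L per fattening pig; energy 0.42 kWh per kg LW split
70/20/10 over electricity/oil/gas (the carrier split is an assumption);
feed transport 0.10 tkm per kg feed (assumption).  Everything is linear in
its driver, so per-kg-LW results are herd-size invariant.

## Fixture factor tables

No licensed inventory database is used.  The diet is a one-phase
cereal/soybean-meal style feed (9.7 MJ NE/kg, 160 g CP/kg) and the per-kg
ingredient impact factors, characterization factors (e.g. CH4 34, N2O 298
kg CO2-eq/kg; NH3 1.96 kg SO2-eq/kg), and sow/post-weaning herd profiles
are explicit synthetic fixtures, tagged as such in their provenance fields
and overridable from JSON files.  Land occupation is carried by feed
ingredients only, which makes the feed segment's LO share exactly 100% —
a structural property the tests assert.  Absolute impact levels therefore
depend on fixture choices and should be read as order-of-magnitude
(climate change lands at ~3.4–3.6 kg CO2-eq/kg LW, within the published
range for European pig systems); *relative* line differences, correlations
and sensitivities are the quantities this package is built to estimate.

## Synthetic cohorts

`default_line_specs()` encodes the study conditions: LRFI n = 60 and HRFI
n = 58 pigs, fattening from day 68 (28 kg) to 115 kg target BW, the HRFI
mean pig finishing at day 179; LRFI ADFI exactly 7% below HRFI and LRFI
FCR exactly 0.130 kg/kg below the HRFI baseline of 2.60.  (The baseline
FCR is chosen from the energy feasibility of the growth closure; the
absolute −0.130 difference is treated as primary.)  Trait SDs (ADFI 0.16,
FCR 0.15 kg, BFT 1.8 mm, BP/BL 0.05) and the 4×4 correlation matrix are
documented assumptions emulating a selection experiment's within-line
structure; BP/BL means (0.94 vs 0.86) make the efficient line leaner while
keeping slaughter body protein nearly identical between lines.

Two design choices matter for interpretation:

* **Mean-centering.** Each cohort's multivariate-normal draw is centered so
  realized line trait means equal the specified means exactly.  The line
  contrast *is* the study condition; without centering, sampling noise of
  the means at n ≈ 60 would dominate the line comparison.  Within-line
  variances and correlations are untouched (up to O(1/n)).
* **Determinism of ADG.** With fixed start and target weights, ADG =
  ADFI/FCR identically, so ADG has no variation independent of intake and
  efficiency.  Within-line RFI–impact correlations consequently come out
  higher (~0.6–0.9) than in real data, where ADG varies independently.
  Results involving RFI correlations are upper bounds in that specific
  sense.

Rows outside wide plausibility bounds, or (rarely) unreachable by the
calibration, are redrawn individually with bounded retries; generation is
fully reproducible by seed.

## Analyses

* **Line comparison:** Welch (unequal-variance) two-sample t-test per
  category; percent difference defined as 100·(HRFI − LRFI)/HRFI.
* **Correlations:** within-line Pearson r with 95% CI =
  tanh(atanh r ± 1.96/√(n−3)).
* **OAT sensitivity:** each of ADFI, ADG, FCR, BP, PD, BL, BP/BL, BFT is
  moved to mean ± 2 SD with the others at means; the representative pig is
  rebuilt (ADFI at fixed ADG scales the intake curve over an unchanged
  window; ADG at fixed ADFI stretches the window; composition traits move
  the partition parameter at fixed intake) and re-run through the full LCA.
  A trait is sensitive if any category moves more than 5%.  BFT has no
  lever in the deterministic model (it enters only the RFI regression) and
  is reported as impact-inert, zero change.  Infeasible perturbations are
  reported as failed cells, not raised.  SDs for the non-drawn traits (ADG
  55 g/d, BP 1.0 kg, PD 10 g/d, BL 1.5 kg) are assumptions on the cohort
  scale.
* **Parallel Monte Carlo:** uncertainty lives on the *background* factors
  (every emission factor except the printed equivalencies and the CH4 gas
  density, every feed-impact cell, every characterization cell) as
  log-normal multipliers with median 1 and geometric SDs 1.3 / 1.2 / 1.1
  respectively (within the 1.1–1.5 range typical of inventory databases).
  Each draw is applied to both lines' mean pigs simultaneously; a category
  is counted for LRFI when its impact is *strictly* lower (ties count as
  no win).  Animal traits are not resampled.  Because the deterministic
  difference is positive in every category and the model is monotone in
  each factor, shared draws essentially never reverse the ranking.

## Numerical choices and degenerate inputs

* Intake calibration: the two targets (mean DFI and total FI over the same
  window) are redundant when consistent, so shape and rate stay at their
  defaults and the amplitude is solved in closed form; inconsistent targets
  beyond 20% violate the precondition, and residuals beyond 0.5% raise a
  calibration error reporting them.
* Brent tolerances: 1e−8 on ρ, 1e−7 on the maintenance multiplier;
  brackets ρ ∈ [0.03, 0.97], m ∈ [0.55, 1.70], shrunk adaptively where an
  endpoint stalls the pig (energy deficit or non-convergence).
* A pig whose NE intake falls below maintenance raises an energy-deficit
  error naming the day; a pig not reaching target BW within 400 days raises
  a non-convergence error.
* Problem sizes: the packaged analyses run 118-pig cohorts, five cohort
  replicates for the correlation checks and 1000 Monte Carlo draws — about
  a minute end to end on one CPU.

## Known limitations

* Absolute impact levels depend on fixture factor tables; only relative
  and structural results are database-independent.
* One-phase feeding; no amino-acid nutrition, no digestive (GE→DE→ME)
  model — diet NE/ME are taken as given.
* The sow stage is a profile, not a model: no lactation curve, parity
  structure or gilt rearing; sow-litter values are synthetic fixtures.
* No slurry temperature/pH dynamics; solid-manure pathways are out of
  scope; the NO-N housing fraction is an assumption.
* OAT sensitivity ignores trait correlations by construction; a global
  (variance-based) sensitivity analysis is out of scope.
* Passing tests on synthetic cohorts demonstrate internal consistency and
  the mechanisms linking efficiency to impacts — not predictive accuracy
  for any particular real herd.
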