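# Methods

## Model structure and assumptions

The model is a linear, time-invariant compartment system for a parent
glycoside (Rh2) and its deglycosylation metabolite (PPD), dosed as an I.V.
bolus of either analyte or an oral bolus of Rh2. State amounts are in nmol
per kg body weight (dose conversion: nmol/kg = mg/kg × 10⁶ / molar mass;
defaults 622.87 g/mol for Rh2 and 460.73 g/mol for PPD, standard literature
values, overridable per dose event). Concentrations are central amount
divided by the central volume (L/kg), giving nmol/L.

Compartments: stomach Rh2, stomach PPD, a transit chain T1–T3, colon PPD,
and central/peripheral pairs for each analyte, plus four cumulative
elimination slots that close the mass balance. The full right-hand side is
spelled out in `deglypk.model.system_matrix`; every column of the rate
matrix sums to zero, so mass conservation is structural, not numerical.

Choices made where the published description leaves the equations open:

* **Biliary output feeds the head of the transit chain.** Asymptotic route
  fractions are invariant to where along the chain bile enters (only the
  timing changes, and no printed number constrains the timing), verified by
  the chain-length-invariance test with 1, 3 and 5 transit compartments.
* **Three transit compartments** by default; configurable for that test.
* **One shared k_t** serves Rh2 intestinal transit, the T3→colon
  transformation step, and PPD absorption from both stomach and colon.
* **No separate liver compartment** — hepatic transformation is merged into
  the plasma compartment.
* **k_e is stored as its components** (k_40, k_43, k_45) and exposed as
  their sum, making the identity k_e = k_40 + k_43 + k_45 unbreakable; a
  supplied k_e either checks against supplied components (10⁻⁹ relative) or
  back-fills k_40.
* No lag times, no saturable elimination, no intact-Rh2 oral absorption
  path: plasma Rh2 after an oral dose is structurally zero, which matches
  the below-LLOQ observation the model was built around.

## Simulation

The system is linear, so states are propagated exactly between output
times with the matrix exponential — the result carries no integration
tolerance. An LSODA path (`method="lsoda"`, rtol 10⁻¹⁰) is retained and is
the propagator of the route-accounting oracle, so closed-form results are
confirmed by a genuinely different numerical route. Mass balance is
asserted at every output time to 10⁻⁶ relative.

Individual simulation applies log-normal parameter multipliers
θᵢ = θ·exp(η), η ~ N(0, ω²) — an `"k_e"` entry scales the three
elimination components jointly so the route split within a subject is
preserved — and multiplicative residual noise y = f·(1+ε), ε ~ N(0, σ²),
truncated at zero (a deliberate deviation from the unbounded normal, since
concentrations cannot be negative).

## Route accounting

Because all transfers are first order, the eventual fate of the dose
factors into branching ratios (`deglypk.routes`). The flux oracle augments
the state with per-route cumulative flux accumulators and integrates until
at least 14 half-lives of the slowest relaxation mode (extending the
horizon up to 4³-fold if slow modes still hold back more than 0.1% of the
dose); closed forms and oracle agree to 0.1 percentage points over wide
log-uniform parameter draws. Percentages are reported unrounded;
nearest-whole-percent rounding is the display convention.

## Estimation

Naive-pooled maximum likelihood under the proportional error model, with σ
profiled out analytically. A full nonlinear mixed-effects engine (FOCE or
SAEM) is deliberately out of scope: three animals per group cannot support
stable random-effects estimation, and between-subject spread is absorbed
into the proportional error. Optimisation is on the log-parameter scale
(bounds 10⁻⁵–10⁴): a multi-start trust-region least-squares pass on the
relative residuals (starts at the user init plus uniform ×[0.5, 2]
perturbations) followed by a Nelder–Mead polish of the full profiled
likelihood, which differs from least squares by the Σ log f term. The
returned objective is never worse than the starting point.

CV% is the log-scale standard error from the Gauss–Newton inverse Hessian
(σ̂² with an n−p degrees-of-freedom correction); 95% CIs are
θ̂·exp(±1.96·SE). In the staged calibration, stage C and D covariances
include the uncertainty of carried-over stage-A/B/C estimates via the
delta method (block-diagonal across stages; the frozen k_43 inherits k_e's
log-variance with correlation one). Without this propagation, sequential
estimation understates uncertainty badly (95% CI coverage ~79% in
replicate-study simulation; ~99% with it).

The staged order: (1) sub-model A on Rh2 after I.V. Rh2 estimates
V_Rh2, k_e, k_47, k_74; (2) sub-model B on PPD after I.V. PPD estimates
V_PPD, k_50, k_58, k_85; (3) k_43 is frozen at biliary_fraction·k_e
(default fraction 0.276, reproducing the reported frozen pair 1.29/3.29 at
two decimals) and sub-model C on PPD after I.V. Rh2 estimates k_45, k_t,
k_60 with k_40 = k_e − k_43 − k_45 maintained throughout the search;
(4) sub-model D on PPD after P.O. Rh2 estimates k_13, k_12, k_20 with
k_t/k_60 carried from stage 3. BLQ records are excluded (M1-style); the
LLOQ is a generator/config input.

## Non-compartmental analysis

Linear trapezoidal AUC (not lin-up/log-down — the dialect of the original
software is unknown, so comparisons to reported NCA values are
interpreted loosely). λ_z by log-linear regression over the terminal
window with the best adjusted R², at least three points, excluding T_max;
t½ = ln 2/λ_z. V_ss = Dose·AUMC∞/AUC∞² is reported only when the profile's
analyte was itself dosed intravenously; for formed or orally dosed
analytes the systemically available amount is unknown and no volume is
identifiable.

## Visual predictive check

Per replicate, n_subjects individuals are simulated with IIV and residual
noise; simulated observations are pooled per nominal time (design times
are fixed, so no binning) and the empirical 5th/50th/95th percentiles
reported. Default 1000 replicates; tests and the acceptance script use 200,
which puts the percentile Monte-Carlo error well inside the tolerance
checked. The validation verdict is "majority of observations inside the
90% interval", reported alongside the stricter conventional 90% reference.

## Synthetic data generator

Emulates the modelled experiment: four Rh2 groups (I.V./P.O. × 10/20
mg/kg, three rats each) sampled at 0.25, 0.5, 1, 2, 4, 8, 12, 16 and
20-or-24 h (24 default), plus an auxiliary I.V. PPD 0.2 mg/kg group used
for stage B. The PPD group uses a standard rat I.V. schedule with early
samples (2, 5, 15, 30 min, then 1–24 h): the PPD study predates the Rh2
experiment and its schedule is not described; with a first sample at
0.25 h the ~1-minute distribution phase (k_50+k_58+k_85 ≈ 36 h⁻¹) is
unobserved and k_58/k_85 are unidentifiable, which is incompatible with
the precise reported estimates for those constants.

Variability magnitudes are not published; the generator's stated
assumptions are ω = 0.3 (log-scale SD) on the clearance/volume-like
parameters V_Rh2, k_e, V_PPD and k_50, σ = 0.2 proportional, and an LLOQ
of 1 nmol/L per analyte. Below-LLOQ values are flagged BLQ with the raw
value kept in a shadow column for testing. Body-weight variation is
ignored: every rate and volume is per kg, so weight cancels.

What passing tests show — and do not. The generator reproduces the study's
*structure* (design, error model, dose proportionality, structural-zero
oral Rh2); it does not reproduce assay drift, correlated residuals,
sampling-time deviations, enterohepatic recirculation cycles beyond the
single transit chain, or the true (unpublished) variability magnitudes.
Parameter-recovery results therefore demonstrate estimator correctness
under the assumed error model, not performance on the original raw data;
the published per-parameter CV% values are not reproducible without that
raw data and the original FOCE ELS engine.

## Numerical choices

* Matrix-exponential propagation (exact); LSODA rtol 10⁻¹⁰/atol 10⁻¹²
  where an integrator is used.
* Optimiser bounds 10⁻⁵–10⁴ h⁻¹ (log scale); stage C bounds k_45 below
  0.999·(k_e − k_43) to keep the back-filled k_40 non-negative.
* Ill-conditioned Hessians yield clamped (huge, not overflowing) CIs and
  NaN CV% rather than exceptions; non-convergence is flagged, not raised.
* Ties in the terminal-window search keep the earliest (longest) window.
* Dataset floats are written with `repr`, so a read/write round trip is
  byte-identical.

## Problem sizes

Replicate-study simulations use 20 studies for parameter recovery and 200
VPC replicates with ~2000 pooled test points for coverage — sizes at which
the Monte-Carlo error of a median or a 90%-coverage estimate is a few
percent, comfortably inside the tolerances asserted.

## Known limitations

* Naive pooling biases some estimates when IIV is present (medians within
  ~±20% at the default conditions); a mixed-effects estimator would
  remove this at the cost of instability at n = 3.
* The reconstructed equation system is consistent with every printed
  closed-form fraction and the described topology, but is not asserted to
  be the authors' literal appendix system (initial conditions and possible
  lag times unavailable).
* Route accounting is asymptotic (cumulative); no time-resolved route
  attribution beyond the oracle's flux accumulators.
* Whether the original residual error was proportional on the natural or
  log scale is not stated; proportional-on-natural is implemented.
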