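# Methods

## Model and assumptions

`blifit` fits single-cycle (kinetic-titration) BLI sensorgrams with the
piecewise 1:1 Langmuir model. The assumptions are those of any 1:1
surface-binding analysis: a homogeneous, uniformly oriented ligand layer;
a monodisperse analyte; binding far from mass-transport limitation; and a
response proportional to bound complex. Time runs on a continuous clock
that starts when the sensor enters the first analyte well and runs
unbroken through every association, mini-dissociation and final
dissociation; the response at the start of each segment is *forced* to
equal the response at the end of the previous segment, so continuity is
built into the model rather than fitted. The trace starts at R = 0 — any
pre-analyte baseline offset is assumed removed by clock alignment, and
the loading/blocking/baseline steps are carried through alignment for QC
and ranking but excluded from kinetic fitting.

Because each segment has a closed-form solution (exponential approach to
R_eq within associations, exponential decay within dissociations), the
piecewise model is analytically exact: the test suite verifies agreement
with direct numerical integration of dR/dt = k_on·C·(R_max − R) − k_off·R
to better than 1e−8 nm across random parameter draws.

### Partial dissociation

The partial-dissociation variant lets each dissociation decay towards a
plateau R_∞ > 0. Two parametrisations are provided:

- **local plateau** — one free R_∞ per dissociation segment, clamped to
  [0, R_start] at evaluation time (a plateau above the segment's starting
  response is meaningless for a decay);
- **global mobile fraction** (default) — a single parameter φ shared by
  all dissociation segments with R_∞ = φ·R_start, bounded to [0, 0.95]:
  φ = 0 reduces exactly to the standard model, and the 0.95 cap encodes
  that at least 5% of the signal must eventually dissociate — a flatter
  trace is better explained as a very tight binder than as partial
  dissociation.

One physical caveat is implemented literally on purpose: during
re-association after a plateaued mini-dissociation, the association
segment still relaxes towards the full R_eq computed from R_max. The
immobile fraction influences the next segment only through the propagated
starting response; R_max is not depleted by accumulated immobile
complexes. Modelling such depletion would require assumptions about the
immobile population's fate that the data cannot constrain, and is left as
a documented extension.

## Fitting

All kinetic samples are fitted jointly by unweighted least squares
(per-segment weights are accepted by the API surface of the residual but
deliberately off by default). k_on, k_off and R_max are optimised in
log10 space — their plausible ranges span decades and log-parametrisation
keeps the problem well-scaled — inside a bounded trust-region
least-squares solver (`scipy.optimize.least_squares`, method `trf`,
ftol = xtol = gtol = 1e−15). Default bounds bracket the practical dynamic
range of BLI (K_D roughly 10 pM to 1 mM): k_on ∈ [1e2, 1e8] M⁻¹s⁻¹,
k_off ∈ [1e−7, 1] s⁻¹, R_max ∈ (0, 10] nm, φ ∈ [0, 0.95].

The starting point is data-driven: k_off from a log-linear regression on
the final dissociation; k_on from regressing per-well observed rates
(estimated by regressing dR/dt on R within each association) on
concentration; R_max from the top response divided by the implied
occupancy. A small seeded multistart (5 starts, rates jittered up to
×/÷10) guards against local minima; the best converged start wins. A
trace whose response window is below the noise floor is rejected with an
instruction to check the signal rather than fitted to noise.

Goodness of fit is the dof-corrected RMSE sqrt(SS/(N − p)), with N the
number of fitted samples and p the number of free parameters (3 standard;
4 global-mobile-fraction; 3 + number of dissociation segments for local
plateaus). It is also reported as a fraction of the fitted response
window, which is the number to compare across binders with different
R_max.

Single-fit standard errors come from the Jacobian at the optimum scaled
by the residual variance (covariance s²(JᵀJ)⁻¹), propagated from log
space back to natural units. They are asymptotic and approximate —
a simulation study in the test suite checks they sit within a factor of
two of the empirical scatter across noisy replicates — and replicate
experiments summarised as mean ± SD remain the gold standard.

### Model selection

`choose_model` prefers the standard model unless the partial fit lowers
RMSE by ≥ 5% *and* its plateau is material (φ ≥ 0.02). Both thresholds
are configurable; the rule is a parsimony heuristic, not a statistical
test.

### Steady-state affinity

For weak, fast-exchanging binders, `fit_steady_state` fits
R_eq(C) = R_max·C/(C + K_D) to equilibrium plateaus. It refuses
(< 3 points) or fails with an explicit unidentifiability error when the
responses are simply proportional to concentration (fitted K_D far above
the top concentration — no curvature means no K_D).

### Expression ranking

Sensor loading by irreversible covalent capture is modelled pseudo-first-
order: R(t) = R_sat·(1 − exp(−k_cap·C·t)). Since every sensor ultimately
reaches the same capture density, the observed rate — proportional to
binder concentration in the crude sample — is the ranking score. Traces
at ≥ 95% of fitted R_sat are flagged saturated (rate poorly determined);
flat or failed traces are kept in the output with an error and sorted
last. The mono-exponential form is a modelling choice: real loading
traces only need to be *ordered* correctly, and the rate of a saturating
fit is a robust order statistic for that purpose.

## Pre-processing

- **Clock alignment** shifts times so the first association sample sits
  at t = 0 and annotates every sample with its schedule step. Step
  boundaries come from the programmed dwell times, not from edge
  detection in the data; a one-sample tolerance absorbs acquisition
  jitter at the end of the run.
- **Reference subtraction** interpolates the control trace linearly onto
  the assay grid and subtracts pointwise. It is optional — with covalent,
  non-dissociating ligand capture the baseline is usually flat enough
  that subtraction is unnecessary, but the control sensor should always
  be *run*.
- **Inter-step shift correction** (off by default) rigidly offsets each
  kinetic segment so its first sample equals the last sample of the
  previous segment. This removes bulk refractive-index jumps exactly at
  the boundary sample but also absorbs the genuine signal increment
  across the one-sample gap (~|dR/dt|·Δt per boundary, well below noise
  at typical cadences). The operation is idempotent. Enable it only when
  a control sensor reveals bulk shifts.

## Simulator

The simulator exists so that every estimator in the package can be tested
against known truth. It emulates:

- the routine five-well schedule (association dwells tapered
  300/250/200/150/100 s from lowest to highest concentration, 30 s
  mini-dissociations, 600 s final dissociation, 1200 s in the long
  variant);
- iid Gaussian sample noise, default σ = 0.005 nm — chosen inside the
  0.0035–0.018 nm range of fit RMSEs seen on real traces so synthetic
  difficulty matches reality;
- optional linear drift and optional Gaussian bulk shifts at step
  boundaries that accumulate along the trace, as they do in real runs;
- loading traces under pseudo-first-order irreversible capture;
- whole fixture plates (CSVs + schedule configs + a truth manifest),
  byte-identical for a fixed seed.

What it does **not** emulate: coloured/correlated noise and spectral
artefacts, mass-transport limitation, non-specific binding, analyte
heterogeneity (aggregates, avidity), temperature or evaporation effects.
Passing recovery tests on this generator therefore demonstrates the
correctness of the estimators under the stated model, not robustness to
every real-world artefact; traces violating the 1:1 assumptions will
mis-fit in reality exactly as they would in any 1:1 analysis.

## Assay-design rules

`design.schedule_for_affinity` encodes the design guidance used for the
recovery studies: a five-well 1:2 ladder with top concentration
10 × K_D — floored at 4 nM, because for picomolar binders a 10×-K_D top
would give unmeasurably small signal and practice is to probe them at
fraction-of-nM to nM concentrations — and a final dissociation extended
until the expected fractional signal loss reaches ~5%
(t = −ln(0.95)/k_off, floored at 600 s and capped at 5 h). Slow
dissociations genuinely need these long windows: with k_off ~ 3e−6 s⁻¹,
five hours of dissociation loses only ~5% of the signal.

## Problem sizes and defaults

- Acquisition grid: 0.5 s/sample for simulation (BLI-like cadence),
  1 s/sample for model prediction; both configurable.
- Recovery studies: noiseless recovery uses 7 affinities spanning
  K_D ≈ 2.6 pM–750 nM plus 25 random draws; stochastic recovery uses 50
  replicates at σ = 0.005 nm; the uncertainty calibration uses 50
  replicates on a shortened 3-well schedule at 1 s cadence. These sizes
  give stable medians and factor-of-two calibration checks while keeping
  the whole validation quick on a laptop.
- Multistart: 5 starts by default; 1–3 in the recovery studies, where the
  data-driven initial guess is reliably in the basin of attraction.

## Numerical notes

- Exact continuity across segments holds by construction (each segment is
  evaluated from the propagated boundary state, not from sampled values);
  a sample falling exactly on a boundary belongs to the later segment,
  whose value there *is* the earlier segment's limit.
- Noiseless fits recover generating rate constants to ~1e−13 relative:
  with exact data the optimiser runs to machine precision, limited only
  by evaluation round-off.
- CSV round-trips are bit-exact: responses are written at 17 significant
  digits and re-read with round-trip float parsing.
- Local-plateau parameters are clamped to [0, R_start] inside the model
  evaluation, so the optimiser can roam its box without producing
  unphysical rising "decays".
- Degenerate inputs fail loudly and specifically: flat traces raise a
  guess error, N ≤ p raises a dof error, proportional steady-state data
  raise an unidentifiability error, an ill-conditioned Jacobian raises an
  uncertainty error carrying the condition number.

## Known limitations

- Only 1:1 kinetics (and its partial-dissociation relaxation) are
  modelled — no mass-transport, heterogeneous-ligand (1:2), conformational-
  change or bivalent-analyte models. Traces needing them will show
  systematic residual curvature.
- Multi-cycle (one-concentration-per-sensor) global fitting is out of
  scope, as are proprietary instrument export formats: data enter as tidy
  CSV, and converting vendor exports is the user's responsibility.
- The mobile-fraction model treats φ as time-invariant and shared across
  segments; a slowly accumulating immobile population would violate this.
- Reported single-fit standard errors are asymptotic; for publication,
  run independent replicates and report mean ± SD.
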