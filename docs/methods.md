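# Methods

## Scope and data model

The pipeline consumes already-quantified per-well measurements from
384-well screens (rows A–P, columns 1–24) as a tidy CSV: one row per
(plate, well, readout, timepoint), carrying cell line, culture format
(2D/3D), well role (treatment / vehicle / positive control), up to two
drugs with doses in µM, technical and biological replicate indices, and the
raw signal. Image quantification (confluency area, spheroid diameter,
fluorescent-object counting) is upstream of this package and out of scope.

Wells that belong to a pairwise dose matrix name both drugs, with the
partner dose 0 on the single-agent edges; this makes each matrix cell
attributable to exactly one pair and lets a conservation check hold exactly
(every combination-screen treatment well lands in exactly one grid cell).
Wells of the broad-range single-drug screen leave the second drug empty.
Well coordinates are validated but purely metadata: no spatial (edge-effect)
modeling is attempted.

## Normalization

Treatment effects are expressed relative to the mean of the vehicle wells
matched per (plate, readout, timepoint); vehicle wells then average to 1 on
every plate by construction, and all normalized values are invariant to
rescaling a plate's raw signals. Vehicle wells are pooled regardless of
solvent (DMSO, water, 1:1); solvent-specific matching per drug would be a
straightforward extension but is not implemented. Values above 1 (growth
stimulation, noise) are *not* clamped at this stage; clamping is a synergy
scoring decision (below). Positive-control wells are normalized and carried
through for QC only — they enter no synergy statistic.

Kinetic imaging readouts additionally reference their own 0 h baseline:
value = (raw_t / raw_0) / (mean vehicle_t / mean vehicle_0), i.e.
fold-growth of treated wells relative to fold-growth of vehicle.

## Dose–response summaries

Single-agent viability is fitted with the four-parameter logistic in log10
dose. Choices that matter:

- **Bounds.** 0 ≤ asymptotes ≤ 1.5 (supra-vehicle responses occur in
  imaging readouts), hill ∈ [10⁻³, 10], log10 EC50 within ±3 of the tested
  dose window.
- **Multi-start.** Initial EC50 at every tested dose × hill ∈
  {0.5, 1, 2}, asymptotes from the response extrema; best residual sum of
  squares wins, ties broken toward the shallowest slope; a converged
  solution with an essentially tied RSS is preferred over a marginally
  better one that exhausted its iteration budget (this arises only for
  near-flat noise-only curves). An analytic Jacobian keeps the multi-start
  fit fast.
- **Degenerate input.** A perfectly constant response returns a flat fit
  (both asymptotes at the mean, hill undefined), which downstream maps to a
  `not_reached` IC.
- **IC20** is solved analytically from the fitted curve's inverse, not by
  interpolating raw points, and censored against the tested range
  (default 0.01–20 µM): `value` / `below_range` / `above_range` /
  `not_reached`. The inhibition level (0.2) and range are parameters.
- **AUC** is the mean fitted viability over a uniform log10-dose grid (201
  points, trapezoid rule, normalized by the log-range width). This
  convention is bounded in [lower, upper], unit-free and comparable across
  drugs; it is *not* the raw trapezoid integral of measured points.

On noise-free curves the fit recovers parameters to ~1e-6 relative for
hill ∈ [0.5, 4]; near-flat curves (amplitude ≲ 0.1) carry little parameter
information and only their censoring category is meaningful.

## Bliss synergy scoring

Bliss excess lives on the viability scale: excess = V_obs − V_A·V_B, so
"excess < 0" is synergy. This is algebraically identical to the effect-scale
formulation (E_A + E_B − E_A·E_B) − E_obs with E = 1 − V, a property-tested
identity.

- Single-agent viabilities come from the combination matrix's own dose-0
  edges — same plates, same biological replicate — never from the separate
  single-drug screen, so scoring is truly per replicate.
- Edge viabilities are clamped to [0, 1] before the product (an unclamped
  edge > 1 would make the expectation exceed 1 and manufacture spurious
  synergy); clamping events are logged. Observed combination viability is
  used as measured.
- Scores are computed per biological replicate and then averaged cellwise,
  with the cellwise standard deviation (sample, ddof = 1 — replicate counts
  are 2–4, so the choice is material and applied consistently everywhere)
  reported alongside.
- Matrix summaries average the 16 nonzero-dose cells only (single-agent
  edges excluded), keeping the 2D-vs-3D comparison about combination
  response. Missing cells (e.g. a robotically skipped dose in one
  replicate) propagate as explicit missing values that every mean/count
  skips.
- **Classifier gates.** Synergistic: mean excess strictly < 0.
  Synergistically effective dose: excess < 0 AND viability ≤ 0.5. The
  at-or-below convention for the viability gate was chosen over strictly
  below; the two differ only at exactly 0.5 and the threshold is
  configurable.
- Per-combination mean excesses are also binned into intervals (default
  edges −0.2, −0.1, −0.05, 0, 0.05, 0.1, 0.2; configurable) and counted per
  culture format with at-least-one-cell-line semantics.

A caution that the noisy simulations make vivid: with a strict `< 0` call
on a mean of 16 cells, truly null combinations are coin flips, so the
count of "synergistic" combinations under at-least-one-of-3-cell-lines
semantics is upward biased for null pairs. The pipeline reports the raw
counts as defined; interpreting them requires the per-dose tables and
standard deviations it also writes.

## Agreement and reproducibility

Pearson correlation (complete pairs only, dropped pairs counted) is used
for cross-readout and replicate comparisons: inter-screen (single-agent
doses shared between the single-drug and combination screens, per format)
and intra-screen (biological replicate 1 vs 2 per format and readout).
Group comparisons use a two-tailed t test — Welch by default with a classic
equal-variance option, paired only where conditions are matched — with no
multiple-testing correction, and stars at p ≤ 0.05/0.01/0.001. Technical
variability is the per-condition coefficient of variation (sample sd /
mean over technical replicates), averaged unweighted per (biological
replicate, readout) into an overall CV.

## The synthetic screen generator

The generator emulates the full study design: 3 colorectal-cancer cell
lines (HCT-116, HT-29, SW-620) × 2D/3D, a 7-drug panel (abbreviated OLA,
OXA, PAL, PI, PD, 5-FU, 5Z), an 8-dose single-agent screen over 0.01–20 µM
(4 technical × 1 biological replicate), and all 21 pairwise 5×5 combination
matrices (vehicle + 4 nonzero doses per drug, 4 technical × 2 biological
replicates), at a 48 h endpoint. Per-pair matrix doses default to the
4-dose window of the screen doses that best brackets each drug's contextual
EC50, mirroring how combination doses are picked from single-agent
response.

Ground truth: single-agent viability follows a Hill curve per drug (with
optional per-(cell line, format) EC50 scaling — defaults encode a few
context-dependent sensitivities such as weaker oxaliplatin/palbociclib
response of HT-29 spheroids); combination viability is the Bliss-null
product plus an additive deviation δ, clipped to [0, 1.5], so the true
Bliss excess equals δ wherever the clip is inactive and parameter recovery
is an identity check. δ is uniform across a matrix by default; the default
interaction map has six interacting pairs with |δ| ≤ 0.2 (a convention —
chosen once as a realistic magnitude for cell-line screens) including
MEK-inhibitor synergies that are stronger in 3D, and one antagonistic
pair. Dose-dependent δ surfaces are representable via per-context entries
but default off.

Raw signals are truth × readout baseline × (1 + ε) with multiplicative
Gaussian ε; the default noise sd is 0.05 in 2D and 0.07 in 3D (spheroid
readouts are slightly noisier). The viability baseline is 2²⁰ counts — a
power of two, so scaling to raw counts and back through vehicle
normalization is bit-exact and zero-noise screens recover truth exactly;
this makes boundary semantics (strict < 0) testable without tolerance
fudging. Secondary readouts couple to viability as V^0.8 (confluency,
% area) and V^(1/3) (spheroid diameter ∝ cube root of mass); death
reporters (CellTox/NucView-like) stay at baseline except for drugs flagged
apoptotic (default: the TAK1 inhibitor 5Z), reproducing the qualitative
structure that viability correlates strongly with growth readouts and
weakly with death readouts. Plates hold one (cell line, format, biological
replicate) arm, split across physical plates of ≤ 384 wells, each with its
own 16 vehicle and 8 positive-control wells; everything is deterministic
given the config seed.

What the generator does **not** emulate — and hence what passing tests do
not certify about real screens: spatial plate artifacts (edge evaporation,
dispensing gradients), non-Gaussian outliers, solvent effects,
dose-misdispensing, drift between biological replicates, spheroid geometry
or image segmentation error, and dose-dependent interaction shapes (the
default δ is flat across the matrix).

## Error propagation in recovery studies

The standard error of the matrix-mean excess estimator is *not*
σ/√(t·b·16): noise also enters through the 8 single-agent edge means
(each shared by a whole row or column of the expectation surface) and
through the per-plate vehicle mean (a common scale factor that enters the
observed term once and the expectation twice). A delta-method computation
of the full variance — cell term Σ V_obs²·σ²/t, edge terms
Σ (V_A·ΣV_B)²·σ²/t both ways (all /16²), vehicle term
σ²/n_vehicle·(mean V_obs − 2·mean expectation)², divided by the number of
biological replicates — matches the observed estimator spread and is used
as the oracle in the acceptance tests. Under the default conditions the
edge and vehicle terms roughly double the naive standard error.

## Limitations

- Only Bliss independence is implemented; Loewe additivity, ZIP, HSA and
  Combination Index scoring are out of scope by design.
- No growth-rate-corrected (GR) dose–response metrics and no bootstrap
  confidence intervals on curve parameters.
- The 4PL family is assumed for all single-agent curves; biphasic
  responses will fit poorly (visible in the reported RSS).
- CV and correlation summaries assume technical replicates of a condition
  share a plate; conditions split across plates fold plate-to-plate
  vehicle variation into the replicate correlations (quantified above),
  though never into the CV, which is scale-invariant within a condition.
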