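# Methods

## Rigorous scaling (cubing)

A stem's field record is an ordered series of (height, diameter with bark,
bark thickness) from the cut height (~0.15 m) to the point where the bark
diameter reaches the 5 cm commercial minimum, plus the field-recorded heights
of the 20/15/10/5 cm reference diameters. Cubing is purely geometric:

* sectional area g(d) = π·d²/40000 m² (d in cm);
* section volume between consecutive measurements by Smalian,
  v = L·(g₁+g₂)/2 — exact for cylinders and for second-degree paraboloids
  (g linear in height), an overestimate for cones, converging to the true
  integral as sections shrink;
* tip volume above the last measurement = g(d_last)/2 × (H − h_last);
* total volume = sections + tip, with and without bark
  (d_wood = d_bark − 2·t, bark thickness linearly interpolated where a
  section must be split);
* merchantable volume to top diameter d sums sections up to the height at
  which the *with-bark* diameter reaches d, splitting the containing section
  there. For both bark states the limit is the with-bark diameter: the
  without-bark variant is the inside-bark volume of the same physical log.

Design choices that were genuinely open:

* **Minimum log length** (default 1.0 m) is measured from the cut height to
  the limit height; a merchantable volume whose log is shorter is reported
  absent, not zero. For a whole-stem merchantable volume this is the only
  length the rule can refer to.
* **Limit heights**: the recorded reference heights are used verbatim when
  present; otherwise the height is linearly interpolated between the two
  measurements bracketing the first downward crossing of the target
  diameter (noise can make the series locally non-monotone; the first
  crossing from the base is the physically sensible one).
* **The 5 cm volume** is exactly the sum of all sections, because the
  measurement protocol ends the series at the 5 cm point. This keeps the
  decomposition total = merchantable-to-5 + tip exact to machine precision,
  which the tests assert at 1e-12 m³.
* **Stump exclusion**: volumes accumulate from the cut height, not the
  ground.

## Dataset assembly

Cubed stems expand to the long multi-volume layout: one row
(V, DBH, H, TX, d) per available volume, TX = 1 for without-bark, d = 0 for
total volume. Absent volumes produce no row. Rows with d > DBH — possible
when butt swell pushes a limit diameter just below breast height on a
borderline stem — are dropped with a warning, because the multi-volume
equation's bracket is undefined there. The fit/validation split (default
70/30, an explicit fit count can override the rounding) is by stem, never by
record, so no tree contributes to both sides. Tables round-trip through CSV
and XLSX with a configurable column map, since deposited spreadsheets rarely
share headers.

## Regressions

Both models are estimated by ordinary (unweighted) nonlinear least squares
via a trust-region reflective solver, relative-objective tolerance 1e-10,
Jacobian-based variable scaling, and up to three jittered restarts on
non-convergence. Starting values are the log-linearized ordinary regression
ln V ~ ln DBH + ln H (for the multi-volume model: computed on the
total-with-bark rows, with β₃ = −1, β₄ = 0.1 appended). Asymptotic standard
errors come from the final Jacobian. Unweighted least squares is a
deliberate simplification: volume residuals are heteroscedastic
(multiplicative), and a weighted fit would change the coefficient estimates
slightly; the simulation tests show the unweighted fit still recovers known
coefficients with negligible bias (< 0.2% on β₁ at 7% noise).

β₃ > 0 after fitting triggers a warning: exp(β₃·TX/DBH) is meant to be a
bark *reduction*, and a positive estimate usually means the TX coding is
inverted in the input table.

## Neural networks

The network is an i-h-1 perceptron, i ∈ {3,4} inputs from (DBH, H, TX, d),
h ∈ 1..10 hidden neurons, logistic activation in the hidden *and* output
layers. Because the output is bounded in (0,1), every input and the target
are affinely mapped into [margin, 1−margin] before training (margin 0.1 in
the pipeline: keeping targets off the saturated tails of the logistic
stabilizes training) and predictions are mapped back — so a trained network
can never return a volume outside the inverse image of (0,1).

Training is full-batch gradient descent on the mean squared scaled error
with a momentum term (default 0.9), uniform (−0.5, 0.5) weight
initialization from a seed, early stop when the epoch-to-epoch error change
falls below 1e-8, and an explicit divergence error if the loss becomes
non-finite. The default learning rate is 10.0: with the *mean*-gradient
convention used here the useful rate scale is roughly the per-pattern rate
times the batch size, and rates of order 10 train a 4-6-1 network to
R² ≈ 0.97 on ~2000 records in half a second, while rates of order 0.01–0.1
(the natural scale for per-pattern updates) barely move the weights.

The architecture search re-implements an automated model-selection tool as
random sampling: each trial draws a hidden-layer size uniformly in
1..max_hidden and a fresh initialization seed, trains on a random share of
the fitting records and is scored by RMSE (m³) on the held-out remainder
(default 25%); the best `retain` (default 5) models are kept, ties breaking
toward fewer hidden neurons, then the earlier trial. A diverging trial
scores +∞ rather than aborting the search. Variable importance is Garson's
partition: each hidden neuron's absolute output weight is divided among the
inputs in proportion to their absolute incoming weights, summed and
normalized to 1.

## Evaluation

R² = 1 − SSres/SStot; RMSE(%), MAE(%) and MBE(%) are the root-mean-square,
mean-absolute and mean error as a percent of the observed mean, so positive
MBE means underestimation; per-observation residuals are 100·(y−ŷ)/y.
These definitions imply RMSE ≥ MAE ≥ |MBE| on every dataset, which the
property tests exercise. Statistics are reported per volume label and
jointly (the joint value is computed on the pooled vectors, equal to the
concatenation of the per-label vectors). The observed-vs-estimated test is
a paired t-test by default — the same stems are scaled and predicted — with
Welch's two-sample variant available; all-zero differences are a defined
no-difference result, constant non-zero differences an error.

## Synthetic stem generator

The generator exists so every stage runs, and is testable, without the
destructive field campaign. What it emulates:

* eight clone × rotation populations with the observed DBH and height
  means ± SD (13.4–20.6 cm, 17.9–27.9 m), (DBH, H) drawn from a correlated
  bivariate normal (default ρ = 0.7) truncated to physical values, with a
  warning when truncation exceeds 10% of draws;
* a smooth variable-form taper d(h) = DBH·X^(a+bX), X = (H−h)/(H−1.3):
  equals DBH at breast height, vanishes at the tip, strictly decreasing
  above 1.3 m, mildly swelling below it. Defaults a = 0.75, b = 0.12 give
  form factors ≈ 0.4–0.45 and single-tree volumes ≈ 0.25 m³ at the mean
  tree, consistent with the stand-level volumes of the source populations;
* stem-to-stem form variation: a varies with SD 0.10 between trees, giving
  a volume CV of ~8% at fixed (DBH, H), so regression residuals are on the
  order seen in real stands rather than vanishing;
* bark thickness = ½·diameter × fraction, the fraction (default 0.11 at the
  base) decaying linearly with relative height (default 40% decay at the
  tip), which keeps 2t < d everywhere;
* the measurement protocol above, with independent multiplicative
  log-normal noise (default CV 2%, a free parameter — within-stem
  measurement error is not reported for the source data) on diameters and
  bark thickness; reference heights are taken noise-free.

What it does **not** emulate: real butt-swell irregularity (the taper's
below-1.3 m swell is smooth), crook, broken tops, clone-specific taper or
bark differences (only the (DBH, H) moments differ between populations),
height measurement error, and any spatial or competitive structure. Passing
tests on synthetic data therefore demonstrate the *machinery* — geometry,
estimation, selection, and their invariants — not that any particular
fitted coefficient transfers to a real stand: synthetic allometry
(β₁ ≈ 1.8–2.0) differs from field-fitted values because the taper family,
not a fitted allometry, generates the volumes.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use sizes chosen to make every
stochastic claim stable at fixed seeds while keeping a full run around a
minute: 460-stem studies (~3400 records) for the headline statistics,
1000 stems for bulk cubing invariants, 20–50 replicates of ~2000-record
simulations for coefficient recovery, and 40–100-trial architecture
searches at 2000–6000 epochs (the search quality saturates well below the
1000 trials a production run would use). Geometric identities are asserted
at 1e-12–1e-13, seeded determinism exactly, fitted-coefficient recovery at
1e-5 relative without noise and < 5% bias with noise.

## Known limitations

* The deposited field spreadsheets of the source study are not distributed
  here; the reproduction test that refits them runs only when the files are
  placed under `data/` (see `tests/test_acceptance.py`), and fails with a
  pointer otherwise.
* Per-pattern (online) backpropagation is not implemented; full-batch with
  momentum reaches the same accuracy on these data sizes but is not
  update-for-update identical to classical online training.
* Unweighted least squares (see above); no mixed effects across clones.
* The t-test is applied per volume with no multiplicity correction,
  matching standard practice for this comparison.
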