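# Methods

This note documents the models, conventions and numerical choices behind
`cervinet`, in the package's own terms.

## The problem

Patients with whiplash-associated disorder (WAD) are routinely assessed
with inertial sensors while performing 45-second self-paced oscillations
of the neck in three movement pairs: flexion/extension (F/E), left/right
lateral bending (Llb/Rlb) and left/right rotation (Lrt/Rrt). Each
movement yields three predictors — age-normalized range of motion (ROM,
% of normative), the coefficient of variation (CV) of per-repetition ROM
(a movement-consistency measure), and the speed to peak (deg/s) — for 18
predictors in total. The question the package operationalizes: given a
baseline assessment, how much will a patient's global mobility change
over a course of rehabilitation?

Global mobility is summarized by the Neck Functional Holistic Analysis
Score (NFHAS), and the regression target is the signed difference
`NFHAS(follow-up) − NFHAS(baseline)`.

## Trace segmentation and movement summaries

A repetition is one full oscillation cycle: each prominent peak
(prominence ≥ 5°, inter-extremum spacing ≥ 0.3 s, both configurable)
defines a repetition whose window runs from the preceding trough (or the
trace start) to the next trough (or the trace end). Per repetition, ROM
is the max−min excursion within the window and speed to peak is the
largest absolute finite-difference angular velocity between the window
start and the peak (central differences, one-sided at the trace ends).
On a pure sinusoid of amplitude A and angular frequency ω this recovers
ROM = 2A and peak speed = Aω to discretization error, which the tests
assert.

Conventions worth noting:

* **ROM per movement** is treated as the movement's own directional
  excursion; a recording covers one movement of a pair.
* **CV with a single repetition** is defined as 0 rather than NaN:
  downstream z-scoring cannot absorb missing values. The repetition
  count is carried in the summary so such records can be audited.
* **Speed to peak** is the per-repetition peak |angular velocity| on the
  excursion toward the peak, averaged across repetitions. An alternative
  (peak angle ÷ time to peak) would differ by a factor near π/2 on
  sinusoidal movement; the peak-velocity form was chosen because it is
  robust to where a repetition window begins.
* **Normative ROM** is user-supplied configuration (CSV of age_band ×
  movement). The shipped default spans the range healthy-adult
  goniometry studies report (e.g. 55–60° flexion, 70–75° rotation for
  younger adults, declining with age) and exists so the synthetic
  pipeline is runnable end to end; clinical use requires the user's own
  reference table.

## The NFHAS score

The six normalized ROMs are collapsed to three axis values (mean of the
two directions in a pair). The axis values are placed as vertices on
mutually orthogonal axes — (FE̅,0,0), (0,LB̅,0), (0,0,RT̅) — the three
sides are Euclidean vertex distances, the triangle area follows from
Heron's formula A = √(s(s−a)(s−b)(s−c)), and the score is
100·A/A_ideal with A_ideal the triangle at 100% on every axis.

Properties that pin the definition down (all property-tested):
scaling every ROM by k scales the score by k² ; the ideal assessment
scores exactly 100; the score is monotone in each ROM and symmetric in
the two directions of a pair. For vertices on orthogonal axes the Heron
area equals the closed form ½√(a²b²+b²c²+c²a²), which serves as the
independent oracle.

Because "one triangle from three combined axes" and "six directional
vertices" are both defensible readings of a polygon-area mobility score,
an alternative **octant geometry** (six vertices on ±axes, the eight
octant faces summed) is available behind a `geometry=` switch; it shares
the ideal-case and k² properties. The triangle-with-mean-axes form is
the default. Combining a pair by mean or by sum gives identical scores
(the ideal rescales identically), so `combine=` matters only for
intermediate quantities.

Scores above 100 (hypermobility) are representable and not clipped.

**Severity staging** assigns types 1 (complete ROM) to 5 (severe
limitation). The default is fixed equal-width thresholds at 80/60/40/20
on the score; a 1-D k-means mode (k=5, fixed seed, centroids sorted
descending) is available, falling back to thresholds with a warning when
fewer than five distinct scores exist. The five-group staging of the
score's originating work is not reproducible from published material,
hence thresholds are configuration, not constants.

## Cohort cleaning and predictors

A patient is excluded when **any** of the 18 raw baseline predictors
lies more than 3 scaled MADs from that predictor's cohort median
(scaled MAD = 1.4826·MAD, the Gaussian-consistent form). When the MAD of
a predictor is zero the rule degenerates; the implementation then flags
a value only if it deviates from the median at all *and* a secondary
scaled-IQR criterion (3·IQR/1.349) also flags it — so constant columns
flag nothing while one wild value among near-constants is still caught.
Follow-up records of excluded patients are dropped with them.

Predictors are z-scored with the sample standard deviation (n−1).
Normalization parameters are always fitted on the training side of a
split and reused on the held-out side; the target stays on its native
NFHAS-point scale (so MSEs are in squared NFHAS points).

## Network and training

The regressor is a feed-forward network: 18 inputs, one or two tanh
hidden layers, one linear output. Training is Levenberg–Marquardt on
the squared error: solve (JᵀJ + λI)δ = Jᵀr with the analytic per-sample
Jacobian (reverse-mode, verified against central finite differences),
accept a step only if the training MSE falls (λ ← λ/10), otherwise
reject and re-damp (λ ← 10λ). Defaults: λ₀ = 10⁻³, λ_max = 10¹⁰,
gradient tolerance 10⁻⁷ on ‖Jᵀr‖∞, 1000 epochs (100 inside the
cross-validation loops). Initialization is uniform in [−0.5, 0.5] from a
seed; Nguyen–Widrow is available. With a purely linear model a single
vanishing-damping step reproduces ordinary least squares exactly, which
anchors the trainer against a closed-form oracle. Training is
bit-reproducible given (seed, data, config).

## Architecture search

All architectures with 1–2 hidden layers and at most 17 hidden neurons
in total are enumerated — 17 single-layer widths plus 136 two-layer
splits, 153 candidates, ordered by total neurons, then depth, then
first-layer width. (A greedy add-or-relocate walk would touch a subset
of this space; exhaustive coverage of the same bound is used so the
reported per-architecture comparison is complete.) Each candidate is
scored by Monte-Carlo cross-validation: 10 independent random 70/30
splits, fresh initialization per repeat, z-scoring (and PCA when
enabled) fitted inside the training side, validation MSE recorded; the
summary is the mean with a Student-t 95% interval
mean ± t(0.975, n−1)·sd/√n. The winner is the lowest mean MSE, ties
broken by fewer neurons, then fewer layers. Per-candidate, per-repeat
random substreams are derived from one seed by spawn keys, so results do
not depend on evaluation order and the search is reproducible from a
single integer.

The PCA variant rotates the (training-side standardized) predictors onto
their principal components with the variance-removal fraction at 0, i.e.
a lossless decorrelating rotation; components are sign-fixed by making
each component's largest-magnitude loading positive. On a linear model
such a rotation cannot change the attainable fit, which the tests use as
a rotation-invariance oracle.

## Evaluation

On the held-out split: the Pearson R (and slope/intercept) of the
regression of real on predicted NFHAS change; the MSE; an equal-width
20-bin error histogram; a quadrant cross-classification of real vs
predicted direction of change — improvement means change > 0, an exactly
zero change counts as "did not improve" — with percentages over the
whole sample; and, per quadrant group, paired t-tests (two-sided,
α = 0.05, no multiplicity correction across the table families; a
Holm-adjusted column is emitted as a clearly separate extra) between
baseline and follow-up ROM, speed and CV for each movement. Mean
differences are reported post−pre as primary, with pre−post alongside
for comparability with the opposite sign convention. Paired-test
statistics agree with `scipy.stats.ttest_rel` to 10⁻⁹ by property test.

## The synthetic cohort generator

The generator is the package's stand-in for clinical recordings and
defines the conditions under which the pipeline is tested.

* **Severity profiles.** Five profiles, evenly graded: mean ROM spans
  100% → 30% of the normative reference across types 1 → 5 (fractions
  1.00/0.825/0.65/0.475/0.30), mean speed falls with the same factor
  from full-mobility scales of 95 deg/s (rotation) / 75 (F–E) / 55
  (lateral bending) — preserving the rotation > flexion-extension >
  lateral ordering within every type — and mean ROM CV climbs
  4/7/10/13/16%. The graded structure is qualitative by necessity (the
  underlying per-type means are not published); profiles are
  configuration, not constants.
* **Mixture and demographics.** Types drawn with probabilities
  3.69/16.82/24.67/31.23/23.56% (renormalized; the printed values sum to
  99.97%), age N(37, 12.88²) clipped to [18, 90], 55.1% female, height
  N(1.67, 0.09²) m, mass N(72.41, 15.47²) kg. Patient-level kinematics
  are lognormal around the profile means (σ = 0.08 ROM, 0.10 speed,
  0.15 CV).
* **Traces.** 45 s at 50 Hz, built cycle by cycle as raised cosines
  0 → R_k → 0; per-cycle excursions R_k are lognormal with the profile's
  mean and CV (so the downstream ROM CV is controlled), and periods take
  the base period π·ROM/speed jittered ±10%. Feeding generated traces
  back through the kinematics module recovers the profile's mean ROM and
  speed within 5% (tested at ≥ 200 aggregate repetitions).
* **Ground-truth recovery model.** true change = intercept + Σ wᵢzᵢ +
  ε, with zᵢ standardizing each raw predictor by a *population*
  reference scale computed analytically from the profiles and mixture
  weights (not from the realized sample, so the ground truth is
  well-defined per patient). Default weights: −1.6 per normalized-ROM
  predictor (less baseline mobility → more room to improve), +0.5 per
  CV, −0.4 per speed, intercept +10. The change is then saturated so the
  follow-up score stays in [0, 100], ε is Gaussian with default
  σ = 27 NFHAS points — a level at which the held-out correlation of a
  well-fitted predictor sits near 0.5, the moderate regime typical of
  kinematics-only clinical outcome prediction. The follow-up record is
  constructed consistently: all six ROMs scale by k with
  k² = NFHAS₂/NFHAS₁ (exact by the score's scaling law, so the
  record-derived target reproduces the stored truth to rounding), speed
  scales with k and CV with 1/k.
* **Seeding.** One global seed expands to per-patient, per-purpose
  substreams via `numpy` SeedSequence spawn keys; patient i's data is
  identical whatever the cohort size or generation order.

What the generator does **not** emulate: measurement error of the
sensors, fatigue or learning across the 45 s, correlations between
demographics and kinematics, feigned-effort patterns beyond an elevated
CV, dropout between assessments, or any treatment-modality effect. A
passing parameter-recovery test therefore shows the pipeline recovers a
known signal of realistic shape and size — not that the clinical effect
itself has that shape.

Note on the noise-dominated control: with the saturating ground truth,
inflating ε does **not** drive the achievable R to zero — the saturation
bounds depend on the baseline score, which is itself a function of the
predictors, flooring R near 0.37. That residual correlation is genuine
signal introduced by the cap, not leakage. The "no signal" control
therefore uses the unsaturated (`nonlinearity="none"`) ground truth with
σ = 150, where the measured held-out R is ≈ 0.05.

## Problem sizes and determinism

The test suite exercises the full pipeline at n = 1082 patients with a
reduced search grid (5 candidate architectures, 5 repeats, 40-epoch
training inside the search) — the scale at which the low-noise recovery
check (R ≥ 0.9) and the noise-dominated control (R < 0.2) run in a few
seconds. The smoke-level pipeline tests use 50–60 patients and a 2-wide
search. A full 153-candidate × 10-repeat search at n ≈ 1000 runs in
minutes and is exposed through the CLI rather than the test suite. All
CSV/JSON artifacts of a run are byte-identical across reruns with the
same configuration and seed.

## Known limitations

* The staging thresholds are a convention, not a fitted clustering; the
  k-means mode will not reproduce any particular published centroids.
* The outlier rule's MAD=0 fallback is a design choice; other packages
  flag nothing (leaving wild values in) or everything nonequal.
* CI construction on the repeat MSEs assumes approximate normality of
  per-split MSEs; with 10 repeats the t-interval is indicative, not
  exact.
* LM as implemented is dense: O(p²) memory in the parameter count, fine
  for ≤ 17 hidden neurons, unsuitable for large networks.
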