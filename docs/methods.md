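# Methods

This note documents the models implemented in `sowpatterns`, the defaults
they ship with, and the reasoning behind the choices that were genuinely
open.  Nothing here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The behavioural process model

### State space and observation model

Sow behaviour is modelled on the six-posture ethogram — standing (ST),
sitting (SI), kneeling (K), sternal lying (SL), lateral lying with the
udder hidden (LL) and lateral lying with the udder exposed (LLU) — observed
once every 5 s (17,280 ticks per 24-h day).  While standing, the sow is
additionally eating, drinking, or doing something other (nest-building,
rooting, locomotion).  Days are indexed relative to farrowing, D−3…D7,
grouped into the three peripartum periods bf (D−3…D−1), df (D0, the 24 h
after the first birth) and af (D1…D7).  Day windows are farrowing-anchored
for all days, so no partial days arise.

### Generator

The simulator is a continuous-time Markov chain with exponential holding
times (the simplest semi-Markov process consistent with the two observable
summaries: daily time budgets and daily transition counts), discretised by
labelling each tick with the state occupying its start time.  Rates use the
reversible "uniform jump" form `q_ij = theta * pi_j (i != j)`, which has
stationary distribution `pi` and total jump rate `theta * (1 − sum pi²)` —
so the time budget (`pi`) and the expected daily number of posture changes
can be calibrated independently:

* `pi` per period encodes ~77 % lying before farrowing, 92 % on the
  farrowing day, 89 % (LLU-dominated) after farrowing;
* `theta` per period is set so the period-mean daily jump count matches the
  observed restlessness level (~330/day bf, ~280 df, ~245 af), and per-day
  multipliers shape the within-period profile with its peak on D−1
  (×1.43) — the nest-building surge;
* per-sow heterogeneity: a log-normal overall restlessness effect
  (σ = 0.55, mean 1), a log-normal per-sow×period effect (σ = 0.30) so
  activity is repeatable but not identical across periods (cross-period
  trait correlations ≈ 0.75), and a log-normal per-sow preference for
  lying with the udder exposed (σ = 0.25, a multiplicative bias on the
  rates *into* LLU) driving within-breed budget variation;
* breeds add fixed biases of the same column-multiplier form (defaults: one
  breed prefers LLU, the other LL, ×1.3), so breeds differ in lying style
  more than in activity level;
* each standing bout draws one activity from the period's eat/drink/other
  distribution; label noise flips each tick independently with probability
  0.01 to a random wrong posture, producing exactly the single-tick
  artefacts the despiking rule removes.

The chain's fixed transition structure ties the three count traits
together more rigidly than real data: exits from LLU are a constant share
of all transitions given the budget, so the simulated PCStopNurse and
PCRiskCrush levels (~100 and ~65 per day after farrowing) are stylised
rather than calibrated, and only PCAll magnitudes should be read
quantitatively.  No nursing-bout microstructure is modelled.

Randomness is hierarchical: every sow consumes substreams derived from
`(master seed, purpose tag, sow index)`, so adding a sow leaves the others
bit-identical.

### Piglet outcomes

Litters are uniform on 12–21 piglets; each piglet's sire breed is drawn
with probability ½ (mixed-semen design), giving four dam/sire genetic
types with type-specific birth-weight distributions.  Death days follow a
discrete-time proportional-hazards model on days 1–28: per-day hazard
`h0_d * exp(eta)` with `eta` linear in the dam's *realised* traits
(defaults: log 0.56 per 100 posture changes/day af, log 0.72 per hour/day
of LLU af, both centred at typical values), and `h0_d` decaying from 0.03
so an average litter loses ~15 % of piglets.  Survivors are censored at
day 28.  Average daily gain is an intercept (229.5 g/d) plus genetic-type
offsets, additive shifts for dams in the upper tertile (S) of selected
traits (−22.37 g/d for bf PCAll, −45.33 for D0 PCStopNurse, +70.84 for af
PCStopNurse), and Gaussian noise (σ = 55 g/d).  Weights after the death
day are missing, so piglets dying before D7 contribute no ADG — the same
selection a real study faces.

Because the hazards and growth shifts are driven by the traits *computed
from the simulated streams*, parameter-recovery studies close the loop:
the association stage should return the planted effect sizes.

## 2. Trait extraction

Processing order is fixed: **despike → merge → budgets/counts**.

*Despiking.*  A posture run lasting exactly one observation is treated as a
classifier error and replaced by the posture of the previous observation.
The pass is causal (left-to-right) with run lengths measured on the raw
stream, so chains of adjacent singletons collapse onto the nearest
preceding run of length ≥ 2; a leading singleton has no previous
observation and is kept.  A replaced tick's activity is recomputed to match
its new posture (inherited when the new posture is ST, none otherwise) —
whether the original study recomputed activities is unstated; this keeps
the stream internally consistent.  A property test documents that merging
before despiking can change results; the pipeline never does it.

*Merging.*  Sitting and kneeling are visually confusable from overhead
video and are pooled into `SI+K` by default; the map is configurable since
other poolings are defensible.  Posture changes are counted after merging
by default (configurable), so SI↔K flicker never counts as restlessness.

*Counts.*  PCAll counts every adjacent-tick posture change; PCRiskCrush the
crush-risk subset {ST→SL, ST→LL, ST→LLU, SL→LL, SL→LLU}; PCStopNurse every
exit from LLU.  An independent brute-force pair scanner backs these in the
tests.

*Budgets.*  Daily postural budgets are tick shares (closed to 1); the
standing-activity budget is the eat/drink/other share of standing ticks and
is *missing* — not zero — on a day without a single standing tick
(compositional absence, excluded from that sow's activity trajectory).

*Standing activity from geometry.*  Given head coordinates, a tick is
DRINK within `r_drink` of the trough, else EAT within `r_eat` of the
feeder, else OTHER.  Drinking takes precedence when both radii are
satisfied (the trough is the smaller target); radii are configuration
values with no canonical default.

## 3. Compositional clustering

Budgets are compositions, so Euclidean analysis is done in isometric
log-ratio (ILR) coordinates.  Bases come from a sequential binary
partition; the default postural basis contrasts lying vs upright first,
then udder-exposed vs other lying, lateral vs sternal, and ST vs SI+K; the
activity basis contrasts other vs maintenance, then eat vs drink.  Because
the ILR is an isometry for *any* orthonormal basis, distances — and hence
k-means assignments — are basis-invariant (asserted by test), so the
specific partition only affects coordinate interpretability.  Zeros are
replaced multiplicatively with δ = 1/(2·17,280), half of one tick's daily
share, before taking logs.

Cross-sectional clustering (the single farrowing day) is Lloyd k-means,
best of `n_init = 50` random starts, seeded.  Multi-day periods are
clustered longitudinally by flattening each sow's days × coordinates
matrix and applying the same algorithm — the joint Euclidean trajectory
distance of multivariate longitudinal k-means; the equivalence to
flattened k-means is definitional and tested.  ILR coordinates share a
scale, so no per-coordinate standardisation is applied (configurable).
The number of clusters maximises the second difference of the inertia
profile over consecutive k (elbow rule), ties toward smaller k; a sweep
safeguard reuses the previous k's centres as an extra initialisation so
inertia is provably non-increasing in k.  Cluster letters A, B, … are
assigned by descending size (ties by lexicographic centre order).

## 4. Association protocol

Piglet-level outcomes are regressed on dam-level behaviour with fixed
effects of piglet genetic type (4 levels), litter-size class (12–14,
15–16, 17–21 born alive) and pen (A–D) always included and never dropped.

* **Step 1 — screening.**  Each period-eligible behavioural item enters
  alone (plus fixed effects).  Count traits are coded continuous or as
  empirical tertile classes I/M/S (boundaries at the 33rd/66th percentiles
  with linear interpolation, ≤/> semantics, computed over unique dams;
  growth models may also use the two-class S vs M+I coding); the coding
  with the lower AIC wins.  A significant cluster factor may be replaced by
  the raw trait that mainly explains the cluster contrast — operationalised
  as the largest standardised mean difference between the two largest
  clusters — when that trait achieves the lower AIC.  Items with
  likelihood-ratio p < 0.05 survive.  Before farrowing only the two pattern
  factors and PCAll are eligible; PCStopNurse is ineligible on D0 for
  survival (no nursing to interrupt during farrowing) but eligible for
  growth.
* **Step 2 — per-period reduction.**  Survivors enter a saturated model,
  pruned by backward elimination: repeatedly drop the term whose removal
  gives the largest LRT p > 0.05 (ties broken toward the smaller |coef|/SE).
* **Step 3 — global model.**  Survivors of all periods are pooled (terms
  making the pooled design rank-deficient are dropped greedily and
  recorded) and pruned the same way.

Survival fits maximise the Cox partial likelihood with **Efron's tie
correction** — death days are whole days (recorded each morning), so ties
are the rule and Breslow would be noticeably biased.  Numerical
optimisation is delegated to lifelines; a brute-force partial-likelihood
grid search is the oracle in the tests.  Piglets are treated as independent
given the dam covariates (no frailty term, matching the modelled design);
dam-clustered robust errors are a possible extension, not a default.  The
proportional-hazards assumption is checked with scaled Schoenfeld
residuals: per term, the correlation of the residual with the rank of the
event time; globally, the joint chi-square statistic
`z' (Σ(g−ḡ)² V̄)⁻¹ z` with `V̄` the average per-event information — for a
single-term model the global test coincides with the term test.  Growth
uses OLS with the identical selection protocol (likelihood-ratio tests on
the Gaussian likelihood).

Every screening comparison, drop and keep is appended to a
`SelectionTrace`; replaying a trace (refitting its final term set) must
reproduce the final coefficients exactly, which is tested.

Note on screening calibration: choosing the coding by AIC *before* the
α = 0.05 significance test makes the realised type-I error of the screen
slightly exceed 5 % (a selection-then-test effect); the acceptance study
measures the realised rate under a pure-noise candidate.

## 5. Study sizes in the test suite

Simulations are sized to what one CPU core handles comfortably while
leaving Monte-Carlo error well inside the asserted bounds: recovery runs
use 300-sow cohorts (~4,500 piglets) pooled over three replicates for the
planted hazard ratio (0.56 per 100 posture changes) and the three growth
shifts; screening type-I error uses 200 null replicates of 60-sow studies;
calibration checks use 50-sow cohorts; clustering recovery uses 40 sows
over D1–D7 with two planted lying-style regimes (~91 % vs ~80 % of lying
time with the udder exposed) and every between-sow nuisance effect
switched off — a continuum of preferences or activity levels is precisely
what a two-regime structure is not, and extreme activity outliers distort
the joint trajectory distance (see limitations).
Posture-change counting is verified against the brute-force oracle on
10,000 random streams; the Cox oracle on ≤ 6-subject instances to 1e−4.

## 6. What passing tests do and do not show

The generator reproduces the *structure* the analysis assumes — budget
closure, period anchoring, restlessness dynamics, compositional cluster
separation, proportional hazards with heavy day-resolution ties,
trait-driven growth — so green tests show the pipeline recovers known
truths under that structure at realistic sizes.  They do not show that
real sows satisfy the model: real streams carry autocorrelated classifier
error (not independent tick flips), nursing-bout microstructure inside
LLU, circadian rhythm within days, and count traits whose mutual
correlations are free rather than fixed by a transition matrix.  Cluster
*memberships* of any real cohort are likewise outside what synthetic
recovery can certify.

## 7. Known limitations

* Exponential holding times: dwell distributions are memoryless, so the
  simulator understates long consolidated lying bouts.
* The uniform-jump chain fixes the ratio between transition types;
  PCRiskCrush/PCStopNurse are usable as relative traits only.
* The discrete-day hazard is a first-order approximation to a continuous
  Cox model; with per-day hazards ≤ ~0.05 the bias on log-HRs is well
  below the Monte-Carlo noise at the sizes used.
* k-means on ILR coordinates is sensitive to outliers produced by the
  zero-replacement floor: a hypo-active sow with zero ticks in a rare
  posture class on some day gets an extreme log-ratio coordinate and can
  be isolated as a singleton cluster.  The planted-regime recovery study
  therefore switches between-sow nuisance effects off; on real data a
  larger replacement δ, amalgamating rare parts, or a robust clustering
  variant would be the corresponding remedies.
* Tertile boundaries follow one fixed quantile definition (type-7
  interpolation); other definitions shift boundary animals between
  classes.
* No multiple-testing control beyond the protocol's own LRT thresholds,
  matching the analysis it implements.
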