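# Methods

This note records the model and procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Outcome definition and anchoring

AKI is operationalized purely through serum creatinine (AKIN stage 1): a
rise of ≥ 0.3 mg/dL absolute, or to ≥ 150% of an earlier value, between two
measurements at most 48 h apart. Urine-output criteria and stage 2–3
grading are out of scope. Three interpretation choices deserve note:

* **All ordered pairs.** The criterion is evaluated over every ordered pair
  of measurements within 48 h, not only adjacent ones; the rule is stated
  on measurements taken within a time window, and restricting it to
  consecutive draws would make the label depend on sampling density.
* **Ratio band.** "150–200%" is read as ratio ≥ 1.5 with no upper cap:
  rises beyond 200% indicate more severe injury, not its absence. A
  `ratio_cap` config flag restores the literal band for sensitivity
  analyses.
* **Boundaries.** The 48 h bound is inclusive on minute-precision
  timestamps, and Δ ≥ 0.3 is tested with a 10⁻⁹ guard so decimal values
  arriving through CSV round-trips compare as intended.

The *AKI Time* — the second measurement of the earliest qualifying pair —
anchors every data-collection window. Non-AKI encounters are anchored at
their last creatinine measurement. The eligibility rules (a prior
non-qualifying pair for AKI patients; at least one pair within 48 h for
non-AKI patients) guarantee the label was decidable and not present on
admission. Duplicate timestamps within one test keep the last-reported
value, which preserves strictly increasing times and finite slopes.

## Windows, representations, similarities

Windows are [anchor − (w + d), anchor − d] days, closed at both ends
(printed interval notation is closed; a point exactly at a bound is
evidence available at that bound). Note a structural consequence: at d = 0
the window contains the anchor itself, i.e. the diagnostic creatinine pair.
Day-zero performance therefore partly reflects detection rather than
prediction; this is inherent to the window definition, not an artifact of
this implementation.

Slopes are computed from minute differences converted to days and carried
at full precision; rounding to two decimals is display-only, since rounding
before DTW would perturb distances. Symbolization uses mean/SD breakpoints
with every boundary belonging to the lower symbol; σ = 0 collapses all bins
onto μ and maps every value to symbol 3 (the branch whose interval limit
contains the point mass). The symbolizer uses the sample (n−1) standard
deviation — a convention choice; nothing downstream is sensitive to it at
realistic n. Breakpoints are fitted on the **selection part only** and then
applied to both parts: fitting on all patients pools information across the
train/test boundary. Because the original protocol reads as pooled
("for all inpatients"), an `all_inpatients_sigma` flag reproduces that
variant.

DTW is the plain unnormalized recursion with no warping-window constraint.
Unnormalized DTW carries a length bias (longer sequences accumulate more
cost); it is kept because KNN only ranks distances within one channel, and
any normalization would be an additional modeling decision with no basis in
the protocol being implemented.

## Classification, fusion, selection

Defaults: k = 5 (smallest odd k above 1 that smooths noise; vote ties are
then only possible with truncated neighborhoods), distance ties at the k-th
rank broken by encounter id under a stable sort (determinism over
neighborhood expansion), vote ties resolved positive (screening favors
sensitivity; configurable). Missing representations abstain rather than
being imputed; OR fusion treats abstains as negative evidence.

Channel-subset accuracy during selection is computed **leave-one-out** on
the selection part: the protocol never states how selection-part accuracy
avoids contaminating neighbors, and leave-one-out uses all records without
an extra split while staying deterministic. A `resubstitution_selection`
flag provides the variant where a record may be its own neighbor. SFS stops
when no addition strictly improves accuracy — OR fusion accumulates false
positives, so the loop terminates naturally, and on balanced data the empty
set already scores 0.5. SBS removes down to one channel and returns the
best subset along the trace (ties prefer the smaller subset): greedy
backward pruning of a large OR ensemble is poorly informed in its early
steps, which is visible in practice as SBS underperforming SFS.

The continuous score for ROC analysis (maximum positive-neighbor fraction
over non-abstaining selected channels) is an explicit convention layered on
top of the binary OR rule; the underlying procedure defines no score, so
AUC values are comparable only within this package.

## Synthetic cohort

The generator emulates the statistical shape this pipeline assumes:
encounters of patients aged 60–95 with stays of at least 10 days to the
anchor, ~10% AKI prevalence by default, an 8-analyte panel (creatinine,
BUN, and six uninformative analytes that exercise the selection stage's
ability to discard noise), and irregular sampling at 2 draws/test/day.

* **Exact class counts.** Exactly round(n·prevalence) encounters are made
  AKI, assigned by seeded permutation. A per-encounter Bernoulli draw at
  prevalence 0.5 — the balanced study condition — would make positives
  outnumber negatives about half the time, under which the balancing
  contract (⌊n_neg/n_pos⌋ datasets keeping all positives) yields nothing.
* **Sampling times.** Homogeneous Poisson per test, truncated to the stay,
  with a 2 h refractory period. The dead time matters: slope noise scales
  as 1/Δt, so draws minutes apart would dominate the pooled slope SD and
  erase the trend channel for every analyte — and repeat labs are not
  redrawn within minutes in practice.
* **Values.** Per-test Gaussian baseline + per-encounter offset
  (between-patient variation) + white measurement noise scaled by
  `noise_sd`. Informative analytes ramp linearly over the 5 days before
  the planted event, by +0.25 mg/dL (creatinine) and +15 mg/dL (BUN) per
  unit `effect_size`. Between-patient SD exceeds within-patient SD
  (creatinine 0.25/0.05, BUN 5.0/0.6, in line with the biological/analytic
  variance ratio of these analytes), which has a deliberate consequence:
  slopes cancel the per-patient offset, so near the event the TREND channel
  is cleaner than LAST and (BUN, TREND) emerges as the dominant channel at
  short horizons.
* **Exact labels.** A forward sweep caps each creatinine value below both
  stage-1 thresholds relative to every value in the preceding 48 h
  (margins 0.02 mg/dL and 0.05 in ratio, sized so 2-decimal CSV rounding
  cannot re-cross a threshold); AKI encounters then get an explicit
  qualifying pair (+0.35 mg/dL) planted at the event time, with helper
  points at −44 h and −24 h guaranteeing the pre-event eligibility pair.
  The AKIN labeler therefore recovers every planted label and event time
  exactly, which the tests assert at 100%.

What the generator does **not** emulate: comorbidity, medication effects,
inter-test correlation beyond the shared ramp, missingness that depends on
clinical state, or heavy-tailed laboratory error. Passing tests show the
pipeline recovers the signal it was designed for under its own assumptions;
they say nothing about transportability to real EHR data.

## Study conditions used by the tests and acceptance script

Recovery experiments use 400 balanced encounters (prevalence 0.5 → one
balanced dataset), k = 5, SFS, 8:2 split, 5-day window, averaged over 5
seeds — large enough for stable selection behavior while keeping a full run
in tens of seconds. Under the default strong drift, mean F1 at d = 0 is
≈ 0.97 with (BUN, TREND) selected in every seed, decaying to ≈ 0.5–0.6 at
d = 5 where the window predates the ramp. The null check (effect_size = 0)
is run at **horizon 1**: at horizon 0 the window provably contains the
diagnostic creatinine pair, so the label is a deterministic function of
window content and no implementation can sit at chance there; at d ≥ 1 the
null generator carries no class signal and fused F1 stays within ±0.1 of
0.5 (the residual upward drift of F1 over accuracy comes from OR fusion's
positive lean combined with selection overfitting on noise channels).

## Numerical and degenerate-input conventions

Precision with zero predicted positives is reported as 0 with an explicit
flag rather than NaN. AUC uses midrank tie handling and requires both
classes. Metrics across balanced datasets are macro-averaged by default
(`micro_average` pools confusion counts instead). An encounter whose window
contains no measurements abstains everywhere and is classified negative.
Empty candidate sets, empty classes, non-positive creatinine values, and
malformed tables are rejected with explicit errors.

## Known limitations

Greedy SFS/SBS offer no optimality guarantee under OR fusion; KNN is
unweighted; the AUC score is a stand-in convention; day-zero metrics
conflate detection with prediction (above); and all performance claims are
conditional on the synthetic data model.
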