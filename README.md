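# akipair

Early prediction of acute kidney injury (AKI) for older inpatients from
laboratory-test time series.

AKI is common among hospitalized patients and, once established, sharply
raises mortality; flagging high-risk patients days before the event gives
clinicians time to act. `akipair` implements a similarity-based prediction
pipeline for this problem: encounters are labeled by the AKIN stage-1 serum
creatinine criterion, every laboratory test is summarized by two symbolic
feature channels, patients are classified channel-by-channel with K-nearest
neighbors under channel-specific similarities, and a greedy search selects
the channel subset that predicts best. A synthetic EHR generator with
planted, exactly recoverable AKI events makes the whole pipeline testable
without access to protected hospital data.

## Method

**Labeling (AKIN stage 1).** An encounter is AKI if two serum-creatinine
measurements taken at most 48 h apart (any ordered pair, not only adjacent
measurements) show Δ ≥ 0.3 mg/dL or a rise to ≥ 150%. The *AKI Time* is the
second measurement of the earliest qualifying pair and anchors all windows;
non-AKI encounters are anchored at their last creatinine measurement.
Eligibility requires a non-qualifying pair before the event (AKI) or at
least one pair within 48 h (non-AKI); patients younger than 60 or with
stays under 10 days (admission to anchor) are excluded.

**Windows.** Predicting *d* days early with window length *w* uses only
laboratory values in [anchor − (w + d), anchor − d] days, closed at both
ends; defaults are w = 5, d ∈ {0..5}.

**Representations.** For a test's value sequence L = ((t₁,v₁),…,(tₙ,vₙ)):

* LAST — the final value v_last = vₙ;
* TREND — the slope sequence S = (s₁,…,sₙ₋₁), sⱼ = (vⱼ₊₁ − vⱼ)/(tⱼ₊₁ − tⱼ)
  in value change per day (timestamps at minute precision).

Both are discretized into six symbols by mean/SD breakpoints
(μ−σ, μ−σ/2, μ, μ+σ/2, μ+σ; every boundary belongs to the lower symbol)
fitted per (test, type) on the selection part of the data.

**Similarity and classification.** Two patients are compared per channel:
LS = |r_last₁ − r_last₂| for LAST, and for TREND the unnormalized dynamic
time warping distance D(m,n) over the symbolic slope sequences, with local
cost δ(i,j) = |r¹ᵢ − r²ⱼ| and D(i,j) = δ(i,j) + min{D(i,j−1), D(i−1,j−1),
D(i−1,j)}. Each channel casts a K-nearest-neighbor vote (k = 5 by default);
a patient lacking a channel's representation abstains on it. Votes are
**OR-fused**: positive if any selected channel votes positive.

**Channel selection.** Classes are balanced by repeated disjoint
under-sampling (⌊n_neg/n_pos⌋ datasets); each balanced dataset is split
into selection and prediction parts (8:2 or 5:5, stratified). Sequential
forward selection (SFS) grows the channel set while leave-one-out OR-fused
accuracy on the selection part strictly improves; sequential backward
selection (SBS) prunes from the full set and keeps the best subset seen.

## Worked example

Generate a balanced synthetic cohort of 400 encounters with the default
strong pre-event drift in creatinine and BUN, then run the pipeline at
horizons 0, 2 and 5 days with a 5-day window:

```yaml
# example.yaml
horizon_days: [0, 2, 5]
window_days: [5]
seed: 11
generator:
  n_encounters: 400
  aki_prevalence: 0.5
  seed: 11
```

```text
$ akipair run-all --config example.yaml --out results
w=5d d=0: precision=0.975 recall=0.975 F1=0.975 accuracy=0.975 auc=0.999
w=5d d=2: precision=0.923 recall=0.900 F1=0.911 accuracy=0.912 auc=0.962
w=5d d=5: precision=0.524 recall=0.825 F1=0.641 accuracy=0.537 auc=0.510
```

On the day of the event (d = 0) the classifier is nearly perfect and SFS
selects the single channel (BUN, TREND) — the blood-urea-nitrogen drift is
the cleanest signature of impending AKI. Performance decays as the horizon
grows; at d = 5 the window ends before the pre-event drift begins and the
AUC sits at chance, which is exactly what the generator's 5-day ramp
implies. `results/` receives `metrics.json`, per-window CSV tables, and the
effective config + environment manifest for reproducibility.

The stages are also available separately (`akipair generate | cohort |
select | predict | evaluate`), and everything is callable as a library:

```python
from akipair import GeneratorConfig, PipelineConfig, run_experiment

cfg = PipelineConfig(horizon_days=(0,), window_days=(5,), seed=11,
                     generator=GeneratorConfig(n_encounters=400,
                                               aki_prevalence=0.5, seed=11))
report = run_experiment(cfg)[0]
print(report.f1, report.per_dataset[0]["selected_pairs"])
```

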