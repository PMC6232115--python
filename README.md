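# memtrace

Analysis pipeline for **recognition memory of one-second real-life events**,
plus a calibrated synthetic-cohort simulator that gives every stage of the
pipeline a known ground truth.

## The problem

In the paradigm this package supports, a subject spends about an hour walking
a fixed route while head-mounted video (and, indoors, an eye tracker) records
their first-person experience.  Later they take an old/new forced-choice
test: one-second **target** clips from their own walk are interleaved with an
equal number of **foil** clips from another subject's walk on the same route,
and the subject answers *yes* (my experience) or *no*.  Because the design is
balanced, chance is 50%.  A small set of clips is covertly repeated to
measure response **self-consistency**.

The scientific questions the pipeline quantifies:

* **How much detail is retained?**  Per-subject percent correct, hit rate
  P_CD, false-alarm rate P_FA, sensitivity d′ = Φ⁻¹(P_CD*) − Φ⁻¹(P_FA*) and
  criterion c = −(Φ⁻¹(P_CD*) + Φ⁻¹(P_FA*))/2 (log-linear corrected rates
  p* = (x+0.5)/(n+1)), with one-sample t-tests of the cohort against chance
  and QC flags for yes-biased responders and accuracy outliers.
* **Do memories have temporal extent?**  The normalized conditional
  probability y(Δt) = P(correct at t | correct at t−Δt) / P(correct) over
  *encoding-time* lags, fitted with y = 1 + α·exp(−Δt/τ).  A τ of tens of
  seconds means events are remembered (or forgotten) in episodes longer than
  the one-second probes.  A test-order control curve checks that the
  dependence lives on the encoding timeline, not the test sequence.
* **What makes an event memorable?**  Performance split by annotated clip
  content (targets vs foils) and by fixated content (targets only), with
  two-sided Wilcoxon rank-sum tests across subjects; and a per-subject
  cross-validated classifier (AdaBoost over depth-1 decision trees)
  predicting single-trial correctness from visual features, content
  annotations, and eye-movement features, with feature-group ablations.

The simulator (`memtrace.synthetic`) generates cohorts whose statistical
structure matches these analyses' assumptions: yes/no responses are
thresholded Gaussian familiarity, correctness inherits an exponential
autocorrelation from a latent Ornstein–Uhlenbeck process on the encoding
timeline, and covert-repeat agreement is calibrated through exact bivariate
normal orthant probabilities.

## Worked example

```python
import memtrace as mt

cfg = mt.experiment_i(n_subjects=16, seed=7)   # outdoor-walk, 1-day conditions
study = mt.build_cohort(cfg)
rep = mt.group_report(study)
pc, cons = rep["percent_correct_vs_chance"], rep["self_consistency_vs_chance"]
print(f"percent correct: {pc.mean:.1f} +/- {pc.dispersion:.1f}% (SD), "
      f"t = {pc.t_statistic:.2f}, p = {pc.p_value:.2g} vs 50%")
print(f"mean d' = {rep['mean_d_prime']:.2f} +/- {rep['sd_d_prime']:.2f} (SD)")
print(f"self-consistency: {cons.mean:.1f} +/- {cons.dispersion:.1f}% (SEM)")

curve = mt.conditional_curve(study)            # 5 s bins up to 120 s, targets only
fit = mt.fit_decay(curve, weights="pair_counts")
print(f"history dependence: y = 1 + {fit.alpha:.2f} exp(-dt/{fit.tau_s:.1f} s)")
```

prints

```
percent correct: 56.4 +/- 6.1% (SD), t = 4.17, p = 0.00083 vs 50%
mean d' = 0.35 +/- 0.33 (SD)
self-consistency: 79.6 +/- 1.5% (SEM)
history dependence: y = 1 + 0.24 exp(-dt/21.8 s)
```

Reading the output: the cohort remembers the minutiae of its hour only
slightly — but reliably — above chance (d′ ≈ 0.35); answers to covertly
repeated clips agree ~80% of the time, so the weak performance is not random
key-pressing; and being correct about one moment predicts being correct about
moments a few tens of seconds away.  A single 16-subject cohort estimates
(α, τ) noisily — `memtrace.recovery.pooled_lag_recovery` pools the curve over
replicate cohorts for stable recovery.

The same pipeline runs from the shell on any directory of study tables
(`trials.csv`, `annotations.csv`, `fixations.csv`, `cv_features.csv`,
`study.yaml`):

```bash
memtrace simulate --out study/ --preset experiment_II --seed 7
memtrace validate study/
memtrace analyze lag study/ --bin 5 --max-lag 60
memtrace report study/ --out report/
```

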