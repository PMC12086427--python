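# neurostates

Individual-level neural state segmentation for multichannel time series,
with boundary-alignment statistics and memory-linkage regressions.

## The problem

While people watch a continuous, naturalistic stimulus (e.g. a movie), their
brain activity moves through a sequence of *neural states* — periods during
which the spatial pattern of activity across channels stays relatively
stable before transitioning to a new pattern.  These transitions tend to
align with perceived event boundaries and are a candidate neural substrate
of event segmentation, which in turn shapes episodic memory.  This package
implements the full analysis chain needed to study those states in
*individual subjects'* EEG-like recordings:

1. **Segmentation** — Greedy State Boundary Search (GSBS) finds the
   boundary locations that maximize within-state pattern similarity, one
   subject at a time.
2. **Model selection** — the number of states `k` is chosen by the
   *t-distance*: a two-sample t statistic separating the distribution of
   pattern correlations for timepoint pairs within a state from pairs in
   adjacent states.  Because slow drifts make tiny `k` spuriously
   attractive, the selected `k` is the *first t-distance peak at or above a
   minimum* (default 15 states).
3. **Alignment** — a subject's boundaries are Gaussian-smoothed
   (SD = 2 samples ≈ 400 ms) and correlated with a leave-one-out group
   average or a behavioral button-press density (presses shifted by a 0.9-s
   response-time correction, counted in 2-s windows), giving the
   *adjusted match*

   `adjusted_match = r_raw / r_max − null_mean / r_max`,

   where `r_max` is the best correlation attainable with that subject's
   boundary count and the null comes from 1,000 duration-preserving shuffles
   of the subject's states.  Values above 0 mean above-chance alignment.
4. **Boundary distinctiveness** — for each boundary, all spatial patterns
   in the 2 s before it are correlated with all patterns in the 2 s after
   it; the median across boundaries minus the same quantity at state
   midpoints (`delta`) measures how sharply activity changes at boundaries
   (negative = distinct).
5. **Memory linkage** — `proportion_internal ~ neural + group +
   neural × group` fit by OLS with stratified subject-level bootstrap
   (B = 5,000); coefficients are reported as bootstrap medians with
   percentile CIs.

A synthetic-cohort generator plants known shared-but-jittered boundaries,
noise, slow drift, button presses and memory couplings, so every stage can
be validated against ground truth.

## Worked example

```python
import numpy as np
from neurostates import (simulate_cohort, segment_subject, align_cohort,
                         boundary_distinctiveness, one_sample_t)

recs, truth = simulate_cohort(
    n_young=6, n_old=6, n_shared_states=18, T_samples=512, n_channels=32,
    jitter_sd_samples=1.0, p_idiosyncratic=0.1, seed=0,
)
segs = [segment_subject(rec, k_min=15) for rec in recs]
print("selected state counts:", [s.selected_k for s in segs])

align = align_cohort(segs, n_shuffles=1000, seed=1)
t, df, p, d = one_sample_t(align["adjusted_match"])
print(f"adjusted match to group: M={align['adjusted_match'].mean():.3f} "
      f"SD={align['adjusted_match'].std(ddof=1):.3f}, t({df})={t:.2f}, p={p:.2g}")

deltas = [boundary_distinctiveness(r.data.T, s).delta for r, s in zip(recs, segs)]
t, df, p, d = one_sample_t(deltas)
print(f"boundary distinctiveness: M={np.mean(deltas):.3f}, t({df})={t:.2f}, p={p:.2g}")
```

prints

```
selected state counts: [17, 18, 16, 17, 17, 18, 18, 18, 18, 18, 18, 18]
adjusted match to group: M=0.777 SD=0.101, t(11)=26.61, p=2.5e-11
boundary distinctiveness: M=-0.802, t(11)=-98.41, p=1.5e-17
```

Twelve simulated subjects sharing 18 planted states (with one-sample jitter
and 10% idiosyncratic boundaries) are segmented individually; the selected
state counts cluster on the planted 18, boundary placements align with the
group far above chance, and activity patterns change much more sharply at
boundaries than within states (negative delta).  On real recordings the
alignment and delta values are far smaller in magnitude — synthetic state
patterns are independent across states, real ones are not — but their signs
and tests behave the same way.

A command-line interface mirrors the library:

```bash
neurostates simulate --out cohort/ --seed 0
neurostates segment --input cohort/Y01.csv --kmin 15
neurostates run-all --out results/ --seed 42
```

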