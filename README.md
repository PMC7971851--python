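# mrcrit

Distance-to-criticality inference from population spiking activity.

Cortical population dynamics can be described as an activity-propagation
process whose stability is summarized by a single branching parameter
*m*: each active neuron triggers on average *m* successors per time
step, on top of external drive *h*. Dynamics are stable (subcritical)
for *m* < 1, unstable for *m* > 1, and *m* = 1 marks the critical point
of a second-order phase transition. `mrcrit` is built for the question
of how close recorded brain activity operates to that instability — in
particular for within-patient comparisons in focal epilepsy, where one
asks whether the epileptogenic hemisphere operates closer to criticality
than the contralateral one, and whether activity drifts towards
instability in the minutes before a seizure.

The package provides, end to end:

* a driven branching-process simulator,
  *A*<sub>*t*+1</sub> = Σ<sub>*i*=1..*A_t*</sub> *Y*<sub>*t,i*</sub> + *h*<sub>*t*</sub>,
  with Poisson offspring (mean *m*, optionally time-varying) and Poisson
  drive, plus a binomial-thinning observation model for electrode
  subsampling;
* the **multistep-regression (MR) estimator** of *m*: the activity
  autocorrelation *C*(*k*) is computed over lags *k*·Δ*t* ∈ [4, 1600] ms
  and fitted with an exponential-with-offset,
  *f*(*k*) = *B m*<sup>*k*</sup> + *D* = *B* e<sup>−*k*Δ*t*/τ</sup> + *D*,
  giving *m̂* = e<sup>−Δ*t*/τ̂</sup> and the intrinsic timescale τ̂.
  Subsampling only rescales the amplitude *B*, not the decay rate, so
  the estimate is **subsampling-invariant** — unlike the conventional
  lag-1 regression slope, which is biased towards zero by the recorded
  fraction. Estimates carry block-bootstrap confidence intervals (20 s
  blocks, stationary-mean variant) and two consistency checks
  (≥ 1000 non-zero bins; exponential must beat a straight line);
* spike-table I/O: pooling single-unit spike times per hemisphere /
  MTL subregion (H, A, PHC, EC) and binning into 4 ms population
  activity counts;
* time-resolved estimation (80 s sliding windows, 2 s step) with the
  rule that a recording is excluded when more than 5% of its windows are
  inconsistent;
* cohort statistics on the logarithmic distance to criticality
  ε = log(1 − *m̂*): mixed-model hemispheric contrasts
  (`epsilon ~ focus + (1 | patient_id)`), per-subregion contrasts with
  Bonferroni control, split-half pre-seizure comparisons (Wilcoxon
  signed-rank), and MAD variability changes;
* a synthetic-cohort generator calibrated to clinical medians (pooled
  firing rate ≈ 25.8 Hz, ≈ 10% non-zero 4 ms bins) with null,
  closer-to-critical, drift, and variability-increase regimes.

## Worked example

Simulate a subcritical process at *m* = 0.95 for 10 minutes, observe
only 0.4% of its activity, and recover the branching parameter:

```python
from mrcrit import (simulate_stationary, subsample_trace, SubsampleSpec,
                    estimate_m, EstimationConfig)

full = simulate_stationary(m=0.95, h=1.0, duration_bins=150_000, seed=7)
observed = subsample_trace(full, SubsampleSpec(alpha=0.004, seed=8))
result = estimate_m(observed, EstimationConfig(n_boot=250, boot_seed=9))

print(f"m_hat   = {result.m_hat:.4f}  (95% CI {result.ci_low:.4f}-{result.ci_high:.4f})")
print(f"tau     = {result.tau * 1e3:.1f} ms")
print(f"epsilon = {result.epsilon:.3f}")
print(f"B       = {result.fit.B:.4f}")
print(f"accepted: {result.accepted}  (n_nonzero = {result.n_nonzero})")
```

prints

```
m_hat   = 0.9522  (95% CI 0.9439-0.9604)
tau     = 81.6 ms
epsilon = -3.040
B       = 0.0391
accepted: True  (n_nonzero = 11152)
```

Despite seeing only a 0.004 fraction of the activity, the estimate
brackets the generating *m* = 0.95; the subsampling shows up solely in
the amplitude *B* ≈ 0.04 ≈ α·10 (the lag-1 slope, by contrast, would be
≈ 0.04 and useless as an estimate of *m*). τ ≈ 80 ms is the intrinsic
timescale implied by *m̂*, and ε ≈ −3.0 is the logarithmic distance to
criticality used by all cohort-level statistics.

A command-line interface mirrors the library:

```bash
mrcrit simulate --m 0.95 --h 1 --alpha 0.004 --duration-s 600 --seed 1 --out trace.tsv
mrcrit estimate --trace trace.tsv --boot 250 --seed 1
mrcrit timeresolved --trace trace.tsv --window-s 80 --step-s 2 --out series.tsv
mrcrit synth --scenario A --patients 8 --seed 1 --out cohort/
mrcrit cohort --manifest cohort/manifest.yaml --out report/
```

## Layout

| module | contents |
|---|---|
| `mrcrit.process_model` | branching-process simulation, subsampling, stationary helpers |
| `mrcrit.mr_estimator` | ACF, exponential-with-offset fit, consistency checks, block bootstrap |
| `mrcrit.spike_data` | spike TSV parsing, pooling/binning, result and manifest I/O |
| `mrcrit.timeresolved` | sliding-window estimation and the 5% exclusion rule |
| `mrcrit.cohort_analysis` | mixed models, rank tests, MAD analysis, cohort orchestration |
| `mrcrit.synthetic_cohort` | scenario-based synthetic cohorts (spike tables + manifests) |

See `docs/methods.md` for the model, estimator, statistical choices and
known limitations.
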