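# Methods

## Model

Population spiking activity is modeled as a driven branching process in
discrete time bins of width Δt = 4 ms (chosen to match the propagation
time of spikes between neurons). With A_t active units in bin t,

    A_{t+1} = sum_{i=1}^{A_t} Y_{t,i} + h_t,

where the offspring counts Y_{t,i} are iid with mean m (the branching
parameter) and h_t is external drive with mean h. Taking conditional
expectations gives the autoregressive representation
⟨A_{t+1} | A_t⟩ = m·A_t + h: the process is an AR(1)-like chain whose
autocorrelation decays as C(k) ∝ m^k. For m < 1 the process is
subcritical with stationary mean h/(1−m); m = 1 is the critical point.

**Offspring and drive distributions.** The offspring distribution is
Poisson with mean m and the drive is Poisson with mean h. Only the means
enter the first-order (autocorrelation) structure that the estimator
uses; Poisson keeps the process integer-valued with variance ≈ mean, as
in the standard branching-network literature. Since a sum of A_t iid
Poisson(m) variables is Poisson(m·A_t), the simulator draws the update
as a single Poisson(m·A_t + h) variate — exactly equivalent and much
faster. The offspring family is parametrized (`offspring_model`) so
alternatives can be added.

**Time-varying m.** `m_profile` is evaluated per bin: offspring
generated in bin t use m_profile[t]. This supports drift scenarios where
m ramps towards 1 before an event.

**Subsampling.** Electrodes record only a tiny fraction of the
population. This is modeled as independent binomial thinning: each event
in each bin is observed with probability α. A fixed-subset-of-neurons
alternative (sampling the same units every bin) is *not* implemented;
for the autocorrelation structure at the population level the two mainly
differ through unit-rate heterogeneity, which the synthetic cohort
reintroduces at the spike-disaggregation step.

**Burn-in.** Stationary runs start at the rounded stationary mean and
discard ceil(10·τ/Δt) initial bins (τ = −Δt/log m of the generating m),
removing initialization transients.

**Ensemble simulation.** Calibration and power studies need hundreds of
replicate traces; `simulate_stationary_ensemble` runs the identical
recursion on a whole matrix of independent columns at once. A one-column
ensemble reproduces `simulate_branching` exactly (tested).

## MR estimation

Estimation of m from an activity trace proceeds in two steps.

1. **Autocorrelation.** For k = 1..k_max (default k_max = ⌊1.6 s/Δt⌋ =
   400, i.e. lags 4–1600 ms, several intrinsic timescales of typical
   data),

       C(k) = Σ_t (A_t − Ā_lead)(A_{t+k} − Ā_lag) / Σ_t (A_t − Ā_lead)²,

   with the leading and lagged segments demeaned separately. This equals
   the OLS slope of the lag-k regression of A_{t+k} on A_t (property
   tested to 1e-10 against a brute-force oracle). The lag grid is every
   integer bin — no log-spacing.

2. **Exponential-with-offset fit.** f(k) = B·m^k + D is fitted by
   bounded least squares (trust-region reflective with analytic
   Jacobian). The offset D absorbs contributions with timescales much
   longer than the fit range and small non-stationarities; B is the
   subsampling bias factor (≈ α·Var-ratio under thinning), and the
   decay rate gives m̂ and τ̂ = −Δt/log m̂. Because only the *rate* of
   decay carries m, the estimate is invariant under subsampling, while
   the conventional lag-1 slope equals B·m and collapses with α.

**Parametrization and bounds.** The fit is parametrized directly in m
with m ∈ [e⁻¹⁰, 1.05], B ∈ [−1, 5], D ∈ [−1, 1]. The lower m bound
corresponds to τ = Δt/10; the upper bound sits slightly above 1 so
near- and supercritical windows remain expressible (time-resolved traces
do occasionally enter the supercritical regime, and clamping them below
1 would hide exactly the events of interest). τ is derived from the
minimizer, so the identity m̂ = exp(−Δt/τ̂) holds to machine precision by
construction, including the negative-τ branch for m̂ > 1 (and τ = ∞ at
m̂ = 1).

**Initialization and restarts.** The landscape is non-convex. Initials
are data-driven: τ₀ from a log-linear regression of the offset-removed
ACF over the first decade of lags, B₀ = C(1), D₀ = mean of the last 10%
of lags. After the first attempt, initials are jittered for up to 10
further attempts (at least 3 attempts total); the lowest-SSE converged
fit wins. Fits are deterministic given the input (jitter uses a fixed
seed from the estimation config).

**Consistency checks (exclusion criteria).** An estimate is `accepted`
only if (i) the trace has at least 1000 non-zero bins (the threshold is
inclusive) and (ii) the exponential fits the autocorrelation better than
a straight line, otherwise the data are not consistent with a stationary
autoregressive process. For (ii) the default statistic is Gaussian AIC,
i.e. SSE with a complexity penalty for the exponential's third
parameter. A raw-SSE comparison is available as a config switch but is
*not* the default: the family B·m^k + D contains near-linear shapes in
the m→1 limit, so with one extra free parameter it beats the best line
on pure noise most of the time, and the raw comparison would keep ~70%
of white-noise traces. Under AIC, white noise is rejected in the large
majority of cases while genuinely exponential (branching) traces pass
essentially always. Near criticality the exponential decay itself
approaches a line on a finite lag range, so this criterion must be used
with care on data suspected to be very close to critical; it is applied
here because it reliably catches non-stationary or noise-dominated
segments.

**Block bootstrap.** CIs on m̂ come from a percentile bootstrap over
consecutive 20 s blocks (250 replicates, 95% by default). Each replicate
resamples blocks with replacement and recomputes the ACF in the
"stationary mean" fashion: lagged cross-products are accumulated per
block but demeaned with the pooled mean of the selected blocks, then the
exponential is refitted. Per-block sufficient statistics are precomputed
once, so replicates are cheap. A trace shorter than two blocks yields no
CI and is flagged (`ci_available=False`) rather than failing.

**Distance to criticality.** All group statistics use
ε = log(1 − m̂) (natural log), which is defined only for m̂ < 1;
supercritical estimates are retained in time-resolved series but
excluded from ε-based statistics with a reported count.

## Spike data conventions

Input is a TSV with one row per spike (patient, recording, epoch kind,
hemisphere role, subregion, unit, quality, time). Only single units are
analyzed; `artifact` and `multi-unit` rows are dropped at parse time.
Hemispheres are labeled by *role* (ipsilateral = containing the focus);
mapping anatomical side to role is an input, not a computation. Binning
uses half-open 0-based bins [iΔt, (i+1)Δt); a spike at exactly the epoch
end is assigned to the last bin when the duration is an exact bin
multiple, otherwise rejected. Pooling is per hemisphere over the full
MTL and per (hemisphere, subregion); "full MTL" sums spikes before
binning rather than averaging subregion-level estimates.

## Time-resolved estimation

Sliding windows of L_w = 80 s advance in steps of L_step = 2 s, anchored
at the epoch start; a tail shorter than L_w is discarded, giving
⌊(T − L_w)/L_step⌋ + 1 windows, each estimate assigned to the window
midpoint. 80 s trades temporal resolution against estimation variance:
at the calibrated activity level a window holds ~2000 non-zero bins, so
the n ≥ 1000 criterion typically passes. Per-window bootstrap is off by
default (an 80 s window holds only four 20 s blocks); variability is
assessed *across* windows via the MAD instead. Both consistency checks
are applied per window; windows where estimation is outright impossible
(e.g. a silent stretch giving zero variance) are recorded as rejected
windows, not errors. A recording with more than 5% inconsistent windows
is flagged `excluded_recording`; its window results are kept for
inspection.

## Cohort statistics

All tests operate on ε, whose distribution is far better behaved than
m̂'s near 1.

* **Hemispheric contrast:** linear mixed model
  `epsilon ~ focus + (1 | patient_id)` (random intercept only, exactly
  the stated structure; no random slopes), fitted by REML via
  statsmodels. Reported p-values use a t-reference with classical
  within-group degrees of freedom, df = n_obs − n_groups − (n_fixed −
  1): the asymptotic Wald z is visibly anticonservative on small
  cohorts (null rejection ~8.5% at α = 0.05 with 4 patients in
  calibration runs; ~5.3% with this correction), and the correction
  converges to z for large cohorts. Per-subregion contrasts use the
  same model per subregion, gated by Bonferroni with the fixed divisor
  4; an interaction model `epsilon ~ focus * subregion + (1 |
  patient_id)` is available through the same interface.
* **Per-patient contrast:** two-sided Mann-Whitney U across that
  patient's recordings (unpaired; each recording contributes one ε per
  hemisphere).
* **Split-half pre-seizure test:** each 10-minute epoch is split into
  halves (odd bin counts: first half gets the extra bin), ε estimated
  per half, and halves compared with the two-sided Wilcoxon signed-rank
  test pairing the halves of the same recording. Zero differences are
  dropped before ranking; the exact null is used for ≤ 25 untied pairs,
  full sign-flip enumeration for ≤ 16 tied pairs, and the tie-corrected
  normal approximation otherwise (verified against brute-force
  enumeration for n ≤ 10).
* **Variability:** per recording, the MAD of the time-resolved ε(t)
  within each half; MADs of first vs second halves compared across
  recordings with the signed-rank test.
* Pairs or observations with undefined ε (supercritical) are dropped
  and counted (`n_dropped`), never silently.

Subset analyses (`all`, `engel1a` for patients seizure-free after
surgery, `paired` for recordings covering both hemispheres
simultaneously) re-run the same battery on the restricted cohort.

## Synthetic cohorts

The generator emulates the statistical structure the clinical analyses
assume: patients × recordings × hemispheres × four MTL subregions, each
subregion an independent branching process at Δt = 4 ms, 600 s epochs
(the first recording per patient is a seizure-free reference, the rest
are pre-seizure), subsampled at α = 0.004 and disaggregated into
per-unit spikes (each sampled event assigned uniformly in time within
its bin and to one of 10 units with Dirichlet(1)-distributed weights, so
single-unit rates are realistically uneven). Defaults m = 0.95, h = 1
put the sampled pooled count at α·h/(1−m) = 0.08 per bin (20 Hz, ~8%
non-zero bins) — within a factor 2 of the clinical medians (25.8 Hz,
9.9% non-zero), which are dataset medians and not matched exactly. A
configuration whose expected rate leaves that factor-2 band is rejected
up front as a calibration error; reduced-size test cohorts therefore
trade α against h to stay in band. Reference epochs share the
pre-seizure baseline m (no systematic reference/pre-seizure difference
is programmed).

Scenarios: `null` (constant m everywhere), `closer_to_critical`
(constant ipsilateral offset, default m_ipsi = 0.98 vs m_contra = 0.95),
`drift` (linear ramp of +0.04 over the final 300 s of ipsilateral
pre-seizure epochs), `variability_increase` (20 s-blockwise jitter of m
in the second half). Generation is fully seed-deterministic and
disaggregation conserves counts exactly.

**What the generator does not emulate:** refractoriness, oscillations,
circadian/medication drifts, electrode drift, correlated subregions,
non-Poisson offspring variance, and clinical seizure-onset uncertainty.
Passing tests therefore validate the inference machinery under the
model's own assumptions, not the clinical claims themselves.

## Problem sizes in tests and the acceptance script

Parameter-recovery and subsampling-invariance checks use 100 × 600 s
runs at the reference configuration; the window-validity check pools
sliding-window estimates from 5–20 subsampled traces; statistical
calibration uses 500 null cohorts of 4 patients × 2 recordings with
60 s epochs at m = 0.9, α = 0.05 (rate structure in the calibrated
band, small enough for 500 end-to-end replicates); power checks use 12
replicates each of a closer-to-critical cohort (m 0.98 vs 0.95) and a
drift cohort (+0.06 over the final 120 s of 240 s epochs). These sizes
were chosen so the full suite runs in a few minutes on one CPU while
keeping every check a genuine end-to-end computation.

## Known limitations

* The MR estimator assumes a stationary autoregressive structure within
  the analysis window; strong non-stationarity inflates D or fails the
  linearity check rather than being modeled.
* Very close to criticality (τ ≫ fit range) the exponential/linear
  discrimination loses power and the exclusion rule can bias against
  near-critical windows; this is inherent to finite lag ranges.
* MixedLM offers no Satterthwaite degrees of freedom; the within-group
  df correction is a classical approximation, exact only for balanced
  designs.
* The bootstrap treats 20 s blocks as exchangeable; with τ ~ 0.1 s the
  residual block-to-block dependence is negligible, but for much larger
  τ the CI would be anticonservative.
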