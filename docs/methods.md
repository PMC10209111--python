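# Methods

`layerphys` quantifies layer-resolved optogenetic electrophysiology and
sensory/affective behavior: it classifies optotagged cortical units,
measures per-unit stimulus modulation in a laser (L) / mechanical (M) /
combined (ML) protocol, runs the population proportion statistics, and
computes the behavioral readouts (von Frey psychometrics, sensitization
AUC, place-preference indices, paw-lift thresholds) plus fiber-optic
irradiance estimates. Everything is exercised end to end on a synthetic
generator with known ground truth.

## Analysis windows

All spike-train quantities use a 1.5 s response window beginning 500 ms
after stimulus onset (the delay discards onset transients and the
mechanical actuator's lag) and a 1.5 s baseline window immediately before
onset. The same windows apply to every condition, laser-only trials
included, so L and ML are directly comparable.

Windows are half-open: baseline is `[onset - 1.5, onset)`, response is
`[onset + 0.5, onset + 2.0)`. This is a package choice made so that every
spike in a trial span belongs to exactly one of {baseline, delay gap,
response, post}; a spike exactly at onset falls in the delay gap. The
partition property is property-tested.

## Response quantities

Per unit and condition, from per-trial aligned spike times:

* **Mean rate** `r = (total count / n_trials) / 1.5 s`, separately for
  baseline and response windows.
* **Modulation index** `MI = (r_stim - r_base) / (r_stim + r_base)`,
  bounded in [-1, 1]; undefined (NaN) when both rates are zero. MI is
  computed from the window-mean rates, not averaged over per-trial MIs.
* **Response probability** RP: fraction of trials with at least one
  response-window spike.
* **Burst probability** BP: spikes preceded by an inter-spike interval
  < 5 ms belong to a burst; runs of such spikes form one burst event and
  isolated spikes form single events. `BP = bursts / (bursts + singles)`,
  pooled over response windows across trials; ISIs never bridge trials.
  Units are called bursty when BP > 0.1 (strict), tonic otherwise. The
  per-unit ranking by BP is insensitive to moving the cutoff from 5 to
  10 ms (Spearman >= 0.9 on synthetic populations, checked in the
  acceptance suite).
* **ISI distributions**: per-unit empirical CDFs of within-trial
  response-window ISIs on a 1 ms grid (default 500 bins), summarized
  across units by the per-bin median. A 1e-6 ms tolerance is added at bin
  edges so ISIs nominally equal to an edge are counted in that bin.

## Modulation inference

A unit counts as modulated in a condition if either test is significant
at alpha = 0.05 (no correction across units; per-unit significance counts
are the population readout):

* **Count test** — two-sided Wilcoxon signed-rank on paired per-trial
  baseline vs response counts. Zero differences are dropped, tied
  absolute differences get midranks. For n <= 25 the p-value is exact
  (dynamic programming over the 2^n sign null); above that, a
  tie-corrected normal approximation with continuity correction.
  Two-sided p-values double the smaller tail (capped at 1).
* **Timing test** — a ZETA-style deviation statistic: pool relative spike
  times over the response window, take the empirical CDF minus the
  time-uniform CDF evaluated at the spike times, mean-centre it, and use
  its maximal absolute value. The null is resampled by circularly
  shifting each trial's spikes by independent uniform offsets (default
  250 resamples); p is the empirical tail probability with an add-one
  correction, so the smallest attainable p is 1/251 and the test is
  assumption-free. The published analytic (Gumbel-tail) variant is not
  re-derived; the permutation form is the default because it needs no
  distributional assumption. Null calibration: rejection at alpha = 0.05
  is 0.049 over 1000 homogeneous-Poisson units (the acceptance suite
  recomputes this; the band checked is [0.03, 0.07]).

Direction is *enhanced* / *suppressed* when the count test is significant,
by the sign of the mean count change; units significant only in timing
are *timing_only* and carry a zero count change. The combined decision's
type-I error under a stationary Poisson null is the union of two
alpha = 0.05 tests, ~0.095-0.10 empirically; the test suite checks the
0.10 bound with a one-sided binomial test on the simulated rejection
count rather than a raw point estimate, so sampling noise around the
bound does not produce spurious failures.

## Unit classification

* **QC**: accept units with a refractory-violation fraction (ISIs < 1 ms)
  below 0.5% and an overall rate above 0.1 Hz.
* **Optotagging**: per 10 ms laser pulse, the first-spike latency within
  a 25 ms search window (wide enough for the slowest credible evoked
  spike while keeping background contamination low; a config default). Tagged iff mean latency < 9.5 ms and jitter (sample SD,
  n - 1) below 3 ms for L5 or 2 ms for L6-CT populations, with at least
  half the pulses evoking a spike (the 0.5 responsive-fraction floor is a
  package default, config-exposed). Sensitivity and specificity are both
  >= 0.95 on planted populations at 40 pulses.
* **Fast-spiking**: waveform peak-to-second-trough latency < 215 us
  (strict); the metric is taken as supplied in cluster metadata —
  computing it from raw waveforms is out of scope. FS units are excluded
  from optotagged sets.
* **Layers**: units are assigned by depth into configured boundary
  intervals. The default table (L2/3 [100, 350), L4 [350, 500),
  L5 [500, 900), L6 [900, 1300) um) is only justified by consistency
  with example unit depths; real use requires histology-derived borders.
* **VPL**: the contiguous channel span from the first to the last channel
  hosting a unit significantly modulated by M or ML; all units on
  channels inside the span are VPL.

## Population statistics

Implemented from first principles with exact small-sample branches, each
validated against full enumeration in the tests (scipy appears only as an
independent cross-check):

* Pearson chi-square homogeneity of proportions across k groups
  (df = k - 1), with the Marascuillo procedure for pairwise comparisons:
  pair (i, j) significant when |p_i - p_j| >
  sqrt(chi2_{1-a, k-1}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j).
  The k - 1 df quantile is the standard form of the procedure.
* McNemar for paired proportions: exact two-sided binomial on the
  discordant counts below 25 discordant pairs, continuity-corrected
  chi-square above (the switch point is a package default).
* Friedman with within-block midranks and tie correction; exact
  permutation p (all within-block orderings) when the enumeration is
  small, chi-square(k - 1) otherwise.
* Mann-Whitney rank-sum, exact by enumeration for m + n <= 20.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
nothing more:

* **Spike trains**: Poisson cluster (Neyman-Scott-like) processes. Event
  onsets are Poisson at the unit's baseline rate, multiplied by the
  per-condition gain inside `[onset + 0.5 s, onset + 5 s)`. Each event
  becomes a burst with probability `burst_prob`, adding a geometric
  number of extra spikes (mean 1.5) at a 2.5 ms intra-burst interval.
  Suppression is gain < 1; no rebound is modelled. A 1.5 ms absolute
  dead time is imposed afterwards, matching the curated-single-unit
  assumption of QC (a pure Poisson train at a few Hz would fail the
  0.5% refractory criterion by construction). Baseline rates are
  lognormal with median 4 Hz and sigma 0.6 — a modelling choice for a
  somatosensory relay population, exposed in config. Default protocol:
  5 s stimuli, 60 s from M to ML onsets and 30 s otherwise, 40
  trials/condition (within the 31-52 range of the study design), plus a
  40-pulse optotagging train. Optotagged units fire one extra spike per
  pulse with the specified reliability at a truncated-normal latency.
* **von Frey**: per-trial Bernoulli withdrawal under a logistic
  psychometric function of log10 force with the ascending stop rule
  (after an all-withdrawal filament, stronger filaments are censored).
  The planted `threshold_g` parameter is defined as the force evoking
  withdrawal in 60% of trials — i.e. a logit(0.6) offset is added to the
  logistic — so the planted value is directly the assay's reported
  threshold and recovery by `threshold_at(level=0.6)` is parameter-
  consistent at any slope. Default slope 3 per decade of force (a
  realistic psychometric steepness for this assay); laser trials divide
  the threshold by `laser_shift` (default 4, the hypersensitivity
  direction). At 50 trials/filament the 60% threshold is recovered with
  a mean relative error of ~13%; the +/-25% recovery check therefore
  holds at typical seeds but is a statistical, not deterministic,
  guarantee.
* **Place sessions**: a paired/neutral/unpaired Markov chain on a fixed
  time step; an occupied chamber is left with probability
  `1 - p_stay`, and the neutral corridor routes to either chamber with
  equal probability. The stationary preference index has the closed form
  `PI = (w_p - w_u)/(w_p + w_u)` with `w = 1/(1 - p_stay)`, used as the
  test oracle. Positions are uniform within the occupied region so the
  occupancy-from-positions path is exercised.

What the generators do *not* emulate: membrane-potential dynamics
(T-type burst biophysics, rebound), anesthesia-state fluctuations, LFP,
drift or unit instability, sensory adaptation, inter-animal correlations
beyond the planted threshold spread. Passing tests therefore demonstrate
correctness of the measurement pipeline under the assumed statistical
structure, not robustness to every failure mode of real recordings.

## Behavior metrics

Censored (untested) filaments are imputed at probability 1.0 — the
conservative continuation, since the stop rule fires only after an
all-withdrawal filament — and flagged so they can be excluded. The 60%
threshold interpolates on log10(force) between the bracketing filaments
(the filament series is approximately geometric). The sensitization AUC
is the trapezoid rule over the *linear* force axis (probability x grams),
with config switches for a log axis and range normalization since the
axis convention is not standardized. The preference index is
`(t_paired - t_unpaired)/(t_paired + t_unpaired)`; neutral-corridor time
cancels. The paw-lift threshold is the highest laser intensity with zero
lifts across its trials (flagged when none qualifies).

## Optics

Tip irradiance is `P / (pi r^2)`. Published worked-example values
(318.18 mW/mm^2 for 10 mW from a 100 um, NA 0.39 fiber) correspond to
pi ~ 22/7; the implementation uses true pi, a discrepancy below 0.05%.
Depth attenuation uses the standard geometric-spread-plus-scattering
transmission `T(z) = rho^2 / ((S z + 1)(z + rho)^2)` with
`rho = r sqrt((n/NA)^2 - 1)`, defaults n = 1.36 and S = 11.2 /mm (the
commonly used mouse-cortex calculator values, config-exposed). Because
the exact parameter set behind literature depth values is not published,
at-depth numbers are reported but are not treated as reference values.

## Problem sizes and numerical choices

Simulated problem sizes used in the tests and acceptance script — 200
units x 40 trials/condition for recovery, 1000 units for null
calibration, 250 resamples for the timing null, 500 windows for BP
recovery, 50 trials/filament for threshold recovery — are the package's
chosen operating points: large enough that the statistical guarantees
quoted above are sharp, small enough to run interactively. All
randomness flows from a single seed through spawned, per-stage
`SeedSequence` streams, so unit order and stage order do not affect
results and identical config + seed reproduces result tables
byte-for-byte. Degenerate inputs (all-zero differences, zero discordant
pairs, empty event groups, silent units) return flagged neutral values
(p = 1, NaN metrics, warnings) rather than raising, except where the
input violates a precondition.

## Known limitations

* The timing test evaluates deviation at spike times of the pooled train
  only (no temporal interpolation) and offers no analytic tail; with 250
  resamples the smallest p is ~0.004.
* BP conflates genuinely clustered events with chance coincidences
  closer than the cutoff; at event rates above ~10 Hz this inflates BP
  by a few percent (visible as a small positive bias in recovery at high
  planted gains).
* The chi-square homogeneity test is asymptotic; at small expected
  counts the exact conditional test should be preferred (the
  implementation refuses zero expected counts outright).
* Layer assignment is purely depth-interval lookup; probe geometry
  corrections and histological registration are upstream of this
  package.
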