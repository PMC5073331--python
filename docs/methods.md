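# Methods

`meanet` analyzes spontaneous activity of cultured cortical networks
recorded on micro-electrode arrays (MEAs): 60 extracellular electrodes
sampled at 10 kHz for 20 minutes, at culture ages (days in vitro, DIV) 10,
13, 15 and 17, in two conditions (control vs EHMT1-deficient). This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Spike detection

Raw voltage is high-pass filtered (6th-order Butterworth, 300 Hz cutoff)
and offset-corrected per channel. Filtering is applied forward-backward
(zero phase) so spike times carry no group-delay bias; the filter's phase
handling is otherwise unconstrained by the acquisition chain. Offset
correction subtracts the per-channel *median* of the signal, which centers
it at zero; subtracting the median of the *absolute* value (available as a
switch, `offset_operand="abs_median"`) does not center an already
zero-mean trace and is retained only for comparison. The detection
threshold per channel is

    theta_ap = f * median(|signal|) * 1.5,   f = 8.

For Gaussian noise, median(|x|) = 0.6745 sd, so theta_ap ~ 8.1 sd — a
conservative peak-to-peak criterion. A spike is registered at each local
minimum whose surrounding peak-to-peak excursion (1 ms window) exceeds
theta_ap; candidates closer than a 2 ms dead time are pruned greedily,
deepest trough first, which makes detection counts monotone in the
threshold. The peak-to-peak window and dead time are not fixed by the
threshold formula; the defaults match typical extracellular spike widths
and are exposed as parameters. The threshold is computed on the whole
recording (not blockwise). Active electrodes fire strictly above
0.1 spikes/s; electrodes above a 100 Hz ceiling are discarded as noisy.

## Network bursts

Spikes on the active electrodes are summed into a spike-density trace:
each spike contributes a unit-amplitude Gaussian (A = 1, sigma = 50 ms),
evaluated on a 1 ms grid (two orders of magnitude below sigma, so crossing
discretization is negligible) with the kernel truncated at +-5 sigma
(truncation error < 1e-6 of kernel mass). A network burst runs from an
upward crossing of the detection threshold to the fall back below it, with
sub-bin crossing times by linear interpolation. The nominal threshold of
10 (kernel-sum units, ~10 near-coincident spike-equivalents) is referenced
to 60 active channels and scaled proportionally with the actual active
count (`10 * n_active / 60`, switchable to fixed), keeping per-electrode
sensitivity constant as cultures recruit electrodes during development.
Burst size is the density area over the burst divided by the single-spike
kernel area (A sigma sqrt(2 pi)); burst duration is offset minus onset; the
interburst interval (IBI) is the quiescent gap from offset to the next
onset (onset-to-onset is available as an option). A burst already in
progress at either recording edge has no complete onset/offset pair and is
discarded.

Because the Gaussian kernel is non-causal, detected onsets lead the first
burst spikes by an amount that grows with burst amplitude relative to
threshold (up to ~1 sigma for very strong bursts). Onset accuracy is
therefore validated with moderate-amplitude bursts, where the crossing
stays within ~35 ms of the planted onset; all interval-based statistics
are unaffected because the lead is common to all bursts of a recording.

In parallel, a two-step inter-spike-interval rule labels spikes background
vs burst-candidate: step 1 marks a spike background when both its
within-electrode pre- and post-ISIs exceed theta_1 = 100 ms (a missing
edge ISI counts as infinite); step 2 pools the survivors of all electrodes
into one train and marks spikes background when both pooled ISIs exceed
theta_2 = 5 ms. The density trace is built from *all* spikes on active
electrodes; the labels feed only the background/burst percentage (the
window-based percentage is reported alongside).

## Per-recording metrics

* MFR: total spike count on active electrodes / duration / number of
  electrodes active at the final DIV (so developmental recruitment does
  not masquerade as a rate change); falls back to the current active count
  when the final-DIV reference is unknown.
* Burst rate (per minute), mean burst duration, size and IBI.
* CV_ISI: per-electrode SD/mean of inter-spike intervals, averaged over
  active electrodes.
* Fano factor: variance/mean of spike counts in 5 s windows slid by 1 s,
  per electrode, averaged over active electrodes. The overlapping windows
  correlate neighboring counts; tolerances in the calibration tests are
  widened accordingly rather than changing the definition.
* CV_IBI and IR, the rate-independent burst irregularity
  IR = mean |ln(IBI_{i+1}/IBI_i)|. Natural log; condition contrasts are
  invariant to the log base up to a global constant. IR is exactly
  invariant under uniform time rescaling; it is 0 for periodic bursting
  and 2 ln 2 for iid exponential IBIs (the log-ratio of iid exponentials
  is standard logistic). Sample (n-1) standard deviations are used in
  every CV; with tens of bursts per recording the n-denominator bias would
  not be negligible.
* Autocovariance half-width, below.

Metrics with fewer than the required observations (e.g. < 2 IBIs) are
missing (NaN), never zero.

## Autocovariance

Per electrode, the spike train is binned at 1 ms and

    C_xx(tau) = sum_n (x_n - mu_x)(x_{n+tau} - mu_x) / (T - |tau|)

is evaluated for 0 < |tau| < 2 s, i.e. the biased estimator normalized by
the recording length adjusted by the lag. The accumulation is done by
histogramming spike-pair bin separations with exact edge corrections —
algebraically identical to the direct binned sum (verified against a
brute-force implementation) at O(pairs) cost. The 1 ms lag bin sits well
inside the 5 ms moving-average smoothing applied across tau. The zero-lag
bin holds the binned variance — a delta that the lag restriction excludes;
it is bridged by neighbor interpolation before smoothing so that the
moving average does not smear it into the neighboring lags (the raw value
is kept separately). Smoothed per-electrode curves are averaged over the
active electrodes, the average is peak-normalized to 1 per recording
(idempotent and scale-invariant), and the half-width is the full width at
half maximum around the global off-zero peak, with linear interpolation at
the crossings; a curve that never falls below half maximum within the lag
range returns the full 4 s range with a saturation flag. Excluding the
zero-lag bin can place the found peak one bin off a true apex at tau = 0,
costing up to one bin of width — irrelevant for the relative comparisons
the statistic feeds.

## Group statistics

Per-culture metric vectors are frequently non-normal (Jarque–Bera screen,
chi-squared(2) reference, recorded per group); group differences at each
DIV are therefore tested with the two-sided Mann–Whitney rank-sum test
(exact enumeration when the pooled sample is <= 12 and tie-free, normal
approximation with tie and continuity corrections otherwise). Raw
p-values are pooled per DIV into one family and adjusted with the
Benjamini–Yekutieli step-up procedure, which is valid under arbitrary
dependence between the metrics — the metrics of one recording are strongly
dependent (burst rate and IBI are near-reciprocal). A q-value estimator
with data-driven lambda selection was considered and rejected: with ~10
p-values per family the null-proportion estimate is unstable. Adjusted
p-values are additionally clipped from below by the raw p-value, so the
correction can never increase significance; Benjamini–Hochberg is
available as an option. Significance is adjusted p < 0.05. Families are
partitioned strictly by DIV: adjusting one DIV never alters another.

## The synthetic-culture generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for every planted feature:

* Background firing: homogeneous Poisson per electrode.
* Network bursts: onsets follow a gamma renewal process parametrized by
  the IBI mean and CV (shape = 1/CV^2, scale = mean * CV^2), giving
  independent control of burst rate and burst-timing irregularity. Each
  burst recruits each electrode independently (participation probability);
  recruited electrodes fire a Poisson-count volley positioned by a
  rise-and-fall gamma envelope (shape 2, mean at half the burst span;
  a uniform envelope is available). Burst spans are gamma (CV 0.2).
  Bursts running past the recording end are truncated and flagged.
* Raw voltage (optional): each spike rendered as a biphasic template
  (sharp ~0.1 ms negative deflection, slower 40% positive rebound) scaled
  to the requested negative-peak amplitude, added to Gaussian noise;
  overlapping templates superpose additively.
* Longitudinal design: each culture keeps a lognormal activity factor
  (CV 0.3) shared across DIVs, scaling its background rate and burst rate,
  so cultures differ persistently as real dishes do; per-(culture, DIV)
  child seeds are derived from the master seed via `SeedSequence`, making
  any single recording reproducible in isolation.

Condition presets encode the developmental fingerprint: control cultures
ramp from sparse, weakly coordinated firing at DIV 10 to stationary
bursting by DIV 15; the deficient presets reduce background firing by 18%
and the burst rate by 40% at DIV 13 with 24% longer bursts, recover by
DIV 15, and at DIV 17 raise the IBI CV (0.65 vs 0.40) while leaving rates
unchanged. Only the direction and approximate relative size of the
condition contrasts are calibrated; absolute firing rates are the
package's own choice of realistic values (background 0.15–0.3 Hz per
electrode, well below the burst-detection threshold). Two consequences
are worth stating plainly: (i) because burst spikes dominate the spike
budget, the 40% burst-rate reduction drags the simulated MFR contrast at
DIV 13 to roughly −30%, larger than the −18% background multiplier alone;
(ii) burst rate and mean IBI are mechanically near-reciprocal in a renewal
model, so their contrasts cannot be set independently.

What the generator does **not** emulate: electrode spatial structure and
burst propagation, refractoriness and spike-sorting ambiguity, electrode
drift and noise nonstationarity, within-burst rate oscillations, and any
biophysics. Passing tests therefore establish that the pipeline recovers
the statistics of data with this generative structure — not that it is
robust to every pathology of real MEA recordings.

## Problem sizes and numerical tolerances

Calibration and recovery experiments use 20-minute recordings (the study's
duration) wherever a single recording is analyzed; the repeated-study
experiments (statistical power of the DIV 13 burst-rate contrast over 100
replicates; the null false-positive-rate check over 200 replicates) use
10-minute recordings and metric-level null draws respectively — the
package's choice of benchmark sizes, with sampling tolerances set from the
analytic or Monte-Carlo spread at those sizes (e.g. Fano factor 1 +- 0.15
for Poisson trains reflects the overlapping-window correlation; CV_ISI
1 +- 0.01 is the 60-electrode average). Monte-Carlo assertions use fixed
seeds. Degenerate inputs are defined, not patched over: all-zero channels
are dead (threshold 0), burstless recordings have missing burst metrics,
empty trains are rejected where a statistic is undefined.

## Known limitations

* Gaussian-kernel burst onsets lead the true onset for very strong bursts
  (above); absolute onset times should not be compared across recordings
  with very different burst amplitudes.
* The peak-to-peak detector does not resolve overlapping spikes closer
  than the dead time, and no spike sorting is attempted.
* With ~10 p-values per family the Jarque–Bera screen and the exact
  Mann–Whitney enumeration operate at small n; the screen is recorded but
  does not gate the rank-sum test.
* Very high background rates (several Hz per electrode on 60 electrodes)
  push the density baseline toward the 10-unit threshold and produce
  occasional background-coincidence bursts; the threshold's scaling switch
  does not remove this regime.
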