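# meanet

Analysis of spontaneous network activity in developing cortical cultures
recorded on micro-electrode arrays (MEAs), for electrophysiologists
studying how a genetic perturbation shifts the maturation of network
dynamics. The package covers the full chain — extracellular spike
detection, network-burst detection and metrics, spike/burst irregularity
statistics, spike-train autocovariance, and the two-condition,
per-developmental-age statistical comparison — together with a
synthetic-culture generator that plants known ground truth, so every stage
is testable without any recordings.

## The methods in brief

**Spike detection.** Per channel, after a zero-phase 6th-order Butterworth
high-pass at 300 Hz and median offset correction, spikes are events whose
local peak-to-peak excursion exceeds

```
theta_ap = f * median(|signal|) * 1.5        (gain factor f = 8)
```

Electrodes firing > 0.1 spikes/s are *active*; MFR divides the total
active-electrode spike count by the recording length and by the number of
active electrodes at the final recording age (DIV 17).

**Network bursts.** All spikes on active electrodes are convolved with a
unit Gaussian (sigma = 50 ms) into a spike-density trace; a network burst
runs from where the density crosses 10 (referenced to 60 active channels,
scaled proportionally with the active count) upward until it falls back
below. Burst size is the density area over the burst divided by the
single-spike kernel area; the IBI is the gap between consecutive bursts.
A two-step ISI rule (theta_1 = 100 ms per electrode, theta_2 = 5 ms on
the pooled train) separates background from burst spikes.

**Irregularity.** CV of the inter-spike intervals, Fano factor of spike
counts in sliding 5 s windows (1 s step), CV of the IBIs, and the
rate-independent IR = mean |ln(IBI_{i+1}/IBI_i)| (0 when bursting is
periodic, 2 ln 2 for Poisson bursting).

**Synchrony.** Per-electrode spike-train autocovariance
C_xx(tau) for 0 < |tau| < 2 s, normalized by (T − |tau|), smoothed with a
5 ms moving average, averaged over electrodes, peak-normalized; the
reported statistic is the full width at half maximum.

**Statistics.** Per DIV, two-sided Mann–Whitney tests per metric
(Jarque–Bera normality screen recorded), Benjamini–Yekutieli FDR within
each DIV's metric family, capped so the correction never increases
significance; the output is a metric × DIV "fingerprint" of directions
and significance stars.

## Worked example

```python
import meanet as mn
from meanet.pipeline import analyze_study
from meanet.stats import metrics_to_table, fingerprint_table

recs = mn.simulate_study(mn.default_presets(),
                         {"control": 6, "deficient": 5}, seed=7)
table = metrics_to_table(analyze_study(recs))
print(table.groupby(["div", "condition"])[["burst_rate", "mean_ibi"]]
      .mean().round(2))
print(fingerprint_table(mn.compare_study(table)))
```

prints (burst rate in bursts/min, IBI in s)

```
               burst_rate  mean_ibi
div condition
10  control          1.27     53.01
    deficient        1.08     54.83
13  control          4.73     13.06
    deficient        2.59     22.19
15  control          7.01      8.66
    deficient        6.04      9.30
17  control          7.09      8.53
    deficient        6.29      8.90

                      10  13  15  17
mfr                   ns  ns  ns  ns
burst_rate            ns  -*  ns  ns
pct_spikes_in_bursts  ns  -*  ns  ns
mean_burst_duration   ns  +*  ns  ns
mean_burst_size       ns  ns  ns  ns
mean_ibi              ns  +*  ns  ns
cv_isi                ns  -*  ns  ns
fano_factor           ns  ns  ns  ns
cv_ibi                ns  ns  ns  ns
ir                    ns  ns  ns  ns
autocov_half_width    ns  +*  ns  ns
```

— the deficient cultures burst at roughly 60% of the control rate at
DIV 13 with correspondingly longer interburst intervals, longer bursts and
a wider autocovariance peak, and the difference closes again by DIV 15:
the transient early-development deficit, summarized exactly the way the
fingerprint table reads. (At these small group sizes the late
irregularity increase at DIV 17 is visible in the means but not yet
significant; it is at the full design size of 25 vs 19.)

The same pipeline runs from the shell:

```
meanet simulate --out culture.csv --seed 1 --raw-out culture.h5
meanet detect culture.h5 --out detected.csv
meanet analyze detected.csv --out metrics.csv
meanet run-all --out-dir study_out --seed 1
```

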