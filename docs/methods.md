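# Methods

This note documents the models, conventions and numerical choices behind
`septorhythm`, in the order data flows through the package.

## Units and conventions

Time is seconds as 64-bit floats everywhere in memory; milliseconds appear
only in reported burst metrics, matching the summary-table conventions.
Oscillation phase is in degrees with the **trough at 0° (= 360°) and the
peak at 180°**, fixed package-wide. Angles are converted to radians only
inside resultant-vector arithmetic. Sample standard deviations use the n−1
denominator.

### Quantiles

All reported IQRs use the quantile at position h = n·p + 1/2 with linear
interpolation between order statistics. For even n this equals the Tukey
hinges (median of each half); for odd n it interpolates a quarter of the
way between the bracketing order statistics. This single convention
reproduces every group IQR in the packaged reference tables for both even
(n = 16) and odd (n = 13, 15) group sizes, which the plain Tukey-hinge rule
does not; it is also the default quartile rule of the numerical environment
the original tables were produced in.

## Behavioral segmentation

Speed comes from a quadrature-encoder tick counter: 2000 edges per
revolution of a 146 mm cylinder, differentiated on a 10 ms grid
(speed = Δticks/2000 · π · 0.146 m / 0.01 s). A calibrated analog channel
maps 1 V to 0.6912 m/s. The movement flag is a latch — raised when the
counter gains ≥ 2 ticks over 10 ms, dropped when it gains < 11 ticks over
50 ms — mirroring the acquisition-side logic, so segmentation can be
replayed identically offline.

The four states are assigned exhaustively and mutually exclusively:
locomotion (LM) is a movement-flag run longer than `lm_min_duration`
(default 1 s) with mean speed ≥ `lm_speed_threshold` (default 1 cm/s); any
other flag run is small movements (SM); whisk-channel activity without
movement is WS; the remainder is immobility (IM). The original
classification was partly video-based and qualitative; the two numeric LM
parameters are this package's choice, made once for reproducibility, and
both are exposed in the configuration and the CLI.

## Oscillation detectors

All filters are zero-phase forward–backward Butterworth (`sosfiltfilt`),
order 4 for theta/delta and gamma, order 6 for the ripple band, with
reflective padding of three periods of the band's low edge to suppress edge
transients. Trough detection takes local minima of the band-passed trace
separated by at least half the band's shortest period, refined to
sub-sample precision by parabolic interpolation; on noiseless sinusoids,
interior trough times deviate by well under one sample from the analytic
positions (the outermost cycle on each end remains perturbed by the
filter's reflective padding and is excluded from such comparisons).

- **Theta epochs**: theta (5–12 Hz) and delta (2–4 Hz) power as 1 s moving
  averages of the squared filtered trace; samples with ratio ≥ 2 are
  theta. Epochs are closed morphologically (gaps < 0.5 s absorbed, both
  polarities). Threshold and windows are configurable.
- **Theta phase**: linear interpolation from 0° to 360° between successive
  filtered-trace troughs; times before the first or after the last trough
  carry no phase.
- **Mid-gamma troughs** (55–80 Hz): the cycle amplitude is the refined
  peak-to-trough difference within each trough-to-trough span. A cycle is
  supra-threshold when its amplitude strictly exceeds the mean + 1 s.d. of
  cycle amplitudes; cycles inside a five-period margin of the trace edges
  are excluded from the statistics. If the amplitude distribution is
  essentially constant (coefficient of variation < 1%), no cycle is
  reported — the s.d. → 0 degenerate case up to numerical residue.
- **SWRs**: "power" is the squared magnitude of the analytic (Hilbert)
  envelope of the 130–230 Hz filtered trace, smoothed with a 10 ms moving
  average (the underlying report does not pin down envelope vs. squared
  envelope vs. RMS; the squared envelope is this package's choice and the
  threshold scales accordingly). Segments above mean + 4 s.d. seed events;
  windows extend outward until power falls back to the mean and merge when
  they touch. The event time is the power maximum in the window.
- **LIA cycles**: 0.08 s moving-average smoothing, DC removal by
  subtracting a 0.2 s moving average, falling zero-crossings thinned to a
  minimum spacing of 0.2 s (earlier crossing kept).

## Spike-train metrics

A burst is a **maximal** run of at least `min_burst_spikes` consecutive
spikes whose ISIs are all < 40 ms. The published criterion "> 3 spikes" is
read literally as ≥ 4 (the literature is split; 3 is one configuration
switch away). Rates and burst incidence are means over non-overlapping 1 s
windows anchored at each epoch start, trailing partial windows dropped;
a state with no complete window is unavailable (never silently 0). Bursts
belong to the state of their first spike; interburst intervals (first spike
to first spike) are measured only between consecutive bursts within the
same epoch, so they never straddle state boundaries. Intraburst frequency
per burst is (n_spikes − 1)/duration — the report prints the quantity
without defining it; this is the natural event-rate estimate. The
autocorrelogram excludes zero-lag self-pairs and finds its rhythmicity peak
as the maximum of 3-bin boxcar-smoothed counts in the 80–250 ms range.

## Circular statistics

Mean phase and mean vector length come from the resultant vector; the
Rayleigh p uses the classical approximation
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)) with R = n·r, which the test
suite checks against an independent implementation and against an empirical
100,000-draw uniform null (agreement within 0.01 for n = 8–500, type-I
error ≤ 5.5% at α = 0.05). Spike–gamma coupling is gated: supra-threshold
gamma troughs must themselves couple significantly to the theta cycle with
a mean phase within ±45° of the theta peak; otherwise the cell is refused
with an explicit status rather than given a meaningless number. Phase
histograms use 20° bins and wrap-around Gaussian smoothing with σ = 1 bin
by default (neither is stated in the source report). The permutation test
on circular group means uses the absolute circular distance between
unweighted group circular means, 10,000 label permutations and the
(b+1)/(m+1) correction.

## SWR firing modulation

Rate inside = spikes in SWR windows / total window duration; λ outside =
rate over the session minus SWR windows minus detected theta epochs. The
Poisson p doubles the smaller tail of Poisson(λ·total window duration),
capped at 1 (two-sided, since both increases and decreases occur). The
shuffle control redraws the same window durations uniformly from the
eligible baseline 1000 times (windows fit inside single eligible intervals,
interval chosen with probability proportional to its fitting length) and
reports the add-one-corrected fraction of draws at least as far from λ as
the observed inside rate. The source material is ambiguous about whether
its printed "Poisson p" is the closed form or the shuffle estimate, so both
are computed; they agree in rejection decision for ≥ 90% of calibrated
synthetic units. Cells with fewer than 20 SWRs are refused.

## Orchid-cell classification

All four criteria must hold; a missing required field yields an
*unavailable* verdict (never a spurious negative), while any definitely
failing criterion yields a negative. The "around the peak" phase window
defaults to 90°–270°: deliberately wide, because identified peak-coupled
cells sit anywhere from 130° to 264°, and the contrasting trough-firing
class sits near 37°. The window, the r > 0.2, incidence > 3 Hz and
duration > 50 ms cutoffs are all configurable.

## Synthetic sessions

The generator emulates the statistical structure of the recordings, not
their biophysics:

- LFP = state-dependent theta (8 Hz/amplitude 1.0 in LM, down to 5.5 Hz/
  0.15 in IM, exponentially smoothed at state transitions) + 3 Hz delta
  (strongest in WS/IM) + a 65 Hz gamma carrier whose envelope is a
  raised-cosine lobe of the theta phase centered on the peak + band-limited
  (0.5–4 Hz) irregular activity during non-theta states + Hanning-windowed
  160 Hz ripple transients (60 ms, Poisson rate 0.4/s, immobility only) +
  1/f Gaussian noise.
- Spikes: per theta cycle, with probability 0.72 a burst is emitted whose
  center phase is von Mises(μ = 178°, κ); within a burst ISIs start at
  1/160 s and grow 6% per spike (accommodation, hence non-decreasing
  ISIs), and the spike count is 4 + Poisson, scaled so the per-state mean
  rate hits the target (55 Hz LM / 40 Hz IM) in expectation. Because the
  accommodating burst is front-loaded in time, each burst is placed so its
  *circular* mean lands exactly on the drawn phase. A small cycle-skip
  probability (0.05) produces occasional double-length bursts spanning two
  cycles; no rate for this is published, the default is a visible-but-rare
  choice. The resulting burst statistics (incidence ≈ 4–5 Hz, median
  duration ≈ 65–120 ms, intraburst frequency ≈ 100–125 Hz, interburst
  interval ≈ 150/190 ms LM/IM) fall inside the published per-cell ranges.
- Behavior: an encoder counter ticking at locomotion speed during LM, in
  brief sub-second pulses during SM, and a whisk flag during WS.
- Ground truth (theta troughs, high-envelope gamma troughs, ripple
  windows, spike phases, bursts, LIA cycle count) is exact by
  construction. The LIA cycle truth applies the operational cycle
  definition to the noiseless slow component, since "a cycle" of irregular
  activity is only defined through that procedure.

What the generator does **not** emulate: electrode drift, spike-sorting
contamination, movement artifacts, sharp-wave polarity structure,
ripple-frequency chirps, theta harmonics and phase-asymmetric theta
waveforms, or any SWR-locked firing modulation. Passing tests therefore
demonstrate correctness of the analysis chain under the assumed statistical
structure, not robustness to every pathology of real recordings.

Default problem sizes — 300 s sessions at 1 kHz, 3-seed averages for
recovery tests, 10,000 trains for the burst oracle, 2,000 simulations for
SWR test calibration — keep the full suite under a minute of compute while
leaving estimator standard errors well inside the asserted tolerances.

## Packaged reference tables

The per-cell summary tables (8 identified orchid cells, 8 putative orchid
cells, 2 septo-hippocampal cells) ship as TSV transcriptions guarded by
SHA-256 checksums. Censored p-values ("< 0.0001") parse to their printed
upper bound; unavailable entries ("u") parse to NaN and propagate as
explicit missing values. Group aggregates over these rows reproduce the
published group statistics to printed precision, with two benign
exceptions: IQRs whose exact value ends in .x5 (42.75, 61.35, 72.95) print
one unit lower in the source (truncation there), and t statistics
recomputed from rounded table entries differ from the published ones in the
second decimal (3.91 vs 3.93), as expected when the source computed from
unrounded data.

## Known limitations

- Theta-epoch detection and the behavioral segmentation are threshold
  rules; on real data the thresholds interact with electrode placement and
  should be checked per subject.
- The group circular means of preferred phases published for the two cell
  classes are not recomputable from rounded per-cell table values under
  any standard pooling; the package computes unweighted circular means and
  does not claim to reproduce those two printed numbers.
- The shuffle control allows redrawn windows to overlap one another
  (matching windows are rare events in a long baseline); for sessions
  where SWR windows occupy a substantial fraction of eligible time this
  slightly widens the null.
- `read_session` expects the package's TSV session layout; native
  acquisition formats and NWB are out of scope.
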