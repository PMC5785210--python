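# Methods

This note documents the models, algorithms and numerical choices behind
`slicephys`, and what the synthetic-data validation does and does not
establish about real recordings.

## SLE detection

**Drift removal.** Slice ΔF/F recordings drift slowly (perfusion,
focus, photobleaching). The detrender subtracts a rolling
lower-percentile baseline: a centered window of `baseline_window_s`
(default 60 s) slides across the trace and its
`baseline_percentile`-th percentile (default 10) is taken as baseline.
A low percentile tracks the inter-event floor of the signal, so
sustained supra-threshold events — which can last tens of seconds — are
not flattened the way a high-pass filter or running mean would flatten
them. The residual of a pure linear drift is bounded by
slope × (distance from window center to the percentile's location),
about 0.4 × window × slope; with the defaults a 0.2 ΔF/F drift over
30 min leaves < 0.003 residual. Percentile filtering is
scale-equivariant, which the detector's threshold rule relies on.

**Noise estimation.** The per-trace noise SD is
`1.4826 × median(|x − median(x)|)` computed over samples at or below
the trace median. Events push samples upward only, so the lower half
of the distribution is event-free to good approximation; for Gaussian
noise the estimator equals the usual MAD estimate of σ. With 10% of
samples inside large events the estimate stays within 15% of the
event-free value.

**Thresholding and segmentation.** Samples strictly above
`threshold_k × σ̂` (default k = 4) form the event mask. Gaps shorter
than `merge_gap_s` (default 2 s) are merged first, then events shorter
than `min_event_s` (default 1 s) are discarded; without this
post-processing, thresholding 10-Hz noisy data fragments each SLE into
many sub-events. Both constants are parameters and are recorded in
every output. All intervals are half-open `[start, end)` in seconds,
float64, with bin edges anchored at recording start.

**Summaries.** The per-bin fraction is event overlap divided by the
nominal bin width (default 300 s), so `Σ fraction × bin_width` equals
total detected event time exactly, including a truncated final bin.
The plateau percentage (default window 2400–4800 s, when event rates
have stabilized after drug onset at 600 s) is computed from the raw
intervals over the window, not by averaging bins, which avoids
edge-bin bias; a recording that ends inside the window yields a
percentage over the overlap and a `plateau_truncated` flag.

**Zero-noise traces.** A trace whose noise estimate is zero (e.g. an
all-zero region) cannot carry an SNR-scaled threshold; the pipeline
then uses a threshold of exactly 0, so only strictly positive
excursions count. Calling `detect_events` directly with zero noise and
no explicit threshold is an error.

## Imaging

ROI-mean extraction averages pixel intensities over each ROI per
frame. Pixel coordinates are 0-based `(row, col)`; a pixel belongs to
a polygon ROI if its center `(row + 0.5, col + 0.5)` is inside under
the even-odd (crossing-number) rule, matching the ImageJ convention in
which ROIs are commonly drawn. A minimal reader/writer for the ImageJ
`.roi`/`.zip` binary format (polygon, freehand, traced and rectangle
types) is included; JSON polygon lists are the text-based alternative.

ΔF/F is `(F − F0)/F0` with F0 the mean over the pre-drug baseline
window (default the first 600 s); the definition makes the result
invariant to multiplicative gain. 0–1 normalization is the affine map
of min→0, max→1 (used for display, as in normalized trace figures);
it is idempotent and order-preserving. Dropped frames are NaN: they
are excluded from F0 and from normalization extrema, and runs longer
than 1 s are an error (shorter runs are linearly interpolated before
detrending only).

## Ephys analysis

**Slope conductance.** OLS slope of recorded current (pA) versus
commanded voltage (mV) over ramp samples with command in
−120…−90 mV, i.e. nS directly. The ramp is located as the longest
strictly-rising run of the command waveform, so prepulse samples at
−100/−120 mV never enter the fit. No leak subtraction and no
liquid-junction-potential correction are applied. The estimator is
exact on linear I–V data (the capacitive current during a linear ramp
is a constant offset and does not bias the slope) and unbiased under
additive zero-mean noise.

**Input resistance.** `R = ΔV/ΔI` between the −100 and −120 mV
prepulse steps, with each step's current averaged over its last 20 ms —
a late window that avoids the capacitive transient at the step edge.

**Washdown time course.** Per-sweep slope conductances normalized to
the sweep nearest 180 s after break-in (ties to the earlier sweep;
an error if no sweep lies within ±30 s). Nearest-sweep anchoring was
chosen over interpolation to keep the normalizing value a measured
quantity; as a consequence the normalized series is exactly 1 at the
anchor for any input.

**AP counting.** Default rule: upward crossings of 0 mV inside the
half-open pulse window, with a 2-ms refractory so a single spike is
never double-counted. A `dvdt` rule (upward crossings of
dV/dt ≥ 20 mV/ms) is provided as an alternative since published
recordings mark the 0-mV level but counting criteria vary between
labs; the rule used is recorded in every F–I output. A spike
straddling the window boundary counts iff its 0-mV crossing falls
inside the window.

## Synthetic data

**Calcium traces.** `trace = baseline + events + noise`. The baseline
is a slow Gaussian process (white noise low-pass filtered at
`drift_tau`, default 120 s, scaled to `drift_amplitude`, default
0.05 ΔF/F — generated on a coarse grid and interpolated, which is
statistically equivalent and much cheaper) plus an exponential
photobleaching decay (`bleach_amplitude` 0.1 toward an asymptote with
`bleach_tau` 1800 s). SLE start times are an inhomogeneous Poisson
process whose rate rises sigmoidally from drug onset (600 s after
recording start, following a 10-min baseline period) and plateaus by
2400 s at `sle_rate_profile` events/min (default 0.75); event
durations are truncated-normal (20 ± 5 s, ≥ 1 s); events that would
overlap an earlier one are dropped so truth intervals are disjoint.
Each event renders as one transient at onset plus a 5-Hz Poisson train
of transients, each a difference of exponentials (rise 0.05 s, decay
0.4 s, peak-normalized) with amplitude 0.5 × U(0.8, 1) ΔF/F, so the
envelope stays elevated throughout the event — SLEs are sustained
epochs, not single transients. Gaussian noise SD defaults to
0.02 ΔF/F, giving event SNR ≈ 20 at the default amplitude.
`forced_events` inserts deterministic ground-truth intervals for
controlled tests. GCaMP6f kinetics and SLE duration statistics are not
published for this preparation numerically; these defaults are
plausible placeholders, fully configurable, not estimates of any
particular dataset.

**Ramp recordings.** A passive membrane: `I = g_leak(V − E_leak) +
g_KATP(t)(V − E_K) + C dV/dt + noise`, with the K_ATP conductance a
single exponential in time from break-in — washdown
`g₀·e^(−t/τ)` (default 3 nS, τ = 60 s: channels closing as high-ATP
pipette solution dialyzes in), run-up `g_inf·(1 − e^(−t/τ))`
(disinhibition as ATP washes out), or constant. A single exponential
is the simplest monotone form consistent with conductance decaying
over the first minutes of recording; it is a parameterized choice, not
a fitted model. The conductance is frozen at its sweep-start value
within each sweep, so the truth function is exact for any within-sweep
fit; the capacitive current uses the piecewise-analytic command
derivative so it is constant within the ramp. Capacitance defaults to
35 pF (the 30–40 pF range of the targeted cell population).

**Current clamp.** A leaky integrate-and-fire (LIF) neuron —
`C dV/dt = −g_L(V−E_L) − g_K(V−E_K) + I_hold + I_inj`, threshold −50 mV,
reset −62 mV — chosen over a conductance-based model because the LIF
has closed-form inter-spike intervals, giving an independent oracle
for every spike count. The `refractory_ms` default of 35 ms lumps the
absolute refractory period with after-hyperpolarization recovery so
firing rates stay in a physiological range (the LIF has no adaptation
mechanism). Integration uses the exact exponential update for
piecewise-constant drive and solves each threshold crossing in
continuous time, so noiseless simulated spike times equal the closed
form to machine precision. Spikes are rendered with a stereotyped
waveform whose peak sample sits at `floor(t_spike × rate)`, so the
0-mV upward crossing falls at (within one sample before) the true
spike time and amplitude- and slope-based counters both see every
spike at its true time, including spikes at the pulse-window boundary.
The holding current is whatever holds the cell at −70 mV and stays
below 30 pA for K_ATP leaks up to 1.5 nS. An added K_ATP leak raises
rheobase strongly but, lacking adaptation, compresses the F–I curve
only modestly at high drive.

All generator randomness flows from a single integer seed per call;
equal configs give bit-identical outputs.

## Statistics

Student's equal-variance t-test is the default two-group test (Welch
behind a flag); one-way ANOVA with Bonferroni-corrected pairwise
equal-variance t-tests (adjusted p = min(1, p × n_pairs)) for three or
more groups, and the two-group ANOVA satisfies F = t² exactly.
Normality is assumed rather than tested; `distribution_diagnostics`
reports skew and kurtosis but never changes which test runs. SEM uses
the n−1 sample SD. Boxplots: median, 25th/75th percentiles (linear
interpolation), whiskers to the furthest point within 1.5×IQR of the
box, points beyond drawn as outliers, and a 95% CI of the median by
the ±1.57×IQR/√n notch convention. Identical constant groups are
reported as no-evidence (t = 0 or F = 0, p = 1) rather than an error;
zero pooled variance with unequal means is an error.

## The demo experiment and what validation shows

The demo programs a knockout group whose plateau SLE rate is half the
wild-type rate (0.375 vs 0.75 events/min, n = 8 slices per group,
80-min traces). Because overlapping candidate events are thinned,
halving the rate reduces plateau occupancy by slightly under half
(≈ 45% relative); the detected and ground-truth reductions are
compared directly, so this nonlinearity is accounted for rather than
assumed away. Validation sizes: 30-sweep ramp recordings (100 for the
noisy-recovery check), 20 parameter sets for the F–I oracle, 10 + 10
traces for detector recovery and specificity, 50 randomized traces for
the detector property checks, 2000 replicates for the ANOVA null
calibration, and 300 replicated experiments for the power analysis —
sizes at which every Monte-Carlo margin is comfortably resolved.

Passing these checks shows the pipeline recovers what its generative
model produces. The generators deliberately omit several features of
real data: motion and focus drift beyond smooth baselines,
non-Gaussian shot noise, inter-region correlation and propagation of
SLEs across the slice, GCaMP saturation and indicator nonlinearity,
seal/access-resistance drift in ephys recordings, and spike-frequency
adaptation. Results on real recordings therefore depend on parameter
choices (notably `threshold_k` and the detrend window) in ways the
synthetic validation cannot fully certify; the per-run provenance logs
exist so those choices are always recorded.

## Known limitations

- The detector reports occupancy, not event counts or propagation
  order between regions; cross-region latency analysis is out of scope.
- The rolling-percentile detrend assumes events occupy well under the
  baseline percentile's complement within any window; near-continuous
  seizure activity (status-like recordings) would depress the baseline
  and bias occupancy downward.
- The LIF closed form holds only for the noiseless model; with
  injected current noise, spike counts are stochastic and only their
  ordering properties are asserted.
- ImageJ ROI support covers polygon-like and rectangular ROIs only
  (no ovals, lines or composite ROIs).
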