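# Methods

This note documents the models, conventions and numerical choices behind
each pipeline, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the underlying procedures were open.

## Synthetic data: the stated world

**Calcium movies.** Cells are points placed uniformly in the field of view
with a 5-pixel minimum separation (somata do not overlap); each renders as
a 2-pixel-radius disk. Connectivity is Erdős–Rényi with configurable mean
degree (default 4) and per-edge conduction delays uniform in 0.2–0.8 s.
The stimulated cell is the one nearest the field centre. Activation
propagates deterministically: cell *j* activates at
`pulse_time + shortest_path_delay(stimulated → j)` (Dijkstra over edge
delays); unreachable cells stay silent, and an optional per-cell
activation probability provides negative-control fixtures. Each activation
emits one transient: a difference-of-exponentials kernel with rise 0.1 s
and decay 1.5 s (the slow transients typical of hiPSC-derived neurons),
unit-normalized and scaled by an amplitude (default 10 fluorescence units
on a baseline of 100). Noise is additive i.i.d. Gaussian. Movies default
to 30 fps, within the 30–50 fps acquisition regime the pipelines target.

**MEA recordings.** Per-electrode spikes are an inhomogeneous Poisson
process realized by thinning: baseline rate (default 1 Hz) everywhere,
multiplied by `evoked_multiplier` inside
`[pulse + latency_mean − jitter, pulse + latency_mean + jitter +
response_span]` on responding electrodes, with a 2.5-ms absolute
refractory. Defaults: latency 12.5 ± 7.5 ms (responses begin 5–20 ms after
the pulse) and `response_span = 0.8 s`. The long span encodes sustained
network reverberation after each pulse — at a 1-Hz pulse rate the elevated
windows cover ~88 % of the stimulation epoch, which is what makes a
windowed mean-firing-rate fold change of ~2.3 (at multiplier 3 on 12/16
electrodes) physically possible; a response confined to the 10-ms pulse
would move the windowed MFR by only ~5 %. Traces are Gaussian noise
(default 5 µV SD) plus a biphasic (negative-then-positive) 1-ms,
50-µV template at each spike time.

**What the generators do not emulate** — and hence what a green test does
not establish: photon shot noise, bleaching, motion, overlapping somata and
neuropil contamination in imaging; electrode drift, correlated noise, LFP
leakage into the spike band, multi-unit amplitude distributions and
synaptic failure in MEA data. Detector performance numbers measured here
are upper bounds relative to real recordings.

## Calcium pipeline

**SVD denoising.** The movie is flattened to frames × pixels, mean-centred,
and reconstructed from the top *k* singular modes. `rank="auto"` takes the
elbow of the singular-value spectrum (largest ratio between consecutive
values); the full spectrum is exposed (`singular_values_`) so users can
override. The Eckart–Young identity (residual = root-sum-square of the
discarded singular values) is asserted in tests to 1e-6.

**Active pixels.** A pixel is retained when its temporal max − min range
reaches the threshold; `"auto"` is Otsu's split of the range image.

**Phase-based spike detection.** The trace is smoothed with a centred
5-frame moving average (shrinking windows at the edges), locally detrended
by subtracting an 11-frame moving-average baseline, and the instantaneous
phase is the argument of the analytic signal (FFT Hilbert transform),
wrapped to (−π, π]. Transient rises begin at a trough of the detrended
signal, where the wrapped phase attains a local minimum; event times are
those minima. Two gates decide which minima are events: the phase
prominence (default π/2) and — decisive in practice — a following
smoothed-trace peak with fluorescence prominence ≥ 5 robust noise SDs
(noise SD from the median absolute first difference, |Δx|-median/0.6745√2).
The amplitude gate is necessary because wrapped-phase prominences saturate
near 2π for any full phase rotation, so phase prominence alone cannot
separate transients from noise; a global-mean-subtraction variant was also
rejected because, on sparse transients over a flat baseline, the phase
minimum sits at the Hilbert-tail zero crossing seconds away from the
onset. With the implemented convention, noiseless onsets are localized to
−1 frame and Monte-Carlo recall/precision at 5 % noise is ≈ 0.98.

**Evoked event and activation maps.** The stimulus-evoked event is the
detected event with the largest fluorescence prominence (for the
single-transient pixels of a propagating wave this is the only event).
T(x, y) = evoked time − stimulus time; pixels without a clear event are
NaN. Latencies up to 2 frames *before* the stimulus are clamped to zero
(detection resolves onsets only to ~1 frame; the stimulated cell itself
would otherwise vanish from the map); earlier events are rejected and
counted.

**Mixture decomposition.** Activation times are fitted with univariate
Gaussian mixtures by EM (scikit-learn), 10 restarts per candidate
component count, best k by BIC, means reported ascending. Requires
≥ max(10, 2·max k) samples.

**Correlations.** Spearman matrices are Pearson correlations of average
ranks; constant traces give NaN rows/columns rather than spurious zeros.

## MEA pipeline

**Filters.** Band-pass 200–3000 Hz and LFP low-pass 500 Hz are 4th-order
Butterworth applied forward–backward (zero phase); LFP is decimated to
1 kHz after filtering.

**Spike detection.** Noise SD is estimated robustly (median(|x|)/0.6745)
over rolling 10-s blocks; events are negative peaks below −k·SD with a
2.16-ms first-peak-wins holdoff. The analysis path uses k = 5.5 on the
filtered trace. The closed-loop path (k = 3) references the *raw* trace's
noise SD instead: at 3 in-band SDs, band-limited Gaussian noise crosses
the threshold ~13 times per second (Rice's formula), a floor that caps
any measurable rate fold change near 1.15 and would make the trigger
inoperable; 3 SDs of the wide-band noise is ~5.7 in-band SDs at 20 kHz,
which keeps detection clean while honouring the stated multiplier. Both
choices are explicit parameters (`noise_reference`).

**Bursts and network bursts.** Maximal runs with every ISI ≤ 100 ms;
single-channel bursts need ≥ 5 spikes; network bursts are runs of the
pooled, sorted multi-electrode train needing ≥ 10 spikes and participation
of ≥ 25 % of the electrode set. Both are verified against exhaustive
brute-force scanners on thousands of random cases.

**STTC.** The standard tiling formula with dt = 20 ms, tiling windows
merged and clipped to [0, T]; NaN for empty trains or degenerate
denominators. Verified against an independent literal transcription of
the formula.

**Synchrony index.** The exact commercial definition is proprietary; here
the raw index is the fraction of pairwise spike-time differences within
± 20 ms among those within ± 1 s, and the normalized index divides by the
uniform-lag expectation (window/support), so independent Poisson trains
score raw ≈ 0.02, normalized ≈ 1.

**LZC.** Trains are binarized into 1-ms presence/absence bins; c(n) is
the phrase count of the exhaustive-history (LZ76) parsing computed by the
Kaspar–Schuster algorithm and verified against a brute-force substring
parser; LZC = c(n)/n·log₂(n) holds exactly by construction. Published
absolute LZC deltas depend on an unstated binarization and are not
reproduction targets.

**Lag times.** For each pulse, the first detected peak strictly after it
and before the next pulse; NaN otherwise.

**Spike sorting.** Waveform snippets (0.6 ms pre-peak to 1.4 ms
post-peak) are centred, projected on 5 principal components, and k-means
is run for k = 1…10; k is selected by the gap statistic against 20
uniform draws from the PC bounding box using the one-standard-error rule.
Zero-variance inputs short-circuit to k = 1.

## Closed-loop controller

Baseline MFR per electrode is estimated on the trailing pre-stimulation
window (default 30 s). The active set is fixed there by the 5-spikes/min
rule; conditioning the active set on spiking within the evaluated window
was rejected because the conditional mean rate of a Poisson electrode
given ≥ 1 spike is inflated by 1/(1 − e^−λ) (≈ 1.58× at 1 Hz over 1 s),
which fires the trigger on unmodulated activity. The trigger is evaluated
every 1 s (matching the 1-Hz stimulation cadence): true iff the active
set has ≥ 8 electrodes and its mean rate is ≥ 2× its mean baseline rate.
The state machine emits one avoidance command per episode (hysteresis
prevents chattering) and one resume command after the trigger has been
false for a full window following stimulation end. Zero-baseline wells
never trigger. End-to-end latency is whatever one evaluation window
implies; the hardware round-trip figure of a physical deployment is not
modelled.

## Thermometry

ln R vs 1/T is fitted by least squares; E_a = slope × 8.314 J mol⁻¹ K⁻¹,
and R₀ is the fitted value at the reference temperature T₀ (default: the
lowest calibration temperature, i.e. room temperature). Conversion uses
T_i = [1/T₀ − (R/E_a) ln(R₀/R_i)]⁻¹, which is strictly decreasing in R_i
over its domain; the bracketed quantity ≤ 0 raises a domain error.
Calibrations must span ≥ 5 K and contain ≥ 3 points. Kelvin internally;
Celsius helpers at the interface.

## Numerical conventions

Times are seconds from recording start; all windows are half-open
[start, end); pixel coordinates 0-based row-major; electrode ids opaque
strings. All generators take a single integer seed; sub-streams are
derived from it, so identical seeds give bit-identical outputs.

## Known limitations

The phase detector's event times sit ~1 frame before the kernel onset by
construction (trough of the pre-rise dip); at low transient amplitude and
high noise, timing can shift several frames even when detection itself
succeeds. The evoked-response span of real organoids is unknown and
surely variable; the 0.8-s default is a modelling choice, not a
measurement. The synchrony index is this package's definition, not a
reimplementation of any vendor metric. Gap-statistic sorting assumes
roughly isotropic clusters in PC space and will merge strongly
overlapping units.
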