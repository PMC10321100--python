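# Methods

This package analyses epoched EEG around a two-presentation recognition
task: a degraded two-tone image is shown (first stage), a congruent or
incongruent greyscale cue follows, and the same two-tone image returns
(third stage), where congruent-cue/"Yes" trials operationalize sudden
recognition (Aha) and incongruent-cue/"No" trials the matched control
(Ctrl). The analyses quantify how third-stage dynamics differ between
conditions after removing first-stage baselines: band power, pairwise
synchrony, its hemispheric lateralization, and the dimensionality of
multichannel activity. Because suitable public recordings do not exist,
every claim the test suite makes is established on synthetic data with
known ground truth; this note records the models, the defaults and their
rationale, and what the synthetic results do and do not show.

## Trial handling

Condition labels follow the task logic exactly: Aha requires a congruent
cue and a "Yes" response, Ctrl an incongruent cue and a "No" response;
everything else is discarded. Third-stage trials enter analysis only with
reaction time strictly greater than 0.5 s (responses faster than that are
plausibly onset-driven rather than recognition-driven). Before any
condition contrast, the larger group is randomly subsampled, without
replacement and seed-deterministically, to the smaller group's size, so
trial-count bias cannot masquerade as a condition effect. Continuous
recordings are high-pass filtered at 0.3 Hz (4th-order Butterworth) and
notch filtered at 50 Hz (2nd-order IIR, Q = 35), both applied
forward-backward for zero phase; the reflect-padding length is tied to
the high-pass time constant because the default padding lets 0.3-Hz edge
transients corrupt several seconds of signal. Artifact handling in this
package is a peak-amplitude trial rejector only; manual/ICA cleaning of
real recordings is out of scope.

## Spectral analysis

Time-frequency coefficients are Hanning-tapered sliding-window Fourier
coefficients on a 1-Hz grid, with window length equal to five cycles of
the analysed frequency, so spectral smoothing grows proportionally with
frequency. The output stride is 5 ms. Windows that would extend beyond
the epoch are reported as missing (NaN), never zero-padded, because
zero-padding biases the dB baseline at the epoch edges; frequencies whose
five-cycle window does not fit in the epoch at all are listed in
`missing_freqs` rather than silently dropped. Kernels are normalized so a
unit-amplitude sinusoid at the kernel frequency has unit magnitude; the
closed-form window gain is exposed (`hann_window_gain`) and tested.

Band power (theta 4–7, alpha 8–12, beta 13–30, gamma 31–100 Hz; inclusive
1-Hz bins) is contrasted as a dB double difference: each condition's
third-stage power map is expressed as `10*log10(P3 / mean(P1))` against a
first-stage baseline window of the same length, and the contrast is the
difference of the two dB maps. Any multiplicative component present
equally in both conditions' third stages — a stimulus-evoked response —
cancels exactly; the tests verify cancellation to machine precision and
the acceptance script reports the residual.

## Connectivity

For two channels with per-trial complex coefficients `A_k e^{j phi_k}`
and `B_k e^{j theta_k}`, coherency is
`sum_k A_k B_k e^{j(phi_k-theta_k)} / sqrt(sum A_k^2) / sqrt(sum B_k^2)`
and the phase resultant is `(1/N) sum_k e^{j(phi_k-theta_k)}`; coherence
and PLV are their magnitudes, iCOH and iPLV their imaginary parts.
Imaginary parts are stored signed (the sign encodes lead/lag) and only
turned into absolute values where a lateralization quantity is formed.

Connectivity time courses use fixed 100-ms Hanning sub-windows stepped at
5 ms rather than five-cycle kernels: a five-cycle alpha kernel spans
500 ms and would smear a ~100-ms coupling episode to invisibility,
whereas the reported effects are resolved on a 5-ms grid. The price is
coarse frequency resolution within a band; metrics are therefore computed
per 1-Hz bin first and band-averaged afterwards, never by averaging
complex coefficients across frequencies (which would mix phases across
bins). Baseline correction subtracts the first-stage value (time-averaged
over a matched window) per pair — a dB transform is not meaningful for
quantities bounded in [0, 1]. Where no first-stage window can be defined,
raw third-stage values can be used instead.

## Laterality

LI = (V_R − V_L) / (V_R + V_L). For connectivity, V_R averages the
C(8,2) = 28 intra-right pairs plus the 8x4 = 32 right-midline pairs of
the 10–20 sets (right: Fp2, F4, F8, C4, T4, P4, T6, O2; left: Fp1, F7,
F3, T3, C3, T5, P3, O1; midline: Fz, CPz, Pz, Oz); V_L mirrors this.
Cross-hemisphere and intra-midline pairs are excluded. Baseline-corrected
values feed the connectivity LI by default; they can be negative, so LI
is not guaranteed to stay inside [−1, 1] — such values are propagated
as-is. For the dimension LI the raw (uncorrected) local dimensions feed
V_R/V_L instead: corrected dimension curves are centered on zero and
would make the ratio numerically meaningless, while raw local dimensions
are positive and stable. Group inference on LI time courses is a paired
cluster permutation test over time bins (below).

## Dimensionality

The correlation integral of a point cloud is the ordered-pair count
within distance delta divided by n^2 (strict inequality), and the
scale-resolved dimension is the local slope of ln C versus ln delta via
central differences; the whole curve is reported because the slope is not
constant across scales for real data. Points are per-sample channel
vectors of one regional electrode cluster, z-scored per channel (pooled
over trials and samples in the window), decimated at 5 ms, pooled across
trials, and capped at 2000 points (seeded subsample) to bound the O(n^2)
distance computation. No Theiler-style temporal exclusion is applied by
default. The default ln-delta grid is 40 points on [0, 2.3]: z-scored
m-channel vectors (m = 8–10 per cluster) have typical distances around
sqrt(2m), and this grid brackets them for every cluster size, keeping the
grid identical across clusters and conditions so curves can be subtracted
and lateralized bin-by-bin.

For scalar summaries (manifold recovery), the plateau estimate is the
median local slope over scales where C lies in [0.005, 0.05]: large
enough for stable pair counts, small enough that saturation effects
(which bias the slope low) stay negligible. With this window the
estimator recovers a line (n = 2000) to ~0.99, a unit square (n = 4000)
to ~1.9, and iid Gaussians in 1–3 dimensions within 0.15.

The ten regional clusters (left/right x frontal, central, temporal,
parietal, occipital, 8–10 electrodes each) cannot be formed from the 20
10–20 electrodes alone; the bundled dense montage anchors each cluster on
its standard electrodes and fills it with systematically named channels
at schematic positions. Real high-density membership is hardware
specific, so the montage is plain editable JSON.

## Statistics

Pointwise condition comparisons use a paired t-test when Shapiro-Wilk
(alpha 0.05) does not reject normality of the paired differences, and the
Wilcoxon signed-rank z otherwise; the gate decision is logged per
coordinate. Multiple comparisons over (channel/pair/scale, time) maps are
controlled with a cluster-based permutation test: pointwise statistics
thresholded at two-sided p < 0.05, suprathreshold samples clustered by
spatial adjacency and temporal contiguity (positive and negative clusters
separately), cluster statistics summed, and condition labels exchanged
within subject (sign-flips of the paired differences) 1,000 times by
default (500 in the calibration simulations, for runtime). The null
summary is the maximum absolute cluster sum per permutation, which
controls family-wise error; p-values use (b+1)/(n_perm+1) smoothing and
can never be exactly zero. Sign-flip statistics are computed vectorized
(the squared differences, and the ranks of absolute differences, are
flip-invariant). Measured on 500 simulated null datasets the family-wise
error is 0.058 at nominal 0.05, and power for a broad 0.8-sigma shift is
1.0. Behavioral RTs are compared with the two-sided Wilcoxon rank-sum
test; for small tie-free samples the exact Mann-Whitney p is reported
instead of the normal approximation.

## Synthetic data

Epochs are sums of (i) band-limited oscillations whose per-trial phase
structure is explicit: member channels of an entry share a per-trial
common phase plus von Mises jitter of concentration kappa, so the
expected PLV between members is (I1(kappa)/I0(kappa))^2, with kappa = 0
giving independent phases and the Rayleigh bias floor; (ii) 1/f-shaped
Gaussian noise (default exponent 1); (iii) optional instantaneous linear
mixing emulating volume conduction — deliberately zero-lag, since that is
exactly the confound iCOH/iPLV suppress. Oscillation entries can be
restricted by condition, stage and time window, which is how effects are
injected. Reaction times are lognormal per condition with parameters
chosen to reproduce median 1.13 s / mode 0.90 s (Aha) and median 2.00 s /
mode 1.50 s (Ctrl). The generator's sampling rate defaults to 1,000 Hz
(the acquisition rate of the recordings the analyses target).

The built-in synthetic study uses 8 subjects, 40 trials per cell and
250 Hz — sizes chosen so a full multi-subject run completes in tens of
seconds while leaving the laterality recovery unambiguous; the test
battery states its own sizes per check. Both hemispheres receive an
identical third-stage "task engagement" coupling (kappa 3) in both
conditions, which keeps baseline-corrected connectivity positive and the
LI denominator stable; the "eureka" effect adds a tightly locked
(kappa 20) alpha source on the right 10–20 electrodes, only in Aha
trials, only within 345–450 ms; "mirrored" places it on the left. The
midline channels deliberately carry no coupled source: an added source on
one side of a pair decoheres that pair, so coupling sets and LI pair sets
must be aligned for the injection to have a clean signature.

What the synthetic study does not emulate: real scalp topographies and
lead fields (mixing is an arbitrary matrix, not a head model),
non-stationary artifacts, inter-subject variability beyond seed
differences, cross-frequency structure, and genuinely fractal neural
dynamics (injected low-dimensional regimes are oscillatory, not
self-similar). Passing recovery tests therefore demonstrates correctness
of the estimators and inference chain under the stated generative model,
not sensitivity of the measures on real recordings.

## Numerical choices and edge cases

- Median-split binarization sends pixels equal to the median to black —
  deterministic under heavy ties; the two-tone invariant is checked.
- Histogram equalization maps intensity v to 255*CDF(v); constant images
  are rejected (undefined equalization), as are constant images at the
  median split and zero-variance channels at z-scoring.
- The Gaussian low-pass transfer function is exp(−D²/(2c²)) with D the
  radial frequency in cycles per image; cutoff units are cycles per
  image, and the Mooney default cutoff is 20 with a 150x150 canvas.
  Resizing happens after equalization and blurring, before binarization,
  so the output is strictly two-tone.
- Connectivity with a zero denominator (silent channel) yields NaN with
  an undefined-value meaning, not zero.
- Correlation-integral bins with zero pair count have undefined log-slope
  and are NaN; curves require at least three usable scales.
- Equal seeds give bit-identical generator output; the pipeline embeds
  the seed and a config hash in every artifact it writes.

## Known limitations

- The EDF reader is provided for real recordings but is untested against
  any specific study's data files.
- The sliding sub-window length (100 ms) and step (5 ms) behind the LI
  time courses are package choices; reported significance intervals shift
  by a few bins if these change.
- Whether per-hemisphere dimension curves should be pooled across trials
  or averaged per trial is an open modeling choice; pooling is the
  default and per-trial averaging is not currently implemented.
- Subject-level inference assumes subjects are exchangeable under the
  null; the synthetic study enforces this by construction.
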