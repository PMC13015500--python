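# Methods

This note documents the models, conventions and design choices behind
`fixnov`, in the order data flows through the package.

## Synthetic study conditions

The generator (`fixnov.synth`) defines the conditions under which every
claim in the test suite is evaluated. It emulates *preprocessed* recordings
— the stage at which encoding models are actually fit — not raw amplifier
output.

**Eye movements.** Fixation durations are gamma distributed (shape 4,
scale 0.075 s; mean 0.3 s), resampled below a 0.13 s floor, giving ~3 eye
movements/s as in natural movie viewing. Saccade amplitudes are log-uniform
over 1–15°. Durations follow the main sequence, 2.2 ms/°·θ + 21 ms, with
5 ms Gaussian scatter about the line — the scatter is physiological and is
also what makes the saccade-locked and fixation-locked regressors
separately identifiable at a 100 Hz analysis rate. Saccades displace gaze
along a raised-cosine velocity profile (peak speed ≈ 2·amplitude/duration,
about 300°/s for 5°). Position noise is 0.01° RMS (EyeLink-class
precision). Blink-like windows (100–300 ms, NaN-flagged) occur at ~0.08/s
inside long fixations, so the ±83 ms exclusion rule is exercised without
corrupting detector ground truth.

**Features.** Novelty is built as ρ·standardize(amplitude) + √(1−ρ²)·ε,
rescaled to mean 0.9, SD 0.25, clipped to [0, 2]; the default target
correlation ρ = 0.45 reproduces the strong amplitude–novelty dependence of
natural scenes (larger saccades land on more novel content). Clipping is
rare at these settings, so the empirical correlation sits within a few
hundredths of ρ. Luminance-class features carry a weak (0.1) latent shared
with novelty; Δ-features are first differences with the first event
missing.

**Neural forward model.** Channels × time = Σ_b (pulse train of band b,
feature values standardized) ⊛ (true TRF of band b) + noise. True TRFs are
Hann-windowed sinusoids: saccade (peak 30 ms), fixation (peak 120 ms,
amplitude 1), amplitude and luminance (amplitude 0.3), and novelty
(peak 200 ms, amplitude 0.5) restricted to the modulated-channel subset.
Noise is Gaussian 1/f synthesized in the frequency domain with an f²
rolloff below 0.5 Hz — the spectrum of EEG *after* the 0.5 Hz high-pass the
real pipeline applies. The `snr` parameter is the conventional power ratio
P_signal/P_noise; SNR 0.5 (noise SD = √2 × clean SD per channel) is the
default test condition. In BHA mode the clean sum amplitude-modulates an
8-tone 70–150 Hz carrier before noise, so `compute_bha` must demodulate it.

**Patches.** 1/f^α textures with exactly f^−α Fourier magnitude and random
phase, at moderate contrast so the sRGB→L\* nonlinearity stays near-linear.
Pair sequences mix near-duplicates (small circular-shift jitter) with
independent redraws.

**What the generator does not emulate.** Microsaccades, smooth pursuit,
head movement, photorealistic image content, non-stationary noise,
cross-channel noise correlations, or electrode-specific artifacts (the
saccadic spike is injected only where a test needs it). Passing tests
therefore demonstrate correctness of the machinery under controlled
conditions, not performance on any particular real dataset.

## Event detection

`angular_velocity` is the per-sample finite difference; acceleration is its
finite difference. The threshold detector takes contiguous runs of speed
> 30°/s and keeps those whose peak |acceleration| exceeds 8000°/s² (a
per-sample conjunction would split each saccade at peak velocity, where
acceleration crosses zero). Because a velocity sample reflects motion since
the previous sample, onset is placed one sample before the run.

The statistical detector smooths position with a 21-sample centered median
filter (shrinking windows at the edges), thresholds speed at mean + 2 SD
over valid samples of the recording (single-pass: the SD includes saccadic
samples, which biases the threshold up and costs sensitivity for small
saccades — an inherent property of the published rule, visible in
`analysis/02`), and closes the binary mask with a 5-sample flat structuring
element so post-saccadic overshoot merges into the saccade.

Fixation onset uses the 70th percentile of speeds within [onset − 33 ms,
onset + 120 ms]: the first sample at which speed, **having passed its
post-onset peak**, drops strictly under the percentile. Scanning from the
onset itself would fire while speed is still rising through the percentile
and lands mid-saccade; with the drop reading, 100% of synthetic events are
placed within ±10 ms of truth. Fixation duration runs from fixation onset
to the next saccade onset.

Exclusions: a saccade is dropped if any invalid sample lies within ±83 ms
of [onset, offset], or if the preceding fixation lasted < 110 ms
(strictly). The operation is idempotent.

## Patch features

Pixels per degree = 2·d·tan(0.5°)·(px/cm). The 5° patch is cropped around
gaze, mid-gray-filled off screen (> 20% fill ⇒ invalid), and resampled to
the nominal resolution. Grayscale always means the L\* channel of CIE
L\*a\*b\* under D65, scaled to [0, 1]. Moments are population
(uncorrected); zero-variance patches report skew/kurtosis 0. Hue diversity
is the Shannon entropy of a 16-bin hue histogram over pixels with
saturation > 0.1.

The spectrum slope bins the 2-D Fourier magnitude of L\* into 8
geometrically spaced radial bins over 0.1–10 cycles/°, bin value = mean
magnitude over coefficients with radial frequency in [edge_i, edge_{i+1}),
DC excluded, and fits OLS of log₁₀ magnitude on log₁₀ bin center (geometric
mean of the edges); the negative slope is returned. Empty bins (small
patches at low ppd) are dropped with a warning; fewer than 3 populated bins
is an error. On 100×100 patches at 20 px/° the estimator recovers the
construction exponent to ±0.02 on average.

Texture/shape: LBP (P=8, R=1, uniform) histogram energy; Scharr/Sobel edge
density as the fraction of pixels above the Otsu threshold of the gradient
magnitude; probabilistic Hough lines (canny σ=1, threshold 10, minimum
length side/4, gap 3) and Hough circle peaks (4 radii from side/8 to
side/3, accumulator threshold 0.55); GLCM at offset 1 px, 4 directions
averaged, 32 gray levels (contrast, homogeneity, correlation, ASM); blobs
from thresholding strictly above the mean gray level (a constant patch has
0 blobs), with count, mean eccentricity, mean solidity.

Saliency is a lightweight center-surround bank: Gaussian scales 2^c vs 2^s
with c ∈ {1,2,3}, s = c + {2,3} (6 pairs) on intensity, R−G and B−(R+G)/2
opponency, and 4 Gabor orientation-energy contrasts averaged over the same
pairs; values are sampled at the fixated pixel. An external saliency
predictor (e.g. a trained gaze model) can be injected as a callable;
absent, the column is NaN and the pipeline continues.

Optical flow is consumed as precomputed flow fields stored 10× spatially
downsampled; the feature is the mean flow magnitude over the patch box and
the frames intersecting [onset − 250 ms, onset − 50 ms]; still images give
0, a window before the recording start gives NaN.

The default embedding is a seeded random projection: 224×224 input (cubic
upsampling), reduced to 32×32 grayscale, projected with a fixed Gaussian
matrix to 128 dimensions, offset by a fixed bias (so constant patches have
nonzero norm), through tanh. It preserves patch-similarity structure —
jittered duplicates embed nearby, independent redraws far — which is all
the novelty tests require; it carries no semantics. Pretrained contrastive
encoders plug in through the same callable interface.

## Encoding model

Conventions: the weight at lag τ multiplies the regressor at t − τ, so a
pulse at e contributes over [e + t_min, e + t_max], endpoints inclusive,
zero-padded at the boundaries; event times round to samples half-to-even;
the scalp window is −0.2…0.6 s and the intracranial window −0.5…1.0 s at
100 Hz.

The banded objective ‖y − Xw‖² + Σ_b λ_b‖w_b‖² is solved exactly via the
normal equations (XᵀX + diag(λ))w = Xᵀy with a Cholesky factorization; with
equal λs this reproduces single-penalty ridge to machine precision.

Per training fold, feature values are z-scored with training-event
statistics, and both the response and the design columns are centered
(an implicit intercept: without column centering the pulse design cannot
absorb the event-rate DC component, which then leaks into the TRFs). Both
operations are implemented as exact affine re-parameterizations of the
cached Gram matrix, so cross-validation reuses one design matrix.
B-spline knots (5 cubic basis functions, interior knots at quantiles) are
placed on all events: knot placement is model structure and per-fold knots
would change the meaning of the columns across folds; the basis columns
are left unscaled (partition of unity).

The λ search sweeps the grid (15 points 10⁻²…10⁵ for scalp; 10 points
10⁰…10³ for intracranial) band by band in hierarchy order, freezing each
band's λ at the value maximizing the mean cross-validated r over folds and
channels before appending the next band; ties resolve to the smallest λ.
Cross-validation is leave-one-trial-out over contiguous trials (movies) or
trial-grouped 5-fold (images). Stagewise held-out r gives Δr; by
construction r_final = r_0 + ΣΔr.

Recovery behavior worth knowing: the saccade-locked and fixation-locked
impulse trains differ only by the saccade duration (2–6 samples at 100 Hz),
so the *split* between their TRFs is weakly identified; per-channel errors
in the two recovered TRFs are strongly anti-correlated while their sum is
recovered accurately. The grand-average (channel-mean) TRF cancels this
split noise and is the package's headline recovery metric (r ≈ 0.98–0.99
at SNR 0.5 with 600 s of data), as grand averages are also the standard
way such TRFs are reported.

## Statistics

The hierarchical bootstrap resamples upper units (participants/viewings)
with replacement, then lower units (chapters/segments) within each sampled
upper unit; p = fraction of bootstrap means ≤ 0 (one-sided, improvement
hypothesis), floored at 1/N_boot. TRF peak values use the two-sided
version. FDR is Benjamini–Hochberg. Under λ selection, a truly null band
is driven to the top of the grid and its Δr becomes a small but
*consistently* slightly negative quantity — the test is conservative, which
is the desired direction for false-positive control; exact uniformity of
p-values is a property of the bootstrap under a symmetric null, verified
separately.

The cluster permutation test thresholds the one-sample t map at the
two-sided critical value for α=0.01 per sample, forms same-sign clusters
connected through channel adjacency and lag contiguity, scores them by
summed t, and compares against the max-|cluster| distribution over
sign-flipped viewings; p = (1 + #{null ≥ obs})/(1 + N_perm). The reference
N_boot and N_perm are 10⁴; calibration studies scale them to 10³ with the
scaling stated alongside.

Peak statistics (max |TRF|, its lag and sign) are reported only for
channels passing the Δr significance gate: the peak lag is selected at the
maximum, so ungated peak tests on null channels are biased liberal.
Enhancement vs suppression compares the novelty TRF's sign at its peak lag
with the baseline fixation TRF's sign there; a baseline below 10% of its
own peak is indeterminate. Saccadic-spike channels are found by average-
linkage clustering (cut 0.5) of the saccade-TRF correlation matrix;
clusters whose mean TRF peaks within ±20 ms of saccade onset *and* holds
> 60% of its energy within ±30 ms are flagged.

## Preprocessing numerics

All filters are zero-phase (forward–backward); resampling is polyphase.
Scalp: 4th-order Butterworth band-pass 0.5–64 Hz, resample to 100 Hz, EOG
regressed out by least squares (EOG preprocessed identically), outliers
(|x − median| > 4 IQR per channel) replaced by inverse-distance-weighted
neighbor-channel means over ±40 ms. Intracranial: resample 600 Hz,
4th-order Butterworth 0.5 Hz high-pass, local average reference (no
neighbors ⇒ pass-through with a warning), then 501-tap least-squares FIR
band-stops at 60 and 120 Hz with a 1 Hz stopband and 1.5 Hz transition
bands (a windowed design of this length cannot realize a deep 1 Hz notch;
the least-squares design reaches −40 dB single-pass). BHA: 8 geometric
bands spanning 70–150 Hz, Chebyshev-II order 4 with 40 dB stopband,
Hilbert magnitudes summed, resampled to 100 Hz, z-scored per channel.
A robust-decomposition denoising step can be injected as any
channels×time → channels×time callable; none is applied by default.

## Validation problem sizes

As run by the test suite and `scripts/acceptance.py`: TRF recovery on one
600 s session (5 channels, SNR 0.5); ridge/oracle equivalence on a 500×120
design; hierarchy attribution paired over 50 seeds of 120 s single-channel
sessions (feature correlation 0.7); null calibration over 20 independent
120 s null sessions × 10 channels (N_boot 10³) plus 200 symmetric-null
bootstrap replicates; cluster type-I error over 500 null stacks of
20×16×81 with 10³ permutations; detection on ~100 saccades; 50 texture
patches per spectral exponent; 500 patch pairs for novelty; and 10 seeds of
the 300 s / 20-channel / 5-modulated demo pipeline. These sizes were chosen
to give stable Monte-Carlo estimates at desk scale.

## Known limitations

The toy encoder measures low-level patch similarity, not semantics; real
novelty effects depend on the plugged-in encoder. The 2-SD detector's
single-pass threshold under-detects small saccades by construction. The
generator's feature battery is statistical, not image-derived, so feature
extractors are validated on analytic stimuli and textures rather than
natural scenes. Δr under λ-selection is conservatively biased near zero
effect; borderline modulations need more data, not a looser test.
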