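# fixnov

Fixation-locked encoding of **semantic novelty** in free-viewing
electrophysiology.

During natural vision, gaze moves in saccades separated by brief fixations,
and each fixation delivers a new foveal sample of the scene. If the visual
system integrates semantic content across fixations, neural responses
locked to fixation onset should be modulated by how *semantically novel*
the current foveal patch is relative to the previous one. `fixnov`
implements the full analysis chain needed to test this on gaze + stimulus +
neural recordings, and — because such recordings are rarely shareable — a
seeded synthetic-data generator with known ground truth so every stage is
testable end to end.

The package is aimed at researchers running fixation-related potential /
broadband high-frequency amplitude (BHA) analyses on scalp EEG or
intracranial recordings during movie or image viewing.

## What it computes

**Events.** Saccades and fixation onsets from raw gaze, with two detectors:
velocity+acceleration thresholds (30°/s, 8000°/s²) for EyeLink-class
trackers, and a median-filter + mean+2SD velocity rule with morphological
closing and a 70th-percentile fixation-onset rule for noisier trackers.
Saccades near low-quality data (±83 ms) or after fixations < 110 ms are
excluded. Amplitude θ is the Euclidean norm of the gaze displacement.

**Features.** For each fixation, a 5° foveal patch is extracted and scored
with a battery of luminance/color, contrast/energy, spectral, texture and
shape descriptors plus center-surround saliency values, the pre-saccadic
optical-flow window (−250 to −50 ms), and **novelty**

> ν = 1 − ⟨e₋, e₊⟩ / (‖e₋‖‖e₊‖) ∈ [0, 2],

the cosine distance between embeddings e₋, e₊ of the pre- and
post-saccadic patches (a seeded random-projection toy encoder by default;
any pretrained encoder plugs in as a callable).

**Encoding model.** Events and features enter a lagged design as (scaled)
pulses; the model predicts the neural signal y(t) per channel as

> ŷ(t) = Σ_b Σ_τ w_b(τ) · x_b(t − τ),  τ ∈ [t_min, t_max],

with one ridge penalty λ_b per feature band (banded ridge):
minimize ‖y − Xw‖² + Σ_b λ_b‖w_b‖². The w_b(τ) are the temporal response
functions (TRFs). λs are frozen sequentially along the hierarchy
saccade onset → fixation onset → amplitude (5 cubic B-splines, quantile
knots) → luminance → Δluminance → spectrum slope → Δslope → optical flow →
novelty, so shared variance is attributed to the earlier band. The
cross-validated Pearson r of successive stages gives the per-feature
increment **Δr**; a feature is "encoded" where its Δr is significantly
positive.

**Statistics.** Hierarchical bootstrap of Δr over nested units with
Benjamini–Hochberg FDR across channels; spatiotemporal cluster permutation
of TRF stacks (sign-flip null, summed-t cluster statistic, channel
adjacency × lag contiguity); TRF peak magnitude/latency with bootstrap
significance; enhancement/suppression classification against the baseline
fixation response; saccadic-spike artifact screening by clustering
saccade-TRF correlations; paired condition comparisons and per-region
summaries.

**Signal paths.** Scalp: 0.5–64 Hz zero-phase band-pass, 100 Hz resampling,
EOG regression, IQR-outlier repair by spatial interpolation. Intracranial:
600 Hz resampling, 0.5 Hz high-pass, local-average reference, deep 60/120 Hz
FIR notches, and BHA = summed Hilbert envelopes of 8 log-spaced 70–150 Hz
Chebyshev-II bands, resampled to 100 Hz and z-scored.

## Worked example

```python
import fixnov

cfg = fixnov.PipelineConfig(
    synth=fixnov.SynthConfig(seed=1, duration_s=300.0,
                             n_channels=20, n_modulated=5))
out = fixnov.run_pipeline(cfg, outdir="results/encoding")
print(out["report"])
```

This simulates 300 s of free viewing (848 eye movements, amplitude–novelty
correlation r = 0.459 against a target of 0.45), detects events
(sensitivity 1.000, median onset error 3.0 ms), fits the nine-band
hierarchy, and tests which channels encode novelty. With seed 1 it prints
(abridged):

```
delta_r(novelty): modulated channels 0.0563, others -0.0015
flagged channels [2, 3, 5, 10, 17] (true: [2, 3, 5, 10, 17])
```

i.e. the bootstrap+FDR stage recovers exactly the five channels whose
ground-truth novelty TRF is nonzero, with no false positives, and the
novelty increment Δr ≈ 0.056 on those channels is absent elsewhere.

The numbered scripts under `analysis/` run the same story step by step
(simulate → detect → features → encoding → statistics → validation) and
write their tables under `results/`.

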