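"""Seeded synthetic gaze, features, image patches, and neural recordings.

Everything downstream of raw data acquisition can be exercised against this
module's known ground truth: saccade/fixation event trains with
gamma-distributed fixation durations and main-sequence amplitudes, feature
values with a controlled amplitude-novelty correlation, 1/f-texture patch
pairs for the feature extractors, and neural signals produced by convolving
known temporal response functions with event/feature pulse trains plus 1/f
noise (scalp mode) or amplitude-modulating a 70-150 Hz multi-tone carrier
(BHA mode).

Fixed seeds give byte-identical outputs. Saccades follow a raised-cosine
velocity profile with main-sequence duration 2.2 ms/deg + 21 ms. Blink-like
low-quality windows (100-300 ms) are inserted at Poisson times inside
fixations so the 83 ms exclusion rule is exercised without corrupting the
event-detection ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .encoding import Band, LagWindow, build_design
from .gaze import GazeRecording
from .neural import NeuralRecording

#: main-sequence saccade duration: slope (s/deg) and intercept (s)
SACCADE_DUR_SLOPE = 0.0022
SACCADE_DUR_INTERCEPT = 0.021

FEATURE_COLUMNS = ["amplitude", "luminance", "dluminance", "spectrum_slope",
                   "dspectrum_slope", "optic_flow", "novelty"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic session.

    Defaults give ~3 eye movements per second (gamma fixation durations with
    mean 0.3 s, floored at ``min_fixation_s``), amplitudes log-uniform over
    1-15 degrees, and an amplitude-novelty correlation of 0.45, in the range
    of the strong correlation seen in free viewing of natural scenes.
    """

    seed: int = 0
    duration_s: float = 600.0
    gaze_fs: float = 500.0
    neural_fs: float = 100.0
    n_channels: int = 20
    fixation_duration_shape: float = 4.0
    fixation_duration_scale: float = 0.075
    min_fixation_s: float = 0.13
    amplitude_range: tuple[float, float] = (1.0, 15.0)
    amplitude_novelty_rho: float = 0.45
    noise_sd: float = 1.0
    gaze_noise_sd: float = 0.01
    blink_rate_hz: float = 0.08
    mode: str = "scalp"          # "scalp" | "bha"
    n_modulated: int = 5
    screen_half_deg: float = 14.0
    lag_t_min: float = -0.2
    lag_t_max: float = 0.6

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 <= self.amplitude_novelty_rho < 1:
            raise ValueError("amplitude_novelty_rho must be in [0, 1)")
        if self.mode not in ("scalp", "bha"):
            raise ValueError("mode must be 'scalp' or 'bha'")

    @property
    def lag_window(self) -> LagWindow:
        return LagWindow(self.lag_t_min, self.lag_t_max, self.neural_fs)


@dataclass
class GroundTruth:
    """Known event schedule, TRFs, and modulated-channel set."""

    events: pd.DataFrame          # saccade_onset/offset, fixation_onset, ...
    true_trfs: dict[str, np.ndarray]   # band -> (n_channels, n_lags)
    lag_window: LagWindow
    modulated_channels: np.ndarray

    def to_json(self, path) -> None:
        obj = {
            "events": self.events.to_dict(orient="list"),
            "true_trfs": {k: v.tolist() for k, v in self.true_trfs.items()},
            "lag_window": [self.lag_window.t_min, self.lag_window.t_max,
                           self.lag_window.fs],
            "modulated_channels": self.modulated_channels.tolist(),
        }
        with open(path, "w") as f:
            json.dump(obj, f)


def saccade_duration(amplitude_deg: np.ndarray) -> np.ndarray:
    """Main-sequence duration: 2.2 ms/deg + 21 ms."""
    return SACCADE_DUR_SLOPE * np.asarray(amplitude_deg) + SACCADE_DUR_INTERCEPT


def _event_schedule(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    lead = 0.5
    t = lead
    rows = []
    lo, hi = cfg.amplitude_range
    while True:
        dur = rng.gamma(cfg.fixation_duration_shape, cfg.fixation_duration_scale)
        while dur < cfg.min_fixation_s:
            dur = rng.gamma(cfg.fixation_duration_shape,
                            cfg.fixation_duration_scale)
        amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        # main-sequence duration with physiological scatter about the line
        sdur = float(max(saccade_duration(amp) + rng.normal(0.0, 0.005), 0.015))
        onset = t + dur
        if onset + sdur > cfg.duration_s - lead:
            break
        rows.append((onset, onset + sdur, onset + sdur, amp, dur))
        t = onset + sdur
    if not rows:
        raise ValueError("duration too short to contain a single fixation")
    df = pd.DataFrame(rows, columns=["saccade_onset", "saccade_offset",
                                     "fixation_onset", "amplitude",
                                     "prev_fixation_duration"])
    nxt = df["saccade_onset"].shift(-1)
    df["fixation_duration"] = nxt - df["fixation_onset"]
    df.loc[df.index[-1], "fixation_duration"] = (
        cfg.duration_s - lead - df["fixation_onset"].iloc[-1])
    return df


def _trf_shape(lags: np.ndarray, peak_t: float, width: float,
               freq: float, amp: float) -> np.ndarray:
    """Smooth biphasic impulse response: Hann-windowed sinusoid."""
    w = np.zeros_like(lags)
    in_w = np.abs(lags - peak_t) < width
    tau = lags[in_w] - peak_t
    w[in_w] = amp * np.cos(np.pi * tau / (2 * width)) ** 2 * np.cos(
        2 * np.pi * freq * tau)
    return w


def _true_trfs(cfg: SynthConfig, rng: np.random.Generator
               ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    lw = cfg.lag_window
    lags = lw.lag_times
    C = cfg.n_channels
    gains = 0.8 + 0.4 * rng.random(C)
    polarity = np.where(rng.random(C) < 0.5, 1.0, -1.0)
    trfs = {
        "saccade_onset": np.outer(gains, _trf_shape(lags, 0.03, 0.06, 8.0, 0.6)),
        "fixation_onset": np.outer(gains, _trf_shape(lags, 0.12, 0.12, 4.0, 1.0)),
        "amplitude": np.outer(gains * polarity,
                              _trf_shape(lags, 0.10, 0.10, 5.0, 0.3)),
        "luminance": np.outer(gains, _trf_shape(lags, 0.15, 0.10, 4.0, 0.3)),
    }
    modulated = rng.choice(C, size=min(cfg.n_modulated, C), replace=False)
    modulated.sort()
    nov = np.zeros((C, lw.n_lags))
    nov_shape = _trf_shape(lags, 0.20, 0.15, 3.0, 0.5)
    nov[modulated] = gains[modulated, None] * nov_shape[None, :]
    trfs["novelty"] = nov
    for name in ("dluminance", "dspectrum_slope", "spectrum_slope",
                 "optic_flow"):
        trfs[name] = np.zeros((C, lw.n_lags))
    return trfs, modulated


def generate_gaze(cfg: SynthConfig) -> tuple[GazeRecording, GroundTruth]:
    """Synthesize a gaze trace with known saccade/fixation schedule.

    Fixation positions follow a bounded 2-D walk whose step length equals
    the scheduled saccade amplitude; each saccade displaces gaze along a
    raised-cosine (minimum-jerk-like) velocity profile. Additive Gaussian
    position noise and NaN-flagged blink windows complete the trace.
    """
    rng = np.random.default_rng(cfg.seed)
    events = _event_schedule(cfg, rng)
    trfs, modulated = _true_trfs(cfg, rng)

    n = int(round(cfg.duration_s * cfg.gaze_fs))
    t = np.arange(n) / cfg.gaze_fs
    x = np.zeros(n)
    y = np.zeros(n)
    pos = np.zeros(2)
    half = cfg.screen_half_deg
    seg_start = 0
    for _, ev in events.iterrows():
        theta = rng.uniform(0, 2 * np.pi)
        step = ev.amplitude * np.array([np.cos(theta), np.sin(theta)])
        new = pos + step
        # reflect at the screen bounds, preserving the step length statistics
        for d in range(2):
            if new[d] > half or new[d] < -half:
                step[d] = -step[d]
                new[d] = pos[d] + step[d]
        i0 = int(np.round(ev.saccade_onset * cfg.gaze_fs))
        i1 = int(np.round(ev.saccade_offset * cfg.gaze_fs))
        i1 = max(i1, i0 + 2)
        x[seg_start:i0] = pos[0]
        y[seg_start:i0] = pos[1]
        # raised-cosine velocity -> smooth-step displacement profile
        tau = (t[i0:i1] - t[i0]) / (t[i1 - 1] - t[i0])
        prof = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
        x[i0:i1] = pos[0] + step[0] * prof
        y[i0:i1] = pos[1] + step[1] * prof
        pos = new
        seg_start = i1
    x[seg_start:] = pos[0]
    y[seg_start:] = pos[1]

    if cfg.gaze_noise_sd > 0:
        x = x + rng.normal(0, cfg.gaze_noise_sd, n)
        y = y + rng.normal(0, cfg.gaze_noise_sd, n)

    valid = np.ones(n, bool)
    n_blinks = rng.poisson(cfg.blink_rate_hz * cfg.duration_s)
    fix_starts = events["fixation_onset"].to_numpy()
    fix_durs = events["fixation_duration"].to_numpy()
    long_fix = np.flatnonzero(fix_durs > 0.45)
    for _ in range(n_blinks):
        if not len(long_fix):
            break
        j = int(rng.choice(long_fix))
        blink_dur = rng.uniform(0.10, 0.30)
        start = fix_starts[j] + 0.5 * (fix_durs[j] - blink_dur)
        b0 = int(round(start * cfg.gaze_fs))
        b1 = min(n, b0 + int(round(blink_dur * cfg.gaze_fs)))
        valid[b0:b1] = False
    x[~valid] = np.nan
    y[~valid] = np.nan

    rec = GazeRecording(t, x, y, valid, cfg.gaze_fs)
    truth = GroundTruth(events=events, true_trfs=trfs,
                        lag_window=cfg.lag_window,
                        modulated_channels=modulated)
    return rec, truth


def generate_feature_table(cfg: SynthConfig, truth: GroundTruth,
                           extra_rho: float = 0.1) -> pd.DataFrame:
    """Per-event features with the configured amplitude-novelty correlation.

    Novelty is built as rho * standardized(amplitude) + sqrt(1-rho^2) * noise,
    rescaled to mean 0.9, SD 0.25 and clipped to [0, 2] (clipping is rare at
    these settings, so the empirical correlation stays within a few 1e-2 of
    rho). Luminance optionally shares a weak latent (``extra_rho``) with
    novelty, mirroring the weak luminance-novelty correlations of natural
    scenes. Delta features are first differences; the first event's deltas
    are missing.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ev = truth.events
    m = len(ev)
    amp = ev["amplitude"].to_numpy()
    z_amp = (amp - amp.mean()) / amp.std()
    rho = cfg.amplitude_novelty_rho
    nov_lat = rho * z_amp + np.sqrt(1 - rho ** 2) * rng.standard_normal(m)
    novelty = np.clip(0.9 + 0.25 * nov_lat, 0.0, 2.0)
    z_nov = (nov_lat - nov_lat.mean()) / nov_lat.std()
    lum = 50 + 15 * (extra_rho * z_nov
                     + np.sqrt(1 - extra_rho ** 2) * rng.standard_normal(m))
    slope = 1.0 + 0.2 * rng.standard_normal(m)
    flow = np.abs(rng.standard_normal(m))
    df = pd.DataFrame({
        "amplitude": amp,
        "luminance": lum,
        "dluminance": np.concatenate([[np.nan], np.diff(lum)]),
        "spectrum_slope": slope,
        "dspectrum_slope": np.concatenate([[np.nan], np.diff(slope)]),
        "optic_flow": flow,
        "novelty": novelty,
    })
    return df


def make_null(features: pd.DataFrame, column: str, seed: int) -> pd.DataFrame:
    """Return a copy with one column permuted across events (null model)."""
    if column not in features.columns:
        raise KeyError(f"unknown column {column!r}")
    rng = np.random.default_rng(seed)
    out = features.copy()
    out[column] = rng.permutation(out[column].to_numpy())
    return out


def onef_texture(size: int, alpha: float, rng: np.random.Generator,
                 contrast: float = 0.12, mean: float = 0.5) -> np.ndarray:
    """Grayscale 1/f^alpha texture in [0, 1] with known spectral exponent.

    The Fourier magnitude is set exactly to f^-alpha with random phases, so
    a spectrum-slope estimator should recover ``alpha``. Contrast is kept
    moderate so downstream nonlinear colorspace transforms stay near-linear.
    """
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf
    mag = f ** -alpha
    phase = rng.uniform(0, 2 * np.pi, (size, size))
    spec = mag * np.exp(1j * phase)
    img = np.real(np.fft.ifft2(spec))
    img = img / (np.abs(img).max() + 1e-12)
    return np.clip(mean + contrast * img, 0.0, 1.0)


def generate_patch_pair_sequence(
    cfg: SynthConfig, n_pairs: int = 100, size: int = 100,
    p_duplicate: float = 0.5, jitter_px: int = 2,
    alpha_range: tuple[float, float] = (0.8, 1.4),
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Pairs of RGB patches: near-duplicates or independent redraws.

    Returns ``(pairs, is_duplicate)``. Duplicates are the same 1/f texture
    with a small circular-shift jitter (zero jitter => pixelwise identical);
    redraws are independent textures with independently drawn exponents.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    pairs, labels = [], []
    for _ in range(n_pairs):
        a = rng.uniform(*alpha_range)
        first = onef_texture(size, a, rng)
        dup = rng.random() < p_duplicate
        if dup:
            if jitter_px > 0:
                shifts = rng.integers(-jitter_px, jitter_px + 1, 2)
                second = np.roll(first, tuple(shifts), axis=(0, 1))
            else:
                second = first.copy()
        else:
            second = onef_texture(size, rng.uniform(*alpha_range), rng)
        pairs.append((np.repeat(first[..., None], 3, -1),
                      np.repeat(second[..., None], 3, -1)))
        labels.append(dup)
    return pairs, np.asarray(labels, bool)


def onef_noise(n: int, n_channels: int, rng: np.random.Generator,
               exponent: float = 1.0, fs: float = 100.0,
               f_lo: float = 0.5) -> np.ndarray:
    """Gaussian 1/f noise, unit SD per channel, synthesized in frequency.

    Below ``f_lo`` (Hz) the spectrum rolls off as f^2, emulating the
    high-pass edge of preprocessed EEG (the signals this generator stands
    in for are band-passed at 0.5 Hz before encoding).
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    pos = freqs > 0
    scale[pos] = np.maximum(freqs[pos], f_lo) ** (-exponent / 2)
    low = pos & (freqs < f_lo)
    scale[low] *= (freqs[low] / f_lo) ** 2
    scale[0] = 0.0
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.nan_to_num(np.asarray(v, float))
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v * 0.0


def generate_neural(cfg: SynthConfig, truth: GroundTruth,
                    features: pd.DataFrame,
                    snr: float | None = None) -> NeuralRecording:
    """Forward model: sum over bands of (pulse train (*) true TRF) + noise.

    Feature values are standardized before scaling the pulses, so TRF
    amplitudes are in comparable units across bands. ``snr`` (if given)
    overrides ``cfg.noise_sd`` by scaling the noise to
    std(clean)/snr per channel. In "bha" mode the clean sum instead
    amplitude-modulates a 70-150 Hz multi-tone carrier before noise is
    added; the carrier is synthesized at ``cfg.neural_fs`` (>= 400 Hz).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    lw = cfg.lag_window
    fs = lw.fs
    ev = truth.events
    if len(ev) and ev["saccade_onset"].iloc[-1] > cfg.duration_s:
        raise ValueError("events extend beyond the recording")
    C = cfg.n_channels

    bands = []
    for name, trf in truth.true_trfs.items():
        if not np.any(trf):
            continue
        if name == "saccade_onset":
            bands.append(Band(name, ev["saccade_onset"].to_numpy(), None,
                              "impulse", "saccade_onset"))
        elif name == "fixation_onset":
            bands.append(Band(name, ev["fixation_onset"].to_numpy(), None,
                              "impulse", "fixation_onset"))
        else:
            align = "saccade_onset" if name == "amplitude" else "fixation_onset"
            vals = _standardize(features[name].to_numpy())
            bands.append(Band(name, ev[align].to_numpy(), vals, "linear", align))
    X, info = build_design(bands, cfg.duration_s, lw)
    clean = np.zeros((C, X.shape[0]))
    for b in info.bands:
        clean += truth.true_trfs[b.name] @ X[:, b.sl].T

    if cfg.mode == "scalp":
        signal_out = clean
    else:
        if fs < 400:
            raise ValueError("bha mode needs neural_fs >= 400 Hz")
        tones = np.geomspace(72, 148, 8)
        tvec = np.arange(X.shape[0]) / fs
        phases = rng.uniform(0, 2 * np.pi, (C, len(tones)))
        carrier = np.zeros((C, X.shape[0]))
        for k, f0 in enumerate(tones):
            carrier += np.cos(2 * np.pi * f0 * tvec[None, :] + phases[:, [k]])
        carrier /= np.sqrt(len(tones) / 2)
        sd = clean.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        envelope = 1.0 + 0.5 * np.clip(clean / (3 * sd), -0.95, 0.95) * 1.8
        signal_out = envelope * carrier

    if snr is not None:
        sds = signal_out.std(axis=-1, keepdims=True)
        sds[sds == 0] = np.mean(sds[sds > 0]) if np.any(sds > 0) else 1.0
        noise_amp = sds / np.sqrt(snr)
    else:
        noise_amp = cfg.noise_sd
    data = signal_out + onef_noise(X.shape[0], C, rng, fs=fs) * noise_amp
    names = [f"ch{i:02d}" for i in range(C)]
    # channels on a synthetic circular montage, for adjacency-based stats
    ang = 2 * np.pi * np.arange(C) / C
    positions = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return NeuralRecording(data=data, fs=fs, channel_names=names,
                           positions=positions,
                           modality="scalp" if cfg.mode == "scalp" else "ieeg")
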