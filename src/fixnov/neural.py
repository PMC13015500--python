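"""Neural-signal containers and preprocessing.

Scalp-like recordings are band-passed 0.5-64 Hz, resampled to 100 Hz, have
EOG regressed out, and large residual outliers replaced by spatial
interpolation. Intracranial-like recordings are resampled to 600 Hz,
high-passed at 0.5 Hz, locally re-referenced against nearest neighbors, and
notch-filtered at 60/120 Hz with long zero-phase FIR filters. Broadband
high-frequency amplitude (BHA, 70-150 Hz) is the summed Hilbert envelope of
8 log-spaced Chebyshev-II bands, resampled to 100 Hz and z-scored.

All filtering is applied forward-backward (zero phase). Resampling is
polyphase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import h5py
import numpy as np
from scipy import signal

ANALYSIS_FS = 100.0
IEEG_FS = 600.0
BHA_BAND = (70.0, 150.0)
N_BHA_BANDS = 8


@dataclass
class NeuralRecording:
    """Channels x time array with metadata.

    ``positions`` (n_channels x 2 or x 3) enables spatial interpolation and
    adjacency-based cluster tests; ``adjacency`` may be given directly.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None
    adjacency: np.ndarray | None = None
    modality: str = "scalp"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            f.attrs["modality"] = self.modality
            f.create_dataset("channel_names",
                             data=np.array(self.channel_names, dtype="S"))
            if self.positions is not None:
                f.create_dataset("positions", data=self.positions)

    @classmethod
    def load_h5(cls, path) -> "NeuralRecording":
        with h5py.File(path, "r") as f:
            pos = f["positions"][:] if "positions" in f else None
            return cls(
                data=f["data"][:],
                fs=float(f.attrs["fs"]),
                channel_names=[s.decode() for s in f["channel_names"][:]],
                positions=pos,
                modality=str(f.attrs.get("modality", "scalp")),
            )


def _resample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if fs == target_fs:
        return data
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def adjacency_from_positions(positions: np.ndarray, k: int = 4) -> np.ndarray:
    """Symmetric k-nearest-neighbor adjacency from channel positions."""
    pos = np.asarray(positions, float)
    n = len(pos)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), bool)
    kk = min(k, n - 1)
    for i in range(n):
        adj[i, np.argsort(d[i])[:kk]] = True
    return adj | adj.T


def preprocess_scalp(
    rec: NeuralRecording,
    eog: np.ndarray | None = None,
    band: tuple[float, float] = (0.5, 64.0),
    target_fs: float = ANALYSIS_FS,
    outlier_iqr: float = 4.0,
    interp_window_s: float = 0.040,
) -> NeuralRecording:
    """Scalp pipeline: band-pass, resample, EOG regression, outlier repair.

    ``eog`` is an (n_eog x n_samples) array at the input sampling rate; it is
    filtered and resampled identically before being regressed out of every
    channel by least squares. Residual samples deviating from the channel
    median by more than ``outlier_iqr`` interquartile ranges are replaced by
    the inverse-distance-weighted mean of the other channels averaged over
    +/- 40 ms (requires ``rec.positions``).
    """
    if rec.fs < 128:
        raise ValueError("scalp preprocessing expects fs >= 128 Hz")
    sos = signal.butter(4, band, btype="bandpass", fs=rec.fs, output="sos")
    x = signal.sosfiltfilt(sos, rec.data, axis=-1)
    x = _resample(x, rec.fs, target_fs)
    if eog is not None and len(eog):
        e = signal.sosfiltfilt(sos, np.atleast_2d(np.asarray(eog, float)), axis=-1)
        e = _resample(e, rec.fs, target_fs)
        beta, *_ = np.linalg.lstsq(e.T, x.T, rcond=None)
        x = x - beta.T @ e

    med = np.median(x, axis=1, keepdims=True)
    iqr = np.subtract(*np.percentile(x, [75, 25], axis=1))[:, None]
    bad = np.abs(x - med) > outlier_iqr * iqr
    if bad.any():
        if rec.positions is None:
            raise ValueError("outlier interpolation requires channel positions")
        x = _interpolate_outliers(x, bad, rec.positions, target_fs, interp_window_s)
    return replace(rec, data=x, fs=target_fs)


def _interpolate_outliers(x, bad, positions, fs, window_s):
    """Replace flagged samples by neighbor-channel averages within +/- window."""
    out = x.copy()
    half = int(round(window_s * fs))
    pos = np.asarray(positions, float)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    w = 1.0 / np.maximum(dist, 1e-9)
    n_ch, n_t = x.shape
    good = ~bad
    for c in range(n_ch):
        idx = np.flatnonzero(bad[c])
        for t in idx:
            t0, t1 = max(0, t - half), min(n_t, t + half + 1)
            seg = x[:, t0:t1]
            seg_good = good[:, t0:t1]
            ch_mean = np.full(n_ch, np.nan)
            for o in range(n_ch):
                if o != c and seg_good[o].any():
                    ch_mean[o] = seg[o][seg_good[o]].mean()
            mask = np.isfinite(ch_mean)
            if mask.any():
                out[c, t] = np.average(ch_mean[mask], weights=w[c, mask])
            else:
                out[c, t] = np.median(x[c])
    return out


def preprocess_ieeg(
    rec: NeuralRecording,
    neighbor_map: dict[int, list[int]] | None = None,
    target_fs: float = IEEG_FS,
    hp_cutoff: float = 0.5,
    notch_freqs: tuple[float, ...] = (60.0, 120.0),
    notch_order: int = 501,
    notch_bw: float = 1.0,
) -> NeuralRecording:
    """Intracranial pipeline: resample, high-pass, local reference, notch.

    ``neighbor_map`` maps channel index -> neighbor indices for the local
    average reference; a channel with no neighbors is passed through with a
    warning. Notch filters are ``notch_order``-tap FIR band-stops of
    ``notch_bw`` Hz width applied forward and backward.
    """
    x = _resample(rec.data, rec.fs, target_fs)
    sos = signal.butter(4, hp_cutoff, btype="highpass", fs=target_fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)

    if neighbor_map is None:
        if rec.adjacency is not None:
            neighbor_map = {i: list(np.flatnonzero(rec.adjacency[i]))
                            for i in range(rec.n_channels)}
        else:
            neighbor_map = {i: [] for i in range(rec.n_channels)}
    ref = x.copy()
    for c in range(x.shape[0]):
        nbrs = neighbor_map.get(c, [])
        if nbrs:
            x[c] = ref[c] - ref[nbrs].mean(axis=0)
        else:
            warnings.warn(f"channel {c} has no neighbors; left unreferenced")

    for f0 in notch_freqs:
        # least-squares band-stop: stopband of notch_bw Hz with short
        # transition bands, so the 501-tap design reaches a deep notch
        hw = notch_bw / 2
        b = signal.firls(
            notch_order,
            [0, f0 - hw - 1.5, f0 - hw, f0 + hw, f0 + hw + 1.5, target_fs / 2],
            [1, 1, 0, 0, 1, 1], weight=[1, 100, 1], fs=target_fs)
        x = signal.filtfilt(b, [1.0], x, axis=-1)
    return replace(rec, data=x, fs=target_fs, modality="ieeg")


def bha_band_edges(lo: float = BHA_BAND[0], hi: float = BHA_BAND[1],
                   n_bands: int = N_BHA_BANDS) -> np.ndarray:
    """Geometric band edges: adjacent bands share edges."""
    return np.geomspace(lo, hi, n_bands + 1)


def compute_bha(
    rec: NeuralRecording,
    target_fs: float = ANALYSIS_FS,
    order: int = 4,
    attenuation_db: float = 40.0,
    zscore: bool = True,
) -> NeuralRecording:
    """Broadband high-frequency amplitude.

    Filters the signal into 8 log-spaced bands spanning 70-150 Hz
    (Chebyshev type II, zero phase), takes each band's analytic-signal
    magnitude, sums the envelopes, resamples to ``target_fs`` and z-scores
    per channel.
    """
    if rec.fs < 400:
        raise ValueError("BHA needs fs >= 400 Hz to resolve 150 Hz content")
    edges = bha_band_edges()
    env = np.zeros_like(rec.data)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = signal.cheby2(order, attenuation_db, [lo, hi],
                            btype="bandpass", fs=rec.fs, output="sos")
        band = signal.sosfiltfilt(sos, rec.data, axis=-1)
        env += np.abs(signal.hilbert(band, axis=-1))
    env = _resample(env, rec.fs, target_fs)
    if zscore:
        env = (env - env.mean(axis=1, keepdims=True)) / env.std(axis=1, keepdims=True)
    return replace(rec, data=env, fs=target_fs, modality="bha")
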