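"""Saccade and fixation detection from raw gaze traces.

Two detectors are provided, mirroring the two classes of eye trackers this
pipeline supports:

* a threshold detector (``detect_saccades_thresholds``) in the style of the
  EyeLink online parser: velocity runs above 30 deg/s validated by a peak
  acceleration above 8000 deg/s^2;
* a dispersion-free statistical detector (``detect_saccades_sd``) for noisier
  trackers: a 21-sample median filter, a mean + 2 SD velocity threshold, a
  5-sample morphological closing to absorb post-saccadic overshoot, and a
  70th-percentile rule to place fixation onset.

Exclusion rules drop saccades near low-quality (blink) samples and saccades
following implausibly short fixations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

#: Velocity threshold (deg/s) for the threshold detector.
V_THRESH = 30.0
#: Acceleration threshold (deg/s^2) for the threshold detector.
A_THRESH = 8000.0
#: Window half-widths (s) for the fixation-onset percentile rule.
FIX_WIN_BEFORE = 0.033
FIX_WIN_AFTER = 0.120
#: Exclusion margin (s) around low-quality samples.
LOW_QUALITY_MARGIN = 0.083
#: Minimum duration (s) of the fixation preceding a retained saccade.
MIN_FIXATION = 0.110

EVENT_COLUMNS = [
    "saccade_onset",
    "saccade_offset",
    "fixation_onset",
    "amplitude",
    "fixation_duration",
    "quality_ok",
]


@dataclass
class GazeRecording:
    """Timestamped monocular gaze in degrees of visual angle.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform to ~1%.
    x, y : ndarray
        Gaze angle in degrees of visual angle.
    valid : ndarray of bool
        False where the tracker lost the eye (blinks etc.).
    fs : float
        Sampling rate in Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x_deg": self.x, "y_deg": self.y, "valid": self.valid}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float | None = None) -> "GazeRecording":
        t = df["t"].to_numpy(float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["x_deg"].to_numpy(float), df["y_deg"].to_numpy(float),
                   df["valid"].to_numpy(bool), fs)


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=bool if c == "quality_ok" else float)
                         for c in EVENT_COLUMNS})


def smooth_gaze(rec: GazeRecording, order: int = 20) -> GazeRecording:
    """20th-order (21-sample centered window) median filter of gaze position.

    Edges use shrinking windows so the output has no boundary bias toward an
    arbitrary pad value. ``t`` and ``valid`` are untouched.
    """
    win = order + 1
    if len(rec) < win:
        raise ValueError(f"need at least {win} samples for a {order}th-order median filter")
    xs = pd.Series(rec.x).rolling(win, center=True, min_periods=1).median().to_numpy()
    ys = pd.Series(rec.y).rolling(win, center=True, min_periods=1).median().to_numpy()
    return replace(rec, x=xs, y=ys)


def angular_velocity(rec: GazeRecording) -> np.ndarray:
    """Per-sample angular speed in deg/s.

    Speed at sample ``i`` is the Euclidean norm of the position step from
    ``i-1`` to ``i`` divided by the time step; the first sample copies the
    second so the output has the same length as the recording.
    """
    if len(rec) < 2:
        raise ValueError("need at least 2 samples")
    dx = np.diff(rec.x)
    dy = np.diff(rec.y)
    dt = np.diff(rec.t)
    v = np.hypot(dx, dy) / dt
    return np.concatenate([[v[0]], v])


def acceleration(rec: GazeRecording, velocity: np.ndarray | None = None) -> np.ndarray:
    """First difference of angular speed divided by the time step (deg/s^2)."""
    v = angular_velocity(rec) if velocity is None else velocity
    dt = np.diff(rec.t)
    a = np.diff(v) / dt
    return np.concatenate([[a[0]], a])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_saccades_thresholds(
    rec: GazeRecording,
    v_thresh: float = V_THRESH,
    a_thresh: float = A_THRESH,
) -> pd.DataFrame:
    """EyeLink-style threshold detector.

    Candidate saccades are contiguous runs with speed above ``v_thresh``;
    a run is kept only if its peak |acceleration| also exceeds ``a_thresh``,
    so both thresholds gate every detected event.  (A per-sample conjunction
    would split each saccade at peak velocity, where acceleration crosses
    zero.)  Fixation onset is taken at saccade offset, as in the EyeLink
    parser; fixation duration runs to the next saccade onset.
    """
    v = angular_velocity(rec)
    a = acceleration(rec, v)
    rows = []
    for i0, i1 in _runs(v > v_thresh):
        if np.max(np.abs(a[i0:i1])) <= a_thresh:
            continue
        # velocity sample i reflects motion since sample i-1, so the
        # movement begins one sample before the suprathreshold run
        j0 = max(i0 - 1, 0)
        onset = rec.t[j0]
        offset = rec.t[i1 - 1]
        amp = float(np.hypot(rec.x[i1 - 1] - rec.x[j0], rec.y[i1 - 1] - rec.y[j0]))
        rows.append((onset, offset, offset, amp))
    return _finalize_events(rows, rec)


def detect_saccades_sd(rec: GazeRecording, n_sd: float = 2.0,
                       closing_kernel: int = 5) -> np.ndarray:
    """Binary saccade mask: speed > mean + ``n_sd``*SD, then morphological closing.

    The mean and SD are computed over valid samples of the whole recording.
    Closing uses a flat ``closing_kernel``-sample structuring element, merging
    post-saccadic overshoot into the saccade.
    """
    if not rec.valid.any():
        raise ValueError("recording has no valid samples")
    v = angular_velocity(rec)
    vv = v[rec.valid]
    thresh = float(np.mean(vv) + n_sd * np.std(vv))
    mask = v > thresh
    return ndimage.binary_closing(mask, structure=np.ones(closing_kernel, bool))


def fixation_onset(rec: GazeRecording, saccade_onset: float,
                   velocity: np.ndarray | None = None) -> tuple[float, bool]:
    """Place fixation onset after a saccade by the 70th-percentile rule.

    The percentile is computed from speeds within [onset - 33 ms,
    onset + 120 ms]; fixation onset is the first sample at which the speed,
    having passed its post-onset peak, drops strictly under that
    percentile. (Scanning from the saccade onset itself would fire while
    the speed is still rising through the percentile.)

    Returns ``(time, ok)``; ``ok`` is False when no such drop occurs in the
    window, in which case the time of the last window sample is returned
    and the event should be flagged ``quality_ok=False``.
    """
    v = angular_velocity(rec) if velocity is None else velocity
    lo = saccade_onset - FIX_WIN_BEFORE
    hi = saccade_onset + FIX_WIN_AFTER
    in_win = (rec.t >= lo) & (rec.t <= hi)
    if not in_win.any():
        raise ValueError("percentile window falls outside the recording")
    p70 = np.percentile(v[in_win], 70)
    after = np.flatnonzero((rec.t > saccade_onset) & in_win)
    if not len(after):
        return float(rec.t[in_win][-1]), False
    peak = after[int(np.argmax(v[after]))]
    for i in after[after >= peak]:
        if v[i] < p70:
            return float(rec.t[i]), True
    return float(rec.t[in_win][-1]), False


def saccade_amplitude(rec: GazeRecording, saccade_onset: float,
                      saccade_offset: float) -> float:
    """Euclidean norm of the gaze displacement between onset and offset."""
    i0 = int(np.searchsorted(rec.t, saccade_onset))
    i1 = int(np.searchsorted(rec.t, saccade_offset))
    i0 = min(i0, len(rec) - 1)
    i1 = min(i1, len(rec) - 1)
    return float(np.hypot(rec.x[i1] - rec.x[i0], rec.y[i1] - rec.y[i0]))


def _finalize_events(rows: list[tuple[float, float, float, float]],
                     rec: GazeRecording,
                     quality: list[bool] | None = None) -> pd.DataFrame:
    if not rows:
        return empty_event_table()
    df = pd.DataFrame(rows, columns=["saccade_onset", "saccade_offset",
                                     "fixation_onset", "amplitude"])
    nxt = df["saccade_onset"].shift(-1)
    dur = nxt - df["fixation_onset"]
    # last fixation: runs to the end of the recording
    dur.iloc[-1] = rec.t[-1] - df["fixation_onset"].iloc[-1]
    df["fixation_duration"] = dur
    df["quality_ok"] = quality if quality is not None else True
    return df[EVENT_COLUMNS]


def detect_events(rec: GazeRecording, detector: str = "sd",
                  exclusions: bool = True) -> pd.DataFrame:
    """Full event-detection pipeline -> EyeEventTable.

    ``detector="thresholds"``: raw trace, velocity+acceleration thresholds.
    ``detector="sd"``: median-filter smoothing, 2-SD mask with closing, then
    the 70th-percentile fixation-onset rule per saccade.
    """
    if detector == "thresholds":
        events = detect_saccades_thresholds(rec)
    elif detector == "sd":
        sm = smooth_gaze(rec)
        v = angular_velocity(sm)
        mask = detect_saccades_sd(sm)
        rows, quality = [], []
        for i0, i1 in _runs(mask):
            j0 = max(i0 - 1, 0)
            onset = sm.t[j0]
            offset = sm.t[i1 - 1]
            try:
                fo, ok = fixation_onset(sm, onset, velocity=v)
            except ValueError:
                continue
            fo = max(fo, offset)
            amp = saccade_amplitude(sm, onset, offset)
            rows.append((onset, offset, fo, amp))
            quality.append(ok)
        events = _finalize_events(rows, sm, quality)
    else:
        raise ValueError(f"unknown detector {detector!r}")
    if exclusions:
        events = apply_exclusions(events, rec)
    return events


def apply_exclusions(events: pd.DataFrame, rec: GazeRecording) -> pd.DataFrame:
    """Drop saccades near low-quality data and saccades after short fixations.

    Rule (i): any invalid sample within +/- 83 ms of the saccade interval
    removes the saccade. Rule (ii): a preceding fixation shorter than 110 ms
    removes the following saccade. The operation is idempotent.
    """
    if events.empty:
        return events.copy()
    ev = events.sort_values("saccade_onset").reset_index(drop=True)
    bad_t = rec.t[~rec.valid]
    keep = np.ones(len(ev), dtype=bool)
    for i, row in ev.iterrows():
        if bad_t.size and np.any(
            (bad_t >= row.saccade_onset - LOW_QUALITY_MARGIN)
            & (bad_t <= row.saccade_offset + LOW_QUALITY_MARGIN)
        ):
            keep[i] = False
            continue
        if i > 0:
            prev_fix = row.saccade_onset - ev.loc[i - 1, "fixation_onset"]
            if prev_fix < MIN_FIXATION:
                keep[i] = False
    return ev[keep].reset_index(drop=True)


def match_events(detected: pd.DataFrame, true_onsets: np.ndarray,
                 tol: float = 0.010) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one match of detected saccade onsets to true onsets.

    Returns ``(det_idx, true_idx)`` of matched pairs with |dt| <= tol.
    Used for sensitivity / onset-error scoring against generator truth.
    """
    det = detected["saccade_onset"].to_numpy()
    used = np.zeros(len(true_onsets), bool)
    di, ti = [], []
    for i, t0 in enumerate(det):
        if len(true_onsets) == 0:
            break
        j = int(np.argmin(np.abs(true_onsets - t0)))
        if not used[j] and abs(true_onsets[j] - t0) <= tol:
            used[j] = True
            di.append(i)
            ti.append(j)
    return np.asarray(di, int), np.asarray(ti, int)


def read_gaze_csv(path, fs: float | None = None) -> GazeRecording:
    return GazeRecording.from_frame(pd.read_csv(path), fs=fs)


def write_gaze_csv(rec: GazeRecording, path) -> None:
    rec.to_frame().to_csv(path, index=False)
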