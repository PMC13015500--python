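"""Banded-ridge temporal response function (TRF) encoding models.

Eye-movement events enter the model as unit pulses; per-event features enter
as scaled pulses (or as cubic B-spline basis pulses for nonlinear effects).
Every regressor column is expanded over a window of time lags, and the
stacked design predicts the neural signal channel-wise. Each feature space
("band") receives its own ridge penalty lambda, chosen by a sequential
cross-validated search in a fixed hierarchy order so that variance shared
between features is attributed to the band added first. The cross-validated
Pearson correlation r of successive stages yields the per-feature increment
delta_r, the quantity on which all downstream statistics operate.

Conventions (documented, fixed):

* The weight at lag tau multiplies the regressor at t - tau, so a pulse at
  time e contributes to the prediction over [e + t_min, e + t_max], with
  inclusive endpoints and zero padding at the edges.
* Event times are rounded to samples with round-half-even.
* Feature values are z-scored with training-fold statistics (implemented as
  an exact affine re-parameterization of the design, so the cached Gram
  matrix can be reused across folds); pulses stay unit height; B-spline
  basis columns are left unscaled (they form a partition of unity).
* The response mean and the design-column means are removed per training
  fold (an implicit intercept without an intercept column; pulse regressors
  otherwise leak the event-rate DC component into the TRFs).
* lambda ties are broken toward the smallest lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, linalg

SCALP_LAMBDA_GRID = np.logspace(-2, 5, 15)
IEEG_LAMBDA_GRID = np.logspace(0, 3, 10)
#: Nine-band hierarchy order used throughout the analyses.
DEFAULT_HIERARCHY = [
    "saccade_onset",
    "fixation_onset",
    "amplitude",
    "luminance",
    "dluminance",
    "spectrum_slope",
    "dspectrum_slope",
    "optic_flow",
    "novelty",
]


@dataclass(frozen=True)
class LagWindow:
    """Lag range [t_min, t_max] seconds relative to the event, at rate fs."""

    t_min: float
    t_max: float
    fs: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")

    @property
    def lag_samples(self) -> np.ndarray:
        return np.arange(int(round(self.t_min * self.fs)),
                         int(round(self.t_max * self.fs)) + 1)

    @property
    def lag_times(self) -> np.ndarray:
        return self.lag_samples / self.fs

    @property
    def n_lags(self) -> int:
        return len(self.lag_samples)


SCALP_WINDOW = LagWindow(-0.2, 0.6, 100.0)
IEEG_WINDOW = LagWindow(-0.5, 1.0, 100.0)


@dataclass
class RegressorSpec:
    """One feature space of the hierarchy.

    ``transform``: "impulse" (unit pulses, no values), "linear" (value-scaled
    pulses) or "bspline" (5 cubic B-spline basis columns with quantile knots).
    ``alignment`` names the event time used ("saccade_onset" or
    "fixation_onset"); the impulse band with that alignment also serves as
    the centering column for fold-wise feature z-scoring.
    """

    name: str
    alignment: str = "fixation_onset"
    transform: str = "linear"
    n_splines: int = 5


@dataclass
class Band:
    """A realized regressor band: event times plus optional per-event values."""

    name: str
    times: np.ndarray
    values: np.ndarray | None = None
    transform: str = "impulse"
    alignment: str = "fixation_onset"
    n_splines: int = 5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if self.values is not None:
            self.values = np.asarray(self.values, float)
            if len(self.values) != len(self.times):
                raise ValueError(f"band {self.name}: values/times length mismatch")
        if self.transform == "impulse" and self.values is not None:
            raise ValueError("impulse band carries no feature values")
        if self.transform != "impulse" and self.values is None:
            raise ValueError(f"band {self.name}: {self.transform} needs values")


def impulse_train(times: np.ndarray, duration: float, fs: float,
                  values: np.ndarray | None = None) -> np.ndarray:
    """Pulse train: unit (or value-scaled) pulse at the nearest sample.

    Rounding is round-half-even at the analysis rate. Events with NaN values
    are dropped (missing feature convention).
    """
    n = int(round(duration * fs))
    times = np.asarray(times, float)
    if values is not None:
        values = np.asarray(values, float)
        keep = np.isfinite(values)
        times, values = times[keep], values[keep]
    idx = np.rint(times * fs).astype(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("event times fall outside the recording")
    col = np.zeros(n)
    np.add.at(col, idx, 1.0 if values is None else values)
    return col


def bspline_expand(values: np.ndarray, n: int = 5, degree: int = 3,
                   knots: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis evaluated at each value.

    Returns ``(basis, knot_vector)`` where basis is (n_events, n). Interior
    knots sit at quantiles of the observed values; boundary knots (the 0th
    and 100th percentile) are repeated ``degree+1`` times (clamped spline).
    The basis sums to 1 at every point inside the span.
    """
    v = np.asarray(values, float)
    finite = v[np.isfinite(v)]
    if knots is None:
        qs = np.linspace(0, 1, n - degree + 1)
        kq = np.quantile(finite, qs)
        if len(np.unique(kq)) < len(kq):
            raise ValueError("too few distinct values to place quantile knots")
        knots = np.concatenate([[kq[0]] * degree, kq, [kq[-1]] * degree])
    vc = np.clip(v, knots[0], knots[-1])
    basis = np.empty((len(v), n))
    ok = np.isfinite(vc)
    basis[~ok] = np.nan
    if ok.any():
        dm = interpolate.BSpline.design_matrix(vc[ok], knots, degree).toarray()
        basis[ok] = dm
    return basis, knots


@dataclass
class _BandCols:
    name: str
    sl: slice                 # columns of this band in the design
    n_base: int               # base columns (1, or n_splines)
    transform: str
    alignment: str
    event_idx: np.ndarray     # sample index per retained event
    values: np.ndarray | None  # raw values per retained event (linear bands)
    knots: np.ndarray | None = None


@dataclass
class DesignInfo:
    bands: list[_BandCols]
    lag_window: LagWindow
    duration: float

    @property
    def n_cols(self) -> int:
        return self.bands[-1].sl.stop if self.bands else 0

    def band(self, name: str) -> _BandCols:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def stage_stop(self, k: int) -> int:
        return self.bands[k].sl.stop


def _lagged(col: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    T = len(col)
    out = np.zeros((T, len(lag_samples)))
    for j, s in enumerate(lag_samples):
        if s >= 0:
            out[s:, j] = col[:T - s] if s else col
        else:
            out[:s, j] = col[-s:]
    return out


def build_design(bands: list[Band], duration: float,
                 lag_window: LagWindow) -> tuple[np.ndarray, DesignInfo]:
    """Stack lag-expanded regressor bands into one design matrix.

    Column order is band-major, then base column, then lag; each band
    occupies a contiguous block recorded in the returned :class:`DesignInfo`.
    """
    fs = lag_window.fs
    n = int(round(duration * fs))
    lags = lag_window.lag_samples
    blocks, infos, start = [], [], 0
    for band in bands:
        t = band.times
        if band.transform == "impulse":
            base = [impulse_train(t, duration, fs)]
            vals, keep = None, np.ones(len(t), bool)
        elif band.transform == "linear":
            keep = np.isfinite(band.values)
            base = [impulse_train(t[keep], duration, fs, band.values[keep])]
            vals = band.values[keep]
        elif band.transform == "bspline":
            keep = np.isfinite(band.values)
            basis, knots = bspline_expand(band.values[keep], n=band.n_splines)
            base = [impulse_train(t[keep], duration, fs, basis[:, j])
                    for j in range(band.n_splines)]
            vals = band.values[keep]
        else:
            raise ValueError(f"unknown transform {band.transform!r}")
        cols = np.concatenate([_lagged(c, lags) for c in base], axis=1)
        idx = np.rint(t[keep] * fs).astype(int)
        stop = start + cols.shape[1]
        infos.append(_BandCols(
            name=band.name, sl=slice(start, stop), n_base=len(base),
            transform=band.transform, alignment=band.alignment,
            event_idx=idx, values=vals,
            knots=knots if band.transform == "bspline" else None))
        blocks.append(cols)
        start = stop
    X = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0))
    return X, DesignInfo(infos, lag_window, duration)


def _penalty_vector(info: DesignInfo, lambda_per_band: dict[str, float],
                    upto: int | None = None) -> np.ndarray:
    bands = info.bands if upto is None else info.bands[:upto]
    pen = np.empty(bands[-1].sl.stop)
    for b in bands:
        lam = lambda_per_band[b.name]
        if lam <= 0:
            raise ValueError("lambda must be positive")
        pen[b.sl] = lam
    return pen


def ridge_fit(X: np.ndarray, y: np.ndarray, lambda_per_band: dict[str, float],
              info: DesignInfo) -> np.ndarray:
    """Exact banded-ridge solution.

    Minimizes ``||y - Xw||^2 + sum_b lambda_b ||w_b||^2`` via the normal
    equations ``(X'X + diag(lambda)) w = X'y`` with a Cholesky solve. ``y``
    may be (T,) or (T, C); returns weights (P,) or (P, C).
    """
    pen = _penalty_vector(info, lambda_per_band)
    G = X.T @ X
    G[np.diag_indices_from(G)] += pen
    try:
        c = linalg.cho_factor(G)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "normal equations singular; increase lambda") from e
    return linalg.cho_solve(c, X.T @ y)


def _solve(G: np.ndarray, g: np.ndarray, pen: np.ndarray) -> np.ndarray:
    A = G.copy()
    A[np.diag_indices_from(A)] += pen
    try:
        return linalg.cho_solve(linalg.cho_factor(A), g)
    except (np.linalg.LinAlgError, linalg.LinAlgError) as e:
        raise np.linalg.LinAlgError(
            "normal equations singular at this lambda; use a larger lambda") from e


def _pearson_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = np.einsum("tc,tc->c", a, b)
    den = np.sqrt(np.einsum("tc,tc->c", a, a) * np.einsum("tc,tc->c", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[~np.isfinite(r)] = np.nan
    return r


def _zscore_transform(info: DesignInfo, train_mask_events: dict[str, np.ndarray]
                      ) -> np.ndarray:
    """Dense affine map T with X_z = X_base @ T for fold-wise z-scoring.

    For a linear band, the z-scored pulse column at lag tau equals
    (raw column - mu * impulse column of the alignment band) / sigma, which
    is linear in the base columns; T encodes exactly that. Impulse and
    spline columns pass through unchanged.
    """
    P = info.n_cols
    T = np.eye(P)
    L = info.lag_window.n_lags
    imp = {b.alignment: b for b in info.bands if b.transform == "impulse"}
    for b in info.bands:
        if b.transform != "linear":
            continue
        mask = train_mask_events[b.name]
        v = b.values[mask]
        mu = float(v.mean()) if len(v) else 0.0
        sd = float(v.std()) if len(v) else 1.0
        if sd < 1e-12:
            sd = 1.0
        cols = np.arange(b.sl.start, b.sl.stop)
        T[cols, cols] = 1.0 / sd
        anchor = imp.get(b.alignment)
        if anchor is not None:
            T[np.arange(anchor.sl.start, anchor.sl.stop), cols] = -mu / sd
    return T


def make_trial_slices(n_samples: int, n_trials: int) -> list[tuple[int, int]]:
    """Split a recording into contiguous equal trials (chapters/segments)."""
    edges = np.linspace(0, n_samples, n_trials + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _make_folds(trial_slices, cv) -> list[list[tuple[int, int]]]:
    if cv == "loto":
        return [[sl] for sl in trial_slices]
    if isinstance(cv, tuple) and cv[0] == "kfold":
        k = cv[1]
        groups = [[] for _ in range(k)]
        for i, sl in enumerate(trial_slices):
            groups[i % k].append(sl)
        return [g for g in groups if g]
    raise ValueError(f"unknown cv scheme {cv!r}")


@dataclass
class TRFModel:
    """Fitted banded-ridge TRF model (weights in z-scored feature units)."""

    weights: np.ndarray                 # (P, C), z coordinates
    base_weights: np.ndarray            # (P, C), raw-regressor coordinates
    lambda_per_band: dict[str, float]
    lag_window: LagWindow
    cv_scheme: object
    feature_order: list[str]
    info: DesignInfo
    y_mean: np.ndarray
    col_means: np.ndarray = None
    lambda_grid: np.ndarray = field(default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = X if self.col_means is None else X - self.col_means
        return Xc @ self.base_weights + self.y_mean


@dataclass
class EncodingResult:
    """Cross-validated stage correlations and per-feature increments."""

    stage_names: list[str]
    r_per_stage: np.ndarray     # (C, S), fold-averaged
    r_per_fold: np.ndarray      # (F, C, S)
    delta_r: np.ndarray         # (C, S-1): r[k] - r[k-1] for k >= 1

    def delta_r_for(self, name: str) -> np.ndarray:
        k = self.stage_names.index(name)
        if k == 0:
            raise ValueError("first stage has no increment")
        return self.delta_r[:, k - 1]

    def delta_r_per_fold(self, name: str) -> np.ndarray:
        k = self.stage_names.index(name)
        return self.r_per_fold[:, :, k] - self.r_per_fold[:, :, k - 1]


def fit_hierarchy(
    bands: list[Band],
    y: np.ndarray,
    lag_window: LagWindow,
    trial_slices: list[tuple[int, int]] | None = None,
    lambda_grid: np.ndarray = SCALP_LAMBDA_GRID,
    cv: object = "loto",
    duration: float | None = None,
) -> tuple[TRFModel, EncodingResult]:
    """Sequential banded-ridge fit over a band hierarchy.

    ``y`` is (C, T) or (T,). For each band in order, its lambda is swept over
    ``lambda_grid`` with all previously frozen lambdas held fixed, the value
    maximizing the mean cross-validated r (over folds and channels) is
    frozen, and the next band is appended. The stagewise held-out r gives
    delta_r. The returned model is refit on all data at the frozen lambdas.
    """
    Y = np.atleast_2d(np.asarray(y, float))
    C, n = Y.shape
    Y = Y.T  # (T, C)
    fs = lag_window.fs
    if duration is None:
        duration = n / fs
    X, info = build_design(bands, duration, lag_window)
    if X.shape[0] != n:
        raise ValueError("response length does not match design duration")
    if trial_slices is None:
        trial_slices = make_trial_slices(n, 2)
    folds = _make_folds(trial_slices, cv)
    F = len(folds)
    if F < 2:
        raise ValueError("need at least 2 folds")

    G = X.T @ X
    g = X.T @ Y
    s = X.sum(axis=0)
    ysum = Y.sum(axis=0)

    fold_data = []
    sample_fold = np.full(n, -1, int)
    for fi, sls in enumerate(folds):
        for a, b in sls:
            sample_fold[a:b] = fi
    for fi, sls in enumerate(folds):
        rows = np.concatenate([np.arange(a, b) for a, b in sls])
        Xte = X[rows]
        Yte = Y[rows]
        Gte = Xte.T @ Xte
        gte = Xte.T @ Yte
        n_tr = n - len(rows)
        s_tr = s - Xte.sum(axis=0)
        # center both response and design columns over the training rows
        Gtr = (G - Gte) - np.outer(s_tr, s_tr) / n_tr
        ybar = (ysum - Yte.sum(axis=0)) / n_tr
        gtr = (g - gte) - np.outer(s_tr, ybar)
        masks = {b_.name: sample_fold[b_.event_idx] != fi
                 for b_ in info.bands if b_.transform == "linear"}
        Tm = _zscore_transform(info, masks)
        Gz = Tm.T @ Gtr @ Tm
        gz = Tm.T @ gtr
        fold_data.append((Gz, gz, Xte, Yte, Tm))

    frozen: dict[str, float] = {}
    order = [b.name for b in info.bands]
    S = len(order)
    r_fold = np.full((F, C, S), np.nan)
    for k, name in enumerate(order):
        stop = info.stage_stop(k)
        best_score, best_lam, best_r = -np.inf, None, None
        for lam in lambda_grid:
            trial = dict(frozen, **{name: float(lam)})
            pen = _penalty_vector(info, trial, upto=k + 1)
            r_f = np.empty((F, C))
            for fi, (Gz, gz, Xte, Yte, Tm) in enumerate(fold_data):
                w = _solve(Gz[:stop, :stop], gz[:stop], pen)
                wb = Tm[:stop, :stop] @ w
                r_f[fi] = _pearson_cols(Xte[:, :stop] @ wb, Yte)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                score = np.nanmean(r_f)
            if np.isnan(score):
                raise RuntimeError("all CV folds degenerate (zero-variance response)")
            if score > best_score + 1e-15:
                best_score, best_lam, best_r = score, float(lam), r_f
        frozen[name] = best_lam
        r_fold[:, :, k] = best_r

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_stage = np.nanmean(r_fold, axis=0).reshape(C, S)
    delta = np.diff(r_stage, axis=1)

    masks_all = {b_.name: np.ones(len(b_.event_idx), bool)
                 for b_ in info.bands if b_.transform == "linear"}
    Tm = _zscore_transform(info, masks_all)
    ybar = Y.mean(axis=0)
    gz_full = Tm.T @ (g - np.outer(s, ybar))
    Gz_full = Tm.T @ (G - np.outer(s, s) / n) @ Tm
    pen = _penalty_vector(info, frozen)
    w = _solve(Gz_full, gz_full, pen)
    model = TRFModel(
        weights=w, base_weights=Tm @ w, lambda_per_band=frozen,
        lag_window=lag_window, cv_scheme=cv, feature_order=order,
        info=info, y_mean=ybar, col_means=s / n,
        lambda_grid=np.asarray(lambda_grid))
    result = EncodingResult(order, r_stage, r_fold, delta)
    return model, result


def sequential_lambda_search(bands, y, lag_window, trial_slices=None,
                             lambda_grid=SCALP_LAMBDA_GRID, cv="loto"):
    """Frozen per-band lambdas plus the stagewise CV r used for delta_r."""
    model, result = fit_hierarchy(bands, y, lag_window, trial_slices,
                                  lambda_grid, cv)
    return model.lambda_per_band, result


def crossval_delta_r(bands, y, lag_window, trial_slices=None,
                     lambda_grid=SCALP_LAMBDA_GRID, cv="loto") -> EncodingResult:
    """Per-channel, per-stage held-out r and per-feature delta_r."""
    _, result = fit_hierarchy(bands, y, lag_window, trial_slices,
                              lambda_grid, cv)
    return result


def extract_trf(model: TRFModel, band: str,
                at_values: np.ndarray | None = None) -> np.ndarray:
    """Weight-vs-lag curves for one band.

    Returns (C, n_base, L) in z-scored feature units. For a B-spline band
    with ``at_values`` given, returns instead the reconstructed TRF at each
    query value: (C, len(at_values), L).
    """
    b = model.info.band(band)
    L = model.lag_window.n_lags
    C = model.weights.shape[1]
    w = model.weights[b.sl].reshape(b.n_base, L, C).transpose(2, 0, 1)
    if at_values is not None:
        if b.transform != "bspline":
            raise ValueError("at_values only applies to bspline bands")
        basis, _ = bspline_expand(np.asarray(at_values, float),
                                  n=b.n_base, knots=b.knots)
        return np.einsum("vk,ckl->cvl", basis, w)
    return w


def bands_from_events(events, features: dict[str, np.ndarray],
                      specs: list[RegressorSpec]) -> list[Band]:
    """Realize a band list from an EyeEventTable and a feature-value mapping."""
    out = []
    for sp in specs:
        times = events[sp.alignment].to_numpy(float)
        if sp.transform == "impulse":
            out.append(Band(sp.name, times, None, "impulse", sp.alignment))
        else:
            out.append(Band(sp.name, times, np.asarray(features[sp.name], float),
                            sp.transform, sp.alignment, sp.n_splines))
    return out


def compare_alignments(events, features: dict[str, np.ndarray], y,
                       lag_window: LagWindow, trial_slices=None,
                       lambda_grid=SCALP_LAMBDA_GRID, cv="loto") -> dict:
    """Saccade- vs fixation-locked model comparison.

    For each alignment, fits the three-stage hierarchy onset ->
    onset+amplitude -> onset+amplitude+novelty with every band locked to
    that alignment, and returns the stagewise r and delta_r for both.
    """
    out = {}
    for align in ("saccade_onset", "fixation_onset"):
        specs = [
            RegressorSpec("onset", align, "impulse"),
            RegressorSpec("amplitude", align, "linear"),
            RegressorSpec("novelty", align, "linear"),
        ]
        bands = bands_from_events(events, features, specs)
        _, res = fit_hierarchy(bands, y, lag_window, trial_slices,
                               lambda_grid, cv)
        out[align] = res
    return out
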