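"""Foveal fixation patches and the per-fixation visual feature battery.

A fixation patch subtends 5 degrees of visual angle around the gaze point
(roughly foveal vision) and is resampled to a nominal resolution. From each
patch we compute luminance/color statistics (CIE L*a*b*, D65), contrast and
energy measures, the amplitude-spectrum slope (the 1/f exponent of natural
image statistics), texture and shape descriptors, and center-surround
saliency values at the fixated location. Semantic novelty is the cosine
distance between embeddings of the pre- and post-saccadic patches; the
default encoder is a seeded random-projection toy encoder (deterministic and
download-free), and any pretrained encoder can be plugged in as a callable.

Grayscale throughout means the L* channel of CIE L*a*b*, scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import kurtosis as _kurtosis, skew as _skew
from skimage import color, feature, filters, measure, transform
from skimage.filters import rank
from skimage.transform import (hough_circle, hough_circle_peaks,
                               probabilistic_hough_line)

PATCH_FOV_DEG = 5.0
ENCODER_INPUT = 224


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor geometry; converts pixels to degrees of visual angle."""

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self):
        for v in (self.width_px, self.height_px, self.width_cm,
                  self.height_cm, self.viewing_distance_cm):
            if v <= 0:
                raise ValueError("screen geometry values must be positive")

    @property
    def pixels_per_degree(self) -> float:
        px_per_cm = self.width_px / self.width_cm
        return 2 * self.viewing_distance_cm * np.tan(np.deg2rad(0.5)) * px_per_cm


@dataclass
class FixationPatch:
    pixels: np.ndarray           # (res, res, 3) float in [0, 1]
    fov_deg: float = PATCH_FOV_DEG
    fixation_index: int = -1
    valid: bool = True


@dataclass
class Embedding:
    vector: np.ndarray
    encoder_id: str


def extract_patch(frame: np.ndarray, gaze_xy: tuple[float, float],
                  geom: ScreenGeometry, out_res: int = 100,
                  fill_tolerance: float = 0.2) -> FixationPatch:
    """Crop the 5-degree patch centered on gaze and resample to out_res.

    Off-screen pixels are filled with mid-gray; the patch is flagged invalid
    if more than ``fill_tolerance`` of its area is filled (or gaze is off
    screen entirely).
    """
    frame = np.asarray(frame, float)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    h, w = frame.shape[:2]
    gx, gy = gaze_xy
    side = int(round(PATCH_FOV_DEG * geom.pixels_per_degree))
    half = side // 2
    cx, cy = int(round(gx)), int(round(gy))
    patch = np.full((side, side, 3), 0.5)
    off_screen = not (0 <= gx < w and 0 <= gy < h)
    x0, x1 = cx - half, cx - half + side
    y0, y1 = cy - half, cy - half + side
    sx0, sx1 = max(x0, 0), min(x1, w)
    sy0, sy1 = max(y0, 0), min(y1, h)
    filled = 1.0
    if sx1 > sx0 and sy1 > sy0:
        patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = frame[sy0:sy1, sx0:sx1]
        filled = 1.0 - (sx1 - sx0) * (sy1 - sy0) / side ** 2
    valid = (not off_screen) and filled <= fill_tolerance
    out = transform.resize(patch, (out_res, out_res), order=3,
                           anti_aliasing=True, preserve_range=True)
    return FixationPatch(np.clip(out, 0, 1), valid=valid)


def _as_rgb(patch) -> np.ndarray:
    p = patch.pixels if isinstance(patch, FixationPatch) else np.asarray(patch, float)
    if p.ndim == 2:
        p = np.repeat(p[..., None], 3, axis=-1)
    return p


def _lightness(rgb: np.ndarray) -> np.ndarray:
    """L* channel scaled to [0, 1]."""
    return color.rgb2lab(rgb)[..., 0] / 100.0


def luminance_color_features(patch) -> dict[str, float]:
    """Mean/skew/kurtosis of L*, mean a*, mean b*, mean saturation, hue diversity.

    Hue diversity is the Shannon entropy of a 16-bin hue histogram over
    pixels with saturation > 0.1. A constant patch has skew and kurtosis 0
    by convention (zero variance).
    """
    rgb = _as_rgb(patch)
    lab = color.rgb2lab(rgb)
    L = lab[..., 0].ravel()
    const = L.std() < 1e-12
    hsv = color.rgb2hsv(rgb)
    sat = hsv[..., 1].ravel()
    hue = hsv[..., 0].ravel()
    sel = sat > 0.1
    if sel.any():
        hist, _ = np.histogram(hue[sel], bins=16, range=(0, 1))
        p = hist / hist.sum()
        p = p[p > 0]
        hue_div = float(-(p * np.log2(p)).sum())
    else:
        hue_div = 0.0
    return {
        "luminance": float(L.mean()),
        "luminance_skew": 0.0 if const else float(_skew(L)),
        "luminance_kurtosis": 0.0 if const else float(_kurtosis(L)),
        "a_star": float(lab[..., 1].mean()),
        "b_star": float(lab[..., 2].mean()),
        "saturation": float(sat.mean()),
        "hue_diversity": hue_div,
    }


def contrast_energy_features(patch) -> dict[str, float]:
    """Michelson/RMS contrast, sharpness, oriented energies, entropies, HOG.

    Vertical energy is the mean squared response of the vertical-edge
    (horizontal-derivative) Sobel filter, and vice versa; orientation bias
    is (V - H)/(V + H), 0 for a constant patch by convention.
    """
    g = _lightness(_as_rgb(patch))
    mx, mn = g.max(), g.min()
    michelson = 0.0 if mx + mn == 0 else (mx - mn) / (mx + mn)
    gy, gx = np.gradient(g)
    sharp = float(np.hypot(gx, gy).mean())
    v_energy = float((filters.sobel_v(g) ** 2).mean())
    h_energy = float((filters.sobel_h(g) ** 2).mean())
    denom = v_energy + h_energy
    bias = 0.0 if denom < 1e-20 else (v_energy - h_energy) / denom
    g8 = (np.clip(g, 0, 1) * 255).astype(np.uint8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        local_ent = float(rank.entropy(g8, np.ones((7, 7), bool)).mean())
    hog_vec = feature.hog(g, orientations=8, pixels_per_cell=(16, 16),
                          cells_per_block=(1, 1), feature_vector=True)
    return {
        "michelson_contrast": float(michelson),
        "rms_contrast": float(g.std()),
        "sharpness": sharp,
        "vertical_energy": v_energy,
        "horizontal_energy": h_energy,
        "orientation_bias": float(bias),
        "global_entropy": float(measure.shannon_entropy(g8)),
        "local_entropy": local_ent,
        "hog_energy": float(np.linalg.norm(hog_vec)),
    }


def spectrum_slope(patch, ppd: float, f_lo: float = 0.1, f_hi: float = 10.0,
                   n_bins: int = 8) -> float:
    """Negative slope of log amplitude vs log spatial frequency.

    The 2-D Fourier magnitude of L* is averaged within 8 log-spaced radial
    bins spanning 0.1-10 cycles/degree (DC excluded; bin = [edge_i,
    edge_{i+1})), and an ordinary least-squares line is fit to log magnitude
    vs log bin center. Empty bins are dropped with a warning; fewer than 3
    populated bins is an error.
    """
    g = _lightness(_as_rgb(patch))
    if min(g.shape) < 16:
        raise ValueError("patch too small for spectrum slope")
    if ppd <= 0:
        raise ValueError("ppd must be positive")
    F = np.abs(np.fft.fft2(g))
    fy = np.fft.fftfreq(g.shape[0])[:, None] * ppd
    fx = np.fft.fftfreq(g.shape[1])[None, :] * ppd
    fr = np.hypot(fy, fx)
    edges = np.geomspace(f_lo, f_hi, n_bins + 1)
    mags, cents = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (fr >= lo) & (fr < hi)
        if sel.any():
            mags.append(F[sel].mean())
            cents.append(np.sqrt(lo * hi))
    if len(mags) < n_bins:
        warnings.warn(f"{n_bins - len(mags)} empty frequency bins dropped")
    if len(mags) < 3:
        raise ValueError("fewer than 3 populated frequency bins")
    slope, _ = np.polyfit(np.log10(cents), np.log10(mags), 1)
    return float(-slope)


def texture_shape_features(patch) -> dict[str, float]:
    """LBP energy, edge densities, Hough counts, GLCM stats, blob stats.

    Edge density is the fraction of pixels whose Scharr/Sobel magnitude
    exceeds its Otsu threshold. GLCM uses 32 gray levels, offset 1 px, four
    directions averaged. Blobs come from thresholding strictly above the
    mean gray level (a constant patch therefore has 0 blobs).
    """
    g = _lightness(_as_rgb(patch))
    lbp = feature.local_binary_pattern(
        (g * 255).astype(np.uint8), P=8, R=1, method="uniform")
    hist, _ = np.histogram(lbp, bins=10, range=(0, 10))
    p = hist / hist.sum()
    out = {"lbp_energy": float((p ** 2).sum())}
    for name, fn in (("scharr_edge_density", filters.scharr),
                     ("sobel_edge_density", filters.sobel)):
        mag = fn(g)
        if mag.max() <= 0:
            out[name] = 0.0
        else:
            out[name] = float((mag > filters.threshold_otsu(mag)).mean())
    edges_img = feature.canny(g, sigma=1.0)
    side = g.shape[0]
    lines = probabilistic_hough_line(edges_img, threshold=10,
                                     line_length=max(10, side // 4),
                                     line_gap=3, rng=0)
    out["hough_line_count"] = float(len(lines))
    radii = np.linspace(side // 8, side // 3, 4).astype(int)
    accum = hough_circle(edges_img, radii)
    _, cx, cy, rr = hough_circle_peaks(accum, radii, total_num_peaks=10,
                                       threshold=0.55)
    out["hough_circle_count"] = float(len(cx))
    gq = np.clip((g * 32).astype(np.uint8), 0, 31)
    glcm = feature.graycomatrix(gq, distances=[1],
                                angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                                levels=32, symmetric=True, normed=True)
    for prop, key in (("contrast", "glcm_contrast"),
                      ("homogeneity", "glcm_homogeneity"),
                      ("correlation", "glcm_correlation"),
                      ("ASM", "glcm_asm")):
        out[key] = float(feature.graycoprops(glcm, prop).mean())
    binary = g > g.mean()
    labels = measure.label(binary)
    regions = measure.regionprops(labels)
    out["blob_count"] = float(len(regions))
    out["blob_eccentricity"] = (float(np.mean([r.eccentricity for r in regions]))
                                if regions else 0.0)
    out["blob_solidity"] = (float(np.mean([r.solidity for r in regions]))
                            if regions else 0.0)
    return out


def _blur(img: np.ndarray, sigma: float) -> np.ndarray:
    return filters.gaussian(img, sigma=sigma, preserve_range=True)


def saliency_features(frame: np.ndarray, gaze_xy: tuple[float, float],
                      deepgaze: object | None = None) -> dict[str, float]:
    """Center-surround saliency values at the fixated location.

    A lightweight Itti-Koch-style bank: intensity, red-green and blue-yellow
    opponency at 6 center-surround scale pairs each (Gaussian scales
    sigma = 2^c vs 2^s, c in {1,2,3}, s = c + {2,3}), and 4 orientation
    values (Gabor energy contrasts averaged over the 6 scale pairs). An
    external DeepGaze-style callable may be injected; absent, the column is
    reported missing (NaN).
    """
    frame = np.asarray(frame, float)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    inten = frame.mean(-1)
    rg = r - g
    by = b - (r + g) / 2
    gy, gx = int(round(gaze_xy[1])), int(round(gaze_xy[0]))
    gy = np.clip(gy, 0, frame.shape[0] - 1)
    gx = np.clip(gx, 0, frame.shape[1] - 1)
    pairs = [(c, c + d) for c in (1, 2, 3) for d in (2, 3)]
    out: dict[str, float] = {}
    for name, img in (("intensity", inten), ("rg", rg), ("by", by)):
        for c, s in pairs:
            cs = np.abs(_blur(img, 2.0 ** c) - _blur(img, 2.0 ** s))
            out[f"sal_{name}_{c}_{s}"] = float(cs[gy, gx])
    for k, theta in enumerate(np.arange(4) * np.pi / 4):
        real, imag = filters.gabor(inten, frequency=0.15, theta=theta)
        energy = np.hypot(real, imag)
        vals = [np.abs(_blur(energy, 2.0 ** c) - _blur(energy, 2.0 ** s))[gy, gx]
                for c, s in pairs]
        out[f"sal_orient_{k}"] = float(np.mean(vals))
    if deepgaze is not None:
        out["deepgaze"] = float(deepgaze(frame, gaze_xy))
    else:
        out["deepgaze"] = np.nan
    return out


def optical_flow_feature(flow_fields: np.ndarray | None,
                         flow_times: np.ndarray | None,
                         patch_box: tuple[int, int, int, int],
                         saccade_onset: float,
                         window: tuple[float, float] = (-0.250, -0.050),
                         downsample: int = 10) -> float:
    """Mean flow magnitude in the patch over the pre-saccadic window.

    ``flow_fields`` is (n_frames, H/ds, W/ds, 2) as stored (10x spatially
    downsampled); ``patch_box`` = (x0, x1, y0, y1) in full-resolution pixels.
    Frames with time in [onset - 250 ms, onset - 50 ms] contribute. Still
    images (``flow_fields`` None) return 0; a window entirely before the
    first frame returns NaN (missing).
    """
    if flow_fields is None:
        return 0.0
    flow_times = np.asarray(flow_times, float)
    lo, hi = saccade_onset + window[0], saccade_onset + window[1]
    if hi < flow_times[0]:
        return np.nan
    sel = np.flatnonzero((flow_times >= lo) & (flow_times <= hi))
    if not len(sel):
        return np.nan
    x0, x1, y0, y1 = (int(round(v / downsample)) for v in patch_box)
    x0, y0 = max(x0, 0), max(y0, 0)
    sub = flow_fields[sel, y0:max(y1, y0 + 1), x0:max(x1, x0 + 1)]
    return float(np.hypot(sub[..., 0], sub[..., 1]).mean())


class ToyEncoder:
    """Seeded random-projection encoder: a deterministic embedding stand-in.

    The 224x224 input is reduced to 32x32 grayscale, flattened, projected
    with a fixed Gaussian matrix to ``dim`` dimensions, offset by a fixed
    bias (so even a constant patch has nonzero norm), and passed through
    tanh. Similar patches map to similar embeddings; independent textures
    do not.
    """

    def __init__(self, dim: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self._W = rng.standard_normal((dim, 32 * 32)) / np.sqrt(32 * 32)
        self._b = 0.1 * rng.standard_normal(dim)
        self.encoder_id = f"toy-rp-{dim}-seed{seed}"

    def __call__(self, img224: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(np.asarray(img224, float))
        if g.ndim == 3:
            g = g.mean(-1)
        small = transform.resize(g, (32, 32), order=1, anti_aliasing=True,
                                 preserve_range=True)
        return np.tanh(self._W @ small.ravel() + self._b)


_default_encoder = None


def default_encoder() -> ToyEncoder:
    global _default_encoder
    if _default_encoder is None:
        _default_encoder = ToyEncoder()
    return _default_encoder


def embed_patch(patch, encoder=None) -> Embedding:
    """Resize to 224x224 (cubic spline) and embed with the given encoder."""
    enc = encoder or default_encoder()
    rgb = _as_rgb(patch)
    big = transform.resize(rgb, (ENCODER_INPUT, ENCODER_INPUT), order=3,
                           anti_aliasing=False, preserve_range=True)
    vec = np.asarray(enc(big), float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("encoder produced non-finite embedding")
    return Embedding(vec, getattr(enc, "encoder_id", "custom"))


def novelty(e_prev: Embedding, e_curr: Embedding) -> float:
    """Cosine distance between successive patch embeddings, in [0, 2]."""
    if e_prev.encoder_id != e_curr.encoder_id:
        raise ValueError("embeddings come from different encoders")
    a, b = e_prev.vector, e_curr.vector
    if len(a) != len(b):
        raise ValueError("embedding dimensions differ")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm embedding")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 2.0))


def patch_feature_battery(patch, ppd: float) -> dict[str, float]:
    """All per-patch features (luminance/color + contrast/energy +
    spectrum slope + texture/shape) as one flat mapping."""
    out = luminance_color_features(patch)
    out.update(contrast_energy_features(patch))
    out["spectrum_slope"] = spectrum_slope(patch, ppd)
    out.update(texture_shape_features(patch))
    return out


def feature_correlation_clustering(table: pd.DataFrame
                                   ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Pearson correlations across features, ordered by hierarchical clustering.

    Average-linkage clustering on distance 1 - |r|; returns the reordered
    correlation matrix, the leaf order, and the linkage matrix.
    Zero-variance columns are excluded with a warning.
    """
    if table.shape[1] < 2 or len(table) < 3:
        raise ValueError("need >= 2 features and >= 3 rows")
    stds = table.std()
    drop = stds[stds < 1e-15].index
    if len(drop):
        warnings.warn(f"excluding zero-variance columns: {list(drop)}")
        table = table.drop(columns=drop)
    corr = table.corr()
    dist = 1.0 - np.abs(np.nan_to_num(corr.to_numpy(), nan=0.0))
    dist = np.clip(dist, 0.0, None)   # guard rounding (|r| can exceed 1 by eps)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    ordered = corr.iloc[order, order]
    return ordered, order, link
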