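"""Statistics for encoding increments (delta_r) and TRF weights.

* hierarchical bootstrap of delta_r over nested units (participants ->
  chapters), one-sided for the improvement hypothesis;
* Benjamini-Hochberg FDR across channels/electrodes;
* spatiotemporal cluster permutation of TRF stacks (sign-flip null over
  viewings, cluster statistic = summed t over adjacency-connected
  suprathreshold samples);
* TRF peak magnitude/latency/sign, bootstrap significance of peak values,
  enhancement vs suppression classification against the baseline fixation
  response, saccadic-spike artifact channel detection, paired condition
  comparison, and per-region summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as scihier
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

N_BOOT_DEFAULT = 10_000
N_PERM_DEFAULT = 10_000


@dataclass
class PeakStats:
    magnitude: float
    latency: float
    sign: int
    modulation_class: str = "unknown"


@dataclass
class StatReport:
    p_boot: np.ndarray | None = None
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    clusters: list[dict] = field(default_factory=list)
    n_boot: int = 0
    n_perm: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p_boot": self.p_boot, "q": self.q,
                             "significant": self.significant})


def hierarchical_bootstrap(values: np.ndarray, grouping: np.ndarray,
                           n_boot: int = N_BOOT_DEFAULT, seed: int = 0,
                           alternative: str = "greater") -> np.ndarray:
    """One-sided bootstrap p-values respecting a two-level nesting.

    ``values`` is (n_units,) or (n_units, n_channels): one delta_r per lowest
    unit (chapter/segment). ``grouping`` assigns each unit to its upper unit
    (participant/viewing). Upper units are resampled with replacement, then
    lower units within each sampled upper unit. p is the fraction of
    bootstrap means <= 0 (for ``alternative="greater"``), floored at
    1/n_boot. A single upper unit degrades to an ordinary bootstrap with a
    warning.
    """
    vals = np.asarray(values, float)
    one_d = vals.ndim == 1
    if one_d:
        vals = vals[:, None]
    grouping = np.asarray(grouping)
    uppers = np.unique(grouping)
    if len(uppers) == 1:
        warnings.warn("single upper unit: falling back to one-level bootstrap")
    members = [np.flatnonzero(grouping == u) for u in uppers]
    rng = np.random.default_rng(seed)
    n_up = len(uppers)
    boot_means = np.empty((n_boot, vals.shape[1]))
    for i in range(n_boot):
        ups = rng.integers(0, n_up, n_up)
        idx = np.concatenate([
            members[u][rng.integers(0, len(members[u]), len(members[u]))]
            for u in ups])
        boot_means[i] = vals[idx].mean(axis=0)
    if alternative == "greater":
        p = (boot_means <= 0).mean(axis=0)
    elif alternative == "two-sided":
        p = 2 * np.minimum((boot_means <= 0).mean(axis=0),
                           (boot_means >= 0).mean(axis=0))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = np.clip(p, 1.0 / n_boot, 1.0)
    return p[0] if one_d and p.size == 1 else p


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q, significance mask)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rej, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rej


def _cluster_mask(mask: np.ndarray, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of a channels x lags boolean mask.

    Nodes are connected along the lag axis (temporal contiguity) and across
    channels sharing a lag when the channels are adjacent. ``neighbors`` is
    the per-channel adjacency list.
    """
    idx = np.flatnonzero(mask.ravel())
    if not len(idx):
        return []
    C, L = mask.shape
    pos = -np.ones(C * L, int)
    pos[idx] = np.arange(len(idx))
    parent = np.arange(len(idx))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    chans = idx // L
    lags = idx % L
    for k, (c, l) in enumerate(zip(chans, lags)):
        if l + 1 < L and pos[c * L + l + 1] >= 0:
            union(k, pos[c * L + l + 1])
        for c2 in neighbors[c]:
            if pos[c2 * L + l] >= 0:
                union(k, pos[c2 * L + l])
    roots = np.array([find(k) for k in range(len(idx))])
    return [idx[roots == r] for r in np.unique(roots)]


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    v = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(v))
    return np.nan_to_num(t)


def cluster_permutation(trf_stack: np.ndarray, adjacency: np.ndarray,
                        n_perm: int = N_PERM_DEFAULT,
                        cluster_alpha: float = 0.01, seed: int = 0
                        ) -> tuple[list[dict], np.ndarray]:
    """Spatiotemporal cluster permutation test with a sign-flip null.

    ``trf_stack`` is (viewings, channels, lags). Per channel x lag, a
    one-sample t against zero is thresholded at the two-sided critical value
    for ``cluster_alpha``; same-sign suprathreshold samples connected via
    channel adjacency and lag contiguity form clusters scored by summed t.
    The null distribution is the maximum |cluster sum| over ``n_perm``
    random sign flips of viewings; cluster p = (1 + #{null >= obs}) /
    (1 + n_perm).
    """
    data = np.asarray(trf_stack, float)
    V, C, L = data.shape
    if adjacency.shape != (C, C):
        raise ValueError("adjacency must be channels x channels")
    adj = np.asarray(adjacency, bool).copy()
    np.fill_diagonal(adj, False)
    neighbors = [np.flatnonzero(adj[c]) for c in range(C)]
    t_crit = sps.t.ppf(1 - cluster_alpha / 2, df=V - 1)
    flat = data.reshape(V, C * L)
    sumsq = (flat ** 2).sum(axis=0)

    def max_cluster_stat(t_map: np.ndarray) -> tuple[float, list[tuple[np.ndarray, float]]]:
        out = []
        best = 0.0
        for sign in (1, -1):
            mask = (sign * t_map) > t_crit
            if not mask.any():
                continue
            for nodes in _cluster_mask(mask, neighbors):
                s = float(t_map.ravel()[nodes].sum())
                out.append((nodes, s))
                best = max(best, abs(s))
        return best, out

    t_obs = _one_sample_t(data).reshape(C, L)
    _, obs_clusters = max_cluster_stat(t_obs)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, V))
    m_p = (flips @ flat) / V
    sd_p = np.sqrt(np.maximum(sumsq / V - m_p ** 2, 0.0) * V / (V - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_p = m_p / (sd_p / np.sqrt(V))
    t_p = np.nan_to_num(t_p)
    null_max = np.empty(n_perm)
    supra = np.abs(t_p) > t_crit
    for i in range(n_perm):
        if not supra[i].any():
            null_max[i] = 0.0
            continue
        null_max[i], _ = max_cluster_stat(t_p[i].reshape(C, L))

    clusters = []
    p_values = []
    for nodes, s in obs_clusters:
        p = (1.0 + np.sum(null_max >= abs(s))) / (1.0 + n_perm)
        clusters.append({
            "channels": np.unique(nodes // L),
            "lags": np.unique(nodes % L),
            "nodes": nodes,
            "stat": s,
            "p": float(p),
        })
        p_values.append(p)
    return clusters, np.asarray(p_values)


def trf_peak(trf: np.ndarray, lag_axis: np.ndarray) -> PeakStats:
    """Peak magnitude/latency/sign: the absolute extremum of the TRF.

    Latency is the lag of the highest peak or lowest trough (earliest on
    ties).
    """
    trf = np.asarray(trf, float)
    if trf.size == 0:
        raise ValueError("empty TRF")
    k = int(np.argmax(np.abs(trf)))
    return PeakStats(magnitude=float(np.abs(trf[k])),
                     latency=float(lag_axis[k]),
                     sign=int(np.sign(trf[k])) or 1)


def peak_significance(trf_boots: np.ndarray, peaks: list[PeakStats],
                      lag_axis: np.ndarray, alpha: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided bootstrap p of the TRF value at each channel's peak lag.

    ``trf_boots`` is (n_boot, n_channels, n_lags). p-values are FDR
    corrected across channels; returns (q, mask).
    """
    n_boot = trf_boots.shape[0]
    ps = []
    for c, pk in enumerate(peaks):
        k = int(np.argmin(np.abs(lag_axis - pk.latency)))
        reps = trf_boots[:, c, k]
        p = 2 * min((reps <= 0).mean(), (reps >= 0).mean())
        ps.append(max(p, 1.0 / n_boot))
    return fdr_bh(np.asarray(ps), alpha=alpha)


def classify_modulation(novelty_trf: np.ndarray,
                        baseline_fixation_trf: np.ndarray,
                        lag_axis: np.ndarray) -> str:
    """Enhancement if the novelty TRF shares the baseline's sign at the
    novelty peak lag; suppression otherwise; indeterminate when the baseline
    there is < 10% of its own peak."""
    nov = np.asarray(novelty_trf, float)
    base = np.asarray(baseline_fixation_trf, float)
    if nov.shape != base.shape:
        raise ValueError("TRFs must share the lag axis")
    pk = trf_peak(nov, lag_axis)
    k = int(np.argmin(np.abs(lag_axis - pk.latency)))
    if np.abs(base[k]) < 0.1 * np.abs(base).max():
        return "indeterminate"
    return "enhancement" if np.sign(base[k]) == pk.sign else "suppression"


def detect_spike_artifact_channels(
    saccade_trfs: np.ndarray, lag_axis: np.ndarray,
    peak_window_s: float = 0.020, energy_window_s: float = 0.030,
    energy_threshold: float = 0.6, linkage_cut: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Flag channels carrying the stereotyped saccadic spike artifact.

    Channels are clustered by average linkage on 1 - r of their
    saccade-locked TRFs; a cluster is flagged when its mean TRF peaks within
    +/- 20 ms of saccade onset AND concentrates more than
    ``energy_threshold`` of its energy within +/- 30 ms of onset (a biphasic
    spike shape score). Returns (flagged channel indices, diagnostics).
    """
    trfs = np.asarray(saccade_trfs, float)
    C = trfs.shape[0]
    if C < 3:
        raise ValueError("need >= 3 channels")
    corr = np.corrcoef(trfs)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    link = scihier.linkage(squareform(np.clip(dist, 0, None), checks=False),
                           method="average")
    labels = scihier.fcluster(link, t=linkage_cut, criterion="distance")
    flagged = []
    diag = {"linkage": link, "labels": labels, "clusters": {}}
    near = np.abs(lag_axis) <= energy_window_s
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        mean_trf = trfs[members].mean(axis=0)
        pk = trf_peak(mean_trf, lag_axis)
        energy = mean_trf ** 2
        total = energy.sum()
        score = float(energy[near].sum() / total) if total > 0 else 0.0
        spike = abs(pk.latency) <= peak_window_s and score > energy_threshold
        diag["clusters"][int(lab)] = {"members": members, "peak": pk,
                                      "shape_score": score, "flagged": spike}
        if spike:
            flagged.extend(members.tolist())
    return np.asarray(sorted(flagged), int), diag


def compare_conditions(mags_a: np.ndarray, mags_b: np.ndarray
                       ) -> tuple[float, int, float]:
    """Paired t-test of modulation magnitudes across shared channels.

    Returns (t, df, p). Identical vectors give (0, df, 1); a constant
    nonzero difference with zero variance gives t = +/-inf with p floored
    at machine precision (documented degenerate handling).
    """
    a = np.asarray(mags_a, float)
    b = np.asarray(mags_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    n = len(d)
    df = n - 1
    if np.allclose(d, 0):
        return 0.0, df, 1.0
    if d.std(ddof=1) == 0:
        return float(np.sign(d.mean()) * np.inf), df, float(np.finfo(float).tiny)
    t, p = sps.ttest_rel(a, b)
    return float(t), df, float(p)


def region_summary(values_per_channel: np.ndarray,
                   region_labels: list[str]) -> pd.DataFrame:
    """Mean value and channel count per labeled region ("unknown" excluded)."""
    df = pd.DataFrame({"value": np.asarray(values_per_channel, float),
                       "region": list(region_labels)})
    df = df[df["region"] != "unknown"]
    out = df.groupby("region")["value"].agg(["mean", "count"])
    return out.rename(columns={"count": "n"})
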