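"""Downstream analyses over inferred parameters and summary statistics.

Covers the comparisons run after inference: parameter/statistic
correlation structure across prior simulations, min-max-normalized
deviation between simulated and observed summary vectors, KL divergence
between binned distributions, and pre/post-condition shift tests
(two-sample Kolmogorov-Smirnov per parameter with BH adjustment;
Kruskal-Wallis omnibus plus Dunn's post-hoc tests for three or more
conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants as C
from .summary import STAT_NAMES, SummaryStats

ALPHA = 0.05
KL_EPSILON = 1e-6   # additive smoothing, fraction of total mass
KL_N_BINS = 20


@dataclass
class ConditionDataset:
    """Per-pair MAP parameters and summary statistics of one condition."""

    label: str
    maps: np.ndarray | None = None          # (n_pairs, 9)
    stats: np.ndarray | None = None         # (n_pairs, 6)
    thetas: np.ndarray | None = None        # generating parameters, if known
    pair_ids: list = field(default_factory=list)

    def n_pairs(self) -> int:
        for a in (self.maps, self.stats, self.thetas):
            if a is not None:
                return a.shape[0]
        return 0

    def parameter(self, name: str) -> np.ndarray:
        if self.maps is None:
            raise ValueError("dataset has no inferred MAPs")
        return self.maps[:, C.PARAM_NAMES.index(name)]


def correlation_matrix(thetas, stats_matrix):
    """Pearson correlations between the 6 statistics and 9 parameters.

    Returns a (6, 9) array; entries whose statistic or parameter has zero
    variance are NaN (flagged undefined, not silently zero).
    """
    t = np.asarray(thetas, dtype=float)
    s = np.asarray(stats_matrix, dtype=float)
    if t.shape[0] != s.shape[0] or t.shape[0] < 3:
        raise ValueError("need >= 3 aligned rows")
    ok = np.all(np.isfinite(t), axis=1) & np.all(np.isfinite(s), axis=1)
    t, s = t[ok], s[ok]
    out = np.full((s.shape[1], t.shape[1]), np.nan)
    for i in range(s.shape[1]):
        if np.std(s[:, i]) == 0:
            continue
        for j in range(t.shape[1]):
            if np.std(t[:, j]) == 0:
                continue
            out[i, j] = np.corrcoef(s[:, i], t[:, j])[0, 1]
    return out


def minmax_normalized_deviation(x_sim, x_obs, ranges):
    """|x_sim - x_obs| / (max - min), per statistic.

    ``ranges`` is a (6, 2) array of per-statistic (min, max).
    """
    a = x_sim.to_array() if isinstance(x_sim, SummaryStats) else np.asarray(
        x_sim, dtype=float)
    b = x_obs.to_array() if isinstance(x_obs, SummaryStats) else np.asarray(
        x_obs, dtype=float)
    r = np.asarray(ranges, dtype=float)
    span = r[:, 1] - r[:, 0]
    if np.any(span <= 0):
        raise ValueError("degenerate statistic range (max must exceed min)")
    return np.abs(a - b) / span


def kl_divergence(p_hist, q_hist, eps: float = KL_EPSILON) -> float:
    """KL(p || q) in bits between two histograms on identical binnings.

    Both histograms are normalized and smoothed by ``eps`` of the total
    mass per bin before the divergence is taken (Gibbs: result >= 0).
    """
    p = np.asarray(p_hist, dtype=float)
    q = np.asarray(q_hist, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share one binning")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histogram masses must be non-negative")
    p = p + eps * p.sum()
    q = q + eps * q.sum()
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log2(p / q)))


def kl_between_samples(a, b, n_bins: int = KL_N_BINS,
                       eps: float = KL_EPSILON) -> float:
    """KL divergence between two samples, binned over their pooled range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    return kl_divergence(np.histogram(a, edges)[0], np.histogram(b, edges)[0],
                         eps)


def dunn_posthoc(groups: dict, alpha: float = ALPHA):
    """Dunn's pairwise rank tests after a Kruskal-Wallis omnibus.

    Z statistics use pooled mid-ranks with tie correction; two-sided
    p-values are BH-adjusted across the pairs.  Returns a list of dicts.
    """
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    sizes = np.array([v.size for v in values])
    if np.any(sizes < 2):
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate(values)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for v in values:
        mean_ranks.append(ranks[i0:i0 + v.size].mean())
        i0 += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"a": labels[i], "b": labels[j], "z": float(z),
                         "p": float(min(1.0, p))})
    adj = stats.false_discovery_control([r["p"] for r in rows], method="bh")
    for r, a in zip(rows, adj):
        r["p_adjusted"] = float(a)
        r["significant"] = bool(a <= alpha)
    return rows


def kruskal_dunn(groups: dict, alpha: float = ALPHA) -> dict:
    """Kruskal-Wallis omnibus across >= 3 groups, then Dunn's tests."""
    if len(groups) < 3:
        raise ValueError("need >= 3 groups for the omnibus test")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(v.size < 2 for v in values):
        raise ValueError("each group needs >= 2 observations")
    H, p = stats.kruskal(*values)
    return {
        "H": float(H),
        "p": float(p),
        "significant": bool(p <= alpha),
        "posthoc": dunn_posthoc(groups, alpha) if p <= alpha else [],
    }


def compare_conditions(a: ConditionDataset, b: ConditionDataset,
                       names=C.PARAM_NAMES, alpha: float = ALPHA) -> dict:
    """Two-sample KS shift report between two conditions, per parameter.

    Reports the KS statistic D, raw and BH-adjusted p, the median shift
    (b - a, positive = increase in the second condition) and the sample
    skewness of the second condition.  Requires >= 2 pairs per condition.
    """
    if a.maps is None or b.maps is None:
        raise ValueError("both conditions need inferred MAPs")
    if a.n_pairs() < 2 or b.n_pairs() < 2:
        raise ValueError("need >= 2 observations per condition")
    report = {}
    raw_p = []
    for name in names:
        va, vb = a.parameter(name), b.parameter(name)
        ks = stats.ks_2samp(va, vb)
        report[name] = {
            "D": float(ks.statistic),
            "p": float(ks.pvalue),
            "median_shift": float(np.median(vb) - np.median(va)),
            "skewness_after": float(stats.skew(vb)),
        }
        raw_p.append(ks.pvalue)
    adj = stats.false_discovery_control(raw_p, method="bh")
    for name, pa in zip(names, adj):
        report[name]["p_adjusted"] = float(pa)
        report[name]["significant"] = bool(pa <= alpha)
    return report


def compare_statistic(a: ConditionDataset, b: ConditionDataset,
                      stat_name: str) -> dict:
    """KS shift report for one summary statistic instead of a parameter."""
    if a.stats is None or b.stats is None:
        raise ValueError("both conditions need summary statistics")
    i = STAT_NAMES.index(stat_name)
    va, vb = a.stats[:, i], b.stats[:, i]
    if va.size < 2 or vb.size < 2:
        raise ValueError("need >= 2 observations per condition")
    ks = stats.ks_2samp(va, vb)
    return {
        "D": float(ks.statistic),
        "p": float(ks.pvalue),
        "median_shift": float(np.median(vb) - np.median(va)),
        "skewness_after": float(stats.skew(vb)),
    }
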