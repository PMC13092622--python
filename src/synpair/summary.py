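"""The six-dimensional observable vector x of a neuron pair.

x = (f_pre, f_post, v_pre, v_post, p_syn, lag): somatic firing rates of
both neurons, conduction speeds measured between two axial sites on each
axon, the postsynaptic spike probability within a window around the
coupling lag, and the coupling lag itself (the transfer-entropy-maximizing
source lag).  Vectors with any undefined component are rejected rather
than filled with sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import infotheory as it
from .simulator import SimulationResult, match_spikes_across_sites

DELTA_T_MODEL_MS = 0.5         # window half-width for simulated pairs
DELTA_T_EXPERIMENTAL_MS = 1.0  # window half-width for recorded-style pairs
P_SYN_KEEP_THRESHOLD = 0.05    # downstream keep-filter on p_syn

STAT_NAMES = ("f_pre", "f_post", "v_pre", "v_post", "p_syn", "lag")


class InvalidSummaryError(ValueError):
    """A component of the summary vector is undefined for these trains."""


@dataclass(frozen=True)
class SummaryStats:
    f_pre: float   # Hz
    f_post: float  # Hz
    v_pre: float   # m/s
    v_post: float  # m/s
    p_syn: float   # [0, 1]
    lag: float     # ms

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STAT_NAMES])

    @classmethod
    def from_array(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(**dict(zip(STAT_NAMES, x)))


@dataclass(frozen=True)
class TEConfig:
    bin_width: float = it.BIN_WIDTH_MS
    tau_max_source: float = it.TAU_MAX_SOURCE_MS
    tau_max_target: float = it.TAU_MAX_TARGET_MS
    n_perm: int = it.N_PERMUTATIONS
    alpha: float = it.ALPHA


def firing_rate(train, duration: float) -> float:
    """Spike count divided by duration, in Hz (duration in ms)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return 1000.0 * len(np.asarray(train)) / duration


def conduction_velocity(matched_pairs, delta_z: float) -> float:
    """Site separation (um) divided by the mean matched latency, in m/s."""
    pairs = np.asarray(matched_pairs, dtype=float)
    if pairs.size == 0:
        raise InvalidSummaryError("no matched spikes for velocity")
    lat = pairs[:, 1] - pairs[:, 0]
    mean_lat = float(np.mean(lat))
    if mean_lat <= 0:
        raise InvalidSummaryError("non-positive mean latency")
    return (delta_z / mean_lat) * 1e-3  # um/ms -> m/s


def postsynaptic_spike_probability(pre, post, lag: float,
                                   delta_t: float) -> float:
    """Fraction of presynaptic spikes answered by a postsynaptic spike.

    A postsynaptic spike counts if it falls in
    [t_pre + lag - delta_t, t_pre + lag + delta_t]; each postsynaptic
    spike is credited to at most one (the nearest) presynaptic spike, and
    the result is clipped to [0, 1].
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if pre.size == 0:
        raise InvalidSummaryError("empty presynaptic train")
    if post.size == 0:
        return 0.0
    centers = pre + lag
    idx = np.searchsorted(centers, post)
    # distance to the nearest window center on either side
    left = np.where(idx > 0, np.abs(post - centers[np.maximum(idx - 1, 0)]),
                    np.inf)
    right = np.where(idx < centers.size,
                     np.abs(centers[np.minimum(idx, centers.size - 1)] - post),
                     np.inf)
    hit = np.minimum(left, right) <= delta_t
    return float(min(1.0, hit.sum() / pre.size))


def coupling_lag(pre, post, duration: float,
                 te_config: TEConfig = TEConfig()) -> tuple[float, float, int]:
    """TE-maximizing source lag (ms) of the pre -> post coupling."""
    tgt = it.bin_spike_train(post, te_config.bin_width, duration)
    src = it.bin_spike_train(pre, te_config.bin_width, duration)
    lag, te, k = it.scan_lags(tgt, src, te_config.tau_max_source,
                              te_config.tau_max_target)
    return lag, te, k


def extract_summary(result: SimulationResult,
                    te_config: TEConfig = TEConfig(),
                    delta_t: float = DELTA_T_MODEL_MS,
                    rng: np.random.Generator | None = None,
                    require_significance: bool = False) -> SummaryStats:
    """Assemble the six summary statistics from one pair simulation.

    ``delta_t`` defaults to the simulated-pair preset (0.5 ms); recorded-
    style point-process pairs use 1 ms.  With ``require_significance`` the
    pre -> post transfer entropy must pass its surrogate test (needs
    ``rng``); otherwise an :class:`InvalidSummaryError` is raised.
    """
    if not result.valid:
        raise InvalidSummaryError("simulation flagged invalid")
    dur = result.config.duration
    pre_soma = result.spikes["pre_soma"]
    post_soma = result.spikes["post_soma"]
    if pre_soma.size == 0 or post_soma.size == 0:
        raise InvalidSummaryError("silent neuron")

    f_pre = firing_rate(pre_soma, dur)
    f_post = firing_rate(post_soma, dur)

    mp = match_spikes_across_sites(result.spikes["pre_z200"],
                                   result.spikes["pre_pre_syn"])
    dz_pre = result.site_z["pre_pre_syn"] - result.site_z["pre_z200"]
    v_pre = conduction_velocity(mp, dz_pre)
    mp = match_spikes_across_sites(result.spikes["post_post_syn"],
                                   result.spikes["post_z3000"])
    dz_post = result.site_z["post_z3000"] - result.site_z["post_post_syn"]
    v_post = conduction_velocity(mp, dz_post)

    if require_significance:
        if rng is None:
            raise ValueError("rng required for the significance filter")
        tgt = it.bin_spike_train(post_soma, te_config.bin_width, dur)
        src = it.bin_spike_train(pre_soma, te_config.bin_width, dur)
        res = it.permutation_test(tgt, src, rng, n_perm=te_config.n_perm,
                                  tau_max_source=te_config.tau_max_source,
                                  tau_max_target=te_config.tau_max_target)
        if res.p_value > te_config.alpha:
            raise InvalidSummaryError(
                f"transfer entropy not significant (p={res.p_value:.3f})"
            )
        lag = res.delta_star
    else:
        lag, _, _ = coupling_lag(pre_soma, post_soma, dur, te_config)

    p_syn = postsynaptic_spike_probability(pre_soma, post_soma, lag, delta_t)
    return SummaryStats(f_pre, f_post, v_pre, v_post, p_syn, lag)


def extract_summary_from_trains(pre, post, duration: float,
                                te_config: TEConfig = TEConfig(),
                                delta_t: float = DELTA_T_EXPERIMENTAL_MS,
                                v_pre: float = np.nan,
                                v_post: float = np.nan) -> SummaryStats:
    """Summary vector for recorded-style point-process pairs.

    Conduction speeds cannot be derived from point processes alone; they
    may be supplied externally, otherwise they are NaN and the vector is
    only suitable for rate/p_syn/lag analyses.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0:
        raise InvalidSummaryError("empty presynaptic train")
    lag, _, _ = coupling_lag(pre, post, duration, te_config)
    p_syn = postsynaptic_spike_probability(pre, post, lag, delta_t)
    return SummaryStats(firing_rate(pre, duration),
                        firing_rate(post, duration),
                        v_pre, v_post, p_syn, lag)
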