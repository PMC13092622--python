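"""Synthetic inputs for every pipeline stage — no downloads required.

Three generators: (i) coupled point-process "recordings" that mimic what
sorted microchannel spike trains exhibit (a presynaptic Poisson train and
a postsynaptic train containing lagged, jittered, probabilistic copies of
presynaptic spikes on top of baseline Poisson activity); (ii) populations
of prior-drawn pair simulations; (iii) paired pre/post-stimulation
populations differing in stated parameters (e.g. a multiplicative shift
of the mean AMPA weight), simulated with matched seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import constants as C
from .analysis import ConditionDataset
from .sbi import PriorBox
from .simulator import PairParameters, SimulationConfig, run_pair_simulation
from .summary import (
    DELTA_T_MODEL_MS,
    InvalidSummaryError,
    P_SYN_KEEP_THRESHOLD,
    TEConfig,
    extract_summary,
)

MERGE_RESOLUTION_MS = 1.0   # coincident baseline/transmitted spikes merged


@dataclass(frozen=True)
class CouplingSpec:
    """Generative law of one coupled point-process pair."""

    rate_pre: float = 10.0           # Hz
    rate_post_baseline: float = 5.0  # Hz
    p_transmit: float = 0.4
    lag: float = 4.0                 # ms
    jitter_sd: float = 0.3           # ms
    duration: float = 600_000.0      # ms (10 min of recording)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_transmit <= 1.0):
            raise ValueError("p_transmit must lie in [0, 1]")
        if self.lag <= 0:
            raise ValueError("lag must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _merge(train: np.ndarray, resolution: float) -> np.ndarray:
    """Sort and merge events closer than ``resolution`` (keep the first)."""
    t = np.sort(train)
    if t.size < 2:
        return t
    keep = [0]
    for i in range(1, t.size):
        if t[i] - t[keep[-1]] >= resolution:
            keep.append(i)
    return t[keep]


def generate_coupled_point_process(spec: CouplingSpec):
    """(pre, post) spike-time arrays in ms under the coupling law."""
    ss = np.random.SeedSequence(spec.seed)
    rng_pre, rng_base, rng_tr = (np.random.default_rng(s) for s in ss.spawn(3))
    n_pre = rng_pre.poisson(spec.rate_pre * spec.duration / 1000.0)
    pre = np.sort(rng_pre.uniform(0.0, spec.duration, n_pre))
    n_base = rng_base.poisson(spec.rate_post_baseline * spec.duration / 1000.0)
    base = rng_base.uniform(0.0, spec.duration, n_base)
    transmitted = pre[rng_tr.uniform(size=pre.size) < spec.p_transmit]
    transmitted = transmitted + spec.lag + rng_tr.normal(
        0.0, spec.jitter_sd, size=transmitted.size)
    post = np.concatenate([base, transmitted])
    post = post[(post >= 0.0) & (post < spec.duration)]
    pre = _merge(pre, MERGE_RESOLUTION_MS)
    post = _merge(post, MERGE_RESOLUTION_MS)
    return pre, post


@dataclass
class PopulationMember:
    theta: PairParameters
    result: object
    stats: object | None      # SummaryStats or None
    keep: bool                # passes validity + p_syn keep-filter
    reason: str = ""


def generate_population(n_pairs: int,
                        prior: PriorBox | None = None,
                        sim_config: SimulationConfig = SimulationConfig(),
                        seed: int = 0,
                        te_config: TEConfig = TEConfig()
                        ) -> list[PopulationMember]:
    """Prior-drawn pair simulations with per-pair validity bookkeeping.

    A member is kept when its summary vector is defined and its p_syn
    exceeds the 0.05 keep-filter; otherwise it is flagged with a reason.
    Fully reproducible from ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    prior = prior or PriorBox()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seeds = ss.generate_state(n_pairs) % (2**31 - 1)
    thetas = prior.sample(n_pairs, rng)
    out = []
    for i in range(n_pairs):
        theta = PairParameters.from_array(thetas[i])
        cfg = replace(sim_config, seed=int(sim_seeds[i]))
        res = run_pair_simulation(theta, cfg)
        try:
            s = extract_summary(res, te_config=te_config)
        except InvalidSummaryError as e:
            out.append(PopulationMember(theta, res, None, False, str(e)))
            continue
        keep = s.p_syn > P_SYN_KEEP_THRESHOLD
        out.append(PopulationMember(
            theta, res, s, keep,
            "" if keep else f"p_syn {s.p_syn:.3f} <= {P_SYN_KEEP_THRESHOLD}"))
    return out


def generate_condition_shift(n_pairs: int,
                             theta_base: PairParameters,
                             shift: dict,
                             sim_config: SimulationConfig = SimulationConfig(),
                             seed: int = 0,
                             scatter_fraction: float = 0.05,
                             te_config: TEConfig = TEConfig()
                             ) -> tuple[ConditionDataset, ConditionDataset]:
    """Matched before/after populations with named multiplicative shifts.

    "Before" pairs scatter around ``theta_base`` by ``scatter_fraction``
    of each prior range (population spread); "after" pairs reuse the same
    per-pair parameters and simulation seeds with ``shift`` applied
    (e.g. ``{"mu_ampa": 1.5}`` for +50 % mean AMPA weight).  Parameters
    leaving the prior box raise a validation error.
    """
    if n_pairs < 2:
        raise ValueError("need >= 2 pairs per condition")
    for name in shift:
        if name not in C.PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    prior = PriorBox()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seeds = ss.generate_state(n_pairs) % (2**31 - 1)
    base = theta_base.to_array()
    span = prior.highs - prior.lows
    jitter = rng.normal(0.0, scatter_fraction, size=(n_pairs, prior.ndim))
    thetas_before = np.clip(base + jitter * span, prior.lows, prior.highs)
    thetas_after = thetas_before.copy()
    for name, factor in shift.items():
        j = C.PARAM_NAMES.index(name)
        thetas_after[:, j] = thetas_after[:, j] * factor
    if not np.all(prior.contains(thetas_after)):
        bad = np.flatnonzero(~prior.contains(thetas_after))
        raise ValueError(
            f"shift pushes {len(bad)} pair(s) outside the prior box"
        )

    def _simulate(thetas, label):
        stats_rows, theta_rows, ids = [], [], []
        for i in range(n_pairs):
            theta = PairParameters.from_array(thetas[i])
            cfg = replace(sim_config, seed=int(sim_seeds[i]))
            res = run_pair_simulation(theta, cfg)
            try:
                s = extract_summary(res, te_config=te_config,
                                    delta_t=DELTA_T_MODEL_MS)
            except InvalidSummaryError:
                continue
            stats_rows.append(s.to_array())
            theta_rows.append(thetas[i])
            ids.append(i)
        return ConditionDataset(label=label,
                                stats=np.array(stats_rows),
                                thetas=np.array(theta_rows),
                                pair_ids=ids)

    return _simulate(thetas_before, "before"), _simulate(thetas_after, "after")


def infer_condition_maps(dataset: ConditionDataset, posterior_model,
                         rng: np.random.Generator,
                         n_samples: int = 10_000, n_top: int = 200
                         ) -> ConditionDataset:
    """Populate a condition's MAP matrix by running amortized inference."""
    if dataset.stats is None:
        raise ValueError("dataset has no summary statistics")
    maps = np.empty((dataset.stats.shape[0], posterior_model.prior.ndim))
    for i in range(dataset.stats.shape[0]):
        maps[i] = posterior_model.map_estimate(
            dataset.stats[i], n_samples=n_samples, n_top=n_top, rng=rng
        ).theta_star
    dataset.maps = maps
    return dataset
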