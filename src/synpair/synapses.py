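"""Conductance-based synaptic inputs.

Synaptic (and spontaneous-drive) conductances follow a beta-function
profile normalized so the peak equals the sampled weight:

    G(t) = w * Theta(t) * (exp(-t/tau1) - exp(-t/tau2))
               / (exp(-tau_peak/tau1) - exp(-tau_peak/tau2)),

    tau_peak = tau1*tau2/(tau2 - tau1) * log(tau2/tau1).

Weights are drawn per presynaptic activation from a normal distribution
truncated below at zero; presynaptic event trains are homogeneous Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants as C


@dataclass(frozen=True)
class SynapticKinetics:
    """Rise/decay time constants (ms) and reversal potential (mV)."""

    tau1: float
    tau2: float
    reversal: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if self.tau1 == self.tau2:
            raise ValueError(
                "tau1 == tau2 degenerates to an alpha function (unsupported)"
            )

    @property
    def tau_peak(self) -> float:
        return tau_peak(self.tau1, self.tau2)

    @property
    def norm(self) -> float:
        """Peak-normalization denominator of the beta profile."""
        tp = self.tau_peak
        return float(np.exp(-tp / self.tau1) - np.exp(-tp / self.tau2))


@dataclass(frozen=True)
class WeightDistribution:
    """Parent-normal parameters (uS) of the truncated weight law."""

    mu: float
    sigma: float
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class SpontaneousDrive:
    """Poisson excitatory drive onto the initial axon segment.

    The weight law scales with the target-segment diameter so synaptic
    efficacy is independent of compartment size.
    """

    rate: float  # Hz
    target_diameter: float  # um
    kinetics: SynapticKinetics = SynapticKinetics(
        C.SPONT_TAU1, C.SPONT_TAU2, C.SPONT_REVERSAL
    )

    @property
    def weight_dist(self) -> WeightDistribution:
        return WeightDistribution(
            C.SPONT_MU_PER_UM * self.target_diameter,
            C.SPONT_SIGMA_PER_UM * self.target_diameter,
        )


AMPA_KINETICS = SynapticKinetics(C.AMPA_TAU1, C.AMPA_TAU2, C.SYN_REVERSAL)
NMDA_KINETICS = SynapticKinetics(C.NMDA_TAU1, C.NMDA_TAU2, C.SYN_REVERSAL)


@dataclass(frozen=True)
class SynapseSpec:
    """AMPA + NMDA connection at axial coordinate z_syn.

    Both components activate on the same presynaptic event, each with a
    freshly sampled weight.
    """

    ampa_weights: WeightDistribution
    nmda_weights: WeightDistribution
    z_syn: float  # um
    ampa: SynapticKinetics = AMPA_KINETICS
    nmda: SynapticKinetics = NMDA_KINETICS

    def __post_init__(self) -> None:
        lo, hi = C.PRIOR_RANGES["z_syn"]
        if not (lo <= self.z_syn <= hi):
            raise ValueError(f"z_syn {self.z_syn} outside [{lo}, {hi}] um")


def tau_peak(tau1: float, tau2: float) -> float:
    """Time of the conductance maximum; symmetric under tau1 <-> tau2."""
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    if tau1 == tau2:
        raise ValueError("tau1 == tau2 is a degenerate (alpha) kinetics")
    return tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)


def beta_conductance(t_since_event, w: float, kinetics: SynapticKinetics):
    """Beta-profile conductance (uS) at times since one activation event.

    Zero before the event, exactly ``w`` at ``tau_peak``, and linear in
    superposed events.
    """
    if w < 0:
        raise ValueError("weight must be non-negative")
    t = np.asarray(t_since_event, dtype=float)
    g = np.where(
        t >= 0.0,
        (np.exp(-t / kinetics.tau1) - np.exp(-t / kinetics.tau2))
        / kinetics.norm,
        0.0,
    )
    return w * g


def sample_weight(dist: WeightDistribution, rng: np.random.Generator,
                  size=None):
    """Draw weights from the truncated normal (one fresh draw per event)."""
    if dist.sigma == 0.0:
        out = np.full(size if size is not None else (), dist.mu)
        return np.maximum(out, dist.lower_bound) if size is not None else float(max(dist.mu, dist.lower_bound))
    a = (dist.lower_bound - dist.mu) / dist.sigma
    tn = stats.truncnorm(a, np.inf, loc=dist.mu, scale=dist.sigma)
    return tn.rvs(size=size, random_state=rng)


def generate_poisson_events(rate: float, duration: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Sorted homogeneous-Poisson event times (ms) on [0, duration).

    ``rate`` is in Hz, ``duration`` in ms.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration / 1000.0)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    # enforce strict ordering (ties are measure-zero but guard anyway)
    if n > 1:
        keep = np.concatenate(([True], np.diff(t) > 0))
        t = t[keep]
    return t


def synaptic_point_current(G, V, reversal: float):
    """Ohmic synaptic current I = G*(V - E) in nA (G uS, V mV).

    Negative values are inward (depolarizing toward the reversal).
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("conductance must be non-negative")
    return G * (np.asarray(V, dtype=float) - reversal)
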