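"""Two-neuron network simulation.

Assembles a presynaptic and a postsynaptic ball-and-stick neuron in the
microchannel geometry (post soma shifted to z = 1000 um), drives each with
spontaneous Poisson input onto its initial axon segment, transmits
threshold-triggered AMPA+NMDA events from the presynaptic segment nearest
``z_syn`` into the postsynaptic segment nearest ``z_syn``, detects spikes
at the named axial sites, and optionally records membrane and
line-source extracellular potentials at two electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from . import constants as C
from . import synapses as syn
from ._kernels import run_pair_kernel, match_spikes_kernel
from .model_core import (
    MembraneParams,
    NeuronMorphology,
    build_pair_morphologies,
    discretize,
    gating_tables,
    resting_state,
)

SPIKE_THRESHOLD = 0.0   # mV, intracellular upward-crossing detection
REFRACTORY = 2.0        # ms, detection and transmission refractory
MAX_MATCH_LATENCY = 30.0  # ms, spike matching across axial sites

# Synaptic weight parameters (mu/sigma of AMPA, NMDA and the spontaneous
# drive) are stated in mS — the published unit of G_syn — while the
# internal unit system uses uS.  The uS reading would leave the strongest
# allowed AMPA weight (0.002) an order of magnitude below the local spike
# threshold of the postsynaptic axon, making the connection inert; only
# the mS reading produces the documented saturating dose-response.
WEIGHT_MS_TO_US = 1000.0


@dataclass(frozen=True)
class PairParameters:
    """The nine inferred biophysical parameters of a neuron pair (theta)."""

    d_pre: float = 1.0        # um
    d_post: float = 1.0       # um
    mu_ampa: float = 0.001    # uS
    sigma_ampa: float = 0.0005  # uS
    mu_nmda: float = 0.0001   # uS
    sigma_nmda: float = 0.00005  # uS
    lambda_pre: float = 20.0  # Hz
    lambda_post: float = 20.0  # Hz
    z_syn: float = 1500.0     # um

    def __post_init__(self) -> None:
        for name, (lo, hi) in C.PRIOR_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside prior range [{lo}, {hi}]"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in C.PARAM_NAMES])

    @classmethod
    def from_array(cls, theta) -> "PairParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(C.PARAM_NAMES),):
            raise ValueError(f"theta must have shape ({len(C.PARAM_NAMES)},)")
        return cls(**dict(zip(C.PARAM_NAMES, theta)))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationConfig:
    duration: float = 10_000.0  # ms
    dt: float = 0.1             # ms
    seed: int = 0
    settle: float = 200.0       # ms, silent settling excluded from outputs
    record_traces: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 < self.dt <= 0.1):
            raise ValueError("dt must lie in (0, 0.1] ms")
        if self.settle < 0:
            raise ValueError("settle must be non-negative")


# The published electrode points (0,0,60) and (0,0,1060) sit on the z axis,
# which is also the axis carrying every line source; the line-source kernel
# diverges there.  The default electrodes therefore keep the published z
# coordinates but sit half a soma diameter off-axis.
ELECTRODE_RADIAL_OFFSET = 5.0  # um


def _offset(p):
    return (p[0] + ELECTRODE_RADIAL_OFFSET, p[1], p[2])


@dataclass(frozen=True)
class ElectrodeConfig:
    positions: tuple = (_offset(C.ELECTRODE_1), _offset(C.ELECTRODE_2))
    sigma_ext: float = C.SIGMA_EXT  # S/m

    def __post_init__(self) -> None:
        if self.sigma_ext <= 0:
            raise ValueError("extracellular conductivity must be positive")
        for p in self.positions:
            if len(p) != 3:
                raise ValueError("electrode positions are 3-D points")
            if abs(p[0]) < 1e-12 and abs(p[1]) < 1e-12:
                raise ValueError(
                    "electrode lies on the z axis (on the source lines)"
                )


def default_electrodes() -> ElectrodeConfig:
    return ElectrodeConfig()


SITE_NAMES = (
    "pre_soma", "pre_z200", "pre_pre_syn",
    "post_soma", "post_post_syn", "post_z3000",
)


@dataclass
class SimulationResult:
    spikes: Mapping[str, np.ndarray]
    synapse_events: np.ndarray
    parameters: PairParameters
    config: SimulationConfig
    valid: bool
    site_z: Mapping[str, float] = field(default_factory=dict)
    traces: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    def spike_train(self, site: str) -> np.ndarray:
        return self.spikes[site]


def detect_spikes(v_trace, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY, dt: float = 0.1,
                  t0: float = 0.0) -> np.ndarray:
    """Upward threshold-crossing times from a uniformly sampled trace.

    Sub-dt linear interpolation of the crossing time; crossings within the
    refractory window of an accepted spike are suppressed.
    """
    v = np.asarray(v_trace, dtype=float)
    if v.ndim != 1:
        raise ValueError("v_trace must be one-dimensional")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times = []
    last = -np.inf
    for i in up:
        ts = t0 + dt * (i + (threshold - v[i]) / (v[i + 1] - v[i]))
        if ts - last >= refractory:
            times.append(ts)
            last = ts
    return np.array(times)


def match_spikes_across_sites(site_a, site_b,
                              max_latency: float = MAX_MATCH_LATENCY):
    """Order-preserving one-to-one matching of forward-propagating spikes.

    Returns an (n_matched, 2) array of (t_a, t_b) pairs with latency in
    (0, max_latency].  Among maximum-cardinality order-preserving
    matchings the one with minimal total latency is returned.
    """
    a = np.ascontiguousarray(site_a, dtype=float)
    b = np.ascontiguousarray(site_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.empty((0, 2))
    idx = match_spikes_kernel(a, b, float(max_latency))
    return np.column_stack((a[idx[:, 0]], b[idx[:, 1]]))


def line_source_kernel(morphology: NeuronMorphology, electrode,
                       sigma_ext: float = C.SIGMA_EXT) -> np.ndarray:
    """Per-segment potential (uV) at the electrode per nA of membrane current.

    Line-source approximation in a homogeneous, isotropic medium: the
    potential of a segment spanning [z1, z2] on the z axis, observed at
    radial distance r and height z_e, is

        I / (4 pi sigma (z2-z1)) * [asinh((z2-z_e)/r) - asinh((z1-z_e)/r)].
    """
    xe, ye, ze = (float(q) for q in electrode)
    r = np.hypot(xe, ye)
    if r <= 0:
        raise ValueError("electrode on a source line (zero radial distance)")
    out = np.empty(morphology.n_segments)
    for i, s in enumerate(morphology.segments):
        out[i] = (C.LINE_SOURCE_UV / (sigma_ext * s.length)) * (
            np.arcsinh((s.z_end - ze) / r) - np.arcsinh((s.z_start - ze) / r)
        )
    return out


def extracellular_potential(membrane_currents, morphology: NeuronMorphology,
                            electrode, sigma_ext: float = C.SIGMA_EXT):
    """Electrode potential trace (uV) from per-segment membrane currents (nA).

    ``membrane_currents`` has shape (n_times, n_segments) or (n_segments,).
    """
    im = np.asarray(membrane_currents, dtype=float)
    k = line_source_kernel(morphology, electrode, sigma_ext)
    if im.ndim == 1:
        if im.size != morphology.n_segments:
            raise ValueError("currents must align with segments")
        return float(im @ k)
    if im.shape[-1] != morphology.n_segments:
        raise ValueError("currents must align with segments")
    return im @ k


def membrane_currents_from_traces(V: np.ndarray,
                                  morphology: NeuronMorphology,
                                  params: MembraneParams) -> np.ndarray:
    """Transmembrane (return) currents in nA from voltage traces.

    By Kirchhoff's law the total transmembrane current of a compartment
    (capacitive + ionic, i.e. what enters the extracellular medium) equals
    the net axial current into it; it sums to ~0 over the whole cell.
    """
    _, g_ax, *_ = discretize(morphology, params)
    im = np.zeros_like(V)
    dv = V[:, 1:] - V[:, :-1]
    flow = dv * g_ax  # nA flowing from i+1 toward i (positive into i)
    im[:, :-1] += flow
    im[:, 1:] -= flow
    return im


def _spont_inputs(rate: float, diameter: float, duration: float, dt: float,
                  rng: np.random.Generator):
    drive = syn.SpontaneousDrive(rate, diameter)
    t = syn.generate_poisson_events(rate, duration, rng)
    steps = np.floor(t / dt).astype(np.int64)
    w = np.atleast_1d(syn.sample_weight(drive.weight_dist, rng, size=t.size))
    return steps, np.ascontiguousarray(t, dtype=float), \
        np.ascontiguousarray(w * WEIGHT_MS_TO_US, dtype=float)


def run_pair_simulation(theta: PairParameters,
                        config: SimulationConfig = SimulationConfig(),
                        electrodes: ElectrodeConfig | None = None,
                        params: MembraneParams = MembraneParams()
                        ) -> SimulationResult:
    """Simulate one synaptically connected pair.

    Deterministic given (theta, config.seed).  The synapse activates both
    its AMPA and NMDA component, each with a freshly sampled weight, when
    the presynaptic segment nearest z_syn crosses threshold; the current
    is injected into the postsynaptic segment nearest z_syn.
    """
    morph_pre, morph_post = build_pair_morphologies(theta.d_pre, theta.d_post)
    cap_a, gax_a, gna_a, gk_a, gl_a, _ = discretize(morph_pre, params)
    cap_b, gax_b, gna_b, gk_b, gl_b, _ = discretize(morph_post, params)
    dt = config.dt
    tab = gating_tables(params, dt)
    st_a = resting_state(morph_pre, params)
    st_b = resting_state(morph_post, params)

    ss = np.random.SeedSequence(config.seed)
    rng_pre, rng_post, rng_ampa, rng_nmda = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    sp_steps_a, sp_times_a, sp_w_a = _spont_inputs(
        theta.lambda_pre, theta.d_pre, config.duration, dt, rng_pre)
    sp_steps_b, sp_times_b, sp_w_b = _spont_inputs(
        theta.lambda_post, theta.d_post, config.duration, dt, rng_post)
    n_pool = max(64, int(config.duration / (2.0 * REFRACTORY)) + 8)
    ampa_w = np.atleast_1d(syn.sample_weight(
        syn.WeightDistribution(theta.mu_ampa, theta.sigma_ampa),
        rng_ampa, size=n_pool)).astype(float) * WEIGHT_MS_TO_US
    nmda_w = np.atleast_1d(syn.sample_weight(
        syn.WeightDistribution(theta.mu_nmda, theta.sigma_nmda),
        rng_nmda, size=n_pool)).astype(float) * WEIGHT_MS_TO_US

    spont_kin = syn.SpontaneousDrive(0.0, 1.0).kinetics
    ampa_kin, nmda_kin = syn.AMPA_KINETICS, syn.NMDA_KINETICS

    pre_trig = morph_pre.segment_nearest(theta.z_syn)
    post_seg = morph_post.segment_nearest(theta.z_syn)
    mon_a = np.array([
        0,
        morph_pre.segment_nearest(200.0),
        morph_pre.segment_nearest(theta.z_syn - 100.0),
    ], dtype=np.int64)
    mon_b = np.array([
        0,
        morph_post.segment_nearest(theta.z_syn + 100.0),
        morph_post.segment_nearest(3000.0),
    ], dtype=np.int64)

    n_steps = int(round(config.duration / dt))
    n_settle = int(round(config.settle / dt))
    max_spk = int(config.duration / REFRACTORY) + 8
    spikes_a = np.zeros((3, max_spk))
    spikes_b = np.zeros((3, max_spk))
    counts_a = np.zeros(3, dtype=np.int64)
    counts_b = np.zeros(3, dtype=np.int64)
    syn_times = np.zeros(max_spk)
    rec = 1 if config.record_traces else 0
    rec_Va = np.zeros((n_steps if rec else 1, morph_pre.n_segments))
    rec_Vb = np.zeros((n_steps if rec else 1, morph_post.n_segments))

    status, step, neuron, seg, n_syn = run_pair_kernel(
        dt, n_settle, n_steps,
        cap_a / dt, gax_a, gna_a, gk_a, gl_a,
        st_a.V, st_a.m, st_a.h, st_a.n,
        cap_b / dt, gax_b, gna_b, gk_b, gl_b,
        st_b.V, st_b.m, st_b.h, st_b.n,
        params.e_na, params.e_k, params.e_l,
        tab[0], tab[1], tab[2], tab[3], tab[4], tab[5], tab[6], tab[7], tab[8],
        sp_steps_a, sp_times_a, sp_w_a, sp_steps_b, sp_times_b, sp_w_b,
        np.exp(-dt / spont_kin.tau1), np.exp(-dt / spont_kin.tau2),
        1.0 / spont_kin.norm, spont_kin.reversal, 1,
        pre_trig, post_seg,
        ampa_w, nmda_w,
        np.exp(-dt / ampa_kin.tau1), np.exp(-dt / ampa_kin.tau2),
        1.0 / ampa_kin.norm,
        np.exp(-dt / nmda_kin.tau1), np.exp(-dt / nmda_kin.tau2),
        1.0 / nmda_kin.norm,
        C.SYN_REVERSAL,
        SPIKE_THRESHOLD, REFRACTORY,
        mon_a, mon_b, spikes_a, counts_a, spikes_b, counts_b,
        syn_times, rec, rec_Va, rec_Vb,
    )

    site_keys_a = ("pre_soma", "pre_z200", "pre_pre_syn")
    site_keys_b = ("post_soma", "post_post_syn", "post_z3000")
    spikes = {}
    for q, name in enumerate(site_keys_a):
        spikes[name] = spikes_a[q, :counts_a[q]].copy()
    for q, name in enumerate(site_keys_b):
        spikes[name] = spikes_b[q, :counts_b[q]].copy()
    site_z = {name: morph_pre.segments[mon_a[q]].z_center
              for q, name in enumerate(site_keys_a)}
    site_z.update({name: morph_post.segments[mon_b[q]].z_center
                   for q, name in enumerate(site_keys_b)})

    valid = status == 0
    diagnostics = {"status": int(status), "n_syn_events": int(n_syn)}
    if not valid:
        diagnostics.update({
            "failed_step": int(step),
            "failed_neuron": "pre" if neuron == 0 else "post",
            "failed_segment": int(seg),
        })

    traces = None
    if config.record_traces and valid:
        elec = electrodes if electrodes is not None else default_electrodes()
        im_a = membrane_currents_from_traces(rec_Va, morph_pre, params)
        im_b = membrane_currents_from_traces(rec_Vb, morph_post, params)
        phi = np.stack([
            extracellular_potential(im_a, morph_pre, pos, elec.sigma_ext)
            + extracellular_potential(im_b, morph_post, pos, elec.sigma_ext)
            for pos in elec.positions
        ])
        traces = {"V_pre": rec_Va, "V_post": rec_Vb, "phi": phi, "dt": dt}

    return SimulationResult(
        spikes=spikes,
        synapse_events=syn_times[:n_syn].copy(),
        parameters=theta,
        config=config,
        valid=valid,
        site_z=site_z,
        traces=traces,
        diagnostics=diagnostics,
    )
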