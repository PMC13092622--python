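"""Membrane biophysics of a ball-and-stick neuron.

A neuron is a cylindrical soma (10 um x 10 um) followed by 100 axonal
segments of 19.9 um sharing one diameter.  Each segment carries
Hodgkin-Huxley fast sodium, delayed-rectifier potassium and leak currents;
neighbouring segments are coupled through axial resistance, giving the
discretized cable equation

    c_m dV_n/dt = axial(V_{n-1}, V_n, V_{n+1}) + I_point,n / (pi d L)
                  - i_Na(V_n) - i_K(V_n) - i_L(V_n).

The voltage update is Crank-Nicolson (tridiagonal solve, unconditionally
stable at the reference dt of 0.1 ms); gating variables use the
Rush-Larsen exponential update.  Rate functions use the cortical-neuron
parameterization with a global voltage offset ``V_T`` and temperature
scaling ``phi = 3**((T-37)/10)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import constants as C
from ._kernels import cable_step_kernel


# ----------------------------------------------------------------------
# parameters and geometry
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneParams:
    """Fixed electrical membrane parameters (reference defaults)."""

    r_a: float = C.R_A            # Ohm*cm
    c_m: float = C.C_M            # uF/cm^2
    g_na: float = C.G_NA          # S/cm^2
    g_k: float = C.G_K            # S/cm^2
    g_l: float = C.G_L            # S/cm^2
    e_na: float = C.E_NA          # mV
    e_k: float = C.E_K            # mV
    e_l: float = C.E_L            # mV
    v_t: float = C.V_T            # mV
    temperature: float = C.TEMPERATURE_C  # deg C

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_l) < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.e_k < self.e_l < self.e_na):
            raise ValueError("require E_K < E_L < E_Na")

    @property
    def phi(self) -> float:
        """Temperature scaling of gating kinetics, 3**((T-37)/10)."""
        return 3.0 ** ((self.temperature - 37.0) / 10.0)


@dataclass(frozen=True)
class SegmentGeometry:
    index: int
    z_start: float   # um
    z_end: float     # um
    diameter: float  # um
    kind: str        # "soma" | "axon"

    def __post_init__(self) -> None:
        if self.z_end <= self.z_start:
            raise ValueError("segment must have positive length")
        if self.diameter <= 0:
            raise ValueError("segment diameter must be positive")
        if self.kind not in ("soma", "axon"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def length(self) -> float:
        return self.z_end - self.z_start

    @property
    def z_center(self) -> float:
        return 0.5 * (self.z_start + self.z_end)

    @property
    def lateral_area(self) -> float:
        """pi * d * L in um^2 (the area point currents are spread over)."""
        return np.pi * self.diameter * self.length


@dataclass(frozen=True)
class NeuronMorphology:
    segments: tuple[SegmentGeometry, ...]
    origin_z: float = 0.0

    def __post_init__(self) -> None:
        segs = self.segments
        if len(segs) != 1 + C.N_AXON_SEGMENTS:
            raise ValueError(
                f"expected 1 soma + {C.N_AXON_SEGMENTS} axon segments, got {len(segs)}"
            )
        if segs[0].kind != "soma" or any(s.kind != "axon" for s in segs[1:]):
            raise ValueError("segment 0 must be the soma, the rest axon")
        for a, b in zip(segs, segs[1:]):
            if abs(a.z_end - b.z_start) > 1e-9:
                raise ValueError("segments must be contiguous in z")
        d = {s.diameter for s in segs[1:]}
        if len(d) != 1:
            raise ValueError("all axon segments must share one diameter")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def axon_diameter(self) -> float:
        return self.segments[1].diameter

    def z_centers(self) -> np.ndarray:
        return np.array([s.z_center for s in self.segments])

    def segment_nearest(self, z: float) -> int:
        """Index of the segment whose center is nearest coordinate z."""
        return int(np.argmin(np.abs(self.z_centers() - z)))


def build_morphology(d_axon: float, z0: float = 0.0) -> NeuronMorphology:
    """Ball-and-stick morphology starting at axial coordinate ``z0``."""
    lo, hi = C.AXON_DIAMETER_RANGE
    if not (lo <= d_axon <= hi):
        raise ValueError(f"axon diameter {d_axon} um outside prior range [{lo}, {hi}]")
    soma = SegmentGeometry(0, z0, z0 + C.SOMA_LENGTH, C.SOMA_DIAMETER, "soma")
    segs = [soma]
    z = soma.z_end
    for i in range(C.N_AXON_SEGMENTS):
        segs.append(
            SegmentGeometry(i + 1, z, z + C.AXON_SEGMENT_LENGTH, d_axon, "axon")
        )
        z += C.AXON_SEGMENT_LENGTH
    return NeuronMorphology(tuple(segs), origin_z=z0)


def build_pair_morphologies(
    d_pre: float, d_post: float
) -> tuple[NeuronMorphology, NeuronMorphology]:
    """Presynaptic neuron at z=0, postsynaptic shifted to z=1000 um."""
    return build_morphology(d_pre, 0.0), build_morphology(d_post, C.POST_SOMA_Z0)


# ----------------------------------------------------------------------
# gating kinetics
# ----------------------------------------------------------------------

def _vtrap(u: np.ndarray) -> np.ndarray:
    """u / (exp(u) - 1) with the removable singularity at u = 0 filled in."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-9
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 - u / 2.0 + u * u / 12.0, safe / np.expm1(safe))
    return out


def gating_rates(V, v_t: float = C.V_T):
    """Voltage-dependent opening/closing rates of m, h, n in 1/ms.

    Returns a dict with keys alpha_m, beta_m, alpha_h, beta_h, alpha_n,
    beta_n.  ``v_t`` uniformly shifts the voltage dependence.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    x = V - v_t
    alpha_m = 0.32 * 4.0 * _vtrap((13.0 - x) / 4.0)
    beta_m = 0.28 * 5.0 * _vtrap((x - 40.0) / 5.0)
    alpha_h = 0.128 * np.exp((17.0 - x) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp((40.0 - x) / 5.0))
    alpha_n = 0.032 * 5.0 * _vtrap((15.0 - x) / 5.0)
    beta_n = 0.5 * np.exp((10.0 - x) / 40.0)
    return {
        "alpha_m": alpha_m, "beta_m": beta_m,
        "alpha_h": alpha_h, "beta_h": beta_h,
        "alpha_n": alpha_n, "beta_n": beta_n,
    }


def gating_steady_state_and_tau(V, params: MembraneParams = MembraneParams()):
    """Per-variable (x_inf, tau_x) with temperature scaling of tau.

    x_inf = alpha/(alpha+beta); tau_x = 1/(phi*(alpha+beta)).
    """
    r = gating_rates(V, params.v_t)
    phi = params.phi
    out = {}
    for var in ("m", "h", "n"):
        a, b = r[f"alpha_{var}"], r[f"beta_{var}"]
        out[var] = (a / (a + b), 1.0 / (phi * (a + b)))
    return out


def ionic_current_density(V, m, h, n, params: MembraneParams = MembraneParams()):
    """HH current densities in mA/cm^2, positive outward.

    Returns (total, components) with components keyed na/k/leak.
    """
    V = np.asarray(V, dtype=float)
    m, h, n = (np.asarray(g, dtype=float) for g in (m, h, n))
    for g in (m, h, n):
        if np.any((g < 0) | (g > 1)):
            raise ValueError("gating variables must lie in [0, 1]")
    # S/cm^2 * mV = mA/cm^2
    i_na = params.g_na * m**3 * h * (V - params.e_na)
    i_k = params.g_k * n**4 * (V - params.e_k)
    i_l = params.g_l * (V - params.e_l)
    comps = {"na": i_na, "k": i_k, "leak": i_l}
    return i_na + i_k + i_l, comps


# ----------------------------------------------------------------------
# state and discretization
# ----------------------------------------------------------------------

@dataclass
class MembraneState:
    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        ln = {len(self.V), len(self.m), len(self.h), len(self.n)}
        if len(ln) != 1:
            raise ValueError("state arrays must share one length")

    def copy(self) -> "MembraneState":
        return MembraneState(self.V.copy(), self.m.copy(), self.h.copy(), self.n.copy())


def resting_state(morphology: NeuronMorphology,
                  params: MembraneParams = MembraneParams(),
                  v_init: float | None = None) -> MembraneState:
    """Uniform state at ``v_init`` (default E_L) with gating at steady state."""
    v0 = params.e_l if v_init is None else v_init
    ns = morphology.n_segments
    V = np.full(ns, v0)
    ss = gating_steady_state_and_tau(V, params)
    return MembraneState(V, ss["m"][0].copy(), ss["h"][0].copy(), ss["n"][0].copy())


def discretize(morphology: NeuronMorphology, params: MembraneParams):
    """Per-segment absolute quantities for the compartmental system.

    Returns (cap [nF], g_axial [uS, between centers i and i+1],
    g_na_abs, g_k_abs, g_l_abs [uS], area [um^2]).

    The axial conductance between adjacent segments is the series sum of
    each segment's half axial resistance 4*r_a*(L/2)/(pi*d^2).
    """
    segs = morphology.segments
    area = np.array([s.lateral_area for s in segs])
    cap = params.c_m * area * C.CAP_UF_CM2_UM2_TO_NF
    g_na = params.g_na * area * C.COND_S_CM2_UM2_TO_US
    g_k = params.g_k * area * C.COND_S_CM2_UM2_TO_US
    g_l = params.g_l * area * C.COND_S_CM2_UM2_TO_US
    half_r = np.array([
        4.0 * params.r_a * (s.length / 2.0) / (np.pi * s.diameter**2)
        * C.AXIAL_OHM_FACTOR
        for s in segs
    ])  # Ohm
    g_ax = C.OHM_TO_US / (half_r[:-1] + half_r[1:])
    return cap, g_ax, g_na, g_k, g_l, area


_TABLE_V0 = -150.0
_TABLE_V1 = 100.0
_TABLE_DV = 0.02
_table_cache: dict = {}


def gating_tables(params: MembraneParams, dt: float):
    """Lookup tables of x_inf and exp(-dt/tau_x) on a dense voltage grid.

    Used by the compiled integration kernels; rebuilt per (params, dt).
    """
    key = (params, float(dt))
    if key in _table_cache:
        return _table_cache[key]
    V = np.arange(_TABLE_V0, _TABLE_V1 + _TABLE_DV, _TABLE_DV)
    ss = gating_steady_state_and_tau(V, params)
    tabs = {}
    for var in ("m", "h", "n"):
        xinf, tau = ss[var]
        tabs[var] = (np.ascontiguousarray(xinf), np.ascontiguousarray(np.exp(-dt / tau)))
    out = (V[0], 1.0 / _TABLE_DV, len(V),
           tabs["m"][0], tabs["m"][1], tabs["h"][0], tabs["h"][1],
           tabs["n"][0], tabs["n"][1])
    _table_cache[key] = out
    return out


class CableStepError(RuntimeError):
    """Numerical blow-up during integration; carries the offending segment."""

    def __init__(self, step: int, segment: int):
        super().__init__(
            f"non-finite membrane state at step {step}, segment {segment}"
        )
        self.step = step
        self.segment = segment


def step_cable(state: MembraneState,
               morphology: NeuronMorphology,
               params: MembraneParams,
               point_currents: np.ndarray,
               dt: float) -> MembraneState:
    """Advance the membrane state by one Crank-Nicolson step.

    ``point_currents`` are per-segment injected currents in nA; they are
    spread over the segment's lateral area pi*d*L inside the kernel.
    Sealed-end (zero axial flux) boundaries.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pc = np.asarray(point_currents, dtype=float)
    if pc.shape != state.V.shape:
        raise ValueError("point_currents must align with segments")
    if not np.all(np.isfinite(state.V)):
        raise CableStepError(0, int(np.argmax(~np.isfinite(state.V))))
    cap, g_ax, g_na, g_k, g_l, _ = discretize(morphology, params)
    tab = gating_tables(params, dt)
    out = state.copy()
    gsyn = np.zeros_like(out.V)
    code = cable_step_kernel(
        out.V, out.m, out.h, out.n,
        cap / dt, g_ax, g_na, g_k, g_l,
        params.e_na, params.e_k, params.e_l,
        gsyn, C.SYN_REVERSAL, pc,
        tab[0], tab[1], tab[2], tab[3], tab[4], tab[5], tab[6], tab[7], tab[8],
    )
    if code >= 0:
        raise CableStepError(1, code)
    return out
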