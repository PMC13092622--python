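"""Membrane biophysics: gating kinetics, geometry, cable integration."""

import numpy as np
import pytest

from synpair import constants as C
from synpair.model_core import (
    CableStepError,
    MembraneParams,
    MembraneState,
    build_morphology,
    build_pair_morphologies,
    discretize,
    gating_rates,
    gating_steady_state_and_tau,
    ionic_current_density,
    resting_state,
    step_cable,
)

PASSIVE = MembraneParams(g_na=0.0, g_k=0.0)


# ----------------------------------------------------------------------
# gating rate functions
# ----------------------------------------------------------------------

@pytest.mark.parametrize("offset,key,expected", [
    (13.0, "alpha_m", 0.32 * 4.0),   # removable singularity limit
    (40.0, "beta_m", 0.28 * 5.0),    # removable singularity limit
    (17.0, "alpha_h", 0.128),        # exponent = 0
    (40.0, "beta_h", 2.0),           # logistic midpoint
    (10.0, "beta_n", 0.5),           # exponent = 0
    (15.0, "alpha_n", 0.032 * 5.0),  # removable singularity limit
])
def test_gating_rate_reference_points(offset, key, expected):
    r = gating_rates(C.V_T + offset)
    assert r[key] == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("offset,key", [
    (13.0, "alpha_m"), (40.0, "beta_m"), (15.0, "alpha_n"),
])
def test_gating_rates_continuous_through_singularity(offset, key):
    """Finite and continuous to 1e-6 relative within 1e-7 mV of each
    removable singularity."""
    v0 = C.V_T + offset
    center = gating_rates(v0)[key]
    for eps in (1e-7, -1e-7, 1e-8, -1e-8):
        v = gating_rates(v0 + eps)[key]
        assert np.isfinite(v)
        assert abs(v - center) / center < 1e-6


def test_gating_rates_nonnegative_and_finite(rng):
    V = rng.uniform(-120.0, 60.0, size=500)
    r = gating_rates(V)
    for v in r.values():
        assert np.all(np.isfinite(v))
        assert np.all(v >= 0)


def test_gating_rates_rejects_nonfinite():
    with pytest.raises(ValueError):
        gating_rates(np.array([0.0, np.nan]))


def test_steady_state_in_unit_interval(rng):
    V = rng.uniform(-120.0, 60.0, size=200)
    for xinf, tau in gating_steady_state_and_tau(V).values():
        assert np.all((xinf >= 0) & (xinf <= 1))
        assert np.all(tau > 0)


def test_temperature_scaling_of_tau():
    p37 = MembraneParams(temperature=37.0)
    p47 = MembraneParams(temperature=47.0)
    assert p37.phi == pytest.approx(1.0)
    assert p47.phi == pytest.approx(3.0)
    V = np.array([-50.0, -20.0, 0.0])
    ss37 = gating_steady_state_and_tau(V, p37)
    ss47 = gating_steady_state_and_tau(V, p47)
    for var in ("m", "h", "n"):
        np.testing.assert_allclose(ss47[var][1], ss37[var][1] / 3.0,
                                   rtol=1e-12)
        np.testing.assert_allclose(ss47[var][0], ss37[var][0], rtol=1e-12)


# ----------------------------------------------------------------------
# ionic currents
# ----------------------------------------------------------------------

def test_ionic_current_zero_driving_force():
    p = MembraneParams()
    _, comps = ionic_current_density(p.e_na, 0.5, 0.5, 0.5, p)
    assert comps["na"] == pytest.approx(0.0)


def test_ionic_current_leak_only_and_rest():
    p = MembraneParams()
    total, _ = ionic_current_density(-50.0, 0.0, 0.0, 0.0, p)
    assert total == pytest.approx(p.g_l * (-50.0 - p.e_l))
    total, _ = ionic_current_density(p.e_l, 0.0, 0.0, 0.0, p)
    assert total == pytest.approx(0.0)


def test_ionic_current_components_sum(rng):
    p = MembraneParams()
    V = rng.uniform(-90, 50, size=20)
    g = rng.uniform(0, 1, size=(3, 20))
    total, comps = ionic_current_density(V, *g, p)
    np.testing.assert_allclose(total, sum(comps.values()), rtol=1e-12)


def test_ionic_current_rejects_bad_gating():
    with pytest.raises(ValueError):
        ionic_current_density(0.0, 1.5, 0.0, 0.0)


# ----------------------------------------------------------------------
# morphology
# ----------------------------------------------------------------------

def test_pair_morphologies_geometry():
    pre, post = build_pair_morphologies(1.0, 0.2)
    assert pre.segments[0].z_start == 0.0
    assert pre.segments[0].z_end == 10.0
    assert pre.segments[1].z_start == 10.0
    assert pre.segments[-1].z_end == pytest.approx(10 + 100 * 19.9)
    assert len(pre.segments) == 101
    assert post.segments[0].z_start == 1000.0
    assert post.segments[0].z_end == 1010.0
    assert post.segments[-1].z_end == pytest.approx(1010 + 100 * 19.9)
    assert all(s.length == pytest.approx(19.9) for s in pre.segments[1:])


@pytest.mark.parametrize("bad", [6.0, 0.1, -1.0])
def test_morphology_rejects_out_of_range_diameter(bad):
    with pytest.raises(ValueError):
        build_morphology(bad)


def test_segment_nearest():
    m = build_morphology(1.0)
    assert m.segment_nearest(0.0) == 0
    seg = m.segment_nearest(200.0)
    assert abs(m.segments[seg].z_center - 200.0) <= 19.9 / 2


# ----------------------------------------------------------------------
# cable stepping
# ----------------------------------------------------------------------

def _run_steps(state, morph, params, currents, dt, n):
    for _ in range(n):
        state = step_cable(state, morph, params, currents, dt)
    return state


def test_uniform_passive_relaxes_to_leak_reversal():
    morph = build_morphology(1.0)
    st = resting_state(morph, PASSIVE, v_init=PASSIVE.e_l + 10.0)
    zeros = np.zeros(morph.n_segments)
    st = _run_steps(st, morph, PASSIVE, zeros, 0.5, 100)
    assert np.ptp(st.V) < 1e-9          # Laplacian of a constant is 0
    assert abs(st.V[0] - PASSIVE.e_l) < abs(10.0) * np.exp(-50 / 3.33) + 1e-6


def test_passive_membrane_time_constant():
    """Uniform passive decay time constant equals c_m/g_L within 1%."""
    morph = build_morphology(1.0)
    st = resting_state(morph, PASSIVE, v_init=PASSIVE.e_l + 10.0)
    zeros = np.zeros(morph.n_segments)
    dt, n = 0.05, 40
    v0 = st.V[0] - PASSIVE.e_l
    st = _run_steps(st, morph, PASSIVE, zeros, dt, n)
    v1 = st.V[0] - PASSIVE.e_l
    tau_meas = -dt * n / np.log(v1 / v0)
    tau_true = (PASSIVE.c_m * 1e-6) / PASSIVE.g_l * 1e3  # ms
    assert tau_true == pytest.approx(10.0 / 3.0, rel=1e-6)
    assert tau_meas == pytest.approx(tau_true, rel=0.01)


def test_passive_steady_state_attenuation_matches_length_constant():
    """Voltage decay along a passive cable matches exp(-dz/lambda) with
    lambda = sqrt(d/(4 r_a g_L)) ~ 288.7 um, within 2%."""
    morph = build_morphology(1.0)
    st = resting_state(morph, PASSIVE)
    cur = np.zeros(morph.n_segments)
    cur[-1] = 0.01  # nA, far end (away from the soma)
    st = _run_steps(st, morph, PASSIVE, cur, 1.0, 400)
    lam = np.sqrt((1.0e-4) / (4.0 * PASSIVE.r_a * PASSIVE.g_l)) * 1e4  # um
    assert lam == pytest.approx(288.675, rel=1e-3)
    dv = st.V - PASSIVE.e_l
    # interior window away from both boundaries
    i0, i1 = 95, 55
    dz = (i0 - i1) * 19.9
    # segment i0 is nearer the injection site, so less attenuated
    measured = dv[i0] / dv[i1]
    assert measured == pytest.approx(np.exp(dz / lam), rel=0.02)


def test_gating_stays_in_unit_interval_under_random_drive(rng):
    morph = build_morphology(1.0)
    params = MembraneParams()
    st = resting_state(morph, params)
    for _ in range(400):
        cur = np.zeros(morph.n_segments)
        cur[rng.integers(0, 101)] = rng.uniform(0, 2.0)
        st = step_cable(st, morph, params, cur, 0.1)
        for g in (st.m, st.h, st.n):
            assert np.all((g >= 0) & (g <= 1))


def test_step_cable_propagates_nan_with_diagnostics():
    morph = build_morphology(1.0)
    st = resting_state(morph, MembraneParams())
    st.V[7] = np.nan
    with pytest.raises(CableStepError) as e:
        step_cable(st, morph, MembraneParams(), np.zeros(101), 0.1)
    assert e.value.segment == 7


def _soma_spike_times(i_soma, duration, dt, params=MembraneParams()):
    """Constant somatic drive; spike times from the recorded soma trace."""
    from synpair.simulator import detect_spikes
    morph = build_morphology(1.0)
    st = resting_state(morph, params)
    cur = np.zeros(morph.n_segments)
    cur[0] = i_soma
    n = int(round(duration / dt))
    v = np.empty(n)
    for i in range(n):
        st = step_cable(st, morph, params, cur, dt)
        v[i] = st.V[0]
    return detect_spikes(v, threshold=0.0, refractory=2.0, dt=dt), v


def test_suprathreshold_drive_spikes_periodically_silence_otherwise():
    spikes, v = _soma_spike_times(0.2, 300.0, 0.1)
    assert len(spikes) >= 3
    assert v.max() - MembraneParams().e_l > 60.0  # amplitude peak-to-rest
    isi = np.diff(spikes)
    assert np.ptp(isi[1:]) < 0.1 * np.mean(isi[1:])  # periodic
    silent, _ = _soma_spike_times(0.0, 1000.0, 0.1)
    assert len(silent) == 0


def test_spike_time_convergence_under_dt_halving():
    """Halving dt moves somatic spike times by < 0.05 ms."""
    times = {dt: _soma_spike_times(0.2, 200.0, dt)[0] for dt in
             (0.1, 0.05, 0.025)}
    # compare early spikes; over a long periodic train the per-cycle
    # period error accumulates into phase drift, which is not a
    # per-spike timing error
    for a, b in ((0.1, 0.05), (0.05, 0.025)):
        n = min(5, len(times[a]), len(times[b]))
        assert n >= 3
        assert np.max(np.abs(times[a][:n] - times[b][:n])) < 0.05
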