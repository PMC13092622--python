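"""Pair simulation: determinism, spike detection, matching, electrodes."""

import numpy as np
import pytest

from _oracles import match_bruteforce
from synpair import constants as C
from synpair.model_core import MembraneParams, build_morphology
from synpair.simulator import (
    ElectrodeConfig,
    PairParameters,
    SimulationConfig,
    detect_spikes,
    extracellular_potential,
    line_source_kernel,
    match_spikes_across_sites,
    membrane_currents_from_traces,
    run_pair_simulation,
)

FAST = SimulationConfig(duration=2000.0, seed=5)


def test_pair_parameters_validation():
    PairParameters()  # defaults inside the box
    with pytest.raises(ValueError):
        PairParameters(d_pre=6.0)
    with pytest.raises(ValueError):
        PairParameters(mu_ampa=0.003)
    with pytest.raises(ValueError):
        PairParameters(lambda_pre=2.0)
    t = PairParameters(z_syn=1234.0)
    np.testing.assert_allclose(PairParameters.from_array(t.to_array())
                               .to_array(), t.to_array())


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(duration=-1)
    with pytest.raises(ValueError):
        SimulationConfig(dt=0.2)
    with pytest.raises(ValueError):
        SimulationConfig(dt=0.0)


def test_same_seed_bit_identical():
    th = PairParameters(lambda_pre=20, lambda_post=20)
    r1 = run_pair_simulation(th, FAST)
    r2 = run_pair_simulation(th, FAST)
    for site in r1.spikes:
        np.testing.assert_array_equal(r1.spikes[site], r2.spikes[site])
    np.testing.assert_array_equal(r1.synapse_events, r2.synapse_events)


def test_spike_trains_sorted_within_duration():
    th = PairParameters(lambda_pre=40, lambda_post=40)
    r = run_pair_simulation(th, FAST)
    assert r.valid
    for site, t in r.spikes.items():
        assert np.all(np.diff(t) > 0)
        if t.size:
            assert t.min() >= 0 and t.max() < FAST.duration


def test_forward_conduction_latencies_positive():
    """Presynaptic spikes at z=200 arrive later at z_syn-100."""
    th = PairParameters(lambda_pre=20, lambda_post=5, z_syn=1500.0)
    r = run_pair_simulation(th, FAST)
    mp = match_spikes_across_sites(r.spikes["pre_z200"],
                                   r.spikes["pre_pre_syn"])
    assert mp.shape[0] >= 5
    assert np.all(mp[:, 1] - mp[:, 0] > 0)


def test_post_activity_invariant_to_presynaptic_parameters():
    """With the synapse silenced, the postsynaptic train depends only on
    (d_post, lambda_post): paired seeds, exact equality."""
    base = dict(mu_ampa=0.0, sigma_ampa=0.0, mu_nmda=0.0, sigma_nmda=0.0,
                d_post=1.5, lambda_post=25.0)
    a = run_pair_simulation(PairParameters(d_pre=0.5, lambda_pre=10.0,
                                           z_syn=1200.0, **base), FAST)
    b = run_pair_simulation(PairParameters(d_pre=4.0, lambda_pre=80.0,
                                           z_syn=1900.0, **base), FAST)
    np.testing.assert_array_equal(a.spikes["post_soma"],
                                  b.spikes["post_soma"])


def test_uncoupled_pre_and_post_trains_differ_across_neurons():
    th = PairParameters(lambda_pre=20, lambda_post=20, mu_ampa=0.0,
                        sigma_ampa=0.0, mu_nmda=0.0, sigma_nmda=0.0)
    r = run_pair_simulation(th, FAST)
    # independent streams: the two soma trains are not identical
    assert r.spikes["pre_soma"].size != r.spikes["post_soma"].size or \
        not np.allclose(r.spikes["pre_soma"], r.spikes["post_soma"])


def test_synapse_events_follow_presynaptic_spikes():
    th = PairParameters(lambda_pre=20, lambda_post=5)
    r = run_pair_simulation(th, FAST)
    assert r.synapse_events.size > 0
    # every synapse activation coincides with a presynaptic spike seen at
    # the site nearest z_syn - 100 slightly earlier
    assert np.all(np.diff(r.synapse_events) >= 2.0 - 1e-9)  # refractory


# ----------------------------------------------------------------------
# spike detection
# ----------------------------------------------------------------------

def test_detect_spikes_basic():
    assert detect_spikes(np.full(100, -50.0)).size == 0
    # single clean crossing
    v = np.concatenate([np.full(50, -60.0), np.full(50, 20.0)])
    t = detect_spikes(v, dt=0.1)
    assert t.size == 1
    # crossing between samples 49 (-60) and 50 (+20): interpolated
    assert 4.9 < t[0] < 5.0


def test_detect_spikes_refractory_suppression():
    dt = 0.1
    v = np.full(200, -10.0)
    v[50] = 10.0   # crossing at 5.0 ms
    v[55] = 10.0   # crossing at 5.5 ms, inside the 2 ms refractory
    v[51:55] = -10.0
    t = detect_spikes(v, threshold=0.0, refractory=2.0, dt=dt)
    assert t.size == 1
    assert t[0] == pytest.approx(4.95, abs=0.01)


def test_detect_spikes_interpolates_subsample():
    dt = 0.1
    v = np.full(30, -1.0)
    v[10:] = 3.0  # crossing 1/4 of the way between samples 9 and 10
    t = detect_spikes(v, threshold=0.0, dt=dt)
    assert t[0] == pytest.approx(0.9 + dt * 0.25, abs=1e-9)


# ----------------------------------------------------------------------
# spike matching
# ----------------------------------------------------------------------

def test_match_spikes_examples():
    a = np.array([10.0, 50.0])
    b = np.array([12.0, 12.1, 52.0])
    mp = match_spikes_across_sites(a, b, max_latency=30.0)
    np.testing.assert_allclose(mp, [[10.0, 12.0], [50.0, 52.0]])

    a = np.arange(0, 100, 10.0)
    mp = match_spikes_across_sites(a, a + 2.4)
    assert mp.shape[0] == a.size
    np.testing.assert_allclose(mp[:, 1] - mp[:, 0], 2.4)

    assert match_spikes_across_sites(a, np.array([])).shape[0] == 0


def test_match_spikes_against_exhaustive_oracle(rng):
    for _ in range(60):
        na, nb = rng.integers(0, 7, size=2)
        a = np.sort(rng.uniform(0, 60, na))
        b = np.sort(rng.uniform(0, 60, nb))
        mp = match_spikes_across_sites(a, b, max_latency=15.0)
        pairs, lat = match_bruteforce(a, b, 15.0)
        assert mp.shape[0] == len(pairs)
        got_lat = float(np.sum(mp[:, 1] - mp[:, 0])) if mp.size else 0.0
        assert got_lat == pytest.approx(lat, abs=1e-9)


# ----------------------------------------------------------------------
# extracellular potential
# ----------------------------------------------------------------------

def test_extracellular_zero_currents():
    m = build_morphology(1.0)
    phi = extracellular_potential(np.zeros((5, 101)), m, (5.0, 0.0, 500.0))
    np.testing.assert_array_equal(phi, 0.0)


def test_extracellular_far_field_matches_point_source():
    """One segment at 1 nA seen from 1000 um matches I/(4 pi sigma r)
    within 0.1%."""
    m = build_morphology(1.0)
    seg = m.segments[50]
    cur = np.zeros(101)
    cur[50] = 1.0  # nA
    r = 1000.0
    electrode = (r, 0.0, seg.z_center)
    phi = extracellular_potential(cur, m, electrode, sigma_ext=0.3)
    point = 1.0 * 1e3 / (4 * np.pi * 0.3 * r)  # uV
    assert phi == pytest.approx(point, rel=1e-3)


def test_extracellular_conductivity_scaling():
    m = build_morphology(1.0)
    cur = np.zeros(101)
    cur[10] = 0.5
    e = (20.0, 0.0, 300.0)
    assert extracellular_potential(cur, m, e, 0.6) == pytest.approx(
        0.5 * extracellular_potential(cur, m, e, 0.3), rel=1e-12)


def test_extracellular_rejects_on_axis_electrode():
    m = build_morphology(1.0)
    with pytest.raises(ValueError):
        line_source_kernel(m, (0.0, 0.0, 500.0))
    with pytest.raises(ValueError):
        ElectrodeConfig(positions=((0.0, 0.0, 60.0), (5.0, 0.0, 1060.0)))


def test_membrane_currents_sum_to_zero():
    m = build_morphology(1.0)
    V = np.random.default_rng(0).normal(-40, 10, size=(20, 101))
    im = membrane_currents_from_traces(V, m, MembraneParams())
    np.testing.assert_allclose(im.sum(axis=1), 0.0, atol=1e-9)


def test_electrode1_leads_electrode2_for_presynaptic_spikes():
    """Propagation direction: the proximal electrode (z=60) sees a
    presynaptic spike before the distal one (z=1060)."""
    th = PairParameters(lambda_pre=10, lambda_post=5, mu_ampa=0.0,
                        sigma_ampa=0.0, mu_nmda=0.0, sigma_nmda=0.0)
    cfg = SimulationConfig(duration=1500.0, seed=3, record_traces=True)
    r = run_pair_simulation(th, cfg)
    assert r.traces is not None
    phi = r.traces["phi"]
    dt = r.traces["dt"]
    post = r.spikes["post_soma"]
    lead = []
    for t in r.spikes["pre_soma"]:
        if post.size and np.min(np.abs(post - t)) < 25.0:
            continue  # contaminated by postsynaptic activity
        i0, i1 = int((t - 2) / dt), int((t + 8) / dt)
        if i0 < 0 or i1 > phi.shape[1]:
            continue
        t1 = np.argmax(np.abs(phi[0, i0:i1]))
        t2 = np.argmax(np.abs(phi[1, i0:i1]))
        lead.append(t1 < t2)
    assert lead and np.mean(lead) > 0.8
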