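"""Prior, training-set construction, MDN correctness, posterior ops."""

import numpy as np
import pytest
from scipy import stats as sps

from synpair.sbi import (
    MixtureDensityNetwork,
    PosteriorModel,
    PriorBox,
    TrainingSet,
    build_training_set,
    posterior_for_observation,
    sample_prior,
    train_posterior,
)
from synpair.simulator import SimulationConfig
from synpair.summary import TEConfig


# ----------------------------------------------------------------------
# prior box
# ----------------------------------------------------------------------

def test_prior_samples_within_bounds(rng):
    prior = PriorBox()
    s = prior.sample(20_000, rng)
    assert np.all(prior.contains(s))
    mid = (prior.lows + prior.highs) / 2
    se = prior.std() / np.sqrt(20_000)
    assert np.all(np.abs(s.mean(0) - mid) < 3 * se)


def test_prior_seed_reproducible():
    a = sample_prior(50, rng=np.random.default_rng(9))
    b = sample_prior(50, rng=np.random.default_rng(9))
    np.testing.assert_array_equal(a, b)


def test_prior_rejects_bad_bounds():
    with pytest.raises(ValueError):
        PriorBox(names=("a",), lows=np.array([1.0]), highs=np.array([0.5]))


# ----------------------------------------------------------------------
# 1-D linear-Gaussian toy with a conjugate closed form
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_mdn():
    rng = np.random.default_rng(3)
    theta = rng.uniform(-1, 1, size=(5000, 1))
    x = theta + rng.normal(0, 0.1, size=(5000, 1))
    return MixtureDensityNetwork(random_state=1).fit(x, theta)


def test_mdn_linear_gaussian_posterior_mean(toy_mdn, rng):
    """Posterior mean at x_o=0.3 within 0.05 of the analytic truncated
    Gaussian mean (~0.3 for sigma=0.1 well inside the box)."""
    s = toy_mdn.sample(np.array([[0.3]]), 20_000, rng)
    assert abs(s.mean() - 0.3) < 0.05
    assert 0.06 < s.std() < 0.14


def test_mdn_density_evaluations_deterministic(toy_mdn):
    x = np.array([[0.25]])
    th = np.linspace(-0.5, 0.8, 40)[:, None]
    a = toy_mdn.log_prob(x, th)
    b = toy_mdn.log_prob(x, th)
    np.testing.assert_array_equal(a, b)


def test_mdn_density_normalized(toy_mdn):
    """Numerical integral of q(theta | x_o) over theta is ~1."""
    grid = np.linspace(-3, 3, 2001)[:, None]
    lp = toy_mdn.log_prob(np.array([[0.3]]), grid)
    mass = np.trapezoid(np.exp(lp), grid[:, 0])
    assert mass == pytest.approx(1.0, abs=0.02)


def test_mdn_training_deterministic():
    rng = np.random.default_rng(5)
    theta = rng.uniform(-1, 1, size=(600, 1))
    x = theta + rng.normal(0, 0.2, size=(600, 1))
    m1 = MixtureDensityNetwork(max_epochs=30, random_state=4).fit(x, theta)
    m2 = MixtureDensityNetwork(max_epochs=30, random_state=4).fit(x, theta)
    g = np.linspace(-1, 1, 11)[:, None]
    np.testing.assert_array_equal(m1.log_prob(np.array([[0.1]]), g),
                                  m2.log_prob(np.array([[0.1]]), g))


def test_mdn_sklearn_protocol(toy_mdn):
    params = toy_mdn.get_params()
    assert params["n_components"] == 10
    clone = MixtureDensityNetwork(**params)
    assert clone.get_params() == params


# ----------------------------------------------------------------------
# posterior wrapper
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_posterior():
    rng = np.random.default_rng(3)
    theta = rng.uniform(-1, 1, size=(5000, 1))
    x = theta + rng.normal(0, 0.1, size=(5000, 1))
    prior = PriorBox(names=("theta",), lows=np.array([-1.0]),
                     highs=np.array([1.0]))
    ts = TrainingSet(thetas=theta, stats=x, n_attempted=5000, n_valid=5000)
    return train_posterior(ts, min_valid=100, prior=prior, random_state=1)


def test_posterior_samples_respect_prior_box(toy_posterior, rng):
    s = toy_posterior.sample(np.array([0.95]), 5000, rng)
    assert np.all((s >= -1.0) & (s <= 1.0))
    assert toy_posterior.last_leakage_ is not None


def test_posterior_amortized(toy_posterior, rng):
    sampler, logd = posterior_for_observation(toy_posterior,
                                              np.array([0.2]))
    th = np.array([[0.2]])
    assert logd(th) == logd(th)
    assert sampler(10, np.random.default_rng(0)).shape == (10, 1)


def test_map_estimate_contract(toy_posterior, rng):
    est = toy_posterior.map_estimate(np.array([0.3]), n_samples=4000,
                                     n_top=50, rng=rng)
    # unimodal symmetric posterior: MAP ~ mean; and ascent never ends
    # below the best initializing sample (in the density it optimizes)
    assert abs(est.theta_star[0] - 0.3) < 0.05
    s = toy_posterior.sample(np.array([0.3]), 4000, rng)
    lp = toy_posterior.map_density(np.array([0.3]), s)
    assert est.log_density >= lp.max() - 1e-9


def test_map_finds_taller_mode_of_bimodal_density(rng):
    """Bimodal conditional: MAP lands on the taller mode."""
    n = 6000
    comp = rng.uniform(size=n) < 0.7
    theta = np.where(comp, rng.normal(-0.5, 0.06, n),
                     rng.normal(0.5, 0.06, n))[:, None]
    x = rng.normal(0, 1, size=(n, 1))  # independent of theta
    prior = PriorBox(names=("t",), lows=np.array([-1.5]),
                     highs=np.array([1.5]))
    ts = TrainingSet(thetas=theta, stats=x, n_attempted=n, n_valid=n)
    post = train_posterior(ts, min_valid=100, prior=prior, random_state=2,
                           max_epochs=150)
    est = post.map_estimate(np.array([0.0]), n_samples=4000, n_top=100,
                            rng=rng)
    assert abs(est.theta_star[0] + 0.5) < 0.1


# ----------------------------------------------------------------------
# training-set construction (smoke scale)
# ----------------------------------------------------------------------

SMOKE_CFG = SimulationConfig(duration=3000.0)
SMOKE_TE = TEConfig(n_perm=60)


def test_build_training_set_smoke_and_determinism():
    ts1 = build_training_set(6, SMOKE_CFG, seed=55, te_config=SMOKE_TE)
    ts2 = build_training_set(6, SMOKE_CFG, seed=55, te_config=SMOKE_TE)
    assert ts1.n_attempted == 6
    assert ts1.provenance["seed"] == 55
    np.testing.assert_array_equal(ts1.thetas, ts2.thetas)
    np.testing.assert_array_equal(ts1.stats, ts2.stats)
    assert np.all(PriorBox().contains(ts1.thetas))
    assert np.all(np.isfinite(ts1.stats))


def test_uncoupled_prior_suffers_near_total_attrition():
    """Zero synaptic weights: almost every simulation fails the
    TE-significance filter."""
    zero = 1e-12
    prior = PriorBox(
        lows=np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 20.0, 20.0, 1400.0]),
        highs=np.array([2.0, 2.0, zero, zero, zero, zero, 60.0, 60.0,
                        1600.0]))
    try:
        ts = build_training_set(8, SMOKE_CFG, prior=prior, seed=3,
                                te_config=SMOKE_TE)
        kept = ts.n_valid
    except RuntimeError:
        kept = 0
    assert kept <= 2  # ~ alpha-level false positives only


def test_train_posterior_enforces_minimum():
    ts = TrainingSet(thetas=np.zeros((10, 9)), stats=np.ones((10, 6)),
                     n_attempted=10, n_valid=10)
    with pytest.raises(ValueError):
        train_posterior(ts, min_valid=500)


# ----------------------------------------------------------------------
# population-level properties on the shared desk-scale training run
# ----------------------------------------------------------------------

def test_posterior_contraction(sbi_posterior, sbi_held_out):
    """The posterior is tighter than the prior: strict contraction for
    the strongly identified axon diameters on >= 95 % of observations,
    and never more than 1.25x the prior spread in any dimension (the
    logit-space mixture's edge-heavy marginals allow a bounded excess
    for the weakly identified weight parameters at this training scale).
    """
    rng = np.random.default_rng(21)
    prior_sd = sbi_posterior.prior.std()
    n_obs = min(40, sbi_held_out.n_valid)
    ratios = []
    for i in range(n_obs):
        s = sbi_posterior.sample(sbi_held_out.stats[i], 1500, rng)
        ratios.append(s.std(axis=0) / prior_sd)
    ratios = np.array(ratios)
    assert np.mean(np.all(ratios[:, :2] <= 1.0, axis=1)) >= 0.95
    assert np.all(ratios <= 1.25)


def test_correlation_structure_diameter_velocity(sbi_training_set):
    """Across prior simulations the diameter-velocity coupling dominates:
    |r(d_pre, v_pre)| exceeds |r(d_pre, p_syn)|, and is the largest
    entry of the v_pre row of the statistic-parameter correlation
    matrix."""
    from synpair.analysis import correlation_matrix
    t, s = sbi_training_set.thetas, sbi_training_set.stats
    r_dv = abs(np.corrcoef(t[:, 0], s[:, 2])[0, 1])
    r_dp = abs(np.corrcoef(t[:, 0], s[:, 4])[0, 1])
    assert r_dv > r_dp
    cm = correlation_matrix(t, s)
    v_pre_row = np.abs(cm[2])
    assert np.nanargmax(v_pre_row) == 0  # d_pre
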