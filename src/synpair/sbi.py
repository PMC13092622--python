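"""Amortized posterior inference over the nine pair parameters.

Neural posterior estimation: a mixture density network (MDN) q(theta | x)
is trained by maximum likelihood on simulated (theta, x) pairs, theta
drawn from the uniform prior box, x the six summary statistics of the
corresponding pair simulation.  Only simulations whose pre -> post
transfer entropy passes its surrogate significance test enter the
training set.  The trained network is amortized: posterior sampling,
density evaluation and MAP extraction for any observation require no
retraining.

The MDN (10 diagonal-Gaussian components conditioned through a 2x64 tanh
network, z-scored inputs and outputs, Adam, early stopping) is implemented
here directly; the estimator follows the scikit-learn protocol
(``fit`` / ``sample`` / ``score_samples``, ``get_params``/``set_params``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import constants as C
from .simulator import PairParameters, SimulationConfig, run_pair_simulation
from .summary import (
    InvalidSummaryError,
    SummaryStats,
    TEConfig,
    extract_summary,
)

_LOG2PI = float(np.log(2.0 * np.pi))


# ----------------------------------------------------------------------
# prior
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PriorBox:
    """Independent uniform prior over the nine pair parameters."""

    names: tuple = C.PARAM_NAMES
    lows: np.ndarray = field(
        default_factory=lambda: np.array([C.PRIOR_RANGES[k][0]
                                          for k in C.PARAM_NAMES]))
    highs: np.ndarray = field(
        default_factory=lambda: np.array([C.PRIOR_RANGES[k][1]
                                          for k in C.PARAM_NAMES]))

    def __post_init__(self) -> None:
        if not np.all(self.lows < self.highs):
            raise ValueError("prior bounds must satisfy lower < upper")

    @property
    def ndim(self) -> int:
        return len(self.names)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        return rng.uniform(self.lows, self.highs, size=(n, self.ndim))

    def contains(self, theta) -> np.ndarray:
        t = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((t >= self.lows) & (t <= self.highs), axis=1)

    def std(self) -> np.ndarray:
        return (self.highs - self.lows) / np.sqrt(12.0)

    # -- logit reparameterization -------------------------------------
    # Posteriors over a uniform box often press flat against its faces;
    # a Gaussian mixture fitted in raw coordinates cannot represent such
    # edge plateaus.  The density estimator therefore works in
    # logit((theta-low)/(high-low)) space, where the box maps to R^d and
    # back-transformed samples are inside the box by construction.

    _LOGIT_EPS = 1e-9

    def to_unbounded(self, theta) -> np.ndarray:
        t = np.atleast_2d(np.asarray(theta, dtype=float))
        u = (t - self.lows) / (self.highs - self.lows)
        u = np.clip(u, self._LOGIT_EPS, 1.0 - self._LOGIT_EPS)
        return np.log(u / (1.0 - u))

    def from_unbounded(self, z) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self.lows + (self.highs - self.lows) / (1.0 + np.exp(-z))

    def log_abs_det_jacobian(self, theta) -> np.ndarray:
        """log |dz/dtheta| summed over dimensions, at theta."""
        t = np.atleast_2d(np.asarray(theta, dtype=float))
        u = (t - self.lows) / (self.highs - self.lows)
        u = np.clip(u, self._LOGIT_EPS, 1.0 - self._LOGIT_EPS)
        return -np.sum(np.log(self.highs - self.lows) + np.log(u)
                       + np.log(1.0 - u), axis=1)


def sample_prior(n: int, prior: PriorBox | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    prior = prior or PriorBox()
    rng = rng or np.random.default_rng()
    return prior.sample(n, rng)


# ----------------------------------------------------------------------
# training set
# ----------------------------------------------------------------------

@dataclass
class TrainingSet:
    thetas: np.ndarray   # (n_valid, 9)
    stats: np.ndarray    # (n_valid, 6)
    n_attempted: int
    n_valid: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thetas.shape[0] != self.stats.shape[0]:
            raise ValueError("thetas and stats must align")
        if not np.all(np.isfinite(self.stats)):
            raise ValueError("stats rows must be finite")
        if self.n_valid != self.thetas.shape[0]:
            raise ValueError("n_valid must equal the stored row count")


def build_training_set(n: int,
                       sim_config: SimulationConfig = SimulationConfig(),
                       prior: PriorBox | None = None,
                       seed: int = 0,
                       te_config: TEConfig = TEConfig(),
                       progress: bool = False) -> TrainingSet:
    """Simulate ``n`` prior draws and keep the TE-significant ones.

    Each draw gets its own simulation seed derived from ``seed``; invalid
    draws (numerically failed, silent, undefined statistic, or
    non-significant transfer entropy) are counted as attrition.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prior = prior or PriorBox()
    ss = np.random.SeedSequence(seed)
    rng_prior, rng_te = (np.random.default_rng(s) for s in ss.spawn(2))
    sim_seeds = ss.spawn(1)[0].generate_state(n) % (2**31 - 1)
    thetas = prior.sample(n, rng_prior)
    kept_t, kept_x = [], []
    reasons: dict[str, int] = {}
    for i in range(n):
        theta = PairParameters.from_array(thetas[i])
        cfg = SimulationConfig(duration=sim_config.duration,
                               dt=sim_config.dt,
                               seed=int(sim_seeds[i]),
                               settle=sim_config.settle)
        res = run_pair_simulation(theta, cfg)
        try:
            s = extract_summary(res, te_config=te_config, rng=rng_te,
                                require_significance=True)
        except InvalidSummaryError as e:
            key = str(e).split("(")[0].strip()
            reasons[key] = reasons.get(key, 0) + 1
            continue
        kept_t.append(thetas[i])
        kept_x.append(s.to_array())
    if not kept_t:
        raise RuntimeError("no valid simulations survived the filters")
    return TrainingSet(
        thetas=np.array(kept_t), stats=np.array(kept_x),
        n_attempted=n, n_valid=len(kept_t),
        provenance={"seed": seed, "duration": sim_config.duration,
                    "dt": sim_config.dt, "attrition": reasons},
    )


# ----------------------------------------------------------------------
# mixture density network
# ----------------------------------------------------------------------

def _logsumexp(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
            ).squeeze(axis)


def _softmax(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    e = np.exp(a - m)
    return e / e.sum(axis=axis, keepdims=True)


class MixtureDensityNetwork(BaseEstimator):
    """Conditional density estimator q(y | X) as a Gaussian mixture.

    A two-hidden-layer tanh network maps the conditioning variable to the
    mixture weights, means and per-dimension standard deviations of
    ``n_components`` diagonal Gaussians over y.  Trained by minimizing the
    negative log-likelihood with Adam at its default hyperparameters,
    10 % early-stopping validation split, inputs and outputs z-scored.

    Follows the scikit-learn estimator protocol; fitted attributes carry
    trailing underscores.
    """

    def __init__(self, n_components: int = 10, hidden: int = 64,
                 learning_rate: float = 1e-3, batch_size: int = 256,
                 max_epochs: int = 400, patience: int = 20,
                 val_fraction: float = 0.1, log_sigma_clip: float = 7.0,
                 log_sigma_max: float = 0.0, random_state: int = 0):
        self.n_components = n_components
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.log_sigma_clip = log_sigma_clip
        # cap component spread at the training marginal's own scale
        # (standardized units): a conditional component broader than the
        # marginal is never needed and, for near-flat posteriors, pushes
        # spurious mass toward the support's edges
        self.log_sigma_max = log_sigma_max
        self.random_state = random_state

    # -- internals -----------------------------------------------------

    def _forward(self, Xs, params=None):
        p = params or self.params_
        a1 = np.tanh(Xs @ p["W1"] + p["b1"])
        a2 = np.tanh(a1 @ p["W2"] + p["b2"])
        logits = a2 @ p["W3"] + p["b3"]
        K, D = self.n_components, self._ydim
        mu = (a2 @ p["W4"] + p["b4"]).reshape(-1, K, D)
        ls = np.clip((a2 @ p["W5"] + p["b5"]).reshape(-1, K, D),
                     -self.log_sigma_clip, self.log_sigma_max)
        return a1, a2, logits, mu, ls

    def _log_joint(self, logits, mu, ls, ys):
        """log pi_k + log N(y; mu_k, sigma_k) per sample/component."""
        log_pi = logits - _logsumexp(logits, axis=1)[:, None]
        z = (ys[:, None, :] - mu) / np.exp(ls)
        comp = -0.5 * np.sum(z * z, axis=2) - np.sum(ls, axis=2) \
            - 0.5 * self._ydim * _LOG2PI
        return log_pi + comp, z

    def _nll(self, Xs, ys, params=None):
        _, _, logits, mu, ls = self._forward(Xs, params)
        lj, _ = self._log_joint(logits, mu, ls, ys)
        return -float(np.mean(_logsumexp(lj, axis=1)))

    def _init_params(self, rng, xdim, ydim):
        H, K, D = self.hidden, self.n_components, ydim

        def lin(fi, fo):
            return rng.normal(0.0, 1.0 / np.sqrt(fi), size=(fi, fo))

        return {
            "W1": lin(xdim, H), "b1": np.zeros(H),
            "W2": lin(H, H), "b2": np.zeros(H),
            "W3": lin(H, K) * 0.1, "b3": np.zeros(K),
            "W4": lin(H, K * D) * 0.1,
            "b4": rng.uniform(-1.0, 1.0, size=K * D),
            "W5": lin(H, K * D) * 0.01, "b5": np.zeros(K * D),
        }

    def _gradients(self, Xs, ys, params):
        B = Xs.shape[0]
        K, D = self.n_components, self._ydim
        a1, a2, logits, mu, ls = self._forward(Xs, params)
        lj, z = self._log_joint(logits, mu, ls, ys)
        r = _softmax(lj, axis=1)                      # responsibilities
        pi = _softmax(logits, axis=1)
        d_logits = (pi - r) / B
        sig = np.exp(ls)
        d_mu = -(r[:, :, None] * z / sig) / B
        d_ls = -(r[:, :, None] * (z * z - 1.0)) / B
        # clip boundary: zero gradient where clipped
        clipped = (ls <= -self.log_sigma_clip + 1e-12) | \
            (ls >= self.log_sigma_max - 1e-12)
        d_ls[clipped] = 0.0
        d_a2 = (d_logits @ params["W3"].T
                + d_mu.reshape(B, K * D) @ params["W4"].T
                + d_ls.reshape(B, K * D) @ params["W5"].T)
        d_z2 = d_a2 * (1.0 - a2 * a2)
        d_a1 = d_z2 @ params["W2"].T
        d_z1 = d_a1 * (1.0 - a1 * a1)
        return {
            "W1": Xs.T @ d_z1, "b1": d_z1.sum(0),
            "W2": a1.T @ d_z2, "b2": d_z2.sum(0),
            "W3": a2.T @ d_logits, "b3": d_logits.sum(0),
            "W4": a2.T @ d_mu.reshape(B, K * D),
            "b4": d_mu.reshape(B, K * D).sum(0),
            "W5": a2.T @ d_ls.reshape(B, K * D),
            "b5": d_ls.reshape(B, K * D).sum(0),
        }

    # -- estimator API -------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be aligned 2-D arrays")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        n = X.shape[0]
        self._ydim = y.shape[1]
        self.x_mean_ = X.mean(0)
        self.x_scale_ = np.where(X.std(0) > 1e-12, X.std(0), 1.0)
        self.y_mean_ = y.mean(0)
        self.y_scale_ = np.where(y.std(0) > 1e-12, y.std(0), 1.0)
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng, X.shape[1], self._ydim)
        n_val = max(1, int(round(self.val_fraction * n)))
        perm = rng.permutation(n)
        vi, ti = perm[:n_val], perm[n_val:]
        if ti.size == 0:
            raise ValueError("not enough samples for a validation split")

        mom = {k: np.zeros_like(v) for k, v in params.items()}
        vel = {k: np.zeros_like(v) for k, v in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        wait = 0
        self.loss_curve_ = []
        self.params_ = params
        for epoch in range(self.max_epochs):
            order = rng.permutation(ti)
            for s in range(0, ti.size, self.batch_size):
                idx = order[s:s + self.batch_size]
                g = self._gradients(Xs[idx], ys[idx], params)
                step += 1
                for k in params:
                    mom[k] = b1 * mom[k] + (1 - b1) * g[k]
                    vel[k] = b2 * vel[k] + (1 - b2) * g[k] ** 2
                    mhat = mom[k] / (1 - b1 ** step)
                    vhat = vel[k] / (1 - b2 ** step)
                    params[k] -= self.learning_rate * mhat / (
                        np.sqrt(vhat) + eps)
            vl = self._nll(Xs[vi], ys[vi], params)
            if not np.isfinite(vl):
                raise RuntimeError(f"divergent training loss at epoch {epoch}")
            self.loss_curve_.append(vl)
            if vl < best - 1e-5:
                best = vl
                best_params = {k: v.copy() for k, v in params.items()}
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
            self.params_ = params
        self.params_ = best_params
        self.n_epochs_ = len(self.loss_curve_)
        self.best_val_nll_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def _mixture(self, X):
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean_) / self.x_scale_
        _, _, logits, mu, ls = self._forward(Xs)
        return _softmax(logits, axis=1), mu, np.exp(ls)

    def log_prob(self, X, y):
        """log q(y | X) in the original units of y."""
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if X.shape[0] == 1 and y.shape[0] > 1:
            X = np.broadcast_to(X, (y.shape[0], X.shape[1]))
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_
        _, _, logits, mu, ls = self._forward(Xs)
        lj, _ = self._log_joint(logits, mu, ls, ys)
        return _logsumexp(lj, axis=1) - np.sum(np.log(self.y_scale_))

    def score_samples(self, X, y):
        return self.log_prob(X, y)

    def sample(self, X, n_samples: int, rng: np.random.Generator):
        """Draw ``n_samples`` y's conditioned on a single X row."""
        pi, mu, sig = self._mixture(X)
        pi, mu, sig = pi[0], mu[0], sig[0]
        comp = rng.choice(self.n_components, size=n_samples, p=pi)
        z = rng.standard_normal((n_samples, self._ydim))
        ys = mu[comp] + sig[comp] * z
        return ys * self.y_scale_ + self.y_mean_

    def grad_log_prob(self, X, y):
        """d log q(y|X) / dy in original units (for MAP ascent)."""
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if X.shape[0] == 1 and y.shape[0] > 1:
            X = np.broadcast_to(X, (y.shape[0], X.shape[1]))
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_
        _, _, logits, mu, ls = self._forward(Xs)
        lj, z = self._log_joint(logits, mu, ls, ys)
        r = _softmax(lj, axis=1)
        sig = np.exp(ls)
        g_std = np.sum(r[:, :, None] * (-z / sig), axis=1)
        return g_std / self.y_scale_


# ----------------------------------------------------------------------
# posterior wrapper
# ----------------------------------------------------------------------

@dataclass
class MAPEstimate:
    theta_star: np.ndarray
    log_density: float
    n_starts: int

    def as_parameters(self) -> PairParameters:
        return PairParameters.from_array(self.theta_star)


class PosteriorModel:
    """Amortized posterior over theta.

    The estimator works in the prior box's logit coordinates (see
    ``PriorBox.to_unbounded``), so samples are inside the box by
    construction and no posterior mass leaks past the uniform prior's
    support; ``last_leakage_`` is therefore always 0 after sampling.
    Density evaluations include the change-of-variables Jacobian and are
    reported in the original theta units.
    """

    def __init__(self, estimator: MixtureDensityNetwork,
                 prior: PriorBox | None = None):
        check_is_fitted(estimator, "params_")
        self.estimator = estimator
        self.prior = prior or PriorBox()
        self.last_leakage_ = None

    def _check_obs(self, x_obs) -> np.ndarray:
        x = np.atleast_2d(np.asarray(
            x_obs.to_array() if isinstance(x_obs, SummaryStats) else x_obs,
            dtype=float))
        if x.shape != (1, self.estimator.n_features_in_):
            raise ValueError("x_obs must be a single summary vector")
        if not np.all(np.isfinite(x)):
            raise ValueError("x_obs must be finite")
        dev = np.abs((x - self.estimator.x_mean_) / self.estimator.x_scale_)
        if np.any(dev > 5.0):
            import warnings
            warnings.warn("x_obs lies > 5 scale units outside the training "
                          "standardization; the amortized posterior may be "
                          "unreliable", RuntimeWarning)
        return x

    def sample(self, x_obs, n_samples: int,
               rng: np.random.Generator) -> np.ndarray:
        x = self._check_obs(x_obs)
        z = self.estimator.sample(x, n_samples, rng)
        theta = self.prior.from_unbounded(z)
        self.last_leakage_ = 0.0  # in-box by construction
        return theta

    def log_prob(self, x_obs, theta) -> np.ndarray:
        """log q(theta | x_obs) in original theta units."""
        x = self._check_obs(x_obs)
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        z = self.prior.to_unbounded(theta)
        return (self.estimator.log_prob(x, z)
                + self.prior.log_abs_det_jacobian(theta))

    def map_density(self, x_obs, theta) -> np.ndarray:
        """The density the MAP maximizes: q in the box's logit coordinates.

        This is the posterior density relative to the uniform prior's
        natural parameterization.  The raw-coordinate density of a
        box-transformed mixture develops boundary spikes (the logit
        Jacobian diverges at the faces) that are estimator artifacts, not
        posterior features; modes are therefore located in the unbounded
        coordinates, where they track the posterior bulk.
        """
        x = self._check_obs(x_obs)
        z = self.prior.to_unbounded(np.atleast_2d(np.asarray(theta,
                                                            dtype=float)))
        return self.estimator.log_prob(x, z)

    def map_estimate(self, x_obs, n_samples: int = 10_000,
                     n_top: int = 200, n_steps: int = 100,
                     step_size: float = 1e-2,
                     rng: np.random.Generator | None = None) -> MAPEstimate:
        """MAP by gradient ascent from the best posterior samples.

        Draw ``n_samples``, keep the ``n_top`` with the highest
        ``map_density``, ascend it for ``n_steps`` (step in standardized
        coordinates) and return the best endpoint — never below the best
        initializing sample.
        """
        rng = rng or np.random.default_rng(0)
        x = self._check_obs(x_obs)
        samples = self.sample(x, n_samples, rng)
        lp = self.map_density(x, samples)
        order = np.argsort(lp)
        best_start = float(lp[order[-1]])
        cur_z = self.prior.to_unbounded(samples[order[-n_top:]])
        scale = self.estimator.y_scale_
        for _ in range(n_steps):
            g = self.estimator.grad_log_prob(x, cur_z)
            cur_z = cur_z + step_size * g * scale**2
        cur = self.prior.from_unbounded(cur_z)
        lp_end = self.map_density(x, cur)
        i = int(np.argmax(lp_end))
        if lp_end[i] >= best_start:
            theta_star, ld = cur[i], float(lp_end[i])
        else:  # ascent contract: never worse than the best initializer
            theta_star, ld = samples[order[-1]], best_start
        return MAPEstimate(theta_star=theta_star, log_density=ld,
                           n_starts=n_top)


def train_posterior(ts: TrainingSet, min_valid: int = 500,
                    prior: PriorBox | None = None,
                    **mdn_kwargs) -> PosteriorModel:
    """Fit the MDN posterior on a training set (x -> theta)."""
    if ts.n_valid < min_valid:
        raise ValueError(
            f"training set has {ts.n_valid} valid rows < minimum {min_valid}"
        )
    prior = prior or PriorBox()
    mdn = MixtureDensityNetwork(**mdn_kwargs)
    mdn.fit(ts.stats, prior.to_unbounded(ts.thetas))
    return PosteriorModel(mdn, prior)


def posterior_for_observation(model: PosteriorModel, x_obs):
    """Amortized (sampler, log-density) pair for one observation."""
    x = model._check_obs(x_obs)

    def sampler(n, rng):
        return model.sample(x, n, rng)

    def log_density(theta):
        return model.log_prob(x, theta)

    return sampler, log_density


def sbc_ranks(model: PosteriorModel, thetas: np.ndarray, stats: np.ndarray,
              n_post: int = 99, rng: np.random.Generator | None = None
              ) -> np.ndarray:
    """Simulation-based-calibration ranks of true theta in posterior draws.

    For each (theta_i, x_i), the rank of theta_i among ``n_post``
    posterior samples, per dimension; uniform on {0..n_post} when the
    posterior is calibrated.
    """
    rng = rng or np.random.default_rng(0)
    ranks = np.empty((thetas.shape[0], thetas.shape[1]), dtype=int)
    for i in range(thetas.shape[0]):
        s = model.sample(stats[i], n_post, rng)
        ranks[i] = np.sum(s < thetas[i], axis=0)
    return ranks
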