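"""Linear-Gaussian hidden Markov model and particle Metropolis-Hastings.

The model: X_0 = x0 known, X_t = a X_{t-1} + N(0, sigma_X^2), observed
through Y_t = X_t + N(0, sigma_Y^2).  Its likelihood l(theta; y_{1:T}) is
available exactly through the Kalman prediction-error decomposition, which
makes the model a controlled test bed: the bootstrap particle filter gives
an unbiased estimate l^_N of the same likelihood, so the implied weight
W_{theta,N} = l^_N / l has unit mean and the marginal, pseudo-marginal and
noisy samplers over theta can be compared against each other.

Sampler modes:

``marginal``
    Random-walk MH using the exact Kalman likelihood.
``pseudo_marginal``
    Particle marginal MH: the likelihood estimate of the accepted point is
    stored and recycled until the next acceptance.
``noisy``
    Monte Carlo within Metropolis: the likelihood of *both* the current
    and the proposed parameter is re-estimated afresh at every iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kernels import make_streams

__all__ = [
    "LinearGaussianHMM",
    "LikelihoodEstimate",
    "ThetaTrace",
    "simulate_hmm",
    "kalman_loglik",
    "bootstrap_pf",
    "pmmh_chain",
    "DEFAULT_PRIOR_BOX",
]

_LOG_2PI = math.log(2.0 * math.pi)

PARAM_NAMES = ("x0", "a", "sigma_X2", "sigma_Y2")

#: Box-uniform prior used by default: stable autoregression, bounded variances.
DEFAULT_PRIOR_BOX: Dict[str, Tuple[float, float]] = {
    "x0": (-5.0, 5.0),
    "a": (-1.0, 1.0),
    "sigma_X2": (0.0, 10.0),
    "sigma_Y2": (0.0, 10.0),
}


@dataclass(frozen=True)
class LinearGaussianHMM:
    """Parameters theta = (x0, a, sigma_X2, sigma_Y2) of the AR(1)-plus-noise model."""

    x0: float = 0.0
    a: float = 0.9
    sigma_X2: float = 1.0
    sigma_Y2: float = 1.0

    def __post_init__(self):
        if not (self.sigma_X2 > 0 and self.sigma_Y2 > 0):
            raise ValueError("variances must be positive")


@dataclass
class LikelihoodEstimate:
    """Particle-filter likelihood estimate on the log scale."""

    log_lhat: float
    N_particles: int
    seed: Optional[int] = None


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_hmm(model: LinearGaussianHMM, T: int, seed) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate (X_0..X_T, Y_1..Y_T) from the model."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = _as_rng(seed)
    sx, sy = math.sqrt(model.sigma_X2), math.sqrt(model.sigma_Y2)
    x = np.empty(T + 1)
    x[0] = model.x0
    for t in range(1, T + 1):
        x[t] = model.a * x[t - 1] + sx * rng.standard_normal()
    y = x[1:] + sy * rng.standard_normal(T)
    return x, y


def kalman_loglik(model: LinearGaussianHMM, observations: Sequence[float]) -> float:
    """Exact log-likelihood via the Kalman prediction-error decomposition.

    X_0 = x0 is known, so the filter starts from a point mass.
    """
    ys = np.asarray(observations, dtype=float)
    if ys.size == 0:
        raise ValueError("observations must be non-empty")
    m_f, p_f = model.x0, 0.0
    ll = 0.0
    for y in ys:
        m_p = model.a * m_f
        p_p = model.a ** 2 * p_f + model.sigma_X2
        s = p_p + model.sigma_Y2
        v = y - m_p
        ll += -0.5 * (_LOG_2PI + math.log(s) + v * v / s)
        k = p_p / s
        m_f = m_p + k * v
        p_f = (1.0 - k) * p_p
    return float(ll)


def bootstrap_pf(
    model: LinearGaussianHMM, observations: Sequence[float], N_particles: int, seed
) -> LikelihoodEstimate:
    """Bootstrap particle filter with multinomial resampling at every step.

    Returns the unbiased (on the natural scale) likelihood estimate
    log l^_N = sum_t log( mean_i g(y_t | X_t^i) ).
    """
    if N_particles < 1:
        raise ValueError("N_particles must be >= 1")
    ys = np.asarray(observations, dtype=float)
    if ys.size == 0:
        raise ValueError("observations must be non-empty")
    rng = _as_rng(seed)
    sx = math.sqrt(model.sigma_X2)
    x = np.full(N_particles, model.x0, dtype=float)
    log_lhat = 0.0
    for y in ys:
        x = model.a * x + sx * rng.standard_normal(N_particles)
        logw = -0.5 * (_LOG_2PI + math.log(model.sigma_Y2)
                       + (y - x) ** 2 / model.sigma_Y2)
        mx = float(np.max(logw))
        w = np.exp(logw - mx)
        total = float(w.sum())
        if not total > 0.0:
            raise FloatingPointError("all particle weights vanished")
        log_lhat += mx + math.log(total / N_particles)
        # multinomial resampling
        cum = np.cumsum(w / total)
        idx = np.searchsorted(cum, rng.random(N_particles))
        x = x[idx]
    return LikelihoodEstimate(float(log_lhat), N_particles,
                              seed if isinstance(seed, int) else None)


@dataclass
class ThetaTrace:
    """MCMC trace over the HMM parameters."""

    param_names: Tuple[str, ...]
    thetas: np.ndarray  # shape (n_steps + 1, n_params)
    accepted: np.ndarray
    seed: int
    kernel_descriptor: dict = field(default_factory=dict)

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def samples(self, name: str, burn_in: int = 0) -> np.ndarray:
        j = self.param_names.index(name)
        return self.thetas[burn_in:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.thetas, columns=list(self.param_names))
        df.insert(0, "step", np.arange(len(df)))
        df["accepted"] = np.concatenate([[np.nan], self.accepted.astype(float)])
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _in_box(theta: Dict[str, float], box: Dict[str, Tuple[float, float]]) -> bool:
    return all(box[k][0] < theta[k] < box[k][1] for k in theta)


def pmmh_chain(
    observations: Sequence[float],
    init: LinearGaussianHMM,
    n_steps: int,
    seed: int,
    mode: str = "pseudo_marginal",
    *,
    n_particles: int = 250,
    infer: Sequence[str] = ("a", "sigma_X2", "sigma_Y2"),
    prior_box: Optional[Dict[str, Tuple[float, float]]] = None,
    proposal_scale: float | Dict[str, float] = 0.05,
) -> ThetaTrace:
    """Random-walk MH over a subset of theta, in one of three modes.

    The prior is box-uniform over the inferred coordinates; a joint
    Gaussian random-walk proposal updates all inferred coordinates at
    once, and moves leaving the prior box are rejected through zero prior
    mass.  ``marginal`` mode uses the exact Kalman likelihood; the two
    estimate-driven modes use the bootstrap filter with ``n_particles``.
    """
    if mode not in ("marginal", "pseudo_marginal", "noisy"):
        raise ValueError(f"unknown mode {mode!r}")
    infer = tuple(infer)
    for k in infer:
        if k not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {k!r}")
    box = {k: (prior_box or DEFAULT_PRIOR_BOX)[k] for k in infer}
    if isinstance(proposal_scale, dict):
        scales = np.array([proposal_scale[k] for k in infer])
    else:
        scales = np.full(len(infer), float(proposal_scale))

    theta = {k: getattr(init, k) for k in infer}
    if not _in_box(theta, box):
        raise ValueError("initial parameters fall outside the prior box")

    streams = make_streams(seed)
    ys = np.asarray(observations, dtype=float)

    def model_of(th: Dict[str, float]) -> LinearGaussianHMM:
        return replace(init, **th)

    def exact_ll(th):
        return kalman_loglik(model_of(th), ys)

    def pf_ll(th):
        return bootstrap_pf(model_of(th), ys, n_particles, streams.weights).log_lhat

    thetas = np.empty((n_steps + 1, len(infer)))
    accepted = np.zeros(n_steps, dtype=bool)
    thetas[0] = [theta[k] for k in infer]

    cur_ll = None
    if mode == "marginal":
        cur_ll = exact_ll(theta)
    elif mode == "pseudo_marginal":
        cur_ll = bootstrap_pf(model_of(theta), ys, n_particles, streams.init).log_lhat

    for i in range(n_steps):
        step = scales * streams.proposal.standard_normal(len(infer))
        prop = {k: theta[k] + step[j] for j, k in enumerate(infer)}
        if not _in_box(prop, box):
            streams.accept.random()
            thetas[i + 1] = thetas[i]
            continue
        if mode == "marginal":
            prop_ll = exact_ll(prop)
            lr = prop_ll - cur_ll
        elif mode == "pseudo_marginal":
            prop_ll = pf_ll(prop)
            lr = prop_ll - cur_ll
        else:  # noisy: both likelihoods re-estimated afresh
            prop_ll = pf_ll(prop)
            cur_ll = pf_ll(theta)
            lr = prop_ll - cur_ll
        u = streams.accept.random()
        if lr >= 0.0 or math.log(u) < lr:
            theta = prop
            accepted[i] = True
            if mode != "noisy":
                cur_ll = prop_ll
        thetas[i + 1] = [theta[k] for k in infer]

    desc = {"mode": mode, "n_particles": n_particles, "infer": list(infer),
            "prior_box": {k: list(v) for k, v in box.items()},
            "proposal_scale": scales.tolist(), "T": int(ys.size)}
    return ThetaTrace(infer, thetas, accepted, seed, desc)
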