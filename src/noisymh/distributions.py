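"""Target distributions and proposal kernels.

The stability phenomena studied in this package arise for very simple
targets: a geometric distribution on the positive integers, generic
log-concave distributions on the positive integers, and the standard
normal.  Proposals are nearest-neighbour random walks on the integers
(possibly biased) and Gaussian random walks on the reals.

Discrete targets live on the positive integers {1, 2, ...}; proposals walk
on all integers and moves onto states of zero target mass are rejected
through a zero acceptance probability rather than being excluded from the
proposal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TargetDistribution",
    "ProposalKernel",
    "geometric_target",
    "log_concave_target",
    "std_normal_target",
    "integer_walk_proposal",
    "gaussian_rw_proposal",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TargetDistribution:
    """An (unnormalised) target density with known support.

    Parameters
    ----------
    log_density_unnorm
        Unnormalised log-density; returns ``-inf`` off the support.
    support
        Either ``"positive_integers"`` or ``"reals"``.
    exact_pmf
        For discrete targets, the exactly normalised pmf.
    name, params
        Descriptor echoed into traces and manifests.
    """

    log_density_unnorm: Callable[[float], float]
    support: str
    exact_pmf: Optional[Callable[[int], float]] = None
    name: str = "target"
    params: dict = field(default_factory=dict)

    @property
    def discrete(self) -> bool:
        return self.support == "positive_integers"

    def in_support(self, x) -> bool:
        if self.discrete:
            return float(x).is_integer() and x >= 1
        return bool(np.isfinite(x))

    def log_pdf(self, x) -> float:
        """Unnormalised log-density, ``-inf`` off the support."""
        if not self.in_support(x):
            return -math.inf
        return float(self.log_density_unnorm(x))


@dataclass(frozen=True)
class ProposalKernel:
    """A Markov proposal kernel q(x, .).

    ``sample`` draws a proposal given the current state; ``log_density`` is
    the transition density q(x, y) evaluated pointwise (a pmf for the
    integer walk, a Lebesgue density for the Gaussian walk).
    """

    sample: Callable[[float, np.random.Generator], float]
    log_density: Callable[[float, float], float]
    symmetric: bool
    name: str = "proposal"
    params: dict = field(default_factory=dict)


def geometric_target() -> TargetDistribution:
    """Geometric target pi(m) = (1/2)^m on the positive integers.

    The normalising constant is exactly 1, so ``exact_pmf`` is available in
    closed form.
    """

    def logp(m):
        return -float(m) * math.log(2.0)

    def pmf(m):
        if float(m).is_integer() and m >= 1:
            return 0.5 ** int(m)
        return 0.0

    return TargetDistribution(logp, "positive_integers", pmf, "geometric", {})


def log_concave_target(
    h: Callable[[int], float],
    *,
    tail_cutoff: float = 1e-12,
    convexity_window: int = 100,
    max_states: int = 100_000,
) -> TargetDistribution:
    """Log-concave target pi(m) proportional to exp{-h(m)} on m >= 1.

    ``h`` must be convex (checked via second differences on a finite
    window).  The normalising constant is computed by direct summation
    until the remaining tail mass falls below ``tail_cutoff``; a bounded
    ``h`` makes the sum divergent and raises ``ValueError``.
    """
    ms = np.arange(1, convexity_window + 1)
    hv = np.array([h(int(m)) for m in ms], dtype=float)
    second = np.diff(hv, 2)
    if np.any(second < -1e-9):
        raise ValueError("h is not convex on the checked window")

    # Summation with a geometric-tail bound: once terms decay, the residual
    # tail is bounded by t_m * r / (1 - r) with r the last term ratio.
    total = 0.0
    prev = None
    m = 1
    while m <= max_states:
        try:
            t = math.exp(-h(m))
        except OverflowError:
            raise ValueError("normalising sum diverges; h must grow to +inf") from None
        total += t
        if prev is not None and t < prev:
            r = t / prev
            tail_bound = t * r / (1.0 - r)
            if tail_bound < tail_cutoff * total:
                break
        prev = t
        m += 1
    else:
        raise ValueError("normalising sum did not converge; h may be bounded above")
    log_z = math.log(total)

    def logp(mm):
        return -h(int(mm))

    def pmf(mm):
        if float(mm).is_integer() and mm >= 1:
            return math.exp(-h(int(mm)) - log_z)
        return 0.0

    return TargetDistribution(logp, "positive_integers", pmf, "log_concave", {"log_z": log_z})


def std_normal_target() -> TargetDistribution:
    """Standard normal target on the reals."""

    def logp(x):
        return -0.5 * (x * x + _LOG_2PI)

    return TargetDistribution(logp, "reals", None, "std_normal", {})


def integer_walk_proposal(theta: float) -> ProposalKernel:
    """Nearest-neighbour random walk on the integers.

    q(m, {m+1}) = theta and q(m, {m-1}) = 1 - theta for every integer m.
    The kernel is symmetric exactly when theta = 1/2.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")

    def sample(m, rng: np.random.Generator):
        return int(m) + (1 if rng.random() < theta else -1)

    def log_density(m, mp):
        d = int(mp) - int(m)
        if d == 1:
            return math.log(theta)
        if d == -1:
            return math.log1p(-theta)
        return -math.inf

    return ProposalKernel(
        sample, log_density, symmetric=(theta == 0.5), name="integer_walk", params={"theta": theta}
    )


def gaussian_rw_proposal(variance: float) -> ProposalKernel:
    """Gaussian random walk q(x, .) = N(x, variance) on the reals."""
    if not variance > 0:
        raise ValueError("variance must be positive")
    sd = math.sqrt(variance)

    def sample(x, rng: np.random.Generator):
        return float(x) + sd * rng.standard_normal()

    def log_density(x, y):
        z = (float(y) - float(x)) / sd
        return -0.5 * (z * z + _LOG_2PI) - math.log(sd)

    return ProposalKernel(
        sample, log_density, symmetric=True, name="gaussian_rw", params={"variance": variance}
    )
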