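"""Marginal, pseudo-marginal and noisy Metropolis-Hastings kernels.

Three closely related chains are implemented:

* the *marginal* chain: standard MH with acceptance
  min{1, pi(y) q(y,x) / (pi(x) q(x,y))};
* the *pseudo-marginal* chain on the extended state (x, w): the proposed
  pair (y, u) with u ~ Q_{y,N} is accepted with
  min{1, pi(y) u q(y,x) / (pi(x) w q(x,y))}, and on rejection the current
  weight w is retained (it is an input, never refreshed), which makes pi
  the exact x-marginal of the invariant distribution;
* the *noisy* chain (Monte Carlo within Metropolis): both weights W_{x,N}
  and W_{y,N} are redrawn fresh at every step, giving a Markov chain on x
  alone that is generally non-reversible and need not leave pi invariant.

Acceptance ratios are computed in log space so extreme weight ratios
cannot overflow.  Proposal draws, weight draws and acceptance uniforms
come from three independent named randomness streams; because the unit
weight model consumes no randomness, the noisy chain with unit weights is
seed-for-seed identical to the marginal chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .distributions import ProposalKernel, TargetDistribution
from .weights import WeightModel

__all__ = [
    "RngStreams",
    "ChainState",
    "ChainTrace",
    "make_streams",
    "marginal_step",
    "pseudo_marginal_step",
    "noisy_step",
    "run_chain",
]


@dataclass
class RngStreams:
    """Independent named randomness streams for one chain run."""

    proposal: np.random.Generator
    weights: np.random.Generator
    accept: np.random.Generator
    init: np.random.Generator


def make_streams(seed: int) -> RngStreams:
    """Spawn the four named streams deterministically from one seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    return RngStreams(*(np.random.default_rng(c) for c in children))


@dataclass
class ChainState:
    """Current point of a chain; ``w`` is the retained pseudo-marginal weight."""

    x: float
    w: Optional[float] = None

    def __post_init__(self):
        if self.w is not None and not self.w > 0:
            raise ValueError("pseudo-marginal weight must be positive")


@dataclass
class ChainTrace:
    """States visited by a kernel plus per-step proposals and accept flags.

    ``states`` has length n_steps + 1 (the initial state first);
    ``proposals`` and ``accepted`` have length n_steps.
    """

    states: np.ndarray
    proposals: np.ndarray
    accepted: np.ndarray
    seed: int
    kernel_descriptor: dict = field(default_factory=dict)
    weights_trace: Optional[np.ndarray] = None

    @property
    def n_steps(self) -> int:
        return len(self.accepted)

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "step": np.arange(self.n_steps + 1),
            "x": self.states,
            "proposed": np.concatenate([[np.nan], self.proposals]),
            "accepted": np.concatenate([[np.nan], self.accepted.astype(float)]),
        })
        if self.weights_trace is not None:
            df["w"] = self.weights_trace
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _log_marginal_ratio(target: TargetDistribution, proposal: ProposalKernel, x, y) -> float:
    """log[ pi(y) q(y,x) / (pi(x) q(x,y)) ], -inf off-support."""
    lp_y = target.log_pdf(y)
    if lp_y == -math.inf:
        return -math.inf
    lr = lp_y - target.log_pdf(x)
    if not proposal.symmetric:
        lr += proposal.log_density(y, x) - proposal.log_density(x, y)
    return lr


def _accept(log_ratio: float, accept_rng: np.random.Generator) -> bool:
    # the uniform is always consumed, keeping streams aligned across kernels
    u = accept_rng.random()
    if log_ratio >= 0.0:
        return True
    return math.log(u) < log_ratio


def marginal_step(current: ChainState, target, proposal, streams: RngStreams):
    """One draw of the marginal MH kernel; returns (next_state, proposed, accepted)."""
    x = current.x
    y = proposal.sample(x, streams.proposal)
    lr = _log_marginal_ratio(target, proposal, x, y)
    if lr == -math.inf:
        streams.accept.random()  # consume for alignment
        return ChainState(x), y, False
    if _accept(lr, streams.accept):
        return ChainState(y), y, True
    return ChainState(x), y, False


def pseudo_marginal_step(
    current: ChainState, target, proposal, weights: WeightModel, N: int, streams: RngStreams
):
    """One draw of the pseudo-marginal kernel on (x, w).

    The auxiliary weight of the proposed point is drawn from Q_{y,N}; the
    current weight ``current.w`` is treated as an input and kept unchanged
    on rejection.
    """
    x, w = current.x, current.w
    if w is None or not w > 0:
        raise ValueError("pseudo-marginal step requires a positive current weight")
    y = proposal.sample(x, streams.proposal)
    base = _log_marginal_ratio(target, proposal, x, y)
    if base == -math.inf:
        streams.accept.random()
        return ChainState(x, w), y, False
    u = weights.sample(y, N, streams.weights)
    lr = base + math.log(u) - math.log(w)
    if _accept(lr, streams.accept):
        return ChainState(y, u), y, True
    return ChainState(x, w), y, False


def noisy_step(
    current: ChainState, target, proposal, weights: WeightModel, N: int, streams: RngStreams
):
    """One draw of the noisy (Monte Carlo within Metropolis) kernel.

    Fresh weights W_{y,N} and W_{x,N} are drawn independently of the past
    at every call; the randomised acceptance has expectation equal to the
    exact noisy acceptance probability computed by the ``exact`` module.
    """
    x = current.x
    y = proposal.sample(x, streams.proposal)
    base = _log_marginal_ratio(target, proposal, x, y)
    if base == -math.inf:
        streams.accept.random()
        return ChainState(x), y, False
    wy = weights.sample(y, N, streams.weights)
    wx = weights.sample(x, N, streams.weights)
    lr = base + math.log(wy) - math.log(wx)
    if _accept(lr, streams.accept):
        return ChainState(y), y, True
    return ChainState(x), y, False


_KINDS = ("marginal", "pseudo_marginal", "noisy")


def run_chain(
    kind: str,
    target: TargetDistribution,
    proposal: ProposalKernel,
    x0,
    n_steps: int,
    seed: int,
    weights: Optional[WeightModel] = None,
    N: int = 1,
) -> ChainTrace:
    """Run a chain of ``n_steps`` single-kernel draws from ``x0``.

    Identical arguments and seed give byte-identical traces.  The initial
    pseudo-marginal weight is drawn from Q_{x0,N} at start-up.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown kernel kind {kind!r}; expected one of {_KINDS}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not target.in_support(x0):
        raise ValueError(f"x0={x0!r} is outside the target support")
    if kind != "marginal" and weights is None:
        raise ValueError(f"{kind} chain requires a weight model")

    streams = make_streams(seed)
    xs = np.empty(n_steps + 1)
    proposals = np.empty(n_steps)
    accepted = np.zeros(n_steps, dtype=bool)
    xs[0] = x0

    descriptor = {
        "kind": kind, "target": target.name, "target_params": dict(target.params),
        "proposal": proposal.name, "proposal_params": dict(proposal.params),
        "x0": x0, "n_steps": n_steps, "N": N,
        "weights": weights.name if weights is not None else None,
    }

    if kind == "marginal":
        state = ChainState(x0)
        for i in range(n_steps):
            state, proposals[i], accepted[i] = marginal_step(state, target, proposal, streams)
            xs[i + 1] = state.x
        return ChainTrace(xs, proposals, accepted, seed, descriptor)

    if kind == "noisy":
        state = ChainState(x0)
        for i in range(n_steps):
            state, proposals[i], accepted[i] = noisy_step(
                state, target, proposal, weights, N, streams)
            xs[i + 1] = state.x
        return ChainTrace(xs, proposals, accepted, seed, descriptor)

    # pseudo-marginal
    w0 = weights.sample(x0, N, streams.init)
    ws = np.empty(n_steps + 1)
    ws[0] = w0
    state = ChainState(x0, w0)
    for i in range(n_steps):
        state, proposals[i], accepted[i] = pseudo_marginal_step(
            state, target, proposal, weights, N, streams)
        xs[i + 1] = state.x
        ws[i + 1] = state.w
    return ChainTrace(xs, proposals, accepted, seed, descriptor, weights_trace=ws)
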