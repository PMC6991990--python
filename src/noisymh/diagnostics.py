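"""Chain summaries and total-variation convergence diagnostics.

Total variation between probability measures mu and nu is half the L1
distance between their densities.  For discrete chains it is computed
exactly from pmfs; for continuous chains it is *estimated* through
common-grid histograms (Freedman-Diaconis bin rule on the pooled sample),
an estimator whose bias is of the order of the bin width — monotone
comparisons across replicate counts N are therefore more meaningful than
absolute levels.

The module also exposes the exact one-step kernel perturbation
sup_x || P~_N(x, .) - P(x, .) ||_TV for enumerable integer-state examples,
and the computable bound on || pi~_N - pi ||_TV implied by simultaneous
geometric ergodicity: given constants (R, tau) of the geometric rate
R V(x) tau^n and a perturbation rate r(N), the bound is the minimum over
integer n of f(n) = 2 R tau^n + n / r(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

from .distributions import ProposalKernel, TargetDistribution
from .exact import marginal_transition_table, noisy_transition_table
from .kernels import ChainTrace
from .weights import WeightModel

__all__ = [
    "RateBoundSpec",
    "empirical_pmf",
    "tv_discrete",
    "tv_continuous",
    "acf",
    "sup_kernel_tv",
    "rate_bound",
]


def empirical_pmf(trace: ChainTrace | np.ndarray, burn_in: Optional[int] = None) -> pd.Series:
    """Normalised occupation measure of a discrete trace after burn-in.

    Burn-in defaults to 10% of the trace length.
    """
    xs = trace.states if isinstance(trace, ChainTrace) else np.asarray(trace)
    if burn_in is None:
        burn_in = len(xs) // 10
    if burn_in >= len(xs):
        raise ValueError("burn_in leaves no samples")
    tail = xs[burn_in:]
    vals, counts = np.unique(tail, return_counts=True)
    return pd.Series(counts / counts.sum(), index=vals, name="probability")


def _as_map(p) -> Mapping:
    if isinstance(p, pd.Series):
        return p.to_dict()
    return dict(p)


def tv_discrete(p, q, *, tol: float = 1e-9) -> float:
    """Exact total variation (1/2) sum |p - q| between two pmfs."""
    pm, qm = _as_map(p), _as_map(q)
    for name, m in (("p", pm), ("q", qm)):
        total = sum(m.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"{name} is not normalised (sums to {total!r})")
    keys = set(pm) | set(qm)
    return 0.5 * sum(abs(pm.get(k, 0.0) - qm.get(k, 0.0)) for k in keys)


def tv_continuous(
    sample_a: np.ndarray,
    sample_b: Optional[np.ndarray] = None,
    *,
    analytic_cdf: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    bins: Optional[np.ndarray] = None,
) -> float:
    """Histogram estimate of total variation for continuous laws.

    Compares a sample either with a second sample or with an analytic law
    given through its cdf.  Bin edges default to the Freedman-Diaconis
    rule on the pooled sample; mass outside the binned range enters the
    estimate exactly.
    """
    a = np.asarray(sample_a, dtype=float)
    if a.size < 2 or np.ptp(a) == 0.0:
        raise ValueError("sample_a is degenerate")
    if (sample_b is None) == (analytic_cdf is None):
        raise ValueError("provide exactly one of sample_b or analytic_cdf")
    if sample_b is not None:
        b = np.asarray(sample_b, dtype=float)
        if b.size < 2 or np.ptp(b) == 0.0:
            raise ValueError("sample_b is degenerate")
        pooled = np.concatenate([a, b])
    else:
        pooled = a
    if bins is None:
        bins = np.histogram_bin_edges(pooled, bins="fd")
    pa, _ = np.histogram(a, bins=bins)
    pa = pa / a.size
    out_a = 1.0 - pa.sum()
    if sample_b is not None:
        pb, _ = np.histogram(b, bins=bins)
        pb = pb / b.size
        out_b = 1.0 - pb.sum()
    else:
        cdf_vals = np.asarray(analytic_cdf(bins), dtype=float)
        pb = np.diff(cdf_vals)
        out_b = 1.0 - pb.sum()
    return float(0.5 * (np.abs(pa - pb).sum() + abs(out_a - out_b)))


def acf(trace: ChainTrace | np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations of the numeric state sequence, lags 0..max_lag."""
    xs = trace.states if isinstance(trace, ChainTrace) else np.asarray(trace, dtype=float)
    if max_lag >= len(xs) / 10:
        raise ValueError("max_lag must be below a tenth of the trace length")
    if np.ptp(xs) == 0.0:
        raise ValueError("autocorrelation undefined for a constant trace")
    return _sm_acf(xs, nlags=max_lag, fft=True)


def sup_kernel_tv(
    target: TargetDistribution,
    proposal: ProposalKernel,
    weights: WeightModel,
    N: int,
    states: Sequence[int],
) -> float:
    """Exact sup over the state grid of || P~_N(x,.) - P(x,.) ||_TV.

    Both kernels move only to x +- 1 or hold, so the one-step total
    variation at x is half the sum of the three absolute differences of
    exact transition probabilities.
    """
    states = list(states)
    if not states:
        raise ValueError("states must be non-empty")
    M = max(states)
    noisy = noisy_transition_table(target, proposal, weights, N, M)
    marg = marginal_transition_table(target, proposal, M)
    best = 0.0
    for m in states:
        i = m - 1
        tv = 0.5 * (abs(noisy.p_up[i] - marg.p_up[i])
                    + abs(noisy.p_down[i] - marg.p_down[i])
                    + abs(noisy.p_hold[i] - marg.p_hold[i]))
        best = max(best, float(tv))
    return best


@dataclass(frozen=True)
class RateBoundSpec:
    """Constants of the geometric rate and the kernel-perturbation rate.

    ``R`` and ``tau`` are the constants of the simultaneous geometric
    bound R V(x) tau^n (user inputs; deriving them from drift constants is
    out of scope here), and ``r_of_N`` maps the replicate count N to the
    perturbation rate r(N) with sup_x ||P~_N(x,.) - P(x,.)||_TV <= 1/r(N).
    """

    R: float
    tau: float
    r_of_N: Callable[[int], float]

    def __post_init__(self):
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        if not self.R > 0:
            raise ValueError("R must be positive")


def rate_bound(spec: RateBoundSpec, N: int) -> float:
    """Computable bound on || pi~_N - pi ||_TV from the coupling argument.

    Minimises f(n) = 2 R tau^n + n / r(N) over the two integer neighbours
    of its continuous minimiser s* = log(2 R r log(1/tau)) / log(1/tau).
    Requires log(2 R r(N) log(1/tau)) >= 1; otherwise N is too small for
    the bound to be in its asymptotic regime and an error is raised.
    """
    r = float(spec.r_of_N(N))
    if not r > 0:
        raise ValueError("r(N) must be positive")
    log_inv_tau = math.log(1.0 / spec.tau)
    arg = 2.0 * spec.R * r * log_inv_tau
    if math.log(arg) < 1.0:
        raise ValueError("log(2 R r(N) log(1/tau)) < 1; increase N")
    s_star = math.log(arg) / log_inv_tau

    def f(n: float) -> float:
        return 2.0 * spec.R * spec.tau ** n + n / r

    n1 = max(1, math.floor(s_star))
    n2 = max(1, math.ceil(s_star))
    return min(f(n1), f(n2))
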