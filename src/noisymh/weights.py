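"""State-dependent weight models with unit mean.

A weight model is the family {Q_{x,N}} of distributions of the
multiplicative noise entering a noisy or pseudo-marginal acceptance ratio:
at state x and replicate count N it produces a strictly positive random
weight W_{x,N} with E[W_{x,N}] = 1.  All models here are built from a
single-replicate law Q_x; the N-replicate weight is the arithmetic average
of N i.i.d. replicates, which preserves the unit mean.

Models with an atom at zero are rejected at construction time: the noisy
algorithm is undefined when both weights in a ratio can vanish.

Concrete constructions:

``unit_weights``
    The degenerate model W = 1; the noisy chain then reduces exactly to
    the marginal Metropolis-Hastings chain.
``lognormal_base``
    W ~ logNormal(-sigma2/2, sigma2), homogeneous in x.
``two_point_homogeneous``
    W = (b - eps) Ber(s) + eps with s = (1 - eps)/(b - eps) forced by the
    unit-mean constraint; support {eps, b}.
``two_point_state_dependent``
    The same two-point construction with state-dependent sequences b_m,
    eps_m; the source of the transient examples.

For two-point bases the average of N replicates has exact finite support
{(b - eps) k / N + eps : k = 0..N} with binomial probabilities, which the
``enumerate`` method exposes; exact acceptance probabilities and negative
moments are then finite sums.
"""

from __future__ import annotations

import math
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightModel",
    "unit_weights",
    "lognormal_base",
    "two_point_homogeneous",
    "two_point_state_dependent",
    "arithmetic_average",
    "check_W1",
    "check_negative_moment",
]

Atoms = List[Tuple[float, float]]


class WeightModel:
    """Base class: arithmetic averages of a single-replicate law Q_x."""

    #: True when Q_x does not depend on x (enables vectorised pre-sampling).
    homogeneous: bool = False
    name: str = "weights"
    params: dict = {}

    # -- single-replicate law -------------------------------------------------
    def sample_one(self, x, rng: np.random.Generator) -> float:
        raise NotImplementedError

    def enumerate_one(self, x) -> Optional[Atoms]:
        """Exact finite support of Q_x as (value, probability) pairs."""
        return None

    # -- averaged weight ------------------------------------------------------
    def sample(self, x, N: int, rng: np.random.Generator) -> float:
        """Draw W_{x,N}, the average of N i.i.d. single replicates."""
        if N < 1:
            raise ValueError("N must be >= 1")
        return float(np.mean([self.sample_one(x, rng) for _ in range(N)]))

    def sample_many(self, x, N: int, size: int, rng: np.random.Generator) -> np.ndarray:
        """Vectorised draws of W_{x,N}; generic fallback loops."""
        return np.array([self.sample(x, N, rng) for _ in range(size)])

    def enumerate(self, x, N: int) -> Optional[Atoms]:
        """Exact support of the N-replicate average, when finite.

        Two-point single-replicate laws average to the N+1 binomial atoms
        (b - eps) k / N + eps, k = 0..N.
        """
        if N < 1:
            raise ValueError("N must be >= 1")
        atoms = self.enumerate_one(x)
        if atoms is None:
            return None
        if len(atoms) == 1:
            return [(atoms[0][0], 1.0)]
        if N == 1:
            return list(atoms)
        if len(atoms) == 2:
            (lo, p_lo), (hi, p_hi) = sorted(atoms)
            s = p_hi
            k = np.arange(N + 1)
            vals = lo + (hi - lo) * k / N
            probs = stats.binom.pmf(k, N, s)
            return list(zip(vals.tolist(), probs.tolist()))
        return _convolve_atoms(atoms, N)

    def neg_moment(self, x, N: int) -> Optional[float]:
        """E[W_{x,N}^{-1}] when exactly computable, else None."""
        atoms = self.enumerate(x, N)
        if atoms is None:
            return None
        return float(sum(p / v for v, p in atoms))


def _convolve_atoms(atoms: Atoms, N: int) -> Atoms:
    """Exact distribution of the average of N i.i.d. finite-support draws."""
    dist = {0.0: 1.0}
    for _ in range(N):
        new: dict = {}
        for tot, p in dist.items():
            for v, pv in atoms:
                key = round(tot + v, 12)
                new[key] = new.get(key, 0.0) + p * pv
        dist = new
    return [(tot / N, p) for tot, p in sorted(dist.items())]


class _UnitWeights(WeightModel):
    homogeneous = True
    name = "unit"

    def sample_one(self, x, rng):  # consumes no randomness, by design
        return 1.0

    def sample(self, x, N, rng):
        if N < 1:
            raise ValueError("N must be >= 1")
        return 1.0

    def sample_many(self, x, N, size, rng):
        return np.ones(size)

    def enumerate_one(self, x):
        return [(1.0, 1.0)]


class _LogNormalWeights(WeightModel):
    """Single replicate W ~ logNormal(-sigma2/2, sigma2); E[W] = 1."""

    homogeneous = True
    name = "lognormal"

    def __init__(self, sigma2: float):
        if not sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        self.sigma2 = float(sigma2)
        self.params = {"sigma2": self.sigma2}

    def sample_one(self, x, rng):
        return float(rng.lognormal(-self.sigma2 / 2.0, math.sqrt(self.sigma2)))

    def sample(self, x, N, rng):
        if N < 1:
            raise ValueError("N must be >= 1")
        mu, sd = -self.sigma2 / 2.0, math.sqrt(self.sigma2)
        return float(rng.lognormal(mu, sd, size=N).mean())

    def sample_many(self, x, N, size, rng):
        mu, sd = -self.sigma2 / 2.0, math.sqrt(self.sigma2)
        if N == 1:
            return rng.lognormal(mu, sd, size=size)
        # chunked so size * N draws never exceed ~2e7 floats at once
        out = np.empty(size)
        chunk = max(1, int(2e7) // N)
        for i in range(0, size, chunk):
            j = min(i + chunk, size)
            out[i:j] = rng.lognormal(mu, sd, size=(j - i, N)).mean(axis=1)
        return out

    def neg_moment(self, x, N):
        if N == 1:
            # E[W^{-1}] = exp(-mu + sigma2/2) = exp(sigma2) for mu = -sigma2/2
            return math.exp(self.sigma2)
        return None


def _two_point_s(b: float, eps: float) -> float:
    """Success probability forced by the unit-mean constraint."""
    return (1.0 - eps) / (b - eps)


class _TwoPointHomogeneous(WeightModel):
    homogeneous = True
    name = "two_point"

    def __init__(self, b: float, eps: float):
        if not b > 1:
            raise ValueError("b must exceed 1")
        if not 0.0 < eps < 1.0:
            raise ValueError("eps must lie in (0, 1)")
        self.b, self.eps = float(b), float(eps)
        self.s = _two_point_s(self.b, self.eps)
        self.params = {"b": self.b, "eps": self.eps, "s": self.s}

    def sample_one(self, x, rng):
        return self.b if rng.random() < self.s else self.eps

    def sample(self, x, N, rng):
        if N < 1:
            raise ValueError("N must be >= 1")
        k = int(rng.binomial(N, self.s))
        return self.eps + (self.b - self.eps) * k / N

    def sample_many(self, x, N, size, rng):
        k = rng.binomial(N, self.s, size=size)
        return self.eps + (self.b - self.eps) * k / N

    def enumerate_one(self, x):
        return [(self.eps, 1.0 - self.s), (self.b, self.s)]


class _TwoPointStateDependent(WeightModel):
    """Two-point weights with state-dependent (b_m, eps_m) sequences."""

    homogeneous = False
    name = "two_point_state_dep"

    def __init__(self, b_seq: Callable[[int], float], eps_seq: Callable[[int], float]):
        self._b, self._e = b_seq, eps_seq
        self.params = {"b_seq": getattr(b_seq, "__name__", "b_seq"),
                       "eps_seq": getattr(eps_seq, "__name__", "eps_seq")}

    def _be(self, m) -> Tuple[float, float, float]:
        b, eps = float(self._b(int(m))), float(self._e(int(m)))
        if not 0.0 < eps <= 1.0:
            raise ValueError(f"eps_m must lie in (0, 1] at m={m} (got {eps})")
        if eps == 1.0:
            # degenerate W = 1 regardless of b; the unit-mean constraint
            # forces s = 0, so b never materialises
            return max(b, 1.0), 1.0, 0.0
        if not b > 1:
            raise ValueError(f"b_m must exceed 1 at m={m} (got {b})")
        return b, eps, _two_point_s(b, eps)

    def sample_one(self, x, rng):
        b, eps, s = self._be(x)
        return b if rng.random() < s else eps

    def sample(self, x, N, rng):
        if N < 1:
            raise ValueError("N must be >= 1")
        b, eps, s = self._be(x)
        k = int(rng.binomial(N, s)) if s > 0 else 0
        return eps + (b - eps) * k / N

    def sample_many(self, x, N, size, rng):
        b, eps, s = self._be(x)
        k = rng.binomial(N, s, size=size)
        return eps + (b - eps) * k / N

    def enumerate_one(self, x):
        b, eps, s = self._be(x)
        if s == 0.0:
            return [(eps, 1.0)]
        return [(eps, 1.0 - s), (b, s)]


class _FixedN(WeightModel):
    """A base model with the replicate count N frozen in.

    ``sample(x, M, rng)`` of the wrapper averages M draws of the wrapped
    N-average, i.e. an effective replicate count of M*N; the common use is
    M = 1.
    """

    def __init__(self, base: WeightModel, N: int):
        if N < 1:
            raise ValueError("N must be >= 1")
        self.base, self.N = base, int(N)
        self.homogeneous = base.homogeneous
        self.name = f"{base.name}_avg{N}"
        self.params = {**base.params, "N": self.N}

    def sample_one(self, x, rng):
        return self.base.sample(x, self.N, rng)

    def sample(self, x, M, rng):
        if M < 1:
            raise ValueError("N must be >= 1")
        return self.base.sample(x, self.N * M, rng)

    def sample_many(self, x, M, size, rng):
        return self.base.sample_many(x, self.N * M, size, rng)

    def enumerate_one(self, x):
        return self.base.enumerate(x, self.N)

    def enumerate(self, x, M):
        return self.base.enumerate(x, self.N * M)

    def neg_moment(self, x, M):
        return self.base.neg_moment(x, self.N * M)


def unit_weights() -> WeightModel:
    """Degenerate weights W = 1 (Q_{x,N}({1}) = 1)."""
    return _UnitWeights()


def lognormal_base(sigma2: float) -> WeightModel:
    """Log-normal single-replicate weights with E[W] = 1."""
    return _LogNormalWeights(sigma2)


def two_point_homogeneous(b: float, eps: float) -> WeightModel:
    """Two-point weights on {eps, b}, homogeneous in the state."""
    return _TwoPointHomogeneous(b, eps)


def two_point_state_dependent(
    b_seq: Callable[[int], float] | float, eps_seq: Callable[[int], float]
) -> WeightModel:
    """Two-point weights with state-dependent sequences b_m, eps_m.

    ``b_seq`` may be a constant, in which case only eps varies with the
    state.
    """
    if not callable(b_seq):
        b_const = float(b_seq)
        b_seq = lambda m: b_const  # noqa: E731
    return _TwoPointStateDependent(b_seq, eps_seq)


def arithmetic_average(base: WeightModel, N: int) -> WeightModel:
    """Freeze the replicate count: W_{x,N} = (1/N) sum of N i.i.d. W_x."""
    return _FixedN(base, N)


# ---------------------------------------------------------------------------
# Numerical condition checks
# ---------------------------------------------------------------------------

def _tail_prob_exact(atoms: Atoms, delta: float) -> float:
    return float(sum(p for v, p in atoms if abs(v - 1.0) >= delta))


def check_W1(
    model: WeightModel,
    states: Sequence,
    N_grid: Sequence[int],
    delta: float,
    *,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Concentration check: sup_x P[|W_{x,N} - 1| >= delta] along an N-grid.

    The sup over states is taken on the supplied finite grid, exact where
    the model enumerates and Monte Carlo (common seed across N) otherwise.
    The returned frame carries ``attrs['decreasing']``, flagging whether
    the sup-probability sequence decreases towards its final value.
    """
    if len(states) == 0:
        raise ValueError("states must be non-empty")
    rows = []
    for N in N_grid:
        sup_p, method = 0.0, "exact"
        for x in states:
            atoms = model.enumerate(x, int(N))
            if atoms is not None:
                p = _tail_prob_exact(atoms, delta)
            else:
                method = "monte_carlo"
                rng = np.random.default_rng(seed)
                w = model.sample_many(x, int(N), n_mc, rng)
                p = float(np.mean(np.abs(w - 1.0) >= delta))
            sup_p = max(sup_p, p)
        rows.append({"N": int(N), "sup_prob": sup_p, "method": method})
    out = pd.DataFrame(rows)
    p = out["sup_prob"].to_numpy()
    out.attrs["decreasing"] = bool(np.all(np.diff(p) <= 1e-12)) and p[-1] <= p[0]
    return out


def check_negative_moment(
    model: WeightModel,
    states: Sequence,
    N_grid: Sequence[int],
    *,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Inverse-moment check: E[W_{x,N}^{-1}] per state and N.

    Exact through enumeration when available, Monte Carlo otherwise.  A
    Monte Carlo estimate whose half-sample and full-sample batch means
    disagree grossly is flagged ``diverging`` (the moment may not exist).
    The frame carries ``attrs['sup_by_N']`` (sup over the state grid) and
    ``attrs['approaches_one']``.
    """
    rows = []
    for N in N_grid:
        for x in states:
            exact = model.neg_moment(x, int(N))
            if exact is not None:
                rows.append({"N": int(N), "state": x, "neg_moment": float(exact),
                             "method": "exact", "diverging": False})
                continue
            rng = np.random.default_rng(seed)
            w = model.sample_many(x, int(N), n_mc, rng)
            inv = 1.0 / w
            half = float(np.mean(inv[: n_mc // 2]))
            full = float(np.mean(inv))
            diverging = abs(full - half) > 0.5 * max(1.0, abs(half))
            rows.append({"N": int(N), "state": x, "neg_moment": full,
                         "method": "monte_carlo", "diverging": bool(diverging)})
    out = pd.DataFrame(rows)
    sup_by_n = out.groupby("N")["neg_moment"].max()
    out.attrs["sup_by_N"] = sup_by_n.to_dict()
    vals = sup_by_n.to_numpy()
    out.attrs["approaches_one"] = bool(abs(vals[-1] - 1.0) < abs(vals[0] - 1.0) + 1e-12)
    return out
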