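"""Closed-form cost-benefit model of decision depth.

An organism that bases its decisions on the last ``l`` perceived stimuli
("decision depth" ``l``) faces up to ``N(l) = n**l`` distinct situations in a
world of ``n`` stimuli.  Deeper decisions unlock more information -- the
fraction of length-``l`` histories that admit a productive (utility-maximising)
decision is ``f(l) = 1 - r**l`` with information-distribution rate
``0 < r < 1`` -- but every situation must be learned separately, at a cost of
``tau`` experiences each.  With no innate knowledge the probability that the
decision taken at time ``t`` is productive follows

    u(l, t+1) = u(l, t) + (1 / (tau * N(l))) * (f(l) - u(l, t)),  u(l, 0) = 0,

whose solution is ``u(l, t) = f(l) * (1 - (1 - 1/(tau*N(l)))**t)``.  Lifetime
utility is the expected number of productive decisions over ``T`` exposures,

    U(l, T) = sum_{t=0}^{T-1} u(l, t)
            = f(l) * (T - tau*N(l) * (1 - (1 - 1/(tau*N(l)))**T)).

This module evaluates these quantities with numerically stable power terms and
locates the optimal depth and the alphabet-size boundary between depths.  The
constant scaling of realizable sequence counts is folded into ``tau``, so
``tau`` is real-valued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AnalyticParams",
    "UtilitySurface",
    "NoBoundaryError",
    "fraction_informative",
    "num_sequences",
    "productive_prob_recurrence",
    "productive_prob_closed",
    "lifetime_utility",
    "lifetime_utility_by_sum",
    "optimal_depth",
    "depth_boundary_n",
    "utility_surface",
    "utility_grid",
]


@dataclass(frozen=True)
class AnalyticParams:
    """Scalar world for the analytic model.

    Parameters
    ----------
    n : int
        Count of distinct perceivable stimuli, ``n >= 2``.
    r : float
        Information-distribution rate, ``0 < r < 1``.  Large ``r`` means
        information accrues slowly with depth.
    tau : float
        Experiences needed to learn one productive decision, ``tau > 0``.
        Absorbs any constant scaling of the realizable sequence count.
    T : int
        Lifetime in learning experiences, ``T >= 0``.
    """

    n: int
    r: float
    tau: float
    T: int

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n < 2:
            raise ValueError(f"n must be an integer >= 2, got {self.n!r}")
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"r must lie in (0, 1), got {self.r!r}")
        if not self.tau > 0.0:
            raise ValueError(f"tau must be positive, got {self.tau!r}")
        if not isinstance(self.T, int) or self.T < 0:
            raise ValueError(f"T must be an integer >= 0, got {self.T!r}")


@dataclass(frozen=True)
class UtilitySurface:
    """Lifetime utilities ``U(l, T)`` evaluated on a set of depths."""

    depths: tuple[int, ...]
    utilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.utilities):
            raise ValueError("depths and utilities must have equal length")
        for u in self.utilities:
            if not math.isfinite(u) or u < 0.0:
                raise ValueError(f"utilities must be finite and >= 0, got {u!r}")


class NoBoundaryError(Exception):
    """No alphabet size in the scanned range switches the preferred depth."""


def fraction_informative(depth: int, r: float) -> float:
    """Fraction ``f(l) = 1 - r**l`` of depth-``l`` histories that admit a
    productive decision.

    Monotone nondecreasing in ``depth``; 0 at depth 0 (no information without
    any perceived stimulus).
    """
    if not isinstance(depth, int) or depth < 0:
        raise ValueError(f"depth must be an integer >= 0, got {depth!r}")
    if not 0.0 < r < 1.0:
        raise ValueError(f"r must lie in (0, 1), got {r!r}")
    return 1.0 - r**depth


def num_sequences(n: int, depth: int) -> int:
    """Number ``N(l) = n**l`` of length-``l`` sequences over ``n`` stimuli.

    Exact integer arithmetic; no floating overflow.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n!r}")
    if not isinstance(depth, int) or depth < 1:
        raise ValueError(f"depth must be an integer >= 1, got {depth!r}")
    return n**depth


def _geom_deficit(tau_n: float, t: int) -> float:
    """Return ``1 - (1 - 1/tau_n)**t`` without catastrophic cancellation."""
    if t == 0:
        return 0.0
    # (1 - 1/tau_n)**t = exp(t * log1p(-1/tau_n)); for tau_n <= 1 the factor
    # clamps to 0 (a single experience suffices for the whole repertoire).
    if tau_n <= 1.0:
        return 1.0
    return -math.expm1(t * math.log1p(-1.0 / tau_n))


def productive_prob_recurrence(params: AnalyticParams, depth: int, t: int) -> float:
    """Iterate the learning recurrence ``t`` times from ``u = 0``.

    Brute-force reference for :func:`productive_prob_closed`; O(t).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    f = fraction_informative(depth, params.r)
    rate = 1.0 / (params.tau * num_sequences(params.n, depth))
    u = 0.0
    for _ in range(t):
        u += rate * (f - u)
    return u


def productive_prob_closed(params: AnalyticParams, depth: int, t: int) -> float:
    """Closed-form ``u(l, t) = f(l) * (1 - (1 - 1/(tau*N(l)))**t)``."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    f = fraction_informative(depth, params.r)
    tau_n = params.tau * num_sequences(params.n, depth)
    return f * _geom_deficit(tau_n, t)


def lifetime_utility(params: AnalyticParams, depth: int) -> float:
    """Expected number of productive decisions over a lifetime of ``T`` steps.

    Evaluates ``U(l, T) = f(l) * (T - tau*N(l)*(1 - (1 - 1/(tau*N(l)))**T))``.
    """
    f = fraction_informative(depth, params.r)
    tau_n = params.tau * num_sequences(params.n, depth)
    return f * (params.T - tau_n * _geom_deficit(tau_n, params.T))


def lifetime_utility_by_sum(params: AnalyticParams, depth: int) -> float:
    """Direct summation of the fitness definition, ``sum_t u(l, t)``.

    O(T) cross-check for :func:`lifetime_utility`.
    """
    return math.fsum(
        productive_prob_closed(params, depth, t) for t in range(params.T)
    )


def optimal_depth(params: AnalyticParams, l_max: int) -> int:
    """Depth in ``1..l_max`` maximising lifetime utility; ties favour the
    smaller depth (lower depth is never costlier at equal utility)."""
    if not isinstance(l_max, int) or l_max < 1:
        raise ValueError(f"l_max must be an integer >= 1, got {l_max!r}")
    best_l, best_u = 1, lifetime_utility(params, 1)
    for depth in range(2, l_max + 1):
        u = lifetime_utility(params, depth)
        if u > best_u:
            best_l, best_u = depth, u
    return best_l


def depth_boundary_n(
    r: float,
    tau: float,
    T: int,
    l_a: int,
    l_b: int,
    n_max: int = 1000,
) -> int:
    """Smallest alphabet size ``n <= n_max`` at which the shallower depth
    ``l_a`` is at least as good as the deeper ``l_b``.

    Below the returned ``n`` the deeper representation pays off; from it
    onwards the combinatorial learning cost dominates.  Raises
    :class:`NoBoundaryError` if no such ``n`` exists in range (distinct from
    parameter validation errors, which raise :class:`ValueError`).
    """
    if not (isinstance(l_a, int) and isinstance(l_b, int)) or l_a < 1 or l_b < 1:
        raise ValueError("depths must be integers >= 1")
    if l_a >= l_b:
        raise ValueError(f"require l_a < l_b, got l_a={l_a}, l_b={l_b}")
    if n_max < 2:
        raise ValueError(f"n_max must be >= 2, got {n_max!r}")
    for n in range(2, n_max + 1):
        params = AnalyticParams(n=n, r=r, tau=tau, T=T)
        if lifetime_utility(params, l_a) >= lifetime_utility(params, l_b):
            return n
    raise NoBoundaryError(
        f"U(l={l_a}) < U(l={l_b}) for every n in 2..{n_max}"
    )


def utility_surface(params: AnalyticParams, depths: Iterable[int]) -> UtilitySurface:
    depths = tuple(depths)
    return UtilitySurface(
        depths=depths,
        utilities=tuple(lifetime_utility(params, l) for l in depths),
    )


def utility_grid(
    n_values: Sequence[int],
    T_values: Sequence[int],
    r: float = 0.5,
    tau: float = 10.0,
    l_max: int = 4,
) -> pd.DataFrame:
    """Evaluate ``U(l, T)`` and the optimal depth over a parameter grid.

    Returns a long-format frame with columns
    ``n, T, r, tau, l, utility, optimal_l`` suitable for re-plotting the
    utility curves and the optimal-depth map.
    """
    rows = []
    for n in n_values:
        for T in T_values:
            params = AnalyticParams(n=int(n), r=r, tau=tau, T=int(T))
            l_opt = optimal_depth(params, l_max)
            for depth in range(1, l_max + 1):
                rows.append(
                    {
                        "n": int(n),
                        "T": int(T),
                        "r": r,
                        "tau": tau,
                        "l": depth,
                        "utility": lifetime_utility(params, depth),
                        "optimal_l": l_opt,
                    }
                )
    return pd.DataFrame(rows)
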