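"""Perception: turning a raw stimulus sequence into perception elements.

A percept is a set of *perception elements* ``(K, x)``: a subsequence ``K``
(ordered tuple of stimulus ids) and an intensity ``x``.  The three strategies
differ only in which elements they emit for an input sequence ``(s_1 ... s_L)``:

Trace
    One element per position, ``((s_i,), theta**(L - i))`` -- each stimulus is
    held individually with a geometrically decaying intensity (decay rate
    ``theta``), so recency is encoded in intensity and order is not encoded
    explicitly at all.

Depth-l
    A single element holding the last ``l`` stimuli as one ordered,
    indivisible unit at intensity 1.

Flexible sequence of depth l
    One full-intensity element for every contiguous subsequence of the last
    ``l`` stimuli (``l*(l+1)/2`` elements when all stimuli are distinct).
    Only contiguous subsequences are represented; no gapped pairs.

Elements are keyed by the ordered tuple of ids, so ``(A, B)`` and ``(B, A)``
are distinct keys -- the mechanism by which the depth and flexible strategies
are order-sensitive while the trace is not.  All strategies are pure
functions of their input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

__all__ = [
    "Percept",
    "StrategyConfig",
    "represent_trace",
    "represent_depth",
    "represent_flexible",
    "make_strategy",
]

#: A percept: mapping from subsequence (tuple of stimulus ids) to intensity.
Percept = Mapping[tuple[str, ...], float]


@dataclass(frozen=True)
class StrategyConfig:
    """Named representation strategy plus its parameters.

    ``strategy`` is one of ``trace``, ``depth``, ``flexible``.  ``depth`` is
    the decision depth ``l`` (depth/flexible); ``theta`` the trace decay rate
    in (0, 1); ``trace_merge`` selects how repeated stimuli combine in a trace
    ("sum" accumulates intensities, "recent" keeps only the freshest trace).
    """

    strategy: str
    depth: int = 1
    theta: float = 0.5
    trace_merge: str = "sum"

    def __post_init__(self) -> None:
        if self.strategy not in ("trace", "depth", "flexible"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy in ("depth", "flexible") and self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth!r}")
        if self.strategy == "trace" and not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta!r}")
        if self.trace_merge not in ("sum", "recent"):
            raise ValueError(f"trace_merge must be sum|recent, got {self.trace_merge!r}")

    @property
    def label(self) -> str:
        if self.strategy == "trace":
            return f"trace(theta={self.theta})"
        return f"{self.strategy}-{self.depth}"


def represent_trace(
    seq: tuple[str, ...], theta: float, merge: str = "sum"
) -> dict[tuple[str, ...], float]:
    """Trace percept: each stimulus individually, intensity ``theta**(L-i)``.

    A stimulus occurring more than once leaves more than one trace; with
    ``merge="sum"`` the intensities accumulate, with ``merge="recent"`` only
    the most recent occurrence is kept.
    """
    if not seq:
        raise ValueError("cannot represent an empty sequence")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta!r}")
    last = len(seq) - 1
    percept: dict[tuple[str, ...], float] = {}
    for i, stimulus in enumerate(seq):
        key = (stimulus,)
        intensity = theta ** (last - i)
        if merge == "sum":
            percept[key] = percept.get(key, 0.0) + intensity
        else:  # "recent": later occurrences overwrite fainter earlier traces
            percept[key] = intensity
    return percept


def represent_depth(seq: tuple[str, ...], depth: int) -> dict[tuple[str, ...], float]:
    """Depth-``l`` percept: the last ``l`` stimuli as one unit, intensity 1."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth!r}")
    if depth > len(seq):
        raise ValueError(f"depth {depth} exceeds sequence length {len(seq)}")
    return {tuple(seq[len(seq) - depth :]): 1.0}


def represent_flexible(seq: tuple[str, ...], depth: int) -> dict[tuple[str, ...], float]:
    """Flexible percept: every contiguous subsequence of the last ``l``
    stimuli at intensity 1 (duplicates collapse to a single element)."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth!r}")
    if depth > len(seq):
        raise ValueError(f"depth {depth} exceeds sequence length {len(seq)}")
    window = tuple(seq[len(seq) - depth :])
    percept: dict[tuple[str, ...], float] = {}
    for start in range(len(window)):
        for stop in range(start + 1, len(window) + 1):
            percept[window[start:stop]] = 1.0
    return percept


def make_strategy(
    config: StrategyConfig,
) -> Callable[[tuple[str, ...]], dict[tuple[str, ...], float]]:
    """Bind a :class:`StrategyConfig` to a sequence -> percept function."""
    if config.strategy == "trace":
        theta, merge = config.theta, config.trace_merge
        return lambda seq: represent_trace(seq, theta, merge)
    if config.strategy == "depth":
        depth = config.depth
        return lambda seq: represent_depth(seq, depth)
    depth = config.depth
    return lambda seq: represent_flexible(seq, depth)
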