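"""Associative go/no-go agent: linear values, softmax choice, delta rule.

The agent's repertoire is two behaviors, *go* and *no-go*.  Going at a
rewarding sequence earns reinforcement +5, going at a nonrewarding one costs
-4, and withholding earns 0 regardless of the sequence.

Associative strengths are stored sparsely per (subsequence, behavior); unseen
pairs read as exactly 0 (no innate knowledge).  The value of a behavior given
a percept is the intensity-weighted sum of the strengths of its elements.
During learning the behavior is sampled from a softmax over the two values
(sharpness ``beta``); during test measurement the choice is greedy with ties
resolved to no-go, so the performance metric reflects acquired knowledge
rather than exploration noise.

Updates follow a normalized delta (error-correction) rule: with prediction
error ``delta = R - v(behavior)``, every element ``(K, x)`` of the percept
receives ``w(K, behavior) += alpha * x * delta / sum(x**2)``.  The
normalization by the squared percept norm makes the per-exposure learning
rate comparable across strategies that emit different element counts (one for
Depth-l, up to ten for a flexible depth-4 percept).  Only the chosen
behavior's weights change.  The default ``alpha = 0.26`` makes roughly ten
exposures bring a value within one utility unit of its target
(``0.74**10 * 5 < 1``), placing single-stimulus discriminations on the
``tau ~ 10`` timescale of the analytic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import math

import numpy as np

from .representations import Percept

__all__ = [
    "GO",
    "NOGO",
    "ReinforcementSchedule",
    "AssociativeMemory",
    "behavior_value",
    "decide",
    "update",
]

GO = "go"
NOGO = "no-go"


@dataclass(frozen=True)
class ReinforcementSchedule:
    """Utility units delivered for each (behavior, sequence label) outcome."""

    reward_go_rewarding: float = 5.0
    reward_go_nonrewarding: float = -4.0
    reward_nogo: float = 0.0

    def reinforcement(self, behavior: str, rewarding: bool) -> float:
        if behavior == NOGO:
            return self.reward_nogo
        return self.reward_go_rewarding if rewarding else self.reward_go_nonrewarding


@dataclass
class AssociativeMemory:
    """Sparse associative strengths with learning-rate and choice parameters."""

    alpha: float = 0.26
    beta: float = 1.0
    weights: dict[str, dict[tuple[str, ...], float]] = field(
        default_factory=lambda: {GO: {}, NOGO: {}}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha!r}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be positive, got {self.beta!r}")

    def strength(self, subsequence: tuple[str, ...], behavior: str) -> float:
        return self.weights[behavior].get(subsequence, 0.0)

    def snapshot(self) -> str:
        """JSON snapshot (subsequence -> per-behavior strengths)."""
        doc: dict[str, dict[str, float]] = {}
        for behavior, table in self.weights.items():
            for key, w in table.items():
                doc.setdefault("|".join(key), {})[behavior] = w
        return json.dumps(doc, sort_keys=True)


def behavior_value(memory: AssociativeMemory, percept: Percept, behavior: str) -> float:
    """Linear value: sum over elements of strength(K, behavior) * intensity."""
    table = memory.weights[behavior]
    return sum(table.get(key, 0.0) * x for key, x in percept.items())


def decide(
    memory: AssociativeMemory,
    percept: Percept,
    rng: np.random.Generator | None = None,
    greedy: bool = False,
) -> str:
    """Choose go or no-go.

    Non-greedy (learning) mode samples go with probability
    ``exp(beta*v_go) / (exp(beta*v_go) + exp(beta*v_nogo))``.  Greedy (test)
    mode takes the argmax, resolving exact ties to no-go (withholding is the
    costless default).
    """
    v_go = behavior_value(memory, percept, GO)
    v_nogo = behavior_value(memory, percept, NOGO)
    if greedy:
        return GO if v_go > v_nogo else NOGO
    if rng is None:
        raise ValueError("non-greedy decisions need a random generator")
    p_go = 1.0 / (1.0 + math.exp(-memory.beta * (v_go - v_nogo)))
    return GO if rng.random() < p_go else NOGO


def update(
    memory: AssociativeMemory,
    percept: Percept,
    behavior: str,
    reinforcement: float,
) -> AssociativeMemory:
    """Normalized delta-rule update of the chosen behavior's weights.

    Mutates and returns ``memory``.  With a constant percept the value of the
    chosen behavior converges geometrically to the reinforcement (factor
    ``1 - alpha`` per exposure); reinforcement equal to the current value
    leaves the memory untouched.
    """
    delta = reinforcement - behavior_value(memory, percept, behavior)
    if delta == 0.0:
        return memory
    norm = sum(x * x for x in percept.values())
    if norm == 0.0:
        return memory
    gain = memory.alpha * delta / norm
    table = memory.weights[behavior]
    for key, x in percept.items():
        table[key] = table.get(key, 0.0) + gain * x
    return memory
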