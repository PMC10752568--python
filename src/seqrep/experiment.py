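"""Time-stepped learning simulations with periodic frozen-test measurement.

One simulated time-step is one learning opportunity: a sequence is drawn from
the environment, represented by the agent's strategy, a behavior is sampled
from the softmax over the two behavior values, reinforcement is delivered
(+5 go/rewarding, -4 go/nonrewarding, 0 no-go) and the chosen behavior's
associative strengths receive a delta-rule update.  Every ``measure_every``
steps the simulation is frozen and the agent responds greedily to a fixed
test set (each template instantiated a fixed number of times at the start of
the replicate); the fraction of correct responses is recorded and the test
exposure leaves the memory untouched.

Randomness is structured for paired comparisons: within one master seed, the
environment stream and the frozen test set of replicate ``k`` are identical
for every strategy, so strategy curves differ only through the strategies
themselves (plus their own decision streams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environments import Environment, test_set
from .learner import GO, NOGO, AssociativeMemory, ReinforcementSchedule
from .representations import StrategyConfig, make_strategy

__all__ = [
    "RunConfig",
    "PerformanceCurve",
    "DivergenceError",
    "run",
    "measure_performance",
    "trials_to_reach",
    "compare_strategies",
]


class DivergenceError(RuntimeError):
    """An associative strength exceeded the divergence guard (mis-set
    learning parameters, not a valid result)."""


@dataclass(frozen=True)
class RunConfig:
    """Complete, reproducible description of one simulation."""

    environment: Environment
    strategy: StrategyConfig
    steps: int
    measure_every: int = 100
    test_instantiations: int = 10
    replicates: int = 1
    seed: int = 0
    alpha: float = 0.26
    beta: float = 1.0
    schedule: ReinforcementSchedule = field(default_factory=ReinforcementSchedule)
    divergence_limit: float = 1e6

    def __post_init__(self) -> None:
        if self.measure_every < 1 or self.steps < self.measure_every:
            raise ValueError("require steps >= measure_every >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class PerformanceCurve:
    """Fraction-correct trajectories, one row per replicate."""

    checkpoints: np.ndarray  # shape (n_checkpoints,), strictly increasing
    performance: np.ndarray  # shape (replicates, n_checkpoints), in [0, 1]

    def __post_init__(self) -> None:
        if self.performance.ndim != 2 or (
            self.performance.shape[1] != self.checkpoints.shape[0]
        ):
            raise ValueError("performance must be (replicates, n_checkpoints)")
        if np.any(np.diff(self.checkpoints) <= 0):
            raise ValueError("checkpoints must be strictly increasing")
        if np.any((self.performance < 0) | (self.performance > 1)):
            raise ValueError("performance values must lie in [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        """Replicate-mean performance per checkpoint."""
        return self.performance.mean(axis=0)

    def at(self, step: int) -> float:
        """Replicate-mean performance at an exact checkpoint."""
        idx = np.flatnonzero(self.checkpoints == step)
        if idx.size == 0:
            raise KeyError(f"no checkpoint at step {step}")
        return float(self.mean[idx[0]])

    def to_frame(self, strategy: str = "", environment: str = "") -> pd.DataFrame:
        reps, _ = self.performance.shape
        frames = []
        for rep in range(reps):
            frames.append(
                pd.DataFrame(
                    {
                        "environment": environment,
                        "strategy": strategy,
                        "replicate": rep,
                        "step": self.checkpoints,
                        "performance": self.performance[rep],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def measure_performance(memory, test_items, represent) -> float:
    """Fraction of test items answered correctly by the greedy policy.

    ``test_items`` are (sequence, rewarding) pairs; ``represent`` maps a
    sequence to a percept.  Pure: no weights are modified.
    """
    if not test_items:
        raise ValueError("test set must be non-empty")
    percepts = [(represent(seq), rewarding) for seq, rewarding in test_items]
    return _measure(memory.weights[GO], memory.weights[NOGO], percepts)


def _measure(w_go, w_nogo, percepts) -> float:
    correct = 0
    for percept, rewarding in percepts:
        v_go = 0.0
        v_nogo = 0.0
        for key, x in percept.items():
            w = w_go.get(key)
            if w is not None:
                v_go += w * x
            w = w_nogo.get(key)
            if w is not None:
                v_nogo += w * x
        go = v_go > v_nogo  # exact tie -> no-go, the costless default
        if go == rewarding:
            correct += 1
    return correct / len(percepts)


def _run_replicate(config: RunConfig, rep: int) -> np.ndarray:
    env = config.environment
    represent = make_strategy(config.strategy)
    schedule = config.schedule
    r_go_plus = schedule.reward_go_rewarding
    r_go_minus = schedule.reward_go_nonrewarding
    r_nogo = schedule.reward_nogo

    env_rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep, 0]))
    agent_rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep, 1]))
    test_rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep, 2]))

    test_percepts = [
        (represent(seq), rewarding)
        for seq, rewarding in test_set(env, config.test_instantiations, test_rng)
    ]

    templates = env.templates
    n_templates = len(templates)
    fill_ids = env.fill_ids
    n_fill = len(fill_ids)
    patterns = [list(t.positions) for t in templates]
    wild_slots = [
        [i for i, p in enumerate(t.positions) if p is None] for t in templates
    ]
    rewarding_flags = [t.rewarding for t in templates]
    if any(wild_slots[i] for i in range(n_templates)) and n_fill == 0:
        raise ValueError("templates have wildcards but the fill pool is empty")

    steps = config.steps
    # The environment stream (template choices + noise fills) is drawn up
    # front from its own generator, so it is identical across strategies
    # under the same master seed and step count.
    tpl_idx = env_rng.integers(n_templates, size=steps)
    wild_counts = np.array([len(s) for s in wild_slots])
    n_fills = int(wild_counts[tpl_idx].sum())
    fills = env_rng.integers(n_fill, size=n_fills) if n_fills else np.empty(0, int)
    uniforms = agent_rng.random(steps)

    memory = AssociativeMemory(alpha=config.alpha, beta=config.beta)
    w_go = memory.weights[GO]
    w_nogo = memory.weights[NOGO]
    alpha, beta, limit = config.alpha, config.beta, config.divergence_limit

    n_checkpoints = steps // config.measure_every
    perf = np.empty(n_checkpoints, dtype=float)
    checkpoint = 0
    fill_pos = 0
    measure_every = config.measure_every
    exp = math.exp

    for step in range(steps):
        t = tpl_idx[step]
        slots = wild_slots[t]
        if slots:
            seq_list = patterns[t].copy()
            for slot in slots:
                seq_list[slot] = fill_ids[fills[fill_pos]]
                fill_pos += 1
            seq = tuple(seq_list)
        else:
            seq = tuple(patterns[t])
        percept = represent(seq)

        v_go = 0.0
        v_nogo = 0.0
        for key, x in percept.items():
            w = w_go.get(key)
            if w is not None:
                v_go += w * x
            w = w_nogo.get(key)
            if w is not None:
                v_nogo += w * x

        d = beta * (v_go - v_nogo)
        # logistic choice, clamped to avoid overflow at extreme values
        if d > 35.0:
            go = True
        elif d < -35.0:
            go = False
        else:
            go = uniforms[step] < 1.0 / (1.0 + exp(-d))

        if go:
            reinforcement = r_go_plus if rewarding_flags[t] else r_go_minus
            value, table = v_go, w_go
        else:
            reinforcement = r_nogo
            value, table = v_nogo, w_nogo

        delta = reinforcement - value
        if delta != 0.0:
            norm = 0.0
            for x in percept.values():
                norm += x * x
            gain = alpha * delta / norm
            for key, x in percept.items():
                w_new = table.get(key, 0.0) + gain * x
                table[key] = w_new
                if w_new > limit or w_new < -limit:
                    raise DivergenceError(
                        f"weight {key!r} reached {w_new:.3g} at step {step}"
                    )

        if (step + 1) % measure_every == 0:
            perf[checkpoint] = _measure(w_go, w_nogo, test_percepts)
            checkpoint += 1

    return perf


def run(config: RunConfig) -> PerformanceCurve:
    """Execute the full simulation loop for every replicate.

    Fully reproducible: identical config and seed give identical curves.
    """
    n_checkpoints = config.steps // config.measure_every
    checkpoints = np.arange(1, n_checkpoints + 1) * config.measure_every
    performance = np.vstack(
        [_run_replicate(config, rep) for rep in range(config.replicates)]
    )
    return PerformanceCurve(checkpoints=checkpoints, performance=performance)


def trials_to_reach(curve: PerformanceCurve, level: float) -> int | None:
    """First checkpoint whose replicate-mean performance reaches ``level``;
    ``None`` if the curve never gets there."""
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must lie in (0, 1], got {level!r}")
    mean = curve.mean
    hits = np.flatnonzero(mean >= level)
    if hits.size == 0:
        return None
    return int(curve.checkpoints[hits[0]])


def compare_strategies(
    environment: Environment,
    strategies: list[StrategyConfig],
    config: RunConfig,
) -> pd.DataFrame:
    """Run several strategies against identically seeded environment streams.

    Returns the long-format table (environment, strategy, replicate, step,
    performance).  ``config.strategy`` is ignored; ``config.environment`` is
    replaced by ``environment``.
    """
    if len(strategies) < 2:
        raise ValueError("need at least two strategies to compare")
    frames = []
    for strategy in strategies:
        cfg = replace(config, environment=environment, strategy=strategy)
        curve = run(cfg)
        frames.append(curve.to_frame(strategy.label, environment.name))
    return pd.concat(frames, ignore_index=True)
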