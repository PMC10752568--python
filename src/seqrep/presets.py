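"""Panel presets: the parameter sets behind each simulated comparison.

Each preset bundles an environment builder, the strategy roster and run
parameters.  Step counts are the package's own choices documented in the
methods note: long enough for the qualitative outcome of each panel to be
visible, short enough to simulate on one CPU.

The order-sensitive (``fig5*``) presets use a compact 12-symbol world
(A, B, two single-information symbols, 8 noise symbols): a rote Depth-4
learner must see every concrete noise context of a template separately, so
its time to cover a world with ``z`` noise symbols scales like ``z**2 ..
z**3`` per template -- a compact noise pool keeps its convergence observable
at simulable horizons without changing any qualitative ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .environments import (
    Environment,
    build_graded_depth_env,
    build_order_env,
    build_positional_env,
)
from .representations import StrategyConfig

__all__ = ["Preset", "PRESETS", "get_preset"]

TRACE = StrategyConfig("trace", theta=0.5)
DEPTHS = tuple(StrategyConfig("depth", depth=l) for l in (1, 2, 3, 4))
FLEX4 = StrategyConfig("flexible", depth=4)


@dataclass(frozen=True)
class Preset:
    name: str
    build: Callable[[], Environment]
    strategies: tuple[StrategyConfig, ...]
    steps: int
    measure_every: int = 100
    test_instantiations: int = 10
    replicates: int = 20
    description: str = ""


def _positional(dist, label):
    return lambda: build_positional_env(
        n_stimuli=66, n_templates=32, informative_positions=dist, name=label
    )


_ORDER_P = {"fig5a": 0.0, "fig5b": 0.25, "fig5c": 0.5, "fig5d": 0.75, "fig5e": 1.0}

PRESETS: dict[str, Preset] = {
    "fig2a": Preset(
        name="fig2a",
        build=lambda: build_graded_depth_env(20, name="graded-20"),
        strategies=DEPTHS,
        steps=20_000,
        description="Depth-1..4 in a 20-stimulus graded-depth world",
    ),
    "fig2b": Preset(
        name="fig2b",
        build=lambda: build_graded_depth_env(500, name="graded-500"),
        strategies=DEPTHS,
        steps=160_000,
        measure_every=1000,
        test_instantiations=2,
        description="Depth-1..4 in a 500-stimulus graded-depth world",
    ),
    "fig3b": Preset(
        name="fig3b",
        build=_positional((0, 0, 0, 1.0), "positional-last"),
        strategies=(TRACE,) + DEPTHS,
        steps=10_000,
        description="all information in the last position",
    ),
    "fig3c": Preset(
        name="fig3c",
        build=_positional((0.25, 0.25, 0.25, 0.25), "positional-uniform"),
        strategies=(TRACE,) + DEPTHS,
        steps=10_000,
        description="information uniform over the four positions",
    ),
    "fig3d": Preset(
        name="fig3d",
        build=_positional((1.0, 0, 0, 0), "positional-first"),
        strategies=(TRACE,) + DEPTHS,
        steps=10_000,
        description="all information in the first position",
    ),
}

for _name, _p in _ORDER_P.items():
    PRESETS[_name] = Preset(
        name=_name,
        build=(lambda p=_p, label=f"order-p{_p}": build_order_env(
            p, n_stimuli=34, name=label
        )),
        strategies=(TRACE, DEPTHS[3], FLEX4),
        steps=80_000,
        measure_every=1000,
        test_instantiations=5,
        description=f"order-sensitive world, sequential-information fraction p={_p}",
    )


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
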