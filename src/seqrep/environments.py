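"""Template-sequence worlds for go/no-go sequence discrimination.

An environment is an alphabet of *informative* and *noise* stimuli plus a set
of length-``L`` template sequences.  A template fixes some positions to
concrete informative stimuli and leaves the rest as noise wildcards; it also
carries a reward label.  Exactly half of the templates are rewarding.  On each
draw a template is picked uniformly at random and every wildcard is filled
i.i.d. uniformly from the noise sub-alphabet (with replacement, so noise
symbols may repeat within a sequence).

Three families of worlds are provided:

``build_graded_depth_env``
    The informative position of each template sits at recency ``k`` (k-th from
    the end) with template proportions defaulting to (1/2, 1/4, 1/8, 1/8) for
    ``k = 1..4`` -- a geometric information gradient with ratio 0.5, truncated
    and renormalised at depth 4.  Each template carries its own informative
    identity, so the learning load scales with the alphabet size as in the
    analytic model.

``build_positional_env``
    Two shared informative identities (one rewarding, one nonrewarding)
    concentrated at positions drawn from a configurable distribution over the
    four temporal positions (all-last, uniform, all-first, ...).

``build_order_env``
    Order-sensitive worlds in which a fraction ``p`` of templates carry pure
    sequential information: the bigram (A, B) is rewarding, (B, A) is
    nonrewarding, and A or B alone (among wildcards) take the crossed labels
    A-alone rewarding / B-alone nonrewarding.  The presence of A or B is then
    uninformative on its own -- each occurs in rewarding and nonrewarding
    templates alike -- and only order context determines the label.  The
    remaining ``1 - p`` of templates carry one concrete single-stimulus
    informative symbol at a position uniform over the sequence.

Integer template counts are derived from fraction parameters with
deterministic largest-remainder rounding applied to rewarding/nonrewarding
*pairs*, which keeps the half-rewarding invariant exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WILDCARD",
    "Stimulus",
    "TemplateSequence",
    "Environment",
    "allocate_counts",
    "sample_sequence",
    "build_positional_env",
    "build_graded_depth_env",
    "build_order_env",
    "test_set",
]

#: Marker used for a noise wildcard position inside a template.
WILDCARD = None


@dataclass(frozen=True)
class Stimulus:
    """One perceivable symbol; ``kind`` is ``"informative"`` or ``"noise"``."""

    id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("informative", "noise"):
            raise ValueError(f"kind must be informative|noise, got {self.kind!r}")


@dataclass(frozen=True)
class TemplateSequence:
    """Length-L pattern of concrete stimulus ids and ``None`` wildcards."""

    positions: tuple[str | None, ...]
    rewarding: bool

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_wildcards(self) -> int:
        return sum(1 for p in self.positions if p is WILDCARD)


@dataclass(frozen=True)
class Environment:
    """Alphabet + templates; ``fill_ids`` is the pool wildcards draw from
    (the noise sub-alphabet by default, but an environment may let selected
    informative stimuli occur intermixed as fills as well)."""

    alphabet: tuple[Stimulus, ...]
    templates: tuple[TemplateSequence, ...]
    seq_length: int = 4
    name: str = ""
    fill_ids: tuple[str, ...] | None = None
    noise_ids: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.alphabet]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique within the alphabet")
        n_rewarding = sum(t.rewarding for t in self.templates)
        if 2 * n_rewarding != len(self.templates):
            raise ValueError(
                f"exactly half of the templates must be rewarding; "
                f"got {n_rewarding} of {len(self.templates)}"
            )
        known = set(ids)
        for t in self.templates:
            if len(t) != self.seq_length:
                raise ValueError("template length must equal seq_length")
            for p in t.positions:
                if p is not WILDCARD and p not in known:
                    raise ValueError(f"template references unknown stimulus {p!r}")
        object.__setattr__(
            self,
            "noise_ids",
            tuple(s.id for s in self.alphabet if s.kind == "noise"),
        )
        if self.fill_ids is None:
            object.__setattr__(self, "fill_ids", self.noise_ids)
        else:
            object.__setattr__(self, "fill_ids", tuple(self.fill_ids))
            for fid in self.fill_ids:
                if fid not in known:
                    raise ValueError(f"fill pool references unknown stimulus {fid!r}")

    @property
    def n_stimuli(self) -> int:
        return len(self.alphabet)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "seq_length": self.seq_length,
            "alphabet": [{"id": s.id, "kind": s.kind} for s in self.alphabet],
            "fill_ids": list(self.fill_ids),
            "templates": [
                {"positions": list(t.positions), "rewarding": t.rewarding}
                for t in self.templates
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Environment":
        doc = json.loads(text)
        return cls(
            alphabet=tuple(Stimulus(a["id"], a["kind"]) for a in doc["alphabet"]),
            templates=tuple(
                TemplateSequence(tuple(t["positions"]), bool(t["rewarding"]))
                for t in doc["templates"]
            ),
            seq_length=int(doc["seq_length"]),
            name=doc.get("name", ""),
            fill_ids=tuple(doc["fill_ids"]) if "fill_ids" in doc else None,
        )


def allocate_counts(total: int, fractions: Sequence[float]) -> list[int]:
    """Deterministic largest-remainder split of ``total`` into integer counts
    proportional to ``fractions`` (which must sum to 1 within 1e-9).

    Ties in the remainders are broken toward earlier entries, so the result is
    reproducible.
    """
    fractions = list(fractions)
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
    raw = [total * f for f in fractions]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


def sample_sequence(
    env: Environment, rng: np.random.Generator
) -> tuple[tuple[str, ...], bool]:
    """Draw one concrete stimulus sequence: uniform template, i.i.d. uniform
    noise fills.  Returns ``(sequence, rewarding)``."""
    if not env.templates:
        raise ValueError("environment has no templates")
    template = env.templates[rng.integers(len(env.templates))]
    return _instantiate(env, template, rng), template.rewarding


def _instantiate(
    env: Environment, template: TemplateSequence, rng: np.random.Generator
) -> tuple[str, ...]:
    n_wild = template.n_wildcards
    if n_wild and not env.fill_ids:
        raise ValueError("template has wildcards but the fill pool is empty")
    if n_wild:
        fills = rng.integers(len(env.fill_ids), size=n_wild)
        it = iter(fills)
        return tuple(
            env.fill_ids[next(it)] if p is WILDCARD else p
            for p in template.positions
        )
    return tuple(template.positions)  # type: ignore[arg-type]


def test_set(
    env: Environment,
    instantiations_per_template: int,
    rng: np.random.Generator,
) -> list[tuple[tuple[str, ...], bool]]:
    """Frozen evaluation set: every template instantiated a fixed number of
    times with independently drawn noise.  Generate once per run and reuse at
    every measurement point."""
    if instantiations_per_template < 1:
        raise ValueError("instantiations_per_template must be >= 1")
    items = []
    for template in env.templates:
        for _ in range(instantiations_per_template):
            items.append((_instantiate(env, template, rng), template.rewarding))
    return items


def _alphabet(n_informative: int, n_noise: int, info_names: Sequence[str] | None = None):
    if info_names is None:
        info_names = [f"s{i:03d}" for i in range(n_informative)]
    informative = [Stimulus(name, "informative") for name in info_names]
    noise = [Stimulus(f"z{i:03d}", "noise") for i in range(n_noise)]
    return informative, noise


def build_positional_env(
    n_stimuli: int = 66,
    n_templates: int = 32,
    informative_positions: Sequence[float] = (0.0, 0.0, 0.0, 1.0),
    seq_length: int = 4,
    name: str = "",
) -> Environment:
    """World with two shared informative identities and a configurable
    distribution of the informative position.

    Each template is concrete at exactly one position, holding either the
    rewarding identity (filled circle in the field's usual depiction) or the
    nonrewarding one; all other positions are noise wildcards.  Rewarding/
    nonrewarding template pairs are allocated over positions with
    largest-remainder rounding, so exactly half the templates are rewarding at
    every position.
    """
    if n_templates % 2:
        raise ValueError(f"n_templates must be even, got {n_templates}")
    if len(informative_positions) != seq_length:
        raise ValueError("informative_positions must have one entry per position")
    if n_stimuli < 3:
        raise ValueError("need at least 2 informative + 1 noise stimuli")
    informative, noise = _alphabet(2, n_stimuli - 2, ["pos", "neg"])
    pos_id, neg_id = informative[0].id, informative[1].id
    pairs_per_position = allocate_counts(n_templates // 2, informative_positions)
    templates = []
    for position, n_pairs in enumerate(pairs_per_position):
        for _ in range(n_pairs):
            for symbol, rewarding in ((pos_id, True), (neg_id, False)):
                pattern: list[str | None] = [WILDCARD] * seq_length
                pattern[position] = symbol
                templates.append(TemplateSequence(tuple(pattern), rewarding))
    return Environment(
        alphabet=tuple(informative + noise),
        templates=tuple(templates),
        seq_length=seq_length,
        name=name or f"positional(n={n_stimuli})",
    )


def build_graded_depth_env(
    n_stimuli: int,
    depth_fractions: Sequence[float] = (0.5, 0.25, 0.125, 0.125),
    n_templates: int | None = None,
    seq_length: int = 4,
    name: str = "",
) -> Environment:
    """World with a geometric information-depth gradient.

    A template at recency ``k`` is concrete at the k-th position from the end
    (wildcards elsewhere, including after it), so the fraction of templates
    decidable at depth ``l`` is ``sum(depth_fractions[:l])`` -- with the
    default fractions, 1/2, 3/4, 7/8, 1: the truncated analogue of
    ``f(l) = 1 - 0.5**l``.

    Every template carries its own distinct informative identity, one
    rewarding/nonrewarding identity pair per template pair, so the number of
    discriminations to learn scales with the alphabet, as in the analytic
    model.  By default 4/5 of the alphabet is informative (``n_templates =
    2*round(0.4*n_stimuli)``): 16 templates in a 20-stimulus world, 400 in a
    500-stimulus world.
    """
    if abs(sum(depth_fractions) - 1.0) > 1e-9:
        raise ValueError("depth_fractions must sum to 1 within 1e-9")
    if len(depth_fractions) > seq_length:
        raise ValueError("more depth fractions than sequence positions")
    if n_templates is None:
        n_templates = 2 * round(0.4 * n_stimuli)
    if n_templates % 2 or n_templates < 2:
        raise ValueError(f"n_templates must be even and >= 2, got {n_templates}")
    n_noise = n_stimuli - n_templates
    if n_noise < 1:
        raise ValueError("alphabet too small for the requested template count")
    informative, noise = _alphabet(n_templates, n_noise)
    pairs_per_recency = allocate_counts(n_templates // 2, depth_fractions)
    templates = []
    ids = iter(s.id for s in informative)
    for recency, n_pairs in enumerate(pairs_per_recency, start=1):
        position = seq_length - recency
        for _ in range(n_pairs):
            for rewarding in (True, False):
                pattern: list[str | None] = [WILDCARD] * seq_length
                pattern[position] = next(ids)
                templates.append(TemplateSequence(tuple(pattern), rewarding))
    return Environment(
        alphabet=tuple(informative + noise),
        templates=tuple(templates),
        seq_length=seq_length,
        name=name or f"graded(n={n_stimuli})",
    )


def build_order_env(
    p: float,
    n_stimuli: int = 66,
    n_templates: int = 24,
    seq_length: int = 4,
    name: str = "",
) -> Environment:
    """Order-sensitive world with sequential-information fraction ``p``.

    A fraction ``p`` of template pairs carries sequential information built
    from two designated stimuli A and B: the bigram (A, B) is rewarding and
    (B, A) nonrewarding, placed uniformly over the start offsets where the
    bigram fits; in equal measure A and B occur singly among wildcards with
    the crossed labels A-alone rewarding, B-alone nonrewarding.  Under this
    inventory the mere presence of A or B predicts nothing -- both labels are
    equally represented for each symbol -- and only the order context (is A
    immediately followed by B?) determines the correct response.  In
    trace-intensity space the four classes are not linearly separable, which
    is what makes this family a probe of genuine order sensitivity.

    The remaining ``1 - p`` of template pairs carries one concrete
    single-stimulus informative symbol (distinct from A and B) at a position
    allocated uniformly over the sequence.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if n_templates % 2:
        raise ValueError(f"n_templates must be even, got {n_templates}")
    n_noise = n_stimuli - 2 - n_templates
    if n_noise < 1:
        raise ValueError(
            "alphabet too small: need A, B, one single-information identity "
            "per template and at least one noise stimulus"
        )
    # A stable alphabet across p: A, B, one single-information identity per
    # template slot (used only by the 1-p single block), plus noise.
    single_ids = [f"c{i:03d}" for i in range(n_templates)]
    informative, noise = _alphabet(
        2 + n_templates, n_noise, ["A", "B", *single_ids]
    )
    a, b = informative[0].id, informative[1].id

    n_pairs = n_templates // 2
    n_seq_pairs, n_single_pairs = allocate_counts(n_pairs, (p, 1.0 - p))

    templates: list[TemplateSequence] = []

    # Sequential block: mostly bigram pairs, plus lone-A/B pairs (1/6 of the
    # block, at least one pair whenever the block holds two or more) so that
    # A and B also occur alone, at the most recent position.
    n_bigram_pairs, n_alone_pairs = allocate_counts(n_seq_pairs, (5 / 6, 1 / 6))
    if n_alone_pairs == 0 and n_seq_pairs >= 2:
        n_bigram_pairs, n_alone_pairs = n_seq_pairs - 1, 1
    n_offsets = seq_length - 1
    offsets = allocate_counts(
        n_bigram_pairs, tuple(1.0 / n_offsets for _ in range(n_offsets))
    )
    for offset, count in enumerate(offsets):
        for _ in range(count):
            for first, second, rewarding in ((a, b, True), (b, a, False)):
                pattern: list[str | None] = [WILDCARD] * seq_length
                pattern[offset], pattern[offset + 1] = first, second
                templates.append(TemplateSequence(tuple(pattern), rewarding))
    for _ in range(n_alone_pairs):
        for symbol, rewarding in ((a, True), (b, False)):
            pattern = [WILDCARD] * seq_length
            pattern[seq_length - 1] = symbol
            templates.append(TemplateSequence(tuple(pattern), rewarding))

    # Single-stimulus block: one concrete informative symbol per template,
    # each template with its own identity, positions spread uniformly.
    single_positions = allocate_counts(
        n_single_pairs, tuple(1.0 / seq_length for _ in range(seq_length))
    )
    ids = iter(single_ids)
    for position, count in enumerate(single_positions):
        for _ in range(count):
            for rewarding in (True, False):
                pattern = [WILDCARD] * seq_length
                pattern[position] = next(ids)
                templates.append(TemplateSequence(tuple(pattern), rewarding))

    # A and B also occur intermixed with other stimuli: wildcards may draw
    # them, so neither first nor last element alone identifies the bigram.
    fill_ids = tuple(s.id for s in noise) + (a, b)
    return Environment(
        alphabet=tuple(informative + noise),
        templates=tuple(templates),
        seq_length=seq_length,
        name=name or f"order(p={p})",
        fill_ids=fill_ids,
    )
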