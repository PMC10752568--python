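# Methods

## The analytic model

An organism perceives one of *n* distinct stimuli per time-step and decides
go/no-go from the last ℓ stimuli (its *decision depth*).  Sequences are
formed by drawing stimuli with replacement, so N(ℓ) = n^ℓ histories can
occur.  The fraction of histories that contain enough information for a
productive decision is modelled as f(ℓ) = 1 − r^ℓ with information rate
0 < r < 1: information accrues with depth, quickly when r is small, slowly
when r is near 1.  Learning a single productive decision takes τ
experiences, and with no innate knowledge the probability u(ℓ, t) that the
decision at time t is productive obeys

    u(ℓ, t+1) = u(ℓ, t) + [f(ℓ) − u(ℓ, t)] / (τ N(ℓ)),   u(ℓ, 0) = 0,

whose solution is u(ℓ, t) = f(ℓ)(1 − (1 − 1/(τN(ℓ)))^t).  Lifetime utility
is the expected number of productive decisions over T exposures,
U(ℓ, T) = Σ_{t<T} u(ℓ, t) = f(ℓ)[T − τN(ℓ)(1 − (1 − 1/(τN(ℓ)))^T)].

Implementation notes:

- N(ℓ) is computed in exact integer arithmetic; the power term
  (1 − 1/(τN))^t is evaluated as `expm1(t·log1p(−1/τN))`, which stays
  accurate when τN is large (up to ~10⁹) and t up to 10⁶.  When τN ≤ 1 a
  single experience suffices and the geometric term clamps to zero.
- τ is real-valued: any constant scaling of the number of *realizable*
  sequences multiplies τN and is therefore absorbed into τ.
- `optimal_depth` breaks ties toward the smaller depth — at equal expected
  utility the shallower representation is never the costlier one.
- `depth_boundary_n` scans integer n upward and reports the first n where
  the shallower depth is at least as good; an absent boundary raises a
  distinct `NoBoundaryError` so callers can tell "no crossover in range"
  from invalid parameters.  With r = 0.5, τ = 10, T = 10,000 the
  depth-1/depth-2 boundary is exactly n = 20 (closed form and direct
  summation agree).

The recurrence iterator is retained alongside the closed form; their
equivalence (|difference| ≤ 1e−9 over a broad grid) is asserted in the test
suite, with the closed form additionally checked against a term-by-term
summation of the fitness definition.

## The simulated worlds

All worlds share one grammar.  An environment is an alphabet of stimuli
(informative or noise) plus length-4 *template sequences*: patterns with
some positions holding a concrete informative stimulus and the rest noise
wildcards.  Exactly half of the templates are rewarding — the generators
enforce this exactly by allocating template counts in rewarding/nonrewarding
pairs with deterministic largest-remainder rounding of every fraction
parameter.  Each training step draws a template uniformly and fills its
wildcards i.i.d. uniformly from the fill pool (noise symbols may repeat
within a sequence).

**Graded-depth worlds** (`build_graded_depth_env`).  A template at recency k
is concrete at the k-th position from the end; template mass over
k = 1..4 defaults to (1/2, 1/4, 1/8, 1/8) — a geometric information
gradient with ratio 0.5, truncated at depth 4 and renormalized, so the
fraction of templates decidable at depth ℓ is 1/2, 3/4, 7/8, 1.  Every
template carries its own informative identity and 4/5 of the alphabet is
informative (16 templates in a 20-stimulus world, 400 in a 500-stimulus
world).  This is the deliberate design choice that makes the learning load
scale with the alphabet, as in the analytic model: the expected time for a
depth-1 learner to cover its discriminations grows like 2m (m templates,
the factor 2 from softmax exploration), and for a depth-2 learner like
2·m·z (z noise symbols), because each (noise, stimulus) pair is a distinct
key for it.  With m = 400, z = 100 the depth-1 agent reaches ~75% of test
sequences near 5,000 trials while the depth-2 agent first matches that
level at ~85,000–90,000 trials, a ≥16-fold cost for one extra step of
faithful depth.  Had the informative inventory been a fixed handful of
symbols, depth-1 learning would complete in hundreds of steps regardless of
n and the comparison would degenerate.

**Positional worlds** (`build_positional_env`).  Two shared informative
identities (one rewarding, one nonrewarding) are placed at a position drawn
from a configurable distribution (all-last, uniform, all-first).  These
worlds isolate *where in time* information sits: depth-1 excels when it is
last and is blind when it is first; the trace handles every position but
pays with intensity-faded encodings of early positions.

**Order-sensitive worlds** (`build_order_env`).  A fraction p of template
pairs carries sequential information built from two designated stimuli A
and B: the bigram (A,B) is rewarding and (B,A) nonrewarding, placed evenly
over the three start offsets; in a 1:5 ratio to the bigrams, A and B also
occur *alone* at the last position with the crossed labels A-alone
rewarding / B-alone nonrewarding.  A and B additionally belong to the
wildcard fill pool, so they appear intermixed with other stimuli.  Under
this inventory the presence of A or B predicts nothing (each symbol occurs
under both labels, and neither the first nor the last element alone
identifies a bigram); the correct response is determined only by order
context.  In trace-intensity space the four sequential classes are not
linearly separable — the (A,B)-rewarding constraint requires w_B > w_A
(weights on the two trace features) while the lone-A/B labels require the
opposite sign pattern — and the least-squares equilibrium of a linear
error-correction learner classifies the bigrams at chance or backwards.
This reproduces, inside a discrete-time model with fixed stimulus
durations, the empirical failure mode of trace memory on order reversal.
The remaining 1 − p of template pairs carries one concrete informative
single stimulus (a distinct identity per template, positions uniform over
the sequence).  The alphabet is held fixed across p so curves at different
p are comparable.

The `fig5*` presets use a 34-symbol order world (A, B, 24 single-information
identities, 8 noise).  The compact noise pool is a deliberate scaling
choice: a rote Depth-4 learner must experience every concrete noise context
of a template separately, so its coverage time grows like 2·(templates)·z^w
with w wildcards per template; with z = 8 its convergence is observable
within ~10⁴–10⁵ steps, whereas z ≳ 60 would push it beyond 10⁶.  No
qualitative ordering depends on z (the trace trap is noise-independent and
the flexible representation generalizes over fills); z only sets the clock
for the rote learner.

Environments serialize to/from JSON (`Environment.to_json/from_json`) so an
exact world can be archived next to its results.

## Representations

A percept is a set of elements (K, x): a subsequence K of the input and an
intensity x.  For the input (D, C, B, A):

- Trace (decay θ): (D, θ³), (C, θ²), (B, θ), (A, 1).  Repeated stimuli
  merge by summing intensities (a trace-accumulation convention; keeping
  only the most recent trace is available via `trace_merge="recent"`).
- Depth-ℓ: the single element holding the last ℓ stimuli in order,
  intensity 1 — e.g. ((B, A), 1) for ℓ = 2.
- Flexible of depth ℓ: every *contiguous* subsequence of the last ℓ
  stimuli at intensity 1 — ten elements for ℓ = 4.  Gapped pairs such as
  (D, B) are not represented.

Keys are ordered tuples, so (A, B) and (B, A) are distinct associations —
this is the entire mechanism of order sensitivity for the depth and
flexible strategies, and its absence (single-stimulus keys) for the trace.
Sequence length is fixed at 4 in all presets and no intensity
renormalization is applied for shorter inputs.

## The agent

Behavior values are linear: v(b) = Σ_(K,x) w(K, b)·x, with absent weights
reading exactly 0 (no innate knowledge).  During learning the agent goes
with probability σ(β(v_go − v_nogo)) (softmax, default β = 1: guaranteed
exploration with no separate ε).  Reinforcement is +5 (go, rewarding), −4
(go, nonrewarding) or 0 (no-go); the asymmetry encodes that acting without
payoff costs less than the payoff of acting correctly.  The chosen
behavior's weights receive a normalized delta-rule update with prediction
error δ = R − v(b):

    w(K, b) += α · x · δ / Σ x²,

leaving the unchosen behavior untouched.  Normalizing by the squared
percept norm makes the value-convergence rate per exposure identical across
strategies that emit 1 (depth), ~4 (trace) or up to 10 (flexible) elements;
without it the flexible strategy's effective rate would be inflated roughly
tenfold, confounding every cost comparison.  The default α = 0.26 places
single-discrimination learning on the τ ≈ 10 timescale of the analytic
model ((1 − α)¹⁰ · 5 < 1, i.e. ten exposures close a 5-unit value gap to
under one utility unit).

Test measurement is greedy (argmax, exact ties to no-go — the costless
default) and never updates weights, so curves report acquired knowledge,
not exploration noise.  A fresh agent therefore scores exactly 0.5 on any
half-rewarding test set.  A divergence guard aborts a run if any weight
magnitude exceeds 10⁶ (a symptom of mis-set α/β, never a valid result).

## Simulations and measurement

Each time-step: draw a sequence, represent it, choose a behavior
(softmax), reinforce, update.  Every `measure_every` steps (default 100;
1,000 in the long presets) the agent answers a frozen test set — each
template instantiated `test_instantiations` times at the start of the
replicate — and the fraction correct is recorded.  Replicates use disjoint
random streams spawned from the master seed; within one seed the
environment stream and test set of replicate k are identical across
strategies, so strategy comparisons are paired.  Identical configuration
and seed reproduce curves bitwise.  `trials_to_reach` reports the first
checkpoint whose replicate-mean performance reaches a level (0.75 by
default in summaries, mirroring the headline learning-time comparison);
checkpoint spacing bounds its resolution.

Problem sizes in the presets are the package's own choices: 20 replicates
and 160,000 steps for the 500-stimulus depth comparison (the depth-2
crossing sits near 88,000), 10,000 steps for the positional worlds, 80,000
for the order worlds.  The acceptance script re-runs the 500-stimulus
comparison from scratch at 20 replicates.

## What the generator does and does not emulate

The synthetic worlds reproduce the structural features the comparisons
need: combinatorial growth of contexts with depth, a geometric information
gradient, controlled temporal placement of information, and order-only
information with distractor occurrences of the order-carrying symbols.
They do not emulate naturalistic stimulus statistics — no Zipfian
frequencies, stimulus similarity or generalization, variable stimulus
durations, or temporally correlated streams.  Passing tests therefore show
that the representation strategies differ as predicted under uniform,
independent draws; they do not certify magnitudes in real environments.
In particular, real trace memories are thought to fail order
discrimination partly because stimulus *durations* blur intensities; here
durations are fixed, and the failure is instead induced structurally (the
crossed lone-A/B labels above).

## Known limitations

- One clause of the order-world comparison does not reproduce: with all
  information in single stimuli (p = 0), the flexible representation
  reaches criterion slightly *before* the trace (or ties), rather than
  after.  With θ = 0.5 a single-information stimulus at the earliest
  position enters the trace percept at intensity 0.125, so the trace needs
  ~8× larger weights to classify those templates, while the flexible
  strategy encodes every position at full intensity; its extra-element
  cost (~α/10 per element) never outweighs that handicap under any linear
  error-correction variant we tested.  The corresponding acceptance test
  asserts the expected ordering and is left failing by design; the
  remaining clauses (trace near chance at p = 1 while flexible and depth-4
  exceed 90% with flexible first; flexible ahead of depth-4 at every p)
  hold.
- No evolutionary dynamics: utilities and learning curves are compared;
  nothing is selected or inherited.
- Memory-storage and processing-time costs of deeper representations are
  outside the model; only learning costs are counted.
- The agent is tabular: no stimulus generalization, eligibility traces,
  secondary reinforcement or behavior chaining, and no recursive chunking
  of subsequences.
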