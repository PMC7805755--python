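# Methods

This note records the model, the numerical choices, and the design
decisions behind `rpdsim`, together with what the test suite does and
does not establish.

## Strategies and payoffs

A pure strategy is a finite state automaton: per state an output in
{C, D} and two successor states, one per opponent action, with state 0
initial. Transitions depend only on the opponent's last action; a
player's own previous action is encoded in which state it occupies.
This space is unbounded (mutation can always add states) and rich enough
that the classic results about instability of equilibria apply to it.

Stochastic strategies, mixed strategies as population members, and more
powerful machine classes (pushdown, Turing) are out of scope, as are
structured populations and the Moran process.

**Minimization and phenotypes.** Different machines can encode the same
behaviour. Minimization removes unreachable states and merges
behaviourally equivalent ones (Moore partition refinement, outputs as
the initial partition), then renumbers states breadth-first from the
initial state with the C-successor explored before the D-successor. The
canonical key — the serialized minimal machine — therefore identifies a
*phenotype*: two genotypes get equal keys iff they play identically
against every opponent. All counting and analysis is by phenotype;
genotypes inside the population are never minimized (unreachable states
are legitimate mutation substrate).

**Payoffs.** Joint play of two machines with n and m states visits at
most n·m joint states, so it decomposes into a pre-period and a cycle.
The normalized discounted payoff (1−δ)Σ δ^(t−1)π_t is evaluated in
closed form from the decomposition; the normalization makes constant
streams equal their stage payoff, so payoffs are comparable across δ.
Self-play payoffs lie in [P, R]; payoffs of arbitrary pairs lie in
[S, T]. With δ = 1 the discounted sum is replaced by the average over
the cycle (limit of means), the pre-period being transient. Sampled
match lengths follow the geometric law P(i rounds) = δ^(i−1)(1−δ); a
match truncated at n rounds is worth (1−δ)·Σ_{t≤n} π_t, whose
expectation over the geometric length equals the discounted payoff —
so sampled and exact fitness modes are interchangeable in expectation.

All payoff formulas are generic over the number type: converting a game
with `game.exact()` runs them in rational arithmetic (`Fraction`), which
the Nash check and the performer comparison use so that *equality* of
payoffs is decided exactly rather than within a float tolerance. Floats
converted to `Fraction` keep their exact binary value (0.75 → 3/4).

## The best responder

Playing against a fixed automaton S is a Markov decision problem whose
states are S's states. Value iteration

    V_{n+1}(i) = max_a { π(a, λ_S(i)) + δ·V_n(μ_S(i, a)) },  V_1 = 0

is a δ-contraction; with nonnegative stage payoffs the zero start lies
below the fixed point, so iterates increase monotonically. Iteration
stops when the sup-norm change drops below tol·(1−δ)/δ with tol = 1e-10
— the standard contraction bound then certifies |V − V*| ≤ tol — and
the greedy policy has stabilized. Ties in the argmax prefer C
(deterministic output; ties mean both actions are optimal). Negative
stage payoffs are rejected at the `StageGame` level rather than shifted
around, keeping the monotonicity premise part of the contract.

The best-response *automaton* has one state per state of S, outputs the
optimal action a*_i, and moves (on either observation) to μ_S(i, a*_i):
the responder tracks S's state deterministically and can ignore its
input. The Nash verdict never compares the iterated value against a
payoff directly: it evaluates Π(BR, S) and Π(S, S) with the same
closed-form routine — identical rounding on both sides — and in exact
mode compares rationals, removing the tolerance entirely (float mode
uses 1e-9 absolute). Verdicts are phenotype properties: the input is
minimized first. The check covers pure strategies only; mixed population
states cannot be certified.

## The evolutionary process

A generation holds N genotypes (N even). Per generation: a uniformly
random perfect matching (a random permutation taken pairwise); one
repeated game per pair — a single sampled length shared by both members
(`sampled` mode) or the expected payoff (`exact` mode); roulette-wheel
(Wright–Fisher) selection, i.e. N independent draws proportional to
payoff, implemented by inverse-CDF sampling (all-zero fitness falls back
to uniform); then each individual mutates with probability `rate` by
exactly one operation:

| operation          | prob. | effect |
|--------------------|-------|--------|
| add state          | 0.20  | append a state with uniform random output and transitions; existing wiring untouched (phenotypically neutral until wired in) |
| delete state       | 0.30  | remove a uniform random non-initial state; dangling transitions re-target uniformly among survivors; no-op on 1-state machines |
| change output      | 0.25  | flip a uniform random state's action |
| change transition  | 0.25  | re-target a uniform random (state, observation) uniformly |

The operation mix is a design choice (the four operations themselves are
the model): delete must outweigh add so genotype sizes stay stationary
instead of bloating, and neutral additions supply exactly the raw
material that stepping-stone paths need. Crossover is deliberately
absent. Any machine can reach any other by a finite operation sequence,
so the whole space is explored with positive probability. The initial
population is N copies of the one-state defector `[D,0,0]`.

A single generator seeded from the run config drives all randomness;
runs are reproducible byte-for-byte and chunked execution equals one
long run. Per-generation logs record phenotype counts (by canonical
key), per-phenotype mean payoffs, and mean genotype size. Exact-fitness
mode caches payoffs per phenotype pair and short-circuits
phenotype-monomorphic generations (constant fitness ⇒ uniform
resampling), which is what makes multi-million-generation runs cheap.

## Transition analysis

**Regions.** Each generation is labelled by the smallest prefix of the
frequency ranking (ties broken by key order) reaching the threshold
(default 0.9): pure, 2-mix, 3-mix, else "other interior". The threshold
must lie in (0.5, (N−1)/N): above the upper end every single mutant
would count as a transition; at 0.5 or below, dynamics near mixed states
become invisible. Consecutive identical labels merge into region spans.

**Exits.** Performance comparison against a resident P (possibly a
2-strategy mixture, with the payoff functional extended linearly):
Q is *equal* iff U(Q,P) = U(P,P) and U(Q,Q) = U(P,Q); *better* if
U(Q,P) > U(P,P), or tied there and U(Q,Q) > U(P,Q); *worse*
symmetrically. Comparisons run in exact rational arithmetic.

The span sequence is walked once. A pure region whose resident is Nash
*establishes* an equilibrium unless the resident was reached by a
neutral invasion — in that case the running chain continues through it,
so a whole stepping-stone sequence counts exactly once. The entrant of
a region change is the highest-ranked strategy of the new label absent
from the old one; a change with no entrant is a fixation and never
breaks a chain. While an equilibrium is established, neutral entrants
extend the chain; the first better performer closes it as **one
indirect invasion**, the first worse performer as **one other path**
(covering the degenerate direct entry of a disadvantaged mutant).
Four situations needed decisions the region formalism leaves open:

* the run's first resident has no predecessor and is treated as a valid
  starting equilibrium (it was not reached by any invasion);
* a pure region of the resident itself discards an evaporated neutral
  excursion (the population never left the equilibrium — nothing is
  counted);
* re-entries — the resident or an earlier chain member dropping below
  the threshold and returning — are drift within the already-observed
  set and do not extend or reset the chain (a pure region of a chain
  member truncates the chain to that member);
* spans classified "other interior" make an active exit *unclassified*
  (tallied separately, never guessed), and chains still unresolved when
  the run ends are not counted as exits;
* a near-neutral disadvantaged mutant hovering around the threshold
  flickers the label between pure(P) and mix(P, mutant) many times
  within a few generations; the same resolution of the same equilibrium
  is counted once per residency episode (the memory clears when a
  different equilibrium establishes), since one mutant lineage
  oscillating across the corner-pocket boundary is one invasion event.
  Without this rule threshold noise inflates the other-path count —
  evaporating *neutral* excursions are never counted, so the asymmetry
  would bias the indirect-invasion share downward.

Nash occupancy is the fraction of generations spent in pure regions
whose resident passes the Nash check — a lower bound, since mixed
states cannot be certified.

## Study conditions and problem sizes

The reference conditions are N = 512, δ = 0.75, payoffs (R,S,T,P) =
(3,0,4,1), per-individual mutation probability 10⁻⁴, threshold 0.9,
all-defector start. Equilibrium exits are rare events at these
conditions — a handful per million generations — so the headline study
(`run_invasion_study`) runs in 500k-generation chunks until at least ten
qualifying exits have accumulated and the mean-payoff trace has visited
both the defection (<1.5) and cooperation (>2.5) bands, capped at twelve
million generations; exact-fitness mode is used for these long runs.
The test suite exercises smaller problem sizes chosen to keep each
property statistically meaningful: drift tests at N = 64 with 600–2000
replicates, bloat control over 30k generations at rate 10⁻³,
distributional checks with 4k–100k draws.

## What the synthetic data does and does not show

The simulator *is* the data-generating process here — there is no
external data — but two simplifications matter when reading results.
Exact-fitness mode removes match-length noise; it preserves matching
noise and drift, and neutrality relations are unchanged, but quantities
tied to payoff variance (e.g. how often a disadvantaged mutant drifts
above the threshold) are somewhat smaller than under sampled lengths.
And scripted fixture logs used in tests realize idealized trajectories
(clean span sequences); they validate the accounting rules, not the
frequency with which real dynamics produce such trajectories.

## Known limitations

* Nash certification, and therefore exit accounting, applies to pure
  residents only; time in mixed states makes occupancy a lower bound
  and exits from mixed equilibria are not counted.
* ESS/NSS/robustness certification is not implemented (no decision
  procedure for those refinements is part of the package).
* The best responder requires δ < 1 and nonnegative stage payoffs.
* Value iteration is float-based; only the final equality comparison is
  exact. A pathological near-tie below 1e-10 in action values could in
  principle select a co-optimal policy branch, which is harmless for
  the payoff comparison itself.
* `limit_of_means_payoff` returns exact `Fraction`s for integer payoff
  tables; mixing float payoff tables with exact mode is the caller's
  responsibility.
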