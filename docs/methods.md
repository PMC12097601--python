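# Methods

## Game and payoff scheme

Each round, every player simultaneously plays C or D. Cooperation costs
`unit_cost` (default 10) points per neighbor and delivers each neighbor
`unit_cost · (b/c)` points:

    payoff_i = Σ_{j∈N(i)} unit_cost·(b/c)·1{a_j=C} − unit_cost·deg(i)·1{a_i=C}

With this per-edge convention a degree-k cooperator's total round cost is
exactly `10k` and the benefit-to-cost ratio holds edge-wise, so both
standard formulations — "cost 10k per round" and "net gain b−c on a mutually
cooperative edge" — are reproduced simultaneously. The scheme implies two
exact identities that the tests verify on random instances: payoff
conservation, `Σ_i payoff_i = unit_cost·(b/c−1)·Σ_{i:C} deg(i)`, and strict
within-round dominance of defection, a unilateral C→D switch gaining exactly
`unit_cost·k`.

The dilemma constraint `b/c > 1` is enforced at config construction. The
default parameter grid is `k ∈ {2,4,6} × b/c ∈ {2,4,6}` with designs of 25
players × 15 rounds (the "fewer rounds, more participants" protocol, 5
repetitions) and 8 players (the "more rounds" protocol; its round count is
not pinned by the protocol we mirror, so it is configurable with default 30).

## Interaction structures

**Ring.** The circulant `C_n(1,…,k/2)`: player *i* neighbors `(i±d) mod n`
for `d ≤ k/2`. Static for the whole experiment; neighbor slot labels are
stable, so an agent can track a given neighbor's behavior across rounds.

**Well-mixed.** Realized as an *independently resampled simple k-regular
graph every round* (via networkx's asymptotically uniform regular-graph
sampler), with neighbor slot labels freshly permuted each round. This keeps
each player's per-round stake (degree k, cost 10k) identical to the ring
condition while destroying partner continuity — the "random one-shot"
feature that matters behaviorally — rather than modeling any particular
matching mechanism. Slot labels consequently carry zero information about
partner identity across rounds, which the tests check directly.

## Synthetic agents (what the generator emulates)

The agents parameterize the behavioral regimes reported for human and
chat-model players rather than any specific model's numbers:

* `always_c` / `always_d` — scripted anchors.
* `random_p` — i.i.d. cooperation with probability p; `p = 0.5` captures the
  "cautious, ~50% regardless of context" regime.
* `period_two` — deterministic alternation from a configurable start; the
  machine-like cycling signature absent in humans.
* `conditional` — cooperates with probability
  `logistic(α + β·f + γ·1{own last = C})`, `f` = last-round neighborhood
  cooperation fraction. This 3-parameter form is the package's own minimal
  model of neighborhood-conditional cooperation: β > 0 gives the human-like
  regime (cooperate among cooperators, defect among defectors), β ≈ 0 the
  indifferent regime, and γ adds own-action persistence. It is a
  phenomenological choice, not an estimated description of any population.
* `imitate_best` — copies the last action of the highest-earning neighbor
  (ties toward C); requires `reveal_neighbor_payoffs=True` since payoff
  visibility is off by default (agents see only their own payoff).
* `llm_adapter` — routes the action through the dialogue contract below.

Round 0: every stochastic agent plays C with an explicit `p0` (default 1.0 —
populations start cooperatively). All agents are memory-1; longer memories
are out of scope.

What the generator does **not** emulate: free-text reasoning, cross-round
drift or learning, payoff-magnitude sensitivity beyond what enters the
logistic term, and any particular chat model's empirical cooperation levels.
Passing tests therefore certify the protocol machinery and statistics, not
behavioral claims about real agents.

## Randomness and determinism

One master seed per experiment. Per-round, per-agent substreams are derived
by counter (`SeedSequence([seed, stream, repetition, round])` spawned per
player), so iteration order and per-agent draw counts cannot perturb other
agents' streams; grid repetition seeds derive deterministically from the
base seed and the condition labels. A fixed config yields byte-identical
logs and CSVs, which an acceptance test asserts via file checksums.

## Conditional-model fitting

`fit_conditional` maximizes the logistic likelihood of rounds 1..T−1 with an
exact-gradient/Hessian trust-region Newton solver; covariance is the inverse
observed information, giving Wald intervals. Degenerate data is handled by
flagging rather than hiding: constant responses (guaranteed separation), a
non-converged solve, or estimates beyond ±15 on these 0/1-scaled covariates
set `boundary=True` and the reported estimate switches to a ridge-penalized
fit (penalty 1e-4·‖θ‖²/2), which is finite but still clearly extreme —
the pathology stays visible. The fitter is cross-checked in the tests
against an independent brute-force lattice maximization of the likelihood
([−4,4]³, step 0.1) and against statsmodels' logistic MLE.

`detect_period_two` reports exact alternation (`is_cyclic`) plus a soft
score: the lag-1 autocorrelation normalized by the population variance,
which is exactly −1 for perfect alternation of any length and defined as 0
for constant series. Exact alternation is deliberately strict; the score
covers noisy cycling.

## Controlled-stimulus protocol

A focal agent with four scripted neighbors: all C for the first
`change_round` (default 5) rounds, then a constant 3/2/1 cooperators under
conditions A/B/C for the rest of the 25 rounds; defectors occupy the lowest
slot indices (a fixed convention). The change takes effect at 0-based round
5, i.e. after five all-C rounds. The three conditions are independent
experiments, not one progressive run. Only the focal agent consumes
randomness; schedules are deterministic. The focal payoff uses the standard
degree-4 formula with a default `b/c = 6` — the ratio only feeds the focal
agent's own-payoff observation, since scripted neighbors are stimuli, not
players. Default 10 runs, reported as per-round means with one-SE bands.

## Metrics

* **Cooperation level** — fraction of players playing C in a round.
* **Assortment** — cooperators' mean fraction of cooperative neighbors minus
  defectors'. Undefined for homogeneous populations and then *excluded* from
  averages (never coerced to 0); in [−1, 1] whenever defined.
* **Relative payoff** — a player's payoff minus the round's population mean.
  Centering is this package's definition (chosen for scale-free comparison
  across conditions and for the exact zero-sum identity
  `n_C·rel_C + n_D·rel_D = 0`, which makes it testable); alternatives like
  rank-based or [0,1]-normalized payoffs would be equally defensible.
* **t-test** — Welch's unequal-variance two-sided test, implemented in
  closed form and verified against scipy to 1e-10; equal-mean zero-variance
  samples get p = 1 by convention. Null p-values pass a KS uniformity check.
* **SE bands** — across-run sd/√n per round; omitted for single runs, exact
  0 when runs are identical.

## Dialogue contract for chat agents

Any callable `prompt → reply` can stand behind an `llm_adapter` agent. The
prompt casts the model as a human participant, presents the slot-labelled
last-round actions and the own payoff, and requests a structured
`ANSWER: C` / `ANSWER: D` line, which is parsed preferentially; otherwise a
reply parses only if it mentions exactly one of the cooperate/defect keyword
families. Unparseable replies and transport errors trigger a clarification
re-prompt; after three failed attempts the experiment is deemed a failure
and the engine keeps the truncated log with `status="failed"`. A scripted
mock backend is record-identical to the corresponding synthetic agent
(verified for always-C, always-D and period-two scripts); no test performs
network calls.

## Problem sizes

The default protocol sizes (25 players × 15 rounds × 5 repetitions × 18
conditions; 10-run stimuli; 100 replicate recovery fits at 2000 rounds) run
in seconds on one CPU, so the shipped analyses use them as-is rather than
scaled-down variants.

## Known limitations

* The well-mixed condition is one concrete operationalization (fresh
  k-regular graph per round); other matching schemes would preserve the
  "no partner continuity" property but differ in degree variance.
* The conditional logistic model is memory-1 and has no payoff term, so it
  cannot express payoff-driven strategies; `imitate_best` exercises that
  axis but is not claimed to reproduce the `b/c > k` cooperation law.
* Wald intervals are asymptotic; at few rounds or extreme parameters their
  coverage degrades (the recovery study uses 2000 rounds, where they are
  accurate).
* No live chat backend is bundled; the adapter defines the contract and is
  exercised with mocks only.
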