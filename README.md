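# netdilemma

A simulation and analysis harness for the **repeated Prisoner's Dilemma on
networks**, built for experiments that compare cooperation on a fixed ring
lattice against a well-mixed population — the setting used to study whether
players (humans, or chat-model agents standing in for them) exploit network
reciprocity.

## The game

Players sit on a graph where each has `k` neighbors. Each round, every
player simultaneously chooses **C** (cooperate) or **D** (defect).
Cooperating costs 10 points per neighbor — a total cost `c = 10k` — and
delivers each neighbor a benefit of `10·(b/c)` points, so player *i*'s round
payoff is

```
payoff_i = Σ_{j ∈ N(i)} 10·(b/c)·1{a_j = C}  −  10·k·1{a_i = C}
```

Mutual cooperation nets each endpoint `b − c` per edge; if everyone defects,
everyone earns zero; and defection strictly dominates within a round (a
unilateral switch from C to D gains exactly `10k`). The interesting regime
is the grid `k ∈ {2,4,6} × b/c ∈ {2,4,6}`: on static networks, human
cooperation is classically stabilized when `b/c > k`.

Two interaction structures are supported:

* **ring** — the circulant `C_n(1..k/2)`: each player is linked to the `k/2`
  nearest players on each side of a cycle, fixed for the whole experiment;
* **well-mixed** — a fresh simple `k`-regular graph is drawn every round and
  neighbor slot labels are re-randomized, so no partner identity persists.

## What's in the box

| module | what it does |
|---|---|
| `netdilemma.topology` | circulant rings, per-round k-regular resampling |
| `netdilemma.engine` | payoffs, simultaneous rounds, experiments, the (k, b/c) grid |
| `netdilemma.agents` | synthetic players: conditional cooperators, period-two cyclers, coin-flippers, imitators, chat-adapter agents |
| `netdilemma.inference` | ML fit of the conditional-cooperation model; period-two detection |
| `netdilemma.stimulus` | focal agent with four scripted neighbors degraded at a change point |
| `netdilemma.metrics` | cooperation level, assortment, relative payoffs, Welch t-test, SE bands |
| `netdilemma.adapter` | prompt/parse/3-retry dialogue contract for live chat agents (mock-only in tests) |
| `netdilemma.config` / `cli` | YAML-configured experiment suites and the `netdilemma` command |

The conditional cooperator — the workhorse synthetic agent — cooperates with
probability `logistic(α + β·f + γ·1{own last action = C})`, where `f` is the
fraction of its neighbors that cooperated last round (round 0 uses an
explicit initial probability `p0`, default 1).

## Worked example

Run the controlled-stimulus protocol (25 rounds, four scripted neighbors,
all cooperative for five rounds, then 3/2/1 cooperators in conditions A/B/C,
10 runs) for three focal regimes:

```
$ python analysis/03_stimulus_response.py --seed 0
     focal condition  coop_rounds_0_4  coop_round_24
responsive         A             0.96            0.8
responsive         B             1.00            0.4
responsive         C             1.00            0.0
  cautious         A             0.40            0.5
  cautious         B             0.50            0.4
  cautious         C             0.50            0.5
    cycler         A             0.60            1.0
    cycler         B             0.60            1.0
    cycler         C             0.60            1.0
```

The *responsive* (strongly conditional) agent cooperates while its
neighborhood does and collapses as cooperators are replaced — fully so under
condition C (one cooperator left). The *cautious* coin-flip agent is pinned
near 50% regardless of the environment, and the *cycler* alternates C,D,C,D
forever (its round-24 value is 1 because 24 is even) — the two
non-human-like signatures the harness is designed to expose. Other entry
points:

```
netdilemma grid [--config FILE] [--dry-run]   # the full (k, b/c) grid
netdilemma stimuli [--config FILE]            # conditions A/B/C
netdilemma fit --log FILE                     # per-player model fits
```

and the numbered drivers `analysis/01_run_grid.py` …
`analysis/04_fit_strategies.py` (grid protocol, relative-payoff t-tests,
stimulus curves, strategy inference).

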