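"""Infer strategies from a mixed-population experiment log.

Runs a 25-player ring experiment mixing conditional cooperators, coin-flip
players, period-two cyclers and unconditional cooperators, then (i) fits the
3-parameter logistic conditional-cooperation model to every player and (ii)
scans every player's action series for period-two cycling.  Shows that the
fitted beta separates conditional players from the rest and that cyclicity
detection isolates the cyclers.
"""

import argparse
from pathlib import Path

import pandas as pd

from netdilemma.agents import AgentSpec
from netdilemma.engine import GameConfig, run_experiment
from netdilemma.inference import detect_period_two, fit_conditional, fits_to_dataframe

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--rounds", type=int, default=200)
parser.add_argument("--out", default="results/fits")
args = parser.parse_args()

specs = (
    [AgentSpec("conditional", {"alpha": -1.0, "beta": 3.0, "gamma": 0.5, "p0": 1.0})] * 10
    + [AgentSpec("random_p", {"p": 0.5})] * 8
    + [AgentSpec("period_two", {"start": "C"})] * 4
    + [AgentSpec("always_c")] * 3
)
kinds = [s.kind for s in specs]
cfg = GameConfig(
    n_players=25, degree=4, benefit_cost_ratio=4,
    rounds=args.rounds, seed=args.seed,
)
log = run_experiment(cfg, specs)

fits = [fit_conditional(log, p) for p in range(25)]
table = fits_to_dataframe(fits)
table["true_kind"] = kinds
table["period_two_score"] = [
    detect_period_two([r.actions[p] for r in log.records])["score"]
    for p in range(25)
]
table["is_cyclic"] = [
    detect_period_two([r.actions[p] for r in log.records])["is_cyclic"]
    for p in range(25)
]

Path(args.out).mkdir(parents=True, exist_ok=True)
table.to_csv(f"{args.out}/player_fits.csv", index=False)

print(table[["player", "true_kind", "alpha", "beta", "gamma",
             "period_two_score", "is_cyclic", "flags"]].round(2).to_string(index=False))
print("\nGroup means of fitted beta (neighborhood sensitivity):")
print(table.groupby("true_kind")["beta"].mean().round(2))
print(f"\nwrote {args.out}/player_fits.csv")
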