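"""Controlled-stimulus responses of three focal-agent regimes.

Each focal agent has four scripted neighbors: all cooperators for five
rounds, then 3/2/1 cooperators (conditions A/B/C) for the rest of the 25
rounds, averaged over 10 runs.  Three presets span the regimes of interest:

* responsive  — strongly conditional cooperator (drops as neighbors defect)
* cautious    — coin-flip player pinned near 50% regardless of neighborhood
* cycler      — deterministic period-two alternation
"""

import argparse
from pathlib import Path

import pandas as pd

from netdilemma.agents import AgentSpec
from netdilemma.stimulus import run_stimulus_experiment, stimulus_to_dataframe

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", default="results/stimuli")
args = parser.parse_args()

PRESETS = {
    "responsive": AgentSpec(
        "conditional", {"alpha": -4.0, "beta": 8.0, "gamma": 0.0, "p0": 1.0}
    ),
    "cautious": AgentSpec("random_p", {"p": 0.5}),
    "cycler": AgentSpec("period_two", {"start": "C"}),
}

Path(args.out).mkdir(parents=True, exist_ok=True)
summary = []
for name, spec in PRESETS.items():
    frames = []
    for i, cond in enumerate("ABC"):
        series = run_stimulus_experiment(
            spec, cond, runs=10, seed=(args.seed * 13 + i) & 0x7FFFFFFF
        )
        frames.append(stimulus_to_dataframe(cond, series))
        summary.append(
            {
                "focal": name,
                "condition": cond,
                "coop_rounds_0_4": sum(series.values[:5]) / 5,
                "coop_round_24": series.values[24],
            }
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(f"{args.out}/{name}.csv", index=False)

tbl = pd.DataFrame(summary)
tbl.to_csv(f"{args.out}/summary.csv", index=False)
print(tbl.round(3).to_string(index=False))
print(f"\nwrote per-focal CSVs and summary to {args.out}")
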