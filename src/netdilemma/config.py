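"""Configuration-driven experiment suites.

YAML configs are validated with pydantic models whose defaults mirror the
printed study protocol: 8- and 25-player designs, the degree/benefit grid
{2,4,6} x {2,4,6}, five repetitions per condition, and the 25-round /
10-run controlled-stimulus protocol with the change after five all-C rounds.

:func:`cmd_run_grid` and :func:`cmd_run_stimuli` are the library entry
points behind the CLI; each writes its artifacts plus a machine-readable
manifest (seeds, versions, every artifact path) sufficient to reproduce any
artifact bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__
from .agents import AgentSpec
from .engine import GameConfig, run_grid, grid_to_dataframe, _repetition_seed
from .metrics import grid_summary, final_round_table
from .stimulus import run_stimulus_experiment, stimulus_to_dataframe

__all__ = [
    "GridSpec",
    "DesignSpec",
    "SuiteConfig",
    "StimuliConfig",
    "PROTOCOL_DEFAULTS",
    "load_suite_config",
    "load_stimuli_config",
    "cmd_run_grid",
    "cmd_run_stimuli",
]

logger = logging.getLogger(__name__)

# The printed protocol parameters, recorded verbatim in every manifest.
PROTOCOL_DEFAULTS = {
    "participant_counts": [8, 25],
    "grid_k_values": [2, 4, 6],
    "grid_ratio_values": [2, 4, 6],
    "repetitions": 5,
    "grid_rounds": 15,
    "long_design_rounds": 30,
    "unit_cost": 10,
    "stimulus_rounds": 25,
    "stimulus_change_round": 5,
    "stimulus_runs": 10,
    "adapter_max_attempts": 3,
}

DEFAULT_AGENT = {
    "kind": "conditional",
    "params": {"alpha": -1.0, "beta": 3.0, "gamma": 0.5, "p0": 1.0},
}


class GridSpec(BaseModel):
    k_values: List[int] = [2, 4, 6]
    ratio_values: List[float] = [2, 4, 6]

    @field_validator("k_values")
    @classmethod
    def _even(cls, v):
        if any(k % 2 != 0 or k < 2 for k in v):
            raise ValueError("k_values must be positive even integers")
        return v


class DesignSpec(BaseModel):
    n_players: int = 25
    rounds: int = 15
    repetitions: int = 5


class SuiteConfig(BaseModel):
    grid: GridSpec = Field(default_factory=GridSpec)
    designs: List[DesignSpec] = Field(default_factory=lambda: [DesignSpec()])
    topology_modes: List[str] = ["ring", "well_mixed"]
    agents: Union[dict, List[dict]] = Field(default_factory=lambda: dict(DEFAULT_AGENT))
    seed: int = 0
    unit_cost: float = 10.0
    reveal_neighbor_payoffs: bool = False
    output_dir: str = "results/grid"

    @model_validator(mode="after")
    def _feasible(self):
        for d in self.designs:
            for k in self.grid.k_values:
                if k >= d.n_players:
                    raise ValueError(
                        f"design n_players={d.n_players} infeasible for k={k}"
                    )
        for m in self.topology_modes:
            if m not in ("ring", "well_mixed"):
                raise ValueError(f"unknown topology mode {m!r}")
        return self

    def agent_specs(self, n_players: int) -> List[AgentSpec]:
        if isinstance(self.agents, dict):
            raw = [self.agents] * n_players
        else:
            raw = list(self.agents)
            if len(raw) != n_players:
                raise ValueError(
                    f"agents list has {len(raw)} entries for {n_players} players"
                )
        return [
            AgentSpec(kind=a["kind"], params=dict(a.get("params", {})))
            for a in raw
        ]


class StimuliConfig(BaseModel):
    focal: dict = Field(
        default_factory=lambda: {
            "kind": "conditional",
            "params": {"alpha": -4.0, "beta": 8.0, "gamma": 0.0, "p0": 1.0},
        }
    )
    conditions: List[str] = ["A", "B", "C"]
    runs: int = 10
    rounds: int = 25
    change_round: int = 5
    benefit_cost_ratio: float = 6.0
    seed: int = 0
    output_dir: str = "results/stimuli"

    @field_validator("conditions")
    @classmethod
    def _known(cls, v):
        bad = set(v) - {"A", "B", "C"}
        if bad:
            raise ValueError(f"unknown stimulus condition(s) {sorted(bad)}")
        return v


def load_suite_config(path: Optional[Union[str, Path]]) -> SuiteConfig:
    if path is None:
        return SuiteConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SuiteConfig(**raw)


def load_stimuli_config(path: Optional[Union[str, Path]]) -> StimuliConfig:
    if path is None:
        return StimuliConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StimuliConfig(**raw)


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def cmd_run_grid(
    config: Union[SuiteConfig, str, Path, None],
    dry_run: bool = False,
    output_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Run the full grid for each design and topology mode.

    Writes full-fidelity JSON logs, a long-format CSV, per-condition summary
    and final-round CSVs, plus ``manifest.json``.  With ``dry_run`` only the
    manifest is written.  Returns the manifest.
    """
    cfg = config if isinstance(config, SuiteConfig) else load_suite_config(config)
    out = Path(output_dir) if output_dir is not None else Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds = {}
    for di, design in enumerate(cfg.designs):
        design_seed = _design_seed(cfg.seed, di)
        for mode in sorted(cfg.topology_modes):
            for k in sorted(cfg.grid.k_values):
                for ratio in sorted(cfg.grid.ratio_values):
                    for rep in range(design.repetitions):
                        key = f"design{di}/{mode}/k{k}/bc{ratio:g}/rep{rep}"
                        seeds[key] = _repetition_seed(
                            design_seed, mode, k, ratio, rep
                        )
    manifest = {
        "version": __version__,
        "protocol_defaults": PROTOCOL_DEFAULTS,
        "config": cfg.model_dump(),
        "seeds": seeds,
        "artifacts": [],
        "dry_run": dry_run,
    }
    if dry_run:
        _write_json(out / "manifest.json", manifest)
        return manifest

    artifacts: List[str] = []
    for di, design in enumerate(cfg.designs):
        logger.info(
            "running design %d: n=%d rounds=%d reps=%d",
            di, design.n_players, design.rounds, design.repetitions,
        )
        base = GameConfig(
            n_players=design.n_players,
            degree=min(cfg.grid.k_values),
            benefit_cost_ratio=max(cfg.grid.ratio_values),
            rounds=design.rounds,
            unit_cost=cfg.unit_cost,
            repetitions=design.repetitions,
            seed=_design_seed(cfg.seed, di),
            reveal_neighbor_payoffs=cfg.reveal_neighbor_payoffs,
        )
        specs = cfg.agent_specs(design.n_players)
        grid = run_grid(
            base,
            cfg.grid.k_values,
            cfg.grid.ratio_values,
            specs,
            topology_modes=cfg.topology_modes,
        )
        ddir = out / f"design{di}_n{design.n_players}"
        ddir.mkdir(parents=True, exist_ok=True)
        for (mode, k, ratio), logs in sorted(grid.items()):
            for log in logs:
                p = ddir / f"log_{mode}_k{k}_bc{ratio:g}_rep{log.repetition}.json"
                p.write_text(log.to_json(indent=None) + "\n")
                artifacts.append(str(p.relative_to(out)))
        long_csv = ddir / "rounds_long.csv"
        grid_to_dataframe(grid).to_csv(long_csv, index=False)
        artifacts.append(str(long_csv.relative_to(out)))
        summary_csv = ddir / "summary.csv"
        grid_summary(grid).to_csv(summary_csv, index=False)
        artifacts.append(str(summary_csv.relative_to(out)))
        final_csv = ddir / "final_round.csv"
        final_round_table(grid).to_csv(final_csv, index=False)
        artifacts.append(str(final_csv.relative_to(out)))
    manifest["artifacts"] = artifacts
    _write_json(out / "manifest.json", manifest)
    return manifest


def _design_seed(base_seed: int, design_index: int) -> int:
    ss = np.random.SeedSequence([base_seed & 0x7FFFFFFF, 0xDE5, design_index])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def cmd_run_stimuli(
    config: Union[StimuliConfig, str, Path, None],
    output_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Run the controlled-stimulus conditions and write per-condition CSVs."""
    cfg = config if isinstance(config, StimuliConfig) else load_stimuli_config(config)
    out = Path(output_dir) if output_dir is not None else Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    focal = AgentSpec(kind=cfg.focal["kind"], params=dict(cfg.focal.get("params", {})))
    artifacts = []
    for cond in cfg.conditions:
        logger.info("stimulus condition %s: %d runs", cond, cfg.runs)
        series = run_stimulus_experiment(
            focal,
            cond,
            runs=cfg.runs,
            seed=_condition_seed(cfg.seed, cond),
            rounds=cfg.rounds,
            change_round=cfg.change_round,
            benefit_cost_ratio=cfg.benefit_cost_ratio,
        )
        p = out / f"stimulus_{cond}.csv"
        stimulus_to_dataframe(cond, series).to_csv(p, index=False)
        artifacts.append(str(p.relative_to(out)))
    manifest = {
        "version": __version__,
        "protocol_defaults": PROTOCOL_DEFAULTS,
        "config": cfg.model_dump(),
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def _condition_seed(base_seed: int, condition: str) -> int:
    ss = np.random.SeedSequence([base_seed & 0x7FFFFFFF, 0x57, ord(condition)])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF
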