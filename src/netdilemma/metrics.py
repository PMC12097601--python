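"""Summary statistics for networked cooperation experiments.

Covers the cooperation level (fraction of C-players), the assortment
statistic (cooperators' mean fraction of cooperative neighbors minus the
defectors'), relative payoffs (round payoffs centered by the round's
population mean), Welch's two-sided t-test, and across-run mean series with
one-standard-error bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .agents import C, D
from .engine import ExperimentLog
from .topology import Topology

__all__ = [
    "MetricSeries",
    "AssortmentResult",
    "cooperation_level",
    "assortment",
    "relative_payoffs",
    "payoff_ttest",
    "mean_with_se",
]


@dataclass(frozen=True)
class MetricSeries:
    """Per-round values with optional one-standard-error band."""

    values: Tuple[float, ...]
    se: Optional[Tuple[float, ...]]
    n_runs: int

    def __post_init__(self) -> None:
        if self.se is not None and len(self.se) != len(self.values):
            raise ValueError("se and values must have equal length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": range(len(self.values)),
                "mean": self.values,
                "se": self.se if self.se is not None else [None] * len(self.values),
                "n_runs": self.n_runs,
            }
        )


@dataclass(frozen=True)
class AssortmentResult:
    """Assortment value, or undefined when either action class is empty."""

    value: Optional[float]
    n_cooperators: int
    n_defectors: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def cooperation_level(actions: Sequence[str]) -> float:
    """Fraction of players choosing C."""
    if len(actions) == 0:
        raise ValueError("empty action vector")
    return sum(a == C for a in actions) / len(actions)


def assortment(topology: Topology, actions: Sequence[str]) -> AssortmentResult:
    """Cooperators' average fraction of cooperative neighbors minus the
    defectors' average fraction of cooperative neighbors.

    Positive values mean cooperators cluster with each other.  Undefined
    (``value=None``) when the population is homogeneous; undefined values are
    excluded from cross-round averaging, never coerced to 0.
    """
    if len(actions) != topology.n_players:
        raise ValueError("actions length must equal n_players")
    coop_idx = [i for i, a in enumerate(actions) if a == C]
    defe_idx = [i for i, a in enumerate(actions) if a == D]
    if not coop_idx or not defe_idx:
        return AssortmentResult(None, len(coop_idx), len(defe_idx))

    def frac_coop(i: int) -> float:
        nbrs = topology.neighbors(i)
        return sum(actions[j] == C for j in nbrs) / len(nbrs)

    value = float(
        np.mean([frac_coop(i) for i in coop_idx])
        - np.mean([frac_coop(i) for i in defe_idx])
    )
    return AssortmentResult(value, len(coop_idx), len(defe_idx))


def relative_payoffs(log: ExperimentLog) -> pd.DataFrame:
    """Per-round class means of mean-centered payoffs.

    A player's relative payoff in a round is their payoff minus that round's
    population mean.  Rows: round; columns ``rel_C`` / ``rel_D`` (NaN when a
    class is empty) plus class counts.  By construction
    ``n_C*rel_C + n_D*rel_D = 0`` in every round.
    """
    if not log.records:
        raise ValueError("log has no rounds")
    rows = []
    for rec in log.records:
        pay = np.asarray(rec.payoffs, dtype=float)
        rel = pay - pay.mean()
        c_mask = np.array([a == C for a in rec.actions])
        rows.append(
            {
                "round": rec.round_index,
                "rel_C": float(rel[c_mask].mean()) if c_mask.any() else math.nan,
                "rel_D": float(rel[~c_mask].mean()) if (~c_mask).any() else math.nan,
                "n_C": int(c_mask.sum()),
                "n_D": int((~c_mask).sum()),
            }
        )
    return pd.DataFrame(rows)


def payoff_ttest(
    class_values_a: Sequence[float], class_values_b: Sequence[float]
) -> Dict[str, float]:
    """Welch's two-sided t-test (unequal variances).

    Closed form: t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch–Satterthwaite degrees of freedom.  Two identical zero-variance
    samples get t = 0, p = 1 by convention.
    """
    a = np.asarray(class_values_a, dtype=float)
    b = np.asarray(class_values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    denom_sq = va / na + vb / nb
    if denom_sq == 0.0:
        if a.mean() == b.mean():
            return {"statistic": 0.0, "p_two_sided": 1.0, "df": float(na + nb - 2)}
        return {"statistic": math.inf, "p_two_sided": 0.0, "df": float(na + nb - 2)}
    t = (a.mean() - b.mean()) / math.sqrt(denom_sq)
    df = denom_sq**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * _sps.t.sf(abs(t), df)
    return {"statistic": float(t), "p_two_sided": float(p), "df": float(df)}


def mean_with_se(runs: Sequence[Sequence[float]]) -> MetricSeries:
    """Across-run per-round mean with standard-error band.

    ``se = sample sd across runs / sqrt(n_runs)`` (the one-standard-error
    band); omitted entirely for a single run.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    lengths = {len(r) for r in runs}
    if len(lengths) != 1:
        raise ValueError(f"ragged run lengths {sorted(lengths)}")
    arr = np.asarray(runs, dtype=float)
    mean = tuple(float(x) for x in arr.mean(axis=0))
    if arr.shape[0] == 1:
        return MetricSeries(values=mean, se=None, n_runs=1)
    se_arr = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
    se_arr[arr.max(axis=0) == arr.min(axis=0)] = 0.0  # identical runs: exact 0
    return MetricSeries(
        values=mean, se=tuple(float(x) for x in se_arr), n_runs=arr.shape[0]
    )


def grid_summary(
    grid: Dict[Tuple[str, int, float], List[ExperimentLog]]
) -> pd.DataFrame:
    """Per-condition per-round cooperation and assortment summary.

    Columns: condition_k, condition_ratio, topology_mode, round, coop_mean,
    coop_se, assortment_mean, n_defined — the shape of the grid-experiment
    summary table.
    """
    rows = []
    for (mode, k, ratio), logs in sorted(grid.items()):
        coop_runs = [log.cooperation_series() for log in logs]
        series = mean_with_se(coop_runs)
        n_rounds = len(series.values)
        for r in range(n_rounds):
            assorts = [
                assortment(log.records[r].topology, log.records[r].actions)
                for log in logs
                if len(log.records) > r
            ]
            defined = [a.value for a in assorts if a.defined]
            rows.append(
                {
                    "condition_k": k,
                    "condition_ratio": ratio,
                    "topology_mode": mode,
                    "round": r,
                    "coop_mean": series.values[r],
                    "coop_se": series.se[r] if series.se is not None else math.nan,
                    "assortment_mean": float(np.mean(defined)) if defined else math.nan,
                    "n_defined": len(defined),
                }
            )
    return pd.DataFrame(rows)


def final_round_table(
    grid: Dict[Tuple[str, int, float], List[ExperimentLog]]
) -> pd.DataFrame:
    """Final-round cooperation per condition (bar-chart layout: one row per
    (b/c, k) pair and topology mode, labelled with the b/c-vs-k relation)."""
    summary = grid_summary(grid)
    last = summary["round"].max()
    tbl = summary[summary["round"] == last].copy()
    tbl["relation"] = np.select(
        [
            tbl["condition_ratio"] > tbl["condition_k"],
            tbl["condition_ratio"] == tbl["condition_k"],
        ],
        ["b/c > k", "b/c = k"],
        default="b/c < k",
    )
    cols = [
        "condition_ratio",
        "condition_k",
        "relation",
        "topology_mode",
        "coop_mean",
        "coop_se",
    ]
    return tbl[cols].reset_index(drop=True)
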