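"""Cost-effectiveness arithmetic: ICER with dominance verdicts, net monetary
benefit, and acceptability curves from probabilistic samples."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["StrategyOutcome", "CEResult", "icer", "nmb", "ceac",
           "DOMINANT", "DOMINATED", "COST_ONLY", "EQUIVALENT"]

DOMINANT = "dominant"            # comparator cheaper and more effective
DOMINATED = "dominated"          # comparator costlier and less effective
COST_ONLY = "cost difference only"   # equal effectiveness, unequal cost
EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted total cost and effectiveness of one strategy."""

    label: str
    total_cost: float
    total_qaly: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.total_cost) and np.isfinite(self.total_qaly)):
            raise ValueError(f"{self.label}: outcomes must be finite")
        if self.total_qaly < 0.0:
            raise ValueError(f"{self.label}: total QALY must be nonnegative")

    def nmb(self, wtp: float) -> float:
        return nmb(self.total_qaly, wtp, self.total_cost)


def nmb(qaly: float, wtp: float, cost: float) -> float:
    """Net monetary benefit ``E * lambda - C`` (USD)."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return qaly * wtp - cost


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a comparator against a reference.

    ``icer`` is the cost per QALY gained when the ratio is meaningful
    (positive QALY gain, or losses on both axes); otherwise ``verdict``
    carries the qualitative outcome and ``icer`` is ``None``.
    """

    reference: StrategyOutcome
    comparator: StrategyOutcome
    delta_cost: float
    delta_qaly: float
    icer: float | None
    verdict: str | None
    nmb_by_wtp: Mapping[float, float] = field(default_factory=dict)

    @property
    def favored_at(self) -> dict[float, str]:
        """Which strategy has the higher NMB at each tabulated WTP."""
        out = {}
        for w, inc in self.nmb_by_wtp.items():
            if inc > 0:
                out[w] = self.comparator.label
            elif inc < 0:
                out[w] = self.reference.label
            else:
                out[w] = "tie"
        return out

    def icer_display(self) -> str:
        if self.icer is not None:
            return f"{self.icer:,.2f}"
        return self.verdict.capitalize()

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout mirroring a published base-case results table."""
        rows = [
            dict(strategy=self.reference.label,
                 total_cost=self.reference.total_cost,
                 total_qaly=self.reference.total_qaly,
                 incremental_cost=np.nan, incremental_qaly=np.nan, icer=""),
            dict(strategy=self.comparator.label,
                 total_cost=self.comparator.total_cost,
                 total_qaly=self.comparator.total_qaly,
                 incremental_cost=self.delta_cost,
                 incremental_qaly=self.delta_qaly,
                 icer=self.icer_display()),
        ]
        return pd.DataFrame(rows)


def icer(reference: StrategyOutcome, comparator: StrategyOutcome,
         wtp_grid: Sequence[float] = ()) -> CEResult:
    """Compare two strategies; deltas are comparator minus reference.

    A comparator that costs more and yields less is *dominated*; one that
    costs less and yields more is *dominant*.  Equal effectiveness with a
    cost difference yields no ratio, only a verdict.
    """
    dc = comparator.total_cost - reference.total_cost
    dq = comparator.total_qaly - reference.total_qaly
    ratio: float | None = None
    verdict: str | None = None
    if dq > 0 and dc < 0:
        verdict = DOMINANT
    elif dq < 0 and dc > 0:
        verdict = DOMINATED
    elif dq == 0:
        verdict = EQUIVALENT if dc == 0 else COST_ONLY
    else:
        ratio = dc / dq
    nmb_by_wtp = {float(w): nmb(dq, w, dc) for w in wtp_grid}
    return CEResult(reference, comparator, dc, dq, ratio, verdict, nmb_by_wtp)


def _sample_arrays(samples) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Accept a long DataFrame (iteration, strategy, cost, qaly) or a mapping
    strategy -> (costs, qalys); return labels plus (n_iter, n_strat) arrays."""
    if isinstance(samples, pd.DataFrame):
        labels = list(dict.fromkeys(samples["strategy"]))
        costs, qalys = [], []
        for s in labels:
            sub = samples[samples["strategy"] == s].sort_values("iteration")
            costs.append(sub["cost"].to_numpy())
            qalys.append(sub["qaly"].to_numpy())
    else:
        labels = list(samples)
        costs = [np.asarray(samples[s][0], dtype=float) for s in labels]
        qalys = [np.asarray(samples[s][1], dtype=float) for s in labels]
    n = {len(c) for c in costs} | {len(q) for q in qalys}
    if len(n) != 1 or n == {0}:
        raise ValueError("strategies must share a common, nonempty iteration count")
    return labels, np.column_stack(costs), np.column_stack(qalys)


def ceac(samples, wtp_grid: Iterable[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay value, each strategy's acceptance probability
    is the fraction of iterations in which it attains the strictly highest
    NMB, with exact ties split equally; columns therefore sum to 1 at every
    grid point.
    """
    labels, costs, qalys = _sample_arrays(samples)
    grid = [float(w) for w in wtp_grid]
    out = np.zeros((len(grid), len(labels)))
    for i, w in enumerate(grid):
        nmbs = qalys * w - costs
        best = nmbs.max(axis=1, keepdims=True)
        winners = nmbs == best
        out[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    df = pd.DataFrame(out, columns=labels)
    df.insert(0, "wtp", grid)
    return df


def ceac_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
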