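"""Incremental cost-effectiveness, one-way sensitivity, PSA, and CEACs.

ICERs are reported pairwise against the reference strategy (the convention
the base-case summary table uses), with cost-effectiveness-frontier
dominance labels alongside: a strategy is simply dominated when another
costs less and yields more QALYs, and extendedly dominated when a mix of
two other strategies does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CEAResult, ModelConfig, build_strategies, run_cohort
from .params import ParameterRegistry, sample_parameters

__all__ = [
    "IncrementalRow",
    "TornadoEntry",
    "CEACCurve",
    "incremental_analysis",
    "tornado",
    "run_psa",
    "ceac",
    "pair_icer",
]


@dataclass(frozen=True)
class IncrementalRow:
    strategy: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: float | None  # None when delta_qalys == 0
    dominance: str  # reference | on_frontier | simple_dominated | extended_dominated


def _frontier_labels(results: list[CEAResult]) -> dict[str, str]:
    """Dominance label per strategy from the cost-effectiveness frontier."""
    labels: dict[str, str] = {}
    for r in results:
        if any(
            (o.cost <= r.cost and o.qalys > r.qalys)
            or (o.cost < r.cost and o.qalys >= r.qalys)
            for o in results
        ):
            labels[r.strategy] = "simple_dominated"
    # extended dominance: on the cost-sorted undominated set, any strategy
    # whose incremental ICER exceeds that of the next one up is removed
    alive = sorted(
        (r for r in results if r.strategy not in labels),
        key=lambda r: (r.cost, -r.qalys),
    )
    changed = True
    while changed and len(alive) > 2:
        changed = False
        for i in range(1, len(alive) - 1):
            lo, mid, hi = alive[i - 1], alive[i], alive[i + 1]
            icer_lo = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_lo > icer_hi:
                labels[mid.strategy] = "extended_dominated"
                alive.pop(i)
                changed = True
                break
    for r in alive:
        labels.setdefault(r.strategy, "on_frontier")
    return labels


def incremental_analysis(
    results: list[CEAResult], reference: str
) -> list[IncrementalRow]:
    """Pairwise comparison of every strategy against ``reference``."""
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names in results")
    by_name = {r.strategy: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference strategy {reference!r} not in results")
    ref = by_name[reference]
    labels = _frontier_labels(results)
    rows = []
    for r in results:
        dc = r.cost - ref.cost
        de = r.qalys - ref.qalys
        icer = dc / de if de != 0 else None
        dominance = "reference" if r.strategy == reference else labels[r.strategy]
        rows.append(
            IncrementalRow(
                strategy=r.strategy,
                comparator=reference,
                delta_cost=dc,
                delta_qalys=de,
                icer=icer,
                dominance=dominance,
            )
        )
    return rows


def incremental_table(results: list[CEAResult], reference: str) -> pd.DataFrame:
    rows = incremental_analysis(results, reference)
    by_name = {r.strategy: r for r in results}
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "cost": [by_name[r.strategy].cost for r in rows],
            "pf_lys": [by_name[r.strategy].pf_lys for r in rows],
            "overall_lys": [by_name[r.strategy].overall_lys for r in rows],
            "qalys": [by_name[r.strategy].qalys for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "delta_qalys": [r.delta_qalys for r in rows],
            "icer": [r.icer for r in rows],
            "dominance": [r.dominance for r in rows],
        }
    )


def pair_icer(
    reg: ParameterRegistry,
    cfg: ModelConfig,
    strategy: str,
    comparator: str,
    pap: bool = False,
) -> float:
    """ICER of ``strategy`` versus ``comparator`` at the registry's values."""
    strategies = build_strategies(reg, pap=pap, cfg=cfg)
    res_s = run_cohort(strategies[strategy], reg, cfg)[1]
    res_c = run_cohort(strategies[comparator], reg, cfg)[1]
    de = res_s.qalys - res_c.qalys
    if de == 0:
        return math.nan
    return (res_s.cost - res_c.cost) / de


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        if not (math.isfinite(self.icer_at_low) and math.isfinite(self.icer_at_high)):
            return math.inf
        return abs(self.icer_at_high - self.icer_at_low)

    @property
    def finite(self) -> bool:
        return math.isfinite(self.icer_at_low) and math.isfinite(self.icer_at_high)


def tornado(
    reg: ParameterRegistry,
    cfg: ModelConfig,
    target_pair: tuple[str, str] = ("icotinib", "control"),
    pap: bool = False,
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis of the pairwise ICER.

    Each varied parameter is set to its lower and upper bound in turn (all
    others at base case) and the ICER of ``target_pair`` recomputed.  Entries
    come back ordered by spread, largest first; parameters with a degenerate
    range have zero spread and rank last.  Non-finite ICERs at a bound are
    kept and flagged rather than dropped.
    """
    strategy, comparator = target_pair
    if parameters is None:
        parameters = [spec.name for spec in reg if spec.varied]
    entries = []
    for name in parameters:
        spec = reg[name]
        icer_lo = pair_icer(reg.with_value(name, spec.low), cfg, strategy, comparator, pap)
        icer_hi = pair_icer(reg.with_value(name, spec.high), cfg, strategy, comparator, pap)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=spec.low,
                high=spec.high,
                icer_at_low=icer_lo,
                icer_at_high=icer_hi,
            )
        )
    return sorted(entries, key=lambda e: -e.spread)


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "spread": [e.spread for e in entries],
            "finite": [e.finite for e in entries],
        }
    )


def run_psa(
    reg: ParameterRegistry,
    cfg: ModelConfig,
    n: int = 1000,
    seed: int = 0,
    pap: bool = False,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis.

    For each of ``n`` Monte-Carlo draws, every distribution-equipped
    parameter is sampled once and all four strategies are evaluated on that
    same draw.  Returns a long DataFrame (draw, strategy, cost, qalys),
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        draw = sample_parameters(reg, rng)
        reg_i = reg.with_values(draw)
        strategies = build_strategies(reg_i, pap=pap, cfg=cfg)
        for name, s in strategies.items():
            res = run_cohort(s, reg_i, cfg)[1]
            records.append((i, name, res.cost, res.qalys))
    return pd.DataFrame(records, columns=["draw", "strategy", "cost", "qalys"])


@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective across WTP thresholds."""

    thresholds: np.ndarray
    prob_cost_effective: pd.DataFrame  # one column per strategy

    def at(self, threshold: float) -> pd.Series:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        return self.prob_cost_effective.iloc[idx]

    def to_frame(self) -> pd.DataFrame:
        out = self.prob_cost_effective.copy()
        out.insert(0, "threshold", self.thresholds)
        return out


DEFAULT_THRESHOLDS = np.arange(0.0, 60001.0, 500.0)


def ceac(psa: pd.DataFrame, thresholds: np.ndarray | None = None) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA output.

    At each threshold, a strategy scores the fraction of draws in which its
    net monetary benefit (threshold * QALYs - cost) is strictly maximal;
    exact ties split equally.
    """
    if psa.empty:
        raise ValueError("PSA output is empty")
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    cost = psa.pivot(index="draw", columns="strategy", values="cost")
    qaly = psa.pivot(index="draw", columns="strategy", values="qalys")
    strategies = list(cost.columns)
    n = len(cost)
    probs = np.zeros((len(thresholds), len(strategies)))
    c = cost.to_numpy()
    q = qaly.to_numpy()
    for i, lam in enumerate(thresholds):
        nmb = lam * q - c
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n
    return CEACCurve(
        thresholds=thresholds,
        prob_cost_effective=pd.DataFrame(probs, columns=strategies),
    )
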