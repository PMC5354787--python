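"""Frequentist random-effects network meta-analysis on the log hazard-ratio scale.

Trial-level hazard ratios with 95% confidence intervals are converted to
log-HRs with standard errors, assembled into a treatment network, and
synthesised by weighted least squares on the network design matrix.  A single
between-study variance tau^2, estimated by the moment (DerSimonian-Laird
generalisation) method from the network heterogeneity statistic Q, is shared
across comparisons.  For a loop-free network the node estimates reduce to
products of per-edge pooled hazard ratios, which serves as an independent
oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TrialEffect",
    "EvidenceNetwork",
    "PooledEdge",
    "NMAResult",
    "loghr_from_ci",
    "pool_random_effects",
    "nma_estimate",
    "read_trials_csv",
    "default_network",
]

#: 2 * z_{0.975}; width of a 95% CI in SE units.
_CI_WIDTH_Z = 2.0 * 1.96


@dataclass(frozen=True)
class TrialEffect:
    """One trial's hazard ratio for ``treat_b`` versus ``treat_a``."""

    study: str
    treat_a: str
    treat_b: str
    hr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(
                f"{self.study}: require 0 < ci_low <= hr <= ci_high, "
                f"got ({self.ci_low}, {self.hr}, {self.ci_high})"
            )


def loghr_from_ci(effect: TrialEffect) -> tuple[float, float]:
    """(log HR, SE) from a point estimate with symmetric-on-log-scale 95% CI."""
    loghr = math.log(effect.hr)
    se = (math.log(effect.ci_high) - math.log(effect.ci_low)) / _CI_WIDTH_Z
    return loghr, se


@dataclass
class EvidenceNetwork:
    """A connected network of trial-level comparisons with a reference node."""

    edges: list[TrialEffect]
    reference: str

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.treat_a)
            seen.setdefault(e.treat_b)
        return list(seen)

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for e in self.edges:
            g.add_edge(e.treat_a, e.treat_b, study=e.study)
        return g

    def validate(self) -> None:
        if not self.edges:
            raise ValueError("network has no trials")
        g = self.graph()
        if self.reference not in g:
            raise ValueError(f"reference node {self.reference!r} not in network")
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(f"network is disconnected: components {comps}")


@dataclass(frozen=True)
class PooledEdge:
    """DerSimonian-Laird pooled estimate for one pairwise comparison."""

    loghr: float
    se: float
    q: float
    df: int
    tau2: float
    i2: float

    @property
    def hr(self) -> float:
        return math.exp(self.loghr)


def pool_random_effects(effects: list[TrialEffect]) -> PooledEdge:
    """DerSimonian-Laird random-effects pooling of one comparison's trials.

    Fixed-effect weights w = 1/SE^2 give Q = sum w (y - ybar)^2 on k-1 df;
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)); the pooled estimate
    re-weights by 1/(SE^2 + tau^2).
    """
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    y, se = np.array([loghr_from_ci(e) for e in effects]).T
    w = 1.0 / se**2
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = len(effects) - 1
    if df > 0:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c)
    else:
        tau2 = 0.0
    wr = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wr * y) / np.sum(wr))
    pooled_se = float(1.0 / math.sqrt(np.sum(wr)))
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0
    return PooledEdge(loghr=pooled, se=pooled_se, q=q, df=df, tau2=tau2, i2=i2)


@dataclass
class NMAResult:
    """Pooled log hazard ratios of every node versus the reference."""

    reference: str
    pooled: dict[str, tuple[float, float]]  # node -> (logHR vs reference, SE)
    q: float
    df: int
    tau2: float
    i2: float
    fitted: pd.DataFrame = field(repr=False, default=None)

    def hr(self, node: str) -> float:
        return math.exp(self.pooled[node][0])

    def hrs(self) -> dict[str, float]:
        return {node: math.exp(lh) for node, (lh, _) in self.pooled.items()}


def _design(effects: list[TrialEffect], nodes: list[str], reference: str) -> np.ndarray:
    params = [n for n in nodes if n != reference]
    x = np.zeros((len(effects), len(params)))
    idx = {n: j for j, n in enumerate(params)}
    for i, e in enumerate(effects):
        if e.treat_b != reference:
            x[i, idx[e.treat_b]] += 1.0
        if e.treat_a != reference:
            x[i, idx[e.treat_a]] -= 1.0
    return x


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xtw = x.T * w
    cov = np.linalg.inv(xtw @ x)
    beta = cov @ (xtw @ y)
    return beta, cov


def nma_estimate(net: EvidenceNetwork) -> NMAResult:
    """Fit the network by inverse-variance weighted least squares.

    Stage 1 (fixed effect) yields the network Q on
    df = n_studies - (n_nodes - 1).  tau^2 is the moment estimate
    max(0, (Q - df) / c) with c = tr(W) - tr((X'WX)^-1 X'W^2 X), the network
    generalisation of the DerSimonian-Laird denominator.  Stage 2 refits with
    weights 1/(SE^2 + tau^2).  I^2 = max(0, (Q - df)/Q) * 100.
    """
    net.validate()
    nodes = net.nodes
    params = [n for n in nodes if n != net.reference]
    y, se = np.array([loghr_from_ci(e) for e in net.edges]).T
    x = _design(net.edges, nodes, net.reference)

    w_fe = 1.0 / se**2
    beta_fe, cov_fe = _wls(x, y, w_fe)
    resid = y - x @ beta_fe
    q = float(np.sum(w_fe * resid**2))
    df = len(net.edges) - len(params)
    if df > 0:
        # c = tr(W) - tr((X'WX)^-1 X'W^2 X)
        xtw2x = (x.T * w_fe**2) @ x
        c = float(np.sum(w_fe) - np.trace(cov_fe @ xtw2x))
        tau2 = max(0.0, (q - df) / c)
    else:
        tau2 = 0.0
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0

    w_re = 1.0 / (se**2 + tau2)
    beta, cov = _wls(x, y, w_re)
    ses = np.sqrt(np.diag(cov))

    pooled = {net.reference: (0.0, 0.0)}
    for j, node in enumerate(params):
        pooled[node] = (float(beta[j]), float(ses[j]))
    fitted = pd.DataFrame(
        {
            "study": [e.study for e in net.edges],
            "treat_a": [e.treat_a for e in net.edges],
            "treat_b": [e.treat_b for e in net.edges],
            "loghr": y,
            "se": se,
            "fitted_loghr": x @ beta,
        }
    )
    return NMAResult(
        reference=net.reference, pooled=pooled, q=q, df=df, tau2=tau2, i2=i2, fitted=fitted
    )


def read_trials_csv(path) -> list[TrialEffect]:
    """Read a trial table (study, treat_a, treat_b, hr, ci_low, ci_high)."""
    df = pd.read_csv(path)
    required = {"study", "treat_a", "treat_b", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TrialEffect(
            study=row.study,
            treat_a=row.treat_a,
            treat_b=row.treat_b,
            hr=float(row.hr),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
        )
        for row in df.itertuples()
    ]


def default_network(path=None) -> EvidenceNetwork:
    """The packaged six-trial first-line PFS evidence network.

    Nodes: PC (pemetrexed-cisplatin, the reference), PC plus pemetrexed
    maintenance, non-pemetrexed platinum doublet chemotherapy, gefitinib,
    icotinib.  The pemetrexed-doublet meta-analysis edge links PC to the
    non-pemetrexed doublet, which is the comparator arm of the three
    gefitinib trials; this is the only way the network connects.
    """
    from importlib import resources

    if path is None:
        ref = resources.files("cea_nsclc.data").joinpath("trials.csv")
        with resources.as_file(ref) as p:
            effects = read_trials_csv(p)
    else:
        effects = read_trials_csv(path)
    return EvidenceNetwork(edges=effects, reference="PC")
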