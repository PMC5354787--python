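"""Synthetic-data generators for exercising the fitting and pooling stages.

Real inputs to this model are published summary statistics, so validating
the curve-fitting and meta-analysis machinery requires data with known
truth.  These generators produce (a) Kaplan-Meier PFS curves drawn from a
known Weibull model with independent exponential censoring and (b)
multi-trial log-hazard-ratio networks with known true effects and
between-study heterogeneity.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from lifelines import KaplanMeierFitter

from .nma import TrialEffect
from .params import DistributionSpec, ParameterRegistry
from .survival import KMCurve

__all__ = [
    "SyntheticKMSpec",
    "SyntheticNetworkSpec",
    "gen_km_curve",
    "gen_nma_trials",
    "degenerate_registry",
]


@dataclass(frozen=True)
class SyntheticKMSpec:
    """Weibull event times with independent exponential censoring."""

    true_scale: float = 0.1029
    true_shape: float = 1.3077
    n_subjects: int = 500
    censor_rate: float = 0.02  # exponential rate per time unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("need at least 10 subjects")
        if self.censor_rate < 0:
            raise ValueError("censor rate must be >= 0")
        if not (self.true_scale > 0 and self.true_shape > 0):
            raise ValueError("Weibull parameters must be positive")


def gen_km_curve(spec: SyntheticKMSpec) -> KMCurve:
    """Kaplan-Meier product-limit estimate of a synthetic censored sample.

    Event times satisfy S(t) = exp(-lam t^gamma); T = (E/lam)^(1/gamma) with
    E ~ Exp(1).  Censoring times are exponential with the spec's rate (no
    censoring when the rate is 0).
    """
    rng = np.random.default_rng(spec.seed)
    e = rng.exponential(1.0, spec.n_subjects)
    event_times = (e / spec.true_scale) ** (1.0 / spec.true_shape)
    if spec.censor_rate > 0:
        censor_times = rng.exponential(1.0 / spec.censor_rate, spec.n_subjects)
    else:
        censor_times = np.full(spec.n_subjects, np.inf)
    observed = event_times <= censor_times
    if not observed.any():
        raise ValueError("all subjects censored before the first event")
    times = np.minimum(event_times, censor_times)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(float)
    s = sf.iloc[:, 0].to_numpy(float)
    at_risk = np.asarray(
        [int((times >= ti).sum()) for ti in t], dtype=float
    )
    return KMCurve(times=t, survival=s, at_risk=at_risk)


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """A trial network with known edge effects and heterogeneity tau^2."""

    edges: tuple[tuple[str, str, float], ...]  # (treat_a, treat_b, true logHR)
    tau2: float = 0.0
    trials_per_edge: int = 3
    se_range: tuple[float, float] = (0.1, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.trials_per_edge < 1:
            raise ValueError("need at least one trial per edge")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError("invalid within-trial SE range")


def gen_nma_trials(spec: SyntheticNetworkSpec) -> list[TrialEffect]:
    """Simulate trial-level hazard ratios with 95% CIs.

    Each trial's observed log HR is the edge truth plus a Normal(0, tau^2)
    study effect plus Normal(0, SE^2) sampling error, with SE drawn
    uniformly from the spec's range; the CI is the Wald interval on the log
    scale, so ci_low <= hr <= ci_high by construction.
    """
    rng = np.random.default_rng(spec.seed)
    tau = math.sqrt(spec.tau2)
    trials = []
    for a, b, true_loghr in spec.edges:
        for k in range(spec.trials_per_edge):
            se = float(rng.uniform(*spec.se_range))
            y = true_loghr + rng.normal(0.0, tau) + rng.normal(0.0, se)
            trials.append(
                TrialEffect(
                    study=f"{a}_vs_{b}_{k}",
                    treat_a=a,
                    treat_b=b,
                    hr=math.exp(y),
                    ci_low=math.exp(y - 1.96 * se),
                    ci_high=math.exp(y + 1.96 * se),
                )
            )
    return trials


def degenerate_registry(reg: ParameterRegistry) -> ParameterRegistry:
    """Replace every sampling distribution by a point mass at the base value.

    PSA on the result reproduces the base case exactly, which pins down the
    sampling plumbing in tests.
    """
    entries = {}
    for spec in reg:
        if spec.dist is not None:
            spec = replace(spec, dist=DistributionSpec("point", spec.base))
        entries[spec.name] = spec
    return ParameterRegistry(entries)
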