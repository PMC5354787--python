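"""Typed parameter registry with one-way ranges and PSA sampling distributions.

Every quantity the model consumes — drug and resource costs, health-state
utilities, transition probabilities, pooled hazard ratios, and structural
constants such as the willingness-to-pay threshold — lives in a single
:class:`ParameterRegistry` loaded from a packaged YAML file.  Each entry
carries a base-case value, a one-way sensitivity range, and (where the
parameter is varied probabilistically) a beta, gamma, or normal sampling
distribution following the usual convention for health-economic PSA:
beta for probabilities and utilities, gamma for costs, normal for hazard
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSpec",
    "ParameterRegistry",
    "ConfigurationError",
    "build_default_registry",
    "load_registry",
    "save_registry",
    "validate_registry",
    "sample_parameters",
]

#: Relative tolerance for the distribution-mean vs base-value consistency audit.
MEAN_RTOL = 0.02

_FAMILIES = ("beta", "gamma", "normal", "point")

_KINDS = ("probability", "utility", "cost", "hazard_ratio", "scalar")


class ConfigurationError(ValueError):
    """A parameter file or registry is malformed or incomplete."""


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution.

    ``p1``/``p2`` are (alpha, beta) for beta, (shape, scale) for gamma and
    (mean, sd) for normal.  The degenerate ``point`` family (value ``p1``)
    is used to switch sampling off while keeping the sampling interface.
    """

    family: str
    p1: float
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and not (self.p1 > 0 and self.p2 > 0):
            raise ConfigurationError(
                f"{self.family} distribution needs positive parameters, "
                f"got ({self.p1}, {self.p2})"
            )
        if self.family == "normal" and not self.p2 > 0:
            raise ConfigurationError(f"normal distribution needs sd > 0, got {self.p2}")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.p1 / (self.p1 + self.p2)
        if self.family == "gamma":
            return self.p1 * self.p2
        return self.p1  # normal and point

    @property
    def variance(self) -> float:
        if self.family == "beta":
            s = self.p1 + self.p2
            return self.p1 * self.p2 / (s * s * (s + 1.0))
        if self.family == "gamma":
            return self.p1 * self.p2 * self.p2
        if self.family == "normal":
            return self.p2 * self.p2
        return 0.0


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: base value, one-way range, optional PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    dist: DistributionSpec | None = None
    kind: str = "scalar"
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ConfigurationError(
                f"{self.name}: require low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.kind not in _KINDS:
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def varied(self) -> bool:
        """True when the one-way range is non-degenerate."""
        return self.high > self.low


@dataclass
class ParameterRegistry:
    """Name-keyed collection of :class:`ParameterSpec` entries."""

    entries: dict[str, ParameterSpec] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self.entries[name]
        except KeyError:
            raise ConfigurationError(f"parameter {name!r} is not in the registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def base(self, name: str) -> float:
        return self[name].base

    def bases(self) -> dict[str, float]:
        """Base-case value of every entry."""
        return {spec.name: spec.base for spec in self}

    def add(self, spec: ParameterSpec) -> None:
        if spec.name in self.entries:
            raise ConfigurationError(f"duplicate parameter {spec.name!r}")
        self.entries[spec.name] = spec

    def with_value(self, name: str, value: float) -> "ParameterRegistry":
        """A copy of the registry with one entry's base replaced (range widened
        if the new value falls outside it — used by one-way sensitivity runs)."""
        spec = self[name]
        new = replace(
            spec,
            base=value,
            low=min(spec.low, value),
            high=max(spec.high, value),
        )
        entries = dict(self.entries)
        entries[name] = new
        return ParameterRegistry(entries)

    def with_values(self, values: dict[str, float]) -> "ParameterRegistry":
        reg = self
        for name, value in values.items():
            reg = reg.with_value(name, value)
        return reg


def _spec_from_record(rec: dict) -> ParameterSpec:
    dist = None
    if rec.get("dist") is not None:
        d = rec["dist"]
        dist = DistributionSpec(d["family"], float(d["p1"]), float(d.get("p2", 0.0)))
    return ParameterSpec(
        name=str(rec["name"]),
        base=float(rec["base"]),
        low=float(rec["low"]),
        high=float(rec["high"]),
        dist=dist,
        kind=str(rec.get("kind", "scalar")),
        units=str(rec.get("units", "")),
        source=str(rec.get("source", "")),
    )


def load_registry(path: str | Path) -> ParameterRegistry:
    """Load a registry from a YAML parameter file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ConfigurationError(f"{path}: expected a top-level 'parameters' list")
    reg = ParameterRegistry()
    for rec in doc["parameters"]:
        reg.add(_spec_from_record(rec))
    return reg


def save_registry(reg: ParameterRegistry, path: str | Path) -> None:
    """Write a registry back to YAML (full precision round-trip)."""
    records = []
    for spec in reg:
        rec: dict = {
            "name": spec.name,
            "base": spec.base,
            "low": spec.low,
            "high": spec.high,
        }
        if spec.dist is not None:
            rec["dist"] = {
                "family": spec.dist.family,
                "p1": spec.dist.p1,
                "p2": spec.dist.p2,
            }
        rec["kind"] = spec.kind
        rec["units"] = spec.units
        rec["source"] = spec.source
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": records}, fh, sort_keys=False)


#: Entries every downstream stage relies on; build_default_registry refuses to
#: return a registry missing any of them.
REQUIRED_ENTRIES = (
    "weibull_scale",
    "weibull_shape",
    "hr_maintenance",
    "hr_gefitinib",
    "hr_icotinib",
    "prob_death_post_progression",
    "egfr_prevalence",
    "prob_sae_control",
    "prob_sae_maintenance",
    "prob_sae_gefitinib",
    "prob_sae_icotinib",
    "body_surface_area",
    "cost_pemetrexed_500mg",
    "cost_chemo_backbone_per_cycle",
    "cost_icotinib_per_day",
    "cost_gefitinib_per_day",
    "cost_followup_per_unit",
    "cost_salvage_per_cycle",
    "cost_terminal_care",
    "cost_supportive_per_cycle",
    "cost_sae_unit",
    "cost_egfr_test",
    "utility_pfs",
    "utility_pps",
    "disutility_sae",
    "salvage_uptake",
    "discount_rate_annual",
    "wtp_threshold",
    "pap_cap_gefitinib",
    "pap_cap_icotinib",
)


def build_default_registry(path: str | Path | None = None) -> ParameterRegistry:
    """Load the packaged base-case parameter file (or an override file).

    Raises :class:`ConfigurationError` naming the first missing entry if the
    file does not cover every quantity the model consumes.
    """
    if path is None:
        ref = resources.files("cea_nsclc.data").joinpath("parameters.yaml")
        with resources.as_file(ref) as p:
            reg = load_registry(p)
    else:
        reg = load_registry(path)
    for name in REQUIRED_ENTRIES:
        if name not in reg:
            raise ConfigurationError(f"parameter file is missing required entry {name!r}")
    return reg


def validate_registry(reg: ParameterRegistry, rtol: float = MEAN_RTOL) -> list[dict]:
    """Audit distribution parameterizations against base-case values.

    Returns one report per entry whose distribution mean deviates from its
    base value by more than ``rtol`` (relative), with both values.  Purely a
    reporting operation: printed parameterizations are taken as given even
    when slightly inconsistent.
    """
    reports = []
    for spec in reg:
        if spec.dist is None or spec.base == 0:
            continue
        mean = spec.dist.mean
        rel = abs(mean - spec.base) / abs(spec.base)
        if rel > rtol:
            reports.append(
                {
                    "name": spec.name,
                    "base": spec.base,
                    "dist_mean": mean,
                    "rel_deviation": rel,
                }
            )
    return reports


_MAX_REDRAWS = 1000


def _draw_one(spec: ParameterSpec, rng: np.random.Generator) -> float:
    d = spec.dist
    assert d is not None
    if d.family == "point":
        return d.p1
    if d.family == "beta":
        return float(rng.beta(d.p1, d.p2))
    if d.family == "gamma":
        return float(rng.gamma(d.p1, d.p2))
    # normal: redraw until the draw respects the parameter's support
    # (strictly positive; additionally <= 1 for probabilities/utilities)
    upper = 1.0 if spec.kind in ("probability", "utility") else math.inf
    for _ in range(_MAX_REDRAWS):
        x = float(rng.normal(d.p1, d.p2))
        if 0.0 < x <= upper:
            return x
    raise ConfigurationError(
        f"could not draw a valid value for {spec.name!r} after {_MAX_REDRAWS} tries"
    )


def sample_parameters(
    reg: ParameterRegistry,
    seed: int | np.random.Generator,
    names: list[str] | None = None,
) -> dict[str, float]:
    """One Monte-Carlo draw of every distribution-equipped parameter.

    ``names`` restricts sampling to a subset; requesting an entry without a
    distribution is an error naming it.  Deterministic for a fixed seed.
    Draws are taken in sorted name order so the result does not depend on
    registry insertion order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if names is None:
        names = [spec.name for spec in reg if spec.dist is not None]
    draw: dict[str, float] = {}
    for name in sorted(names):
        spec = reg[name]
        if spec.dist is None:
            raise ConfigurationError(
                f"parameter {name!r} has no sampling distribution"
            )
        draw[name] = _draw_one(spec, rng)
    return draw
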