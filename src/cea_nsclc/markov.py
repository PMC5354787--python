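"""Three-state Markov cohort engine with cost/QALY accrual and PAP drug caps.

The cohort starts 100% progression-free (PFS).  Each 21-day cycle a
time-dependent Weibull hazard moves patients from PFS to post-progression
survival (PPS); PPS patients die with a constant per-cycle probability.
There is no direct PFS-to-death path: overall survival is the composition of
the PFS curve and the geometric post-progression survival.

Accrual conventions that the underlying evidence leaves open (follow-up
billing frequency, salvage-chemotherapy duration, the duration of the
serious-adverse-event disutility, half-cycle correction, the time unit of
the Weibull parameters) are explicit :class:`ModelConfig` flags with
documented defaults, so scenario analyses can vary them transparently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import ConfigurationError, ParameterRegistry
from .survival import CYCLE_DAYS, MONTH_DAYS, WeibullPFS, apply_hazard_ratio, cycle_transition_prob

__all__ = [
    "ModelConfig",
    "StrategySpec",
    "CohortTrace",
    "CEAResult",
    "build_strategies",
    "discount_factor",
    "sae_cost_per_cycle",
    "pap_drug_cost_schedule",
    "apply_pap_cap",
    "run_cohort",
    "run_base_case",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = ("control", "maintenance", "gefitinib", "icotinib")

#: Number of 21-day induction cycles of pemetrexed-cisplatin chemotherapy.
INDUCTION_CYCLES = 4

#: Pemetrexed dose (mg per m^2 of body surface area) and vial size (mg).
PEMETREXED_DOSE_PER_M2 = 500.0
PEMETREXED_VIAL_MG = 500.0


@dataclass(frozen=True)
class ModelConfig:
    """Structural settings and accounting-convention flags.

    Attributes
    ----------
    cycle_days, horizon_years, discount_annual
        21-day cycles over a 10-year horizon with 5%/year discounting of
        costs and QALYs.
    half_cycle_correction
        When on, state-occupancy accruals use the average of start- and
        end-of-cycle membership instead of start-of-cycle membership.
    salvage_max_cycles
        Cycles of salvage chemotherapy offered after progression (to the
        salvage-uptake fraction) before everyone moves to supportive care.
    weibull_time_unit
        Unit the Weibull scale/shape are expressed in ("cycle" or "month").
    followup_per
        Follow-up cost billed once per "cycle" or once per "month" alive.
    sae_disutility_mode
        Cycles in which the SAE utility decrement applies: "on_treatment"
        (default), "all_pfs", or "induction_only".
    """

    cycle_days: float = CYCLE_DAYS
    horizon_years: float = 10.0
    discount_annual: float = 0.05
    half_cycle_correction: bool = True
    salvage_max_cycles: int = 8
    weibull_time_unit: str = "cycle"
    followup_per: str = "month"
    sae_disutility_mode: str = "all_pfs"
    wtp_threshold: float = 22200.0

    def __post_init__(self) -> None:
        if self.followup_per not in ("cycle", "month"):
            raise ConfigurationError(f"unknown follow-up convention {self.followup_per!r}")
        if self.sae_disutility_mode not in ("on_treatment", "all_pfs", "induction_only"):
            raise ConfigurationError(
                f"unknown SAE-disutility convention {self.sae_disutility_mode!r}"
            )
        if self.salvage_max_cycles < 0:
            raise ConfigurationError("salvage_max_cycles must be >= 0")

    @property
    def n_cycles(self) -> int:
        """Whole model cycles in the horizon: floor(365 * years / cycle_days)."""
        return int(365.0 * self.horizon_years // self.cycle_days)

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.0

    @property
    def followup_cost_scale(self) -> float:
        """Follow-up units billed per model cycle under the configured frequency."""
        return 1.0 if self.followup_per == "cycle" else self.cycle_days / MONTH_DAYS


def discount_factor(cfg: ModelConfig, cycle: int) -> float:
    """(1 + r)^(-cycle * cycle_days / 365); cycle 0 is undiscounted."""
    if cycle < 0:
        raise ValueError("cycle index must be >= 0")
    return (1.0 + cfg.discount_annual) ** (-cycle * cfg.cycle_days / 365.0)


@dataclass(frozen=True)
class StrategySpec:
    """A treatment strategy: PFS model, drug schedule, SAE burden, PAP cap."""

    name: str
    pfs_model: WeibullPFS
    induction_cost_per_cycle: float = 0.0
    induction_cycles: int = 0
    continuation_cost_per_cycle: float = 0.0
    continuous_treatment: bool = False  # treated during every PFS cycle?
    sae_prob: float = 0.0
    requires_egfr_test: bool = False
    pap_cap: float | None = None

    def __post_init__(self) -> None:
        if min(self.induction_cost_per_cycle, self.continuation_cost_per_cycle) < 0:
            raise ConfigurationError(f"{self.name}: drug costs must be non-negative")
        if self.induction_cycles < 0:
            raise ConfigurationError(f"{self.name}: induction_cycles must be >= 0")
        if self.pap_cap is not None and self.pap_cap <= 0:
            raise ConfigurationError(f"{self.name}: PAP cap must be positive")

    def on_treatment(self, cycle: int) -> bool:
        """Whether a patient still in PFS receives treatment during ``cycle``."""
        return self.continuous_treatment or cycle <= self.induction_cycles

    def drug_cost(self, cycle: int) -> float:
        """Per-patient drug cost billed in ``cycle`` (1-based), before PAP caps."""
        if cycle <= self.induction_cycles:
            return self.induction_cost_per_cycle
        if self.continuous_treatment:
            return self.continuation_cost_per_cycle
        return 0.0


def pemetrexed_vials(bsa: float) -> int:
    """Whole 500-mg vials needed for one 500 mg/m^2 dose (vial-based billing)."""
    return int(math.ceil(PEMETREXED_DOSE_PER_M2 * bsa / PEMETREXED_VIAL_MG))


def build_strategies(
    reg: ParameterRegistry,
    nma_result=None,
    pap: bool = False,
    cfg: ModelConfig | None = None,
) -> dict[str, StrategySpec]:
    """The four competing first-line strategies.

    Hazard ratios come from the registry's pooled values by default; passing
    an :class:`~cea_nsclc.nma.NMAResult` re-derives them from the evidence
    network instead (node names: pemetrexed_maintenance, gefitinib, icotinib).
    ``pap`` attaches the assistance-program drug-cost caps to both TKI
    strategies.
    """
    cfg = cfg or ModelConfig()
    base = WeibullPFS(
        lam=reg.base("weibull_scale"),
        gamma=reg.base("weibull_shape"),
        time_unit=cfg.weibull_time_unit,
    )
    if nma_result is not None:
        hr_maint = nma_result.hr("pemetrexed_maintenance")
        hr_gef = nma_result.hr("gefitinib")
        hr_ico = nma_result.hr("icotinib")
    else:
        hr_maint = reg.base("hr_maintenance")
        hr_gef = reg.base("hr_gefitinib")
        hr_ico = reg.base("hr_icotinib")

    vials = pemetrexed_vials(reg.base("body_surface_area"))
    pem_cycle = vials * reg.base("cost_pemetrexed_500mg")
    induction = pem_cycle + reg.base("cost_chemo_backbone_per_cycle")
    gef_cycle = reg.base("cost_gefitinib_per_day") * cfg.cycle_days
    ico_cycle = reg.base("cost_icotinib_per_day") * cfg.cycle_days

    return {
        "control": StrategySpec(
            name="control",
            pfs_model=base,
            induction_cost_per_cycle=induction,
            induction_cycles=INDUCTION_CYCLES,
            sae_prob=reg.base("prob_sae_control"),
        ),
        "maintenance": StrategySpec(
            name="maintenance",
            pfs_model=apply_hazard_ratio(base, hr_maint),
            induction_cost_per_cycle=induction,
            induction_cycles=INDUCTION_CYCLES,
            continuation_cost_per_cycle=pem_cycle,
            continuous_treatment=True,
            sae_prob=reg.base("prob_sae_maintenance"),
        ),
        "gefitinib": StrategySpec(
            name="gefitinib",
            pfs_model=apply_hazard_ratio(base, hr_gef),
            continuation_cost_per_cycle=gef_cycle,
            continuous_treatment=True,
            sae_prob=reg.base("prob_sae_gefitinib"),
            requires_egfr_test=True,
            pap_cap=reg.base("pap_cap_gefitinib") if pap else None,
        ),
        "icotinib": StrategySpec(
            name="icotinib",
            pfs_model=apply_hazard_ratio(base, hr_ico),
            continuation_cost_per_cycle=ico_cycle,
            continuous_treatment=True,
            sae_prob=reg.base("prob_sae_icotinib"),
            requires_egfr_test=True,
            pap_cap=reg.base("pap_cap_icotinib") if pap else None,
        ),
    }


def sae_cost_per_cycle(reg: ParameterRegistry, strategy: StrategySpec) -> float:
    """Per-cycle SAE management cost, scaled by the strategy's SAE burden.

    cost_sae_unit * sae_prob(strategy) / sae_prob(control); the unit cost is
    anchored to the control strategy, whose ratio is 1.
    """
    control = reg.base("prob_sae_control")
    if control <= 0:
        raise ConfigurationError("control-strategy SAE probability must be positive")
    return reg.base("cost_sae_unit") * strategy.sae_prob / control


def pap_drug_cost_schedule(strategy: StrategySpec, n_cycles: int) -> np.ndarray:
    """Per-patient drug cost billed in cycles 1..n, with any PAP cap applied.

    Under the assistance program a patient pays full price until the
    cumulative drug cost reaches the cap (a partial payment in the crossing
    cycle) and receives the drug free thereafter until progression.
    """
    raw = np.array([strategy.drug_cost(t) for t in range(1, n_cycles + 1)])
    if strategy.pap_cap is None:
        return raw
    cum_before = np.concatenate([[0.0], np.cumsum(raw)[:-1]])
    return np.clip(strategy.pap_cap - cum_before, 0.0, raw)


def apply_pap_cap(strategy: StrategySpec, drug_costs: np.ndarray) -> np.ndarray:
    """Truncate a per-cycle drug-cost stream at the strategy's PAP cap."""
    if strategy.pap_cap is None:
        return np.asarray(drug_costs, dtype=float)
    if strategy.pap_cap <= 0:
        raise ConfigurationError("PAP cap must be positive")
    raw = np.asarray(drug_costs, dtype=float)
    cum_before = np.concatenate([[0.0], np.cumsum(raw)[:-1]])
    return np.clip(strategy.pap_cap - cum_before, 0.0, raw)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and accrual record."""

    frame: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class CEAResult:
    """Per-strategy totals: discounted cost and QALYs, undiscounted LYs."""

    strategy: str
    cost: float
    pf_lys: float
    overall_lys: float
    qalys: float
    cost_undiscounted: float = 0.0
    qalys_undiscounted: float = 0.0
    lys_discounted: float = 0.0

    def __post_init__(self) -> None:
        if self.qalys > self.overall_lys + 1e-9:
            raise ValueError(f"{self.strategy}: QALYs exceed overall LYs")
        if self.pf_lys > self.overall_lys + 1e-9:
            raise ValueError(f"{self.strategy}: PF LYs exceed overall LYs")


def _check_prob(name: str, p: float) -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} = {p} is outside [0, 1]")
    return p


def run_cohort(
    strategy: StrategySpec,
    reg: ParameterRegistry,
    cfg: ModelConfig | None = None,
) -> tuple[CohortTrace, CEAResult]:
    """Simulate one strategy's cohort over the model horizon.

    Occupancy is tracked at cycle start; transitions happen at cycle end.
    PPS patients are binned by cycles since progression so that salvage
    chemotherapy (for the uptake fraction, during the first
    ``salvage_max_cycles`` post-progression cycles) and supportive care can
    be costed separately.  Terminal care is a one-off cost at death; the
    EGFR-test cost, amortised over mutation prevalence, is a one-off at
    model start for gene-guided strategies.
    """
    cfg = cfg or ModelConfig()
    n = cfg.n_cycles
    p_death = _check_prob("prob_death_post_progression", reg.base("prob_death_post_progression"))
    u_pfs = reg.base("utility_pfs")
    u_pps = reg.base("utility_pps")
    du_sae = reg.base("disutility_sae")
    salvage_uptake = _check_prob("salvage_uptake", reg.base("salvage_uptake"))
    c_salvage = reg.base("cost_salvage_per_cycle")
    c_support = reg.base("cost_supportive_per_cycle")
    c_followup = reg.base("cost_followup_per_unit") * cfg.followup_cost_scale
    c_terminal = reg.base("cost_terminal_care")
    c_sae = sae_cost_per_cycle(reg, strategy)
    drug = pap_drug_cost_schedule(strategy, n)

    # Care cost per progressor-cycle during the salvage phase (the uptake
    # fraction receives salvage chemotherapy, the rest supportive care) and
    # afterwards (supportive care for everyone).
    c_salvage_phase = salvage_uptake * c_salvage + (1.0 - salvage_uptake) * c_support
    k_salvage = cfg.salvage_max_cycles

    pfs = 1.0
    # PPS cohort binned by cycles since progression: salvage-phase bins of
    # age 1..k_salvage plus a single "older" bucket.
    pps_young = [0.0] * (k_salvage + 1)  # index a = cycles since progression
    pps_old = 0.0
    dead = 0.0

    test_cost = 0.0
    if strategy.requires_egfr_test:
        prevalence = reg.base("egfr_prevalence")
        if prevalence <= 0:
            raise ConfigurationError("egfr_prevalence must be positive")
        test_cost = reg.base("cost_egfr_test") / prevalence

    rows = []
    cost_d = test_cost  # one-off, cycle 0, discount factor 1
    cost_u = test_cost
    qaly_d = qaly_u = 0.0
    pf_ly_u = ly_u = ly_d = 0.0

    for t in range(1, n + 1):
        p_prog = _check_prob(
            f"{strategy.name} progression probability at cycle {t}",
            cycle_transition_prob(strategy.pfs_model, t),
        )
        young_total = sum(pps_young)
        pps_total = young_total + pps_old

        # end-of-cycle transitions (needed up front for half-cycle averaging)
        progressed = pfs * p_prog
        pps_deaths = pps_total * p_death
        pfs_end = pfs - progressed
        pps_end = pps_total - pps_deaths + progressed

        if cfg.half_cycle_correction:
            pfs_eff = 0.5 * (pfs + pfs_end)
            pps_eff = 0.5 * (pps_total + pps_end)
            # per-bin membership averaged over the cycle: survivors count
            # (1 - p_death/2), the newly progressed count half a cycle at
            # the salvage-phase rate
            hcc = 1.0 - 0.5 * p_death
            care_cost = (
                c_salvage_phase * (young_total * hcc + 0.5 * progressed)
                + c_support * pps_old * hcc
            )
        else:
            pfs_eff, pps_eff = pfs, pps_total
            care_cost = c_salvage_phase * young_total + c_support * pps_old

        on_trt = strategy.on_treatment(t)
        if cfg.sae_disutility_mode == "all_pfs":
            sae_du_applies = True
        elif cfg.sae_disutility_mode == "induction_only":
            sae_du_applies = t <= max(strategy.induction_cycles, 1)
        else:  # on_treatment
            sae_du_applies = on_trt

        cycle_cost = (
            drug[t - 1] * pfs_eff
            + (c_sae * pfs_eff if on_trt else 0.0)
            + c_followup * (pfs_eff + pps_eff)
            + care_cost
            + c_terminal * pps_deaths
        )
        u_pfs_eff = u_pfs - (du_sae * strategy.sae_prob if sae_du_applies else 0.0)
        cycle_qaly = (u_pfs_eff * pfs_eff + u_pps * pps_eff) * cfg.cycle_years
        cycle_ly = (pfs_eff + pps_eff) * cfg.cycle_years

        disc = discount_factor(cfg, t - 1)
        cost_u += cycle_cost
        cost_d += cycle_cost * disc
        qaly_u += cycle_qaly
        qaly_d += cycle_qaly * disc
        pf_ly_u += pfs_eff * cfg.cycle_years
        ly_u += cycle_ly
        ly_d += cycle_ly * disc

        rows.append(
            {
                "cycle": t,
                "pfs": pfs,
                "post_progression": pps_total,
                "dead": dead,
                "cost": cycle_cost,
                "cost_discounted": cycle_cost * disc,
                "qaly": cycle_qaly,
                "qaly_discounted": cycle_qaly * disc,
                "ly": cycle_ly,
                "ly_discounted": cycle_ly * disc,
            }
        )

        # advance state: age the PPS bins, admit the newly progressed
        surv = 1.0 - p_death
        pps_old = (pps_old + pps_young[k_salvage]) * surv if k_salvage > 0 else (
            pps_old * surv + progressed
        )
        for a in range(k_salvage, 1, -1):
            pps_young[a] = pps_young[a - 1] * surv
        if k_salvage > 0:
            pps_young[1] = progressed
        pfs = pfs_end
        dead += pps_deaths

        total = pfs + sum(pps_young) + pps_old + dead
        if abs(total - 1.0) > 1e-12:
            raise AssertionError(f"occupancy leak at cycle {t}: sum = {total!r}")

    trace = CohortTrace(frame=pd.DataFrame(rows))
    result = CEAResult(
        strategy=strategy.name,
        cost=cost_d,
        pf_lys=pf_ly_u,
        overall_lys=ly_u,
        qalys=qaly_d,
        cost_undiscounted=cost_u,
        qalys_undiscounted=qaly_u,
        lys_discounted=ly_d,
    )
    return trace, result


def run_base_case(
    reg: ParameterRegistry,
    cfg: ModelConfig | None = None,
    pap: bool = False,
    nma_result=None,
) -> dict[str, CEAResult]:
    """Run all four strategies on base-case parameters."""
    cfg = cfg or ModelConfig()
    strategies = build_strategies(reg, nma_result=nma_result, pap=pap, cfg=cfg)
    return {name: run_cohort(s, reg, cfg)[1] for name, s in strategies.items()}
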