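"""Markov cohort engine: strategies, discounting, accrual, PAP caps."""

import math

import numpy as np
import pytest

from cea_nsclc.markov import (
    CEAResult,
    ModelConfig,
    StrategySpec,
    build_strategies,
    discount_factor,
    pap_drug_cost_schedule,
    apply_pap_cap,
    pemetrexed_vials,
    run_cohort,
    sae_cost_per_cycle,
)
from cea_nsclc.params import ConfigurationError
from cea_nsclc.survival import WeibullPFS, cycle_transition_prob

COST_NAMES = [
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
]


class TestStrategies:
    def test_pemetrexed_vial_rounding(self):
        assert pemetrexed_vials(1.72) == 2  # 860 mg -> two 500 mg vials
        assert pemetrexed_vials(1.0) == 1
        assert pemetrexed_vials(2.3) == 3

    def test_drug_costs_per_cycle(self, reg, cfg):
        s = build_strategies(reg, cfg=cfg)
        assert s["control"].induction_cost_per_cycle == pytest.approx(2 * 967.57 + 518.4)
        assert s["maintenance"].continuation_cost_per_cycle == pytest.approx(2 * 967.57)
        assert s["gefitinib"].continuation_cost_per_cycle == pytest.approx(786.03)
        assert s["icotinib"].continuation_cost_per_cycle == pytest.approx(666.12)

    def test_hazard_ratios_applied_to_scale(self, reg, cfg):
        s = build_strategies(reg, cfg=cfg)
        lam0 = s["control"].pfs_model.lam
        assert s["icotinib"].pfs_model.lam == pytest.approx(0.40 * lam0)
        assert s["gefitinib"].pfs_model.lam == pytest.approx(0.48 * lam0)
        assert s["maintenance"].pfs_model.lam == pytest.approx(0.59 * lam0)

    def test_pap_caps_attached_only_when_requested(self, reg, cfg):
        plain = build_strategies(reg, pap=False, cfg=cfg)
        capped = build_strategies(reg, pap=True, cfg=cfg)
        assert plain["icotinib"].pap_cap is None
        assert capped["icotinib"].pap_cap == pytest.approx(11077.0)
        assert capped["gefitinib"].pap_cap == pytest.approx(11538.0)
        assert capped["control"].pap_cap is None

    def test_invalid_specs_rejected(self, reg, cfg):
        model = build_strategies(reg, cfg=cfg)["control"].pfs_model
        with pytest.raises(ConfigurationError):
            StrategySpec(name="x", pfs_model=model, induction_cost_per_cycle=-1.0)
        with pytest.raises(ConfigurationError):
            StrategySpec(name="x", pfs_model=model, pap_cap=0.0)


class TestDiscounting:
    def test_cycle_zero_undiscounted(self, cfg):
        assert discount_factor(cfg, 0) == 1.0

    def test_horizon_end_closed_form(self, cfg):
        expected = 1.05 ** (-173 * 21 / 365)  # ~= 0.615 after ~9.95 years
        assert discount_factor(cfg, 173) == pytest.approx(expected, rel=1e-12)
        assert discount_factor(cfg, 173) == pytest.approx(0.615, abs=1e-3)

    def test_strictly_decreasing(self, cfg):
        factors = [discount_factor(cfg, t) for t in range(0, 174)]
        assert np.all(np.diff(factors) < 0)

    def test_negative_cycle_rejected(self, cfg):
        with pytest.raises(ValueError):
            discount_factor(cfg, -1)


class TestSAECost:
    def test_control_self_ratio(self, reg, cfg):
        control = build_strategies(reg, cfg=cfg)["control"]
        assert sae_cost_per_cycle(reg, control) == pytest.approx(507.4)

    def test_scaling_by_sae_burden(self, reg, cfg):
        s = build_strategies(reg, cfg=cfg)
        assert sae_cost_per_cycle(reg, s["icotinib"]) == pytest.approx(
            507.4 * 0.07 / 0.456
        )
        assert sae_cost_per_cycle(reg, s["maintenance"]) == pytest.approx(
            507.4 * 0.637 / 0.456
        )

    def test_zero_control_probability_rejected(self, reg, cfg):
        bad = reg.with_value("prob_sae_control", 0.0)
        strategy = build_strategies(reg, cfg=cfg)["icotinib"]
        with pytest.raises(ConfigurationError):
            sae_cost_per_cycle(bad, strategy)


class TestPAPCap:
    def test_icotinib_payment_schedule(self, reg, cfg):
        s = build_strategies(reg, pap=True, cfg=cfg)["icotinib"]
        sched = pap_drug_cost_schedule(s, 25)
        # full price through cycle 16, the remainder in cycle 17, free after
        assert np.allclose(sched[:16], 666.12)
        assert sched[16] == pytest.approx(11077.0 - 16 * 666.12)
        assert np.all(sched[17:] == 0.0)
        assert sched.sum() == pytest.approx(11077.0)

    def test_no_cap_is_identity(self, reg, cfg):
        s = build_strategies(reg, pap=False, cfg=cfg)["icotinib"]
        raw = np.full(30, 666.12)
        np.testing.assert_array_equal(apply_pap_cap(s, raw), raw)

    def test_pap_run_never_costs_more(self, reg, cfg):
        plain = build_strategies(reg, pap=False, cfg=cfg)
        capped = build_strategies(reg, pap=True, cfg=cfg)
        for name in ("gefitinib", "icotinib"):
            r_plain = run_cohort(plain[name], reg, cfg)[1]
            r_cap = run_cohort(capped[name], reg, cfg)[1]
            assert r_cap.cost <= r_plain.cost
            assert r_cap.qalys == pytest.approx(r_plain.qalys, rel=1e-12)


class TestCohortDynamics:
    def test_occupancy_conserved_and_monotone(self, reg, cfg):
        for name, s in build_strategies(reg, cfg=cfg).items():
            trace = run_cohort(s, reg, cfg)[0].frame
            total = trace.pfs + trace.post_progression + trace.dead
            np.testing.assert_allclose(total, 1.0, atol=1e-12)
            assert np.all(np.diff(trace.pfs) <= 1e-15), name
            assert np.all(np.diff(trace.dead) >= -1e-15), name

    def test_life_years_partition(self, reg):
        cfg = ModelConfig(half_cycle_correction=False)
        s = build_strategies(reg, cfg=cfg)["control"]
        trace, res = run_cohort(s, reg, cfg)
        cy = cfg.cycle_years
        pf = trace.frame.pfs.sum() * cy
        pps = trace.frame.post_progression.sum() * cy
        assert res.pf_lys == pytest.approx(pf, abs=1e-9)
        assert res.overall_lys == pytest.approx(pf + pps, abs=1e-9)

    def test_discounting_shrinks_life_years(self, reg, cfg):
        res = run_cohort(build_strategies(reg, cfg=cfg)["control"], reg, cfg)[1]
        assert res.lys_discounted < res.overall_lys

    def test_zero_costs_and_utilities_linearity(self, reg, cfg):
        zeroed = reg.with_values({n: 0.0 for n in COST_NAMES})
        zeroed = zeroed.with_values(
            {"utility_pfs": 0.0, "utility_pps": 0.0, "disutility_sae": 0.0}
        )
        base = run_cohort(build_strategies(reg, cfg=cfg)["control"], reg, cfg)[1]
        res = run_cohort(build_strategies(zeroed, cfg=cfg)["control"], zeroed, cfg)[1]
        assert res.cost == 0.0
        assert res.qalys == 0.0
        assert res.overall_lys == pytest.approx(base.overall_lys, rel=1e-12)

    def test_null_hazard_ratio_preserves_survival(self, reg, cfg):
        """A TKI with HR 1 and the control's SAE burden yields identical
        health outcomes; only drug/test cost terms differ."""
        strategies = build_strategies(reg, cfg=cfg)
        control = strategies["control"]
        null_tki = StrategySpec(
            name="null_tki",
            pfs_model=control.pfs_model,
            continuation_cost_per_cycle=666.12,
            continuous_treatment=True,
            sae_prob=control.sae_prob,
            requires_egfr_test=True,
        )
        r_control = run_cohort(control, reg, cfg)[1]
        r_null = run_cohort(null_tki, reg, cfg)[1]
        assert r_null.overall_lys == pytest.approx(r_control.overall_lys, rel=1e-12)
        assert r_null.pf_lys == pytest.approx(r_control.pf_lys, rel=1e-12)
        assert r_null.qalys == pytest.approx(r_control.qalys, rel=1e-12)
        assert r_null.cost != pytest.approx(r_control.cost)

    @pytest.mark.parametrize("mode", ["with_hcc", "without_hcc"])
    def test_lower_hazard_ratio_weakly_improves_outcomes(self, reg, mode):
        cfg = ModelConfig(half_cycle_correction=(mode == "with_hcc"))
        results = []
        for hr in (1.0, 0.6, 0.3):
            r = run_cohort(
                build_strategies(reg.with_value("hr_icotinib", hr), cfg=cfg)["icotinib"],
                reg,
                cfg,
            )[1]
            results.append(r)
        for worse, better in zip(results, results[1:]):
            assert better.pf_lys >= worse.pf_lys
            assert better.qalys >= worse.qalys

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            CEAResult(strategy="x", cost=0.0, pf_lys=2.0, overall_lys=1.0, qalys=0.5)


class TestHandUnrolledOracle:
    def test_five_cycle_accruals_match_spreadsheet(self, reg):
        """Independent spreadsheet-style unrolling of 5 cycles (no half-cycle
        correction, 2 salvage cycles) reproduces the engine to 1e-9."""
        cfg = ModelConfig(
            horizon_years=5 * 21 / 365.0,
            half_cycle_correction=False,
            salvage_max_cycles=2,
            followup_per="cycle",
            sae_disutility_mode="on_treatment",
        )
        assert cfg.n_cycles == 5
        strategy = build_strategies(reg, cfg=cfg)["control"]
        trace, res = run_cohort(strategy, reg, cfg)

        lam, gam = 0.1029, 1.3077
        p_death, uptake = 0.086, 0.566
        u_pfs, u_pps, du = 0.82, 0.58, 0.35
        c_drug = 2 * 967.57 + 518.4
        c_sae, c_fu = 507.4, 55.6
        c_salv, c_sup, c_term = 2352.7, 337.5, 2042.91
        salvage_rate = uptake * c_salv + (1 - uptake) * c_sup
        cy = 21 / 365.0

        pfs, y1, y2, old = 1.0, 0.0, 0.0, 0.0  # y_a: progressed a cycles ago
        cost = qaly = 0.0
        for t in range(1, 6):
            p = 1 - math.exp(lam * (t - 1) ** gam - lam * t**gam)
            disc = 1.05 ** (-(t - 1) * cy)
            pps = y1 + y2 + old
            deaths = pps * p_death
            cost_t = (
                pfs * (c_drug + c_sae) * (t <= 4)
                + c_fu * (pfs + pps)
                + salvage_rate * (y1 + y2)
                + c_sup * old
                + c_term * deaths
            )
            qaly_t = (pfs * (u_pfs - du * 0.456 * (t <= 4)) + pps * u_pps) * cy
            cost += cost_t * disc
            qaly += qaly_t * disc
            old = (old + y2) * (1 - p_death)
            y2 = y1 * (1 - p_death)
            y1 = pfs * p  # progression happens at cycle end
            pfs *= 1 - p

        assert res.cost == pytest.approx(cost, abs=1e-9)
        assert res.qalys == pytest.approx(qaly, abs=1e-9)
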