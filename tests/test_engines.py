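"""Trial-engine tests: scripted conduct paths, safety invariants, and
degenerate scenarios with forced outcomes."""

import numpy as np
import pytest

from titedose import (
    DESIGNS,
    OutcomeDraw,
    Scenario,
    TrialConfig,
    fit_logistic_mtd,
    run_three_plus_three,
    run_tite_ir,
    run_trial,
    simulate_ocs,
    tite_next_dose,
)
from titedose.estimation import PatientRecord

ALL_SAFE = Scenario(name="safe", true_probs=(0.0,) * 6)
ALL_TOXIC = Scenario(name="toxic", true_probs=(1.0,) * 6)


def scripted(outcomes):
    """Outcome hook replaying a fixed per-patient sequence of
    (toxicity, toxicity_time) pairs."""
    queue = list(outcomes)

    def hook(dose_index, rng):
        tox, t = queue.pop(0)
        return OutcomeDraw(toxicity=tox, toxicity_time=t)

    return hook


def cohort3(config=None, **kwargs):
    base = dict(cohort_size=3)
    base.update(kwargs)
    return TrialConfig(**base)


# ---------------------------------------------------------------------------
# 3+3 state machine on scripted outcomes


class TestThreePlusThree:
    def test_zero_toxicities_escalates(self):
        cfg = cohort3(n_max=6)
        res = run_three_plus_three(
            ALL_SAFE, cfg, 0, outcome_hook=scripted([(0, None)] * 6)
        )
        doses = [p.dose_index for p in res.roster]
        assert doses == [1, 1, 1, 2, 2, 2]

    def test_two_toxicities_at_dose_one_declares_dose_one(self):
        cfg = cohort3()
        res = run_three_plus_three(
            ALL_TOXIC, cfg, 0,
            outcome_hook=scripted([(1, 1.0), (1, 2.0), (0, None)]),
        )
        assert res.mtd_index == 1
        assert res.n_enrolled == 3

    def test_expansion_then_toxicity_declares_previous_dose(self):
        """1/3 at dose 3, expansion cohort with a toxicity -> dose 2."""
        cfg = cohort3()
        outcomes = (
            [(0, None)] * 6            # doses 1, 2 clean
            + [(1, 1.0), (0, None), (0, None)]   # dose 3: one toxicity
            + [(0, None), (1, 2.0), (0, None)]   # expansion at dose 3: toxic
        )
        res = run_three_plus_three(ALL_SAFE, cfg, 0, outcome_hook=scripted(outcomes))
        assert res.mtd_index == 2
        assert res.n_enrolled == 12

    def test_expansion_clean_escalates(self):
        cfg = cohort3()
        outcomes = (
            [(1, 1.0), (0, None), (0, None)]  # dose 1: 1/3 -> expansion
            + [(0, None)] * 3                 # expansion clean -> escalate
            + [(1, 1.0), (1, 2.0), (0, None)] # dose 2: >1 -> declare dose 1
        )
        res = run_three_plus_three(ALL_SAFE, cfg, 0, outcome_hook=scripted(outcomes))
        doses = [p.dose_index for p in res.roster]
        assert doses == [1] * 6 + [2] * 3
        assert res.mtd_index == 1

    def test_top_dose_escalation_declares_top_dose(self):
        cfg = cohort3()
        res = run_three_plus_three(
            ALL_SAFE, cfg, 0, outcome_hook=scripted([(0, None)] * 18)
        )
        assert res.mtd_index == 6
        assert res.n_enrolled == 18

    def test_terminal_expansion_past_cap(self):
        """1/3 at the cap buys one expansion cohort (n_max + 3)."""
        cfg = cohort3(n_max=6)
        outcomes = (
            [(0, None)] * 3                      # dose 1 clean
            + [(1, 1.0), (0, None), (0, None)]   # dose 2 at the cap: 1/3
            + [(0, None)] * 3                    # terminal expansion clean
        )
        res = run_three_plus_three(ALL_SAFE, cfg, 0, outcome_hook=scripted(outcomes))
        assert res.n_enrolled == 9  # n_max + 3
        assert res.mtd_index == 2

    def test_sample_size_multiple_of_three_capped(self, scenarios):
        cfg = cohort3()
        for seed in range(40):
            res = run_three_plus_three(scenarios[1], cfg, seed)
            assert res.n_enrolled % 3 == 0
            assert res.n_enrolled <= cfg.n_max + 3


# ---------------------------------------------------------------------------
# up-and-down design D


class TestUpDown:
    def test_moves(self):
        """0 toxicities escalates, >1 de-escalates."""
        cfg = cohort3(n_max=9)
        outcomes = (
            [(0, None)] * 3                      # dose 1 -> escalate
            + [(1, 1.0), (1, 2.0), (0, None)]    # dose 2 -> de-escalate
            + [(1, 1.0), (0, None), (0, None)]   # dose 1 -> repeat
        )
        res = run_trial("UD", ALL_SAFE, cfg, 0, outcome_hook=scripted(outcomes))
        doses = [p.dose_index for p in res.roster]
        assert doses == [1, 1, 1, 2, 2, 2, 1, 1, 1]
        assert res.n_enrolled == 9

    def test_enrolls_exactly_n_max(self, scenarios, config):
        for seed in range(10):
            res = run_trial("UD", scenarios[4], config, seed)
            assert res.n_enrolled == config.n_max


class TestLogisticMtd:
    @staticmethod
    def _roster(dose_tox_pairs):
        return [
            PatientRecord(index=i + 1, arrival_time=0.0, dose_index=d,
                          toxicity=t, toxicity_time=3.0 if t else None, followup=6.0)
            for i, (d, t) in enumerate(dose_tox_pairs)
        ]

    def test_all_nontoxic_falls_back_to_top_dose(self, config):
        roster = self._roster([(d, 0) for d in (1, 2, 3, 4, 5, 6) for _ in range(4)])
        decision = fit_logistic_mtd(roster, config)
        assert decision.dose_index == 6 and not decision.constrained

    def test_all_toxic_falls_back_to_dose_one_constrained(self, config):
        roster = self._roster([(d, 1) for d in (1, 2, 3) for _ in range(8)])
        decision = fit_logistic_mtd(roster, config)
        assert decision.dose_index == 1 and decision.constrained

    def test_positive_slope_mtd_matches_statsmodels(self, config):
        """On an identifiable dataset the declared MTD equals the one
        implied by an independent statsmodels fit of the same model."""
        import statsmodels.api as sm

        pairs = [(1, 0), (1, 0), (1, 0), (2, 1), (2, 0), (2, 0),
                 (3, 1), (3, 1), (3, 0), (4, 1), (4, 1), (4, 1)]
        decision = fit_logistic_mtd(self._roster(pairs), config)
        levels = np.asarray(config.dose_levels)
        X = sm.add_constant([config.dose_levels[d - 1] for d, _ in pairs])
        ref = sm.Logit([t for _, t in pairs], X).fit(disp=0)
        fitted = 1 / (1 + np.exp(-(ref.params[0] + ref.params[1] * levels)))
        acceptable = np.flatnonzero(fitted <= config.target)
        expected = int(acceptable[-1]) + 1 if acceptable.size else 1
        assert ref.params[1] > 0
        assert decision.dose_index == expected

    def test_quasi_separated_data_uses_fallback(self, config):
        """Toxicities 0/3, 1/3, 3/3 over three doses: the logistic MLE
        diverges, so the isotonic proportions (0, 1/3, 1) decide and the
        1/3 dose is the highest at or below the target."""
        pairs = [(1, 0), (1, 0), (1, 0), (2, 0), (2, 0), (2, 1),
                 (3, 1), (3, 1), (3, 1)]
        decision = fit_logistic_mtd(self._roster(pairs), config)
        assert decision.dose_index == 2

    def test_mle_matches_statsmodels(self, config):
        import statsmodels.api as sm

        from titedose.engines import _logistic_mle

        rng = np.random.default_rng(11)
        levels = np.array([5.0, 10.0, 15.0, 20.0, 30.0, 40.0])
        n = np.full(6, 30.0)
        y = rng.binomial(30, 1 / (1 + np.exp(-(-3.0 + 0.1 * levels)))).astype(float)
        a, b, converged = _logistic_mle(levels, n, y)
        assert converged
        X = sm.add_constant(np.repeat(levels, 30))
        obs = np.concatenate([[1] * int(yy) + [0] * int(30 - yy) for yy in y])
        ref = sm.Logit(obs, X).fit(disp=0)
        assert a == pytest.approx(ref.params[0], abs=1e-5)
        assert b == pytest.approx(ref.params[1], abs=1e-6)

    def test_negative_slope_uses_isotonic_fallback(self, config):
        """More toxicity at the low dose: the logistic slope is negative,
        so the pooled isotonic proportions decide."""
        pairs = [(1, 1), (1, 1), (1, 0), (2, 0), (2, 0), (2, 0)]
        decision = fit_logistic_mtd(self._roster(pairs), config)
        # pooled proportion 2/6 = 1/3 at both doses; tie goes high
        assert decision.dose_index == 2


# ---------------------------------------------------------------------------
# TITE conduct


class TestTiteConduct:
    def test_starts_at_lowest_dose_and_treats_on_arrival(self, scenarios, config):
        res = run_tite_ir(scenarios[0], config, 5)
        assert res.roster[0].dose_index == 1
        for p in res.roster:
            assert p.treatment_time == p.arrival_time

    def test_enrolls_exactly_n_max_duration_exact(self, scenarios, config):
        res = run_tite_ir(scenarios[3], config, 9)
        assert res.n_enrolled == config.n_max
        last_arrival = max(p.arrival_time for p in res.roster)
        assert res.duration == pytest.approx(last_arrival + config.tau, abs=1e-12)

    @pytest.mark.parametrize("scenario_idx", [0, 4, 8])
    def test_no_skipping_and_toxicity_block(self, scenarios, config, scenario_idx):
        """No patient is treated more than one level above the highest
        tried dose, and never above the previous patient's dose while
        that patient has an observed toxicity."""
        sc = scenarios[scenario_idx]
        for seed in range(25):
            roster = run_tite_ir(sc, config, seed).roster
            highest = 0
            for i, p in enumerate(roster):
                assert p.dose_index <= highest + 1
                highest = max(highest, p.dose_index)
                if i > 0:
                    prev = roster[i - 1]
                    tox_observed = (
                        prev.toxicity == 1
                        and prev.toxicity_time is not None
                        and prev.treatment_time + prev.toxicity_time <= p.arrival_time
                    )
                    if tox_observed:
                        assert p.dose_index <= prev.dose_index

    def test_audit_log_records_every_decision(self, scenarios, config):
        audit = []
        res = run_tite_ir(scenarios[0], config, 3, audit=audit)
        assert len(audit) == config.n_max
        assert [a["dose"] for a in audit] == [p.dose_index for p in res.roster]
        assert all("estimates" in a for a in audit)

    def test_escalation_needs_three_at_highest_dose(self, config):
        """With two clean, fully followed patients at the top tried dose
        the indicated escalation is withheld."""
        roster = [
            PatientRecord(index=i, arrival_time=0.0, dose_index=1,
                          toxicity=0, toxicity_time=None, followup=6.0)
            for i in (1, 2)
        ]
        decision, _ = tite_next_dose(roster, config)
        assert decision.dose_index == 1
        roster.append(PatientRecord(index=3, arrival_time=0.0, dose_index=1,
                                    toxicity=0, toxicity_time=None, followup=6.0))
        decision, _ = tite_next_dose(roster, config)
        assert decision.dose_index == 2

    def test_monotone_safety_in_offset(self, config):
        """Raising the conservatism offset does not increase the number
        of patients treated above the MTD in a toxic scenario."""
        toxic = Scenario(name="5", true_probs=(0.20, 0.90, 0.90, 0.90, 0.90, 0.90))
        above = {}
        for f_star in (0.05, 0.5):
            cfg = TrialConfig(f_star=f_star)
            oc = simulate_ocs("TITE-IR", toxic, cfg, 2000, seed=99)
            above[f_star] = oc.alloc_above
        assert above[0.5] <= above[0.05]


# ---------------------------------------------------------------------------
# cross-design properties


class TestDegenerateScenarios:
    @pytest.mark.parametrize("design", DESIGNS)
    def test_all_toxic_forces_lowest_dose(self, design, config):
        for seed in range(20):
            res = run_trial(design, ALL_TOXIC, config, seed)
            assert res.mtd_index == 1

    @pytest.mark.parametrize("design", ["3+3", "UD", "IR-A", "IR-B"])
    def test_all_safe_forces_top_dose(self, design, config):
        for seed in range(20):
            res = run_trial(design, ALL_SAFE, config, seed)
            assert res.mtd_index == 6
            assert res.n_toxicities == 0

    def test_all_safe_tite_reaches_top_dose(self, config):
        """The time-to-event design declares the top dose in the large
        majority of trials at the default accrual; the residue are
        fast-accruing trials that end before the staged climb (three
        patients per level plus follow-up) can try dose 6.  With slower
        accrual the climb always completes."""
        picks = [run_trial("TITE-IR", ALL_SAFE, config, s).mtd_index for s in range(200)]
        assert np.mean(np.asarray(picks) == 6) >= 0.75
        assert min(picks) >= 4
        slow = TrialConfig(accrual_rate=1.0)
        assert all(
            run_trial("TITE-IR", ALL_SAFE, slow, s).mtd_index == 6 for s in range(50)
        )


class TestDeterminismAndErrors:
    @pytest.mark.parametrize("design", DESIGNS)
    def test_identical_seed_identical_result(self, design, scenarios, config):
        a = run_trial(design, scenarios[1], config, 123)
        b = run_trial(design, scenarios[1], config, 123)
        assert a == b

    def test_unknown_design(self, scenarios, config):
        with pytest.raises(ValueError):
            run_trial("CRM", scenarios[0], config, 0)

    def test_cohort_size_enforced(self, scenarios):
        with pytest.raises(ValueError):
            run_tite_ir(scenarios[0], TrialConfig(cohort_size=3), 0)
        with pytest.raises(ValueError):
            run_three_plus_three(scenarios[0], TrialConfig(cohort_size=1), 0)

    def test_allocation_partition(self, scenarios, config):
        for design in DESIGNS:
            res = run_trial(design, scenarios[0], config, 7)
            assert sum(res.allocation) == res.n_enrolled

    def test_result_serializes_to_json(self, scenarios, config):
        import json

        payload = json.loads(run_trial("3+3", scenarios[0], config, 1).to_json())
        assert payload["design"] == "3+3"
        assert len(payload["roster"]) == payload["n_enrolled"]
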