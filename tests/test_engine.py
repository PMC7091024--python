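"""Risk scoring, classification, trigger selection, message routing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quitsense import (
    DeliveryHistory,
    EmaResponse,
    EngagementEvent,
    EventLog,
    Message,
    MessageBank,
    RiskConfig,
    classify_risk,
    compute_risk_score,
    decide_responses,
    deliver_message,
    initial_state,
    select_trigger,
    update_state,
)
from quitsense.engine import TRIGGERS, classify_values, risk_score_values
from quitsense.errors import BankError, QuitsenseError

from conftest import make_response

WEIGHT_NAMES = ("w_urge", "w_stress", "w_alcohol", "w_interaction", "w_motivation", "w_availability")


def response(**kw):
    return EmaResponse(**make_response(**kw))


class TestRiskScore:
    def test_minimum_point_scores_zero(self, risk_config):
        assert compute_risk_score(response(), risk_config) == 0.0

    def test_maximum_point_scores_one(self, risk_config):
        resp = response(
            urge=5, stress=5, cigarette_availability=5, motivation_to_avoid=5,
            interacting_with_smoker=True, alcohol_last_hour=True,
        )
        assert compute_risk_score(resp, risk_config) == pytest.approx(1.0)

    def test_hand_computed_weighted_sum(self, risk_config):
        # .25*1 + .15*.5 + 0 + .15*1 + .15*.25 + .25*.75 = 0.70
        resp = response(
            urge=5, stress=3, cigarette_availability=4, motivation_to_avoid=2,
            interacting_with_smoker=True, alcohol_last_hour=False,
        )
        assert compute_risk_score(resp, risk_config) == pytest.approx(0.70)

    def test_weights_are_normalized(self):
        cfg = RiskConfig(w_urge=2, w_stress=2, w_alcohol=2, w_interaction=2, w_motivation=2, w_availability=2)
        assert sum(getattr(cfg, w) for w in WEIGHT_NAMES) == pytest.approx(1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            RiskConfig(w_urge=-0.1)

    @given(
        urge=st.integers(1, 5), stress=st.integers(1, 5), avail=st.integers(1, 5),
        mot=st.integers(1, 5), smoker=st.booleans(), alcohol=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_every_factor(self, risk_config, urge, stress, avail, mot, smoker, alcohol):
        base = risk_score_values(urge, stress, avail, mot, smoker, alcohol, risk_config)
        raised = [
            risk_score_values(min(urge + 1, 5), stress, avail, mot, smoker, alcohol, risk_config),
            risk_score_values(urge, min(stress + 1, 5), avail, mot, smoker, alcohol, risk_config),
            risk_score_values(urge, stress, min(avail + 1, 5), mot, smoker, alcohol, risk_config),
            risk_score_values(urge, stress, avail, min(mot + 1, 5), smoker, alcohol, risk_config),
            risk_score_values(urge, stress, avail, mot, True, alcohol, risk_config),
            risk_score_values(urge, stress, avail, mot, smoker, True, risk_config),
        ]
        assert all(r >= base - 1e-12 for r in raised)


class TestClassifyRisk:
    def test_smoked_yesterday_forces_high_even_at_zero_score(self, calendar, risk_config):
        state = initial_state("smart_t2", calendar)
        state = update_state(state, response(day=9, initiation="smoking_report", kind=None), 9)
        state = update_state(state, response(day=10, completed_at=650), 10)
        assert state.smoked_yesterday
        assert classify_risk(state, response(day=10, completed_at=650), risk_config) == "high"

    def test_likelihood_exactly_at_threshold_is_low(self, calendar, risk_config):
        diary = response(
            day=10, kind="daily_diary", likelihood_smoke_today=25.0,
            gum_pieces=0, patch_category="10-12 hours", drinks=0, completed_at=485,
        )
        state = update_state(initial_state("smart_t2", calendar), diary, 10)
        assert classify_risk(state, diary, risk_config) == "low"

    def test_likelihood_strictly_above_threshold_is_high(self, calendar, risk_config):
        diary = response(
            day=10, kind="daily_diary", likelihood_smoke_today=25.1,
            gum_pieces=0, patch_category="10-12 hours", drinks=0, completed_at=485,
        )
        state = update_state(initial_state("smart_t2", calendar), diary, 10)
        assert classify_risk(state, diary, risk_config) == "high"
        # the flag persists for later same-day assessments (whole-day scope)
        later = response(day=10, completed_at=900)
        state = update_state(state, later, 10)
        assert classify_risk(state, later, risk_config) == "high"

    def test_all_minimal_is_low(self, calendar, risk_config):
        state = update_state(initial_state("smart_t2", calendar), response(day=10), 10)
        assert classify_risk(state, response(day=10), risk_config) == "low"

    def test_score_at_threshold_is_high(self, calendar):
        cfg = RiskConfig(risk_threshold=0.0)
        state = update_state(initial_state("smart_t2", calendar), response(day=10), 10)
        assert classify_risk(state, response(day=10), cfg) == "high"


class TestSelectTrigger:
    def test_highest_rated_trigger_wins(self, risk_config):
        resp = response(cigarette_availability=5, urge=3, stress=2, motivation_to_avoid=1)
        assert select_trigger(resp, risk_config.trigger_priority) == "availability"

    def test_all_equal_falls_to_priority_head(self, risk_config):
        resp = response(urge=3, stress=3, cigarette_availability=3, motivation_to_avoid=3)
        assert select_trigger(resp, risk_config.trigger_priority) == "urge"

    def test_exhaustive_grid_matches_argmax_with_priority_oracle(self, risk_config):
        priority = risk_config.trigger_priority
        for u, s, a, m in itertools.product(range(1, 6), repeat=4):
            resp = response(urge=u, stress=s, cigarette_availability=a, motivation_to_avoid=m)
            ratings = {"urge": u, "stress": s, "availability": a, "motivation": m}
            best_rating = max(ratings.values())
            oracle = next(t for t in priority if ratings[t] == best_rating)
            assert select_trigger(resp, priority) == oracle


class TestDeliverMessage:
    def _decide(self, state, resp, bank, cfg):
        return deliver_message(state, resp, bank, DeliveryHistory(), cfg)

    def test_prequit_routes_to_preparation_without_gum(self, calendar, bank, risk_config):
        resp = response(day=3, urge=5, stress=5, cigarette_availability=5, motivation_to_avoid=5)
        state = update_state(initial_state("smart_t2", calendar), resp, 3)
        decision = self._decide(state, resp, bank, risk_config)
        assert decision.message.category == "prequit_prep"
        assert not decision.gum_prompt and decision.trigger is None

    def test_postquit_high_availability_gets_tailored_message_and_gum(self, calendar, bank, risk_config):
        resp = response(day=10, urge=4, cigarette_availability=5, stress=2, motivation_to_avoid=2)
        state = update_state(initial_state("smart_t2", calendar), resp, 10)
        decision = self._decide(state, resp, bank, risk_config)
        assert decision.risk_class == "high"
        assert decision.trigger == "availability"
        assert decision.message.category == "high_risk_availability"
        assert decision.gum_prompt

    def test_postquit_low_risk_routes_to_low_risk_bank(self, calendar, bank, risk_config):
        resp = response(day=10)
        state = update_state(initial_state("smart_t2", calendar), resp, 10)
        decision = self._decide(state, resp, bank, risk_config)
        assert decision.message.category == "low_risk"
        assert not decision.gum_prompt

    def test_lapsed_and_uninterested_routes_to_recovery(self, calendar, bank, risk_config):
        report = response(
            day=10, initiation="smoking_report", kind=None, still_interested_in_quitting=False
        )
        state = update_state(initial_state("smart_t2", calendar), report, 10)
        decision = self._decide(state, report, bank, risk_config)
        assert decision.message.category == "lapse_recovery"
        assert decision.trigger is None and not decision.gum_prompt

    def test_least_recently_used_rotation(self, calendar, risk_config):
        toy = MessageBank(
            [Message("m1", "low_risk", "a"), Message("m2", "low_risk", "b")]
            + [Message(f"x{i}", c, "t") for i, c in enumerate(
                ("prequit_prep", "high_risk_urge", "high_risk_stress", "high_risk_availability",
                 "high_risk_motivation", "lapse_recovery", "daily_treatment", "gum_prompt"))]
        )
        resp = response(day=10)
        state = update_state(initial_state("smart_t2", calendar), resp, 10)
        history = DeliveryHistory()
        ids = [deliver_message(state, resp, toy, history, risk_config).message.id for _ in range(3)]
        assert ids == ["m1", "m2", "m1"]

    def test_empty_category_raises_bank_error(self, calendar, risk_config):
        empty = MessageBank([])
        resp = response(day=10)
        state = update_state(initial_state("smart_t2", calendar), resp, 10)
        with pytest.raises(BankError):
            deliver_message(state, resp, empty, DeliveryHistory(), risk_config)

    def test_one_decision_per_completed_ema(self, small_trial, bank, risk_config):
        decisions = decide_responses(small_trial.responses(), bank, risk_config, arm_filter=None)
        assert len(decisions) == len(small_trial.responses())

    def test_gum_only_in_high_risk_postquit_decisions(self, small_trial, bank, risk_config, calendar):
        decisions = decide_responses(small_trial.responses(), bank, risk_config)
        assert any(d.gum_prompt for d in decisions)
        for d in decisions:
            if d.gum_prompt:
                assert d.risk_class == "high" and d.day >= calendar.quit_day
            if d.trigger is not None:
                assert d.risk_class == "high"


class TestEventLog:
    def test_counts_by_kind(self):
        log = EventLog()
        for _ in range(3):
            log.record(EngagementEvent(participant_id="P1", kind="quit_tip_view", day=1, at=500))
        log.record(EngagementEvent(participant_id="P1", kind="app_open", day=2, at=510))
        assert log.count("quit_tip_view") == 3
        assert log.count("app_open", day=2) == 1
        assert log.count() == 4

    def test_gum_yes_fraction(self):
        log = EventLog()
        for kind in ["gum_yes"] * 13 + ["gum_no"] * 7:
            log.record(EngagementEvent(participant_id="P1", kind=kind, day=9, at=600))
        assert log.gum_yes_fraction() == pytest.approx(0.65)

    def test_empty_log_counts_zero(self):
        log = EventLog()
        assert log.count() == 0 and log.gum_yes_fraction() is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            EngagementEvent(participant_id="P1", kind="teleport", day=0, at=0)


def test_classifier_equivalence_on_random_configs_small():
    """Vectorized classifier equals a literal transcription of the rule on a
    random sub-grid (the full-grid sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(5)
    grid = rng.integers(1, 6, size=(400, 4))
    booleans = rng.integers(0, 2, size=(400, 2)).astype(bool)
    lik = rng.choice([np.nan, 0.0, 12.5, 25.0, 50.0, 100.0], size=400)
    flags = rng.integers(0, 2, size=(400, 2)).astype(bool)
    for _ in range(5):
        w = rng.dirichlet(np.ones(6))
        cfg = RiskConfig(
            w_urge=w[0], w_stress=w[1], w_alcohol=w[2], w_interaction=w[3],
            w_motivation=w[4], w_availability=w[5], risk_threshold=float(rng.uniform()),
        )
        scores = risk_score_values(grid[:, 0], grid[:, 1], grid[:, 2], grid[:, 3],
                                   booleans[:, 0], booleans[:, 1], cfg)
        impl = classify_values(scores, flags[:, 0], flags[:, 1], lik, cfg)
        for i in range(400):
            s = (
                cfg.w_urge * (grid[i, 0] - 1) / 4
                + cfg.w_stress * (grid[i, 1] - 1) / 4
                + cfg.w_availability * (grid[i, 2] - 1) / 4
                + cfg.w_motivation * (grid[i, 3] - 1) / 4
                + cfg.w_interaction * booleans[i, 0]
                + cfg.w_alcohol * booleans[i, 1]
            )
            oracle = (
                (s >= cfg.risk_threshold)
                or bool(flags[i, 0])
                or bool(flags[i, 1])
                or (not np.isnan(lik[i]) and lik[i] > cfg.likelihood_threshold)
            )
            assert bool(impl[i]) == oracle
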