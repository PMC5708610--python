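import numpy as np
import pytest

from coopeq import (
    ConditionalCounts,
    MarkovStrategy,
    Move,
    RoundRecord,
    SimulationConfig,
    cooperation_level,
    count_conditional_moves,
    estimate_strategy,
    run_full_analysis,
    simulate_pd_session,
)
from reference_values import TABLE6


def rec(t, pid, partner, move, stage="before", session="s1"):
    return RoundRecord(session, stage, t, pid, partner, Move(move))


class TestConditionalCounts:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ConditionalCounts(3, 4, 0, 0)  # recoop > coop
        with pytest.raises(ValueError):
            ConditionalCounts(0, 0, 2, 3)  # tolerant > default
        with pytest.raises(ValueError):
            ConditionalCounts(-1, 0, 0, 0)

    def test_toy_log_hand_enumeration(self, toy_log):
        """(C,C) then (C,D): both round-2 moves follow a cooperation, one
        of them cooperates again."""
        counts = count_conditional_moves(toy_log)[("s1", "before")]
        # a replies C, b replies D -> two classified moves, one re-cooperation
        assert counts == ConditionalCounts(2, 1, 0, 0)

    def test_all_defect_log(self):
        log = []
        for t in range(1, 6):
            log += [rec(t, "a", "b", "D"), rec(t, "b", "a", "D")]
        counts = count_conditional_moves(log)[("s1", "before")]
        assert counts.n_coop == 0
        assert counts.n_default == 8
        assert counts.n_tolerant == 0

    def test_round_one_never_classified(self):
        log = [rec(1, "a", "b", "C"), rec(1, "b", "a", "C")]
        counts = count_conditional_moves(log)[("s1", "before")]
        assert counts == ConditionalCounts(0, 0, 0, 0)

    def test_missing_previous_round_skipped_with_warning(self, caplog):
        log = [
            rec(1, "a", "b", "C"),
            rec(1, "b", "a", "C"),
            rec(3, "a", "b", "C"),
            rec(3, "b", "a", "C"),
        ]
        with caplog.at_level("WARNING", logger="coopeq.empirics"):
            counts = count_conditional_moves(log)[("s1", "before")]
        assert counts == ConditionalCounts(0, 0, 0, 0)
        assert "skipped" in caplog.text

    def test_classifies_by_previous_partner_not_current(self):
        """Under re-pairing the classifying move is the one faced in the
        previous round, not the current partner's history."""
        # round 1: a-b (b defects), c-d (d cooperates)
        # round 2: a-d, b-c; a faced b's defection, c faced d's cooperation
        log = [
            rec(1, "a", "b", "C"),
            rec(1, "b", "a", "D"),
            rec(1, "c", "d", "D"),
            rec(1, "d", "c", "C"),
            rec(2, "a", "d", "C"),
            rec(2, "d", "a", "C"),
            rec(2, "b", "c", "C"),
            rec(2, "c", "b", "C"),
        ]
        counts = count_conditional_moves(log)[("s1", "before")]
        # a saw D (tolerant), b saw C (recoop), c saw C (recoop), d saw D (tolerant)
        assert counts == ConditionalCounts(2, 2, 2, 2)

    def test_recovers_strategy_from_long_simulation(self):
        cfg = SimulationConfig(
            n_players=12,
            strategies=MarkovStrategy(0.3, 0.8),
            rounds=20_000,
            seed=11,
        )
        log = simulate_pd_session(cfg)
        counts = count_conditional_moves(log)[("sim", "before")]
        a_hat, g_hat = estimate_strategy(counts)
        se_a = np.sqrt(0.3 * 0.7 / counts.n_default)
        se_g = np.sqrt(0.8 * 0.2 / counts.n_coop)
        assert abs(a_hat - 0.3) < 3 * se_a
        assert abs(g_hat - 0.8) < 3 * se_g


class TestEstimateStrategy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConditionalCounts(31, 7, 221, 23), (0.104, 0.226)),
            (ConditionalCounts(70, 61, 26, 12), (0.462, 0.871)),
            (ConditionalCounts(10, 10, 10, 0), (0.0, 1.0)),
        ],
    )
    def test_ratio_estimators(self, counts, expected):
        a_hat, g_hat = estimate_strategy(counts)
        assert round(a_hat, 3) == expected[0]
        assert round(g_hat, 3) == expected[1]

    def test_zero_denominators_undefined_not_zero(self):
        a_hat, g_hat = estimate_strategy(ConditionalCounts(0, 0, 5, 2))
        assert g_hat is None and a_hat == pytest.approx(0.4)
        a_hat, g_hat = estimate_strategy(ConditionalCounts(5, 2, 0, 0))
        assert a_hat is None and g_hat == pytest.approx(0.4)


class TestCooperationLevel:
    def test_all_cooperate(self):
        log = [rec(1, "a", "b", "C"), rec(1, "b", "a", "C")]
        assert cooperation_level(log)[("s1", "before")] == 1.0

    def test_alternating_moves(self):
        log = []
        for t in range(1, 5):
            m = "C" if t % 2 else "D"
            log += [rec(t, "a", "b", m), rec(t, "b", "a", m)]
        assert cooperation_level(log)[("s1", "before")] == 0.5

    def test_empty_log_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            cooperation_level([])

    def test_long_run_matches_stationary_value(self):
        cfg = SimulationConfig(
            n_players=12,
            strategies=MarkovStrategy(0.3, 0.8),
            rounds=20_000,
            seed=5,
        )
        level = cooperation_level(simulate_pd_session(cfg))[("sim", "before")]
        n_moves = 12 * 20_000
        se = np.sqrt(0.6 * 0.4 / n_moves)
        assert abs(level - 0.6) < 3 * se


class TestFullAnalysis:
    @pytest.fixture(scope="class")
    def report(self):
        return run_full_analysis()

    def test_strategy_table_matches_published_estimates(self, report):
        # half-unit-in-last-place tolerance: the published 3-dp table
        # rounds halves up (e.g. 91/112 = 0.8125 -> 0.813)
        for row in report.table6.itertuples():
            a_pub, g_pub = TABLE6[(row.session_id, row.stage)]
            assert row.alpha == pytest.approx(a_pub, abs=5e-4 + 1e-9)
            assert row.gamma == pytest.approx(g_pub, abs=5e-4 + 1e-9)

    def test_headline_summary(self, report):
        s = report.summary
        assert s["n_points"] == 16
        assert s["n_within_threshold"] == 6
        assert round(s["max_deviation_pct"], 1) == 1.7
        assert s["n_small_deviation"] == 12
        assert s["share_small_deviation"] == 0.75

    def test_on_curve_synthetic_session_has_zero_deviation(self):
        from coopeq import curve_alpha_given_gamma, deviation_report

        g = 0.85
        a = curve_alpha_given_gamma(g)
        rep = deviation_report(a, g, session_id="synthetic", stage="after")
        assert rep.distance == pytest.approx(0.0, abs=1e-12)
        assert rep.deviation_pct == pytest.approx(0.0, abs=1e-9)

    def test_analysis_from_user_logs(self):
        cfg = SimulationConfig(
            n_players=12,
            strategies=MarkovStrategy(0.2, 0.6),
            rounds=500,
            seed=9,
            session_id="sim1",
        )
        log = simulate_pd_session(cfg)
        report = run_full_analysis(round_log=log)
        assert len(report.table6) == 1
        row = report.table6.iloc[0]
        assert 0 < row.alpha < 1 and 0 < row.gamma < 1
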