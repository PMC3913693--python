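"""Behavioral probability families and stochastic action selection."""

import numpy as np
import pytest

from emobook import actions, space


class TestAffiliationMotivation:
    @pytest.mark.parametrize("anx,sat,expected", [
        (0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.5, 0.5, 0.5)])
    def test_values(self, anx, sat, expected):
        assert actions.affiliation_motivation(anx, sat) \
            == pytest.approx(expected)

    def test_anxiety_weighted_nine_to_one(self):
        # raising anxiety by d moves the motivation 9x as much as lowering
        # satisfaction by d
        base = actions.affiliation_motivation(0.1, 0.5)
        da = actions.affiliation_motivation(0.2, 0.5) - base
        ds = actions.affiliation_motivation(0.1, 0.4) - base
        assert da == pytest.approx(9 * ds)


class TestAffiliationWeight:
    def test_lps_zero_ignores_like(self):
        w0 = actions.p_affiliation(0.0, 0.5, 0.0, base=2.0)
        w1 = actions.p_affiliation(1.0, 0.5, 0.0, base=2.0)
        assert w0 == w1

    def test_high_lps_ratio(self):
        lo = actions.p_affiliation(0.0, 0.5, 0.99, base=2.0)
        hi = actions.p_affiliation(1.0, 0.5, 0.99, base=2.0)
        assert lo / hi == pytest.approx(0.01)

    def test_zero_motivation_floor_positive(self):
        assert actions.p_affiliation(0.5, 0.0, 0.5, base=2.0, m0=0.1) > 0

    def test_monotone_in_like_and_motivation(self):
        like = np.linspace(0, 1, 11)
        w = actions.p_affiliation(like, 0.3, 0.9, base=1.0)
        assert np.all(np.diff(w) > 0)
        mot = np.linspace(0, 1, 11)
        w = actions.p_affiliation(0.5, mot, 0.9, base=1.0)
        assert np.all(np.diff(w) > 0)

    def test_slope_in_like_increases_with_lps(self):
        def slope(lps):
            return (actions.p_affiliation(1.0, 0.5, lps, 1.0)
                    - actions.p_affiliation(0.0, 0.5, lps, 1.0))
        assert slope(0.0) < slope(0.5) < slope(0.99)


class TestAgonisticWeights:
    def test_aggression_decreasing_in_fear(self, cfg):
        fear = np.linspace(-0.95, 0.95, 50)
        w = actions.p_aggression(fear, 0.2, 1.0, cfg)
        assert np.all(np.diff(w) < 0)
        assert w[-1] < 1e-2  # never attack the top from the bottom

    def test_anxiety_makes_aggression_risk_sensitive(self, cfg):
        # more aggressive toward much lower ranks, less toward higher
        assert actions.p_aggression(-0.9, 0.9, 1.0, cfg) \
            > actions.p_aggression(-0.9, 0.0, 1.0, cfg)
        assert actions.p_aggression(0.3, 0.9, 1.0, cfg) \
            < actions.p_aggression(0.3, 0.0, 1.0, cfg)

    def test_submission_unidirectional_and_increasing(self, cfg):
        assert actions.p_submission(-0.5, 0.5, 1.0, cfg) == 0.0
        fear = np.linspace(0.01, 0.95, 30)
        w = actions.p_submission(fear, 0.3, 1.0, cfg)
        assert np.all(np.diff(w) > 0)

    def test_avoidance_far_right_of_submission(self, cfg):
        # mid fear: submission present, avoidance still negligible
        assert actions.p_submission(0.3, 0.0, 1.0, cfg) > 0.01
        assert actions.p_avoidance(0.3, 0.0, 1.0, cfg) < 0.01
        assert actions.p_avoidance(0.9, 0.9, 1.0, cfg) > 0.8

    def test_scan_probability_monotone(self, cfg):
        a = np.linspace(0, 1, 21)
        p = actions.p_scan(a, cfg)
        assert np.all(np.diff(p) >= 0)
        assert np.all((0 <= p) & (p <= 1))
        baseline = 1 / (1 + np.exp(cfg.scan_mid / cfg.scan_slope))
        assert actions.p_scan(0.0, cfg) == pytest.approx(baseline)


class TestSelectAction:
    def test_empty_weights_fall_back_to_rest(self, rng):
        aw = actions.ActionWeights([(space.REST, None)], np.zeros(1))
        assert actions.select_action(aw, rng) == (space.REST, None)

    def test_frequencies_match_weights(self, rng):
        """Selection frequencies over many draws match the normalized
        weights within multinomial 3-sigma."""
        pairs = [(space.GROOM, 1), (space.APPROACH, 2), (space.REST, None)]
        weights = np.array([0.2, 0.5, 1.3])
        aw = actions.ActionWeights(pairs, weights)
        n = 100_000
        counts = {p: 0 for p in pairs}
        for _ in range(n):
            counts[actions.select_action(aw, rng)] += 1
        probs = weights / weights.sum()
        for p, prob in zip(pairs, probs):
            sigma = np.sqrt(n * prob * (1 - prob))
            assert abs(counts[p] - n * prob) < 3 * sigma

    def test_deterministic_under_seed(self):
        aw = actions.ActionWeights(
            [(space.GROOM, 1), (space.REST, None)], np.array([0.3, 0.7]))
        seq1 = [actions.select_action(aw, np.random.default_rng(3))
                for _ in range(10)]
        seq2 = [actions.select_action(aw, np.random.default_rng(3))
                for _ in range(10)]
        assert seq1 == seq2


class TestKernelEquivalence:
    def test_kernel_weights_match_reference_builder(self, cfg, rng):
        """The compiled weight table agrees with the reference composition
        of eligibility rules and probability families."""
        from emobook import _kernels
        from emobook.simulation import Simulation
        sim = Simulation(cfg, seed=9)
        s = sim.state
        s.moving[rng.integers(0, s.n, 4)] = True
        for i in range(s.n):
            ids, w = _kernels.action_weights(
                i, s.pos, s.heading, s.view, sim.dist[i], sim.fear[i],
                s.like[i], s.moving, float(s.arousal[i]),
                float(s.anxiety[i]), float(s.satisfaction[i]), sim._ap)
            cands = space.candidate_partners(
                i, s.pos, s.heading, s.view, sim.dist[i], cfg.interact_dist,
                cfg.max_dist, cfg.max_partners, cfg.world_size)
            assert sorted(ids.tolist()) == sorted(cands.tolist())
            elig = []
            for j in cands:
                e = space.eligible_behaviors(
                    float(sim.dist[i, j]), bool(s.moving[j]),
                    float(sim.fear[i, j]), cfg.interact_dist, cfg.pers_dist,
                    cfg.max_dist)
                if e & {space.AFFILIATIVE_SIGNAL, space.AGGRESSIVE_SIGNAL,
                        space.SUBMISSIVE_SIGNAL}:
                    if not space.perceives(int(j), i, s.pos, s.heading,
                                           s.view, cfg.world_size,
                                           cfg.interact_dist, cfg.max_dist):
                        e -= {space.AFFILIATIVE_SIGNAL,
                              space.AGGRESSIVE_SIGNAL,
                              space.SUBMISSIVE_SIGNAL}
                elig.append(e)
            aw = actions.build_action_weights(
                cfg, float(s.arousal[i]), float(s.anxiety[i]),
                float(s.satisfaction[i]), cands, elig, sim.fear[i],
                s.like[i])
            ref = {(b, t): wt for (b, t), wt in zip(aw.behaviors, aw.weights)}
            order = ("groom", "affiliative_signal", "approach", "attack",
                     "aggressive_signal", "leave", "submissive_signal",
                     "avoid")
            k = len(ids)
            for bi, beh in enumerate(order):
                for m, j in enumerate(ids):
                    got = w[bi * k + m]
                    want = ref.get((beh, int(j)), 0.0)
                    assert got == pytest.approx(want, abs=1e-12), \
                        (beh, i, int(j))
            assert w[8 * k] == pytest.approx(ref[(space.RANDOM_WALK, None)])
            assert w[8 * k + 1] == pytest.approx(ref[(space.REST, None)])
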