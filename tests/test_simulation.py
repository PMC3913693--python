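"""Event-loop behavior: determinism, movement, grooming, fights,
observation bookkeeping and trace-level invariants."""

import dataclasses

import numpy as np
import pytest

from emobook import behaviors, space
from emobook.config import default_config
from emobook.simulation import Simulation
from emobook.state import initialize_group


def short_cfg(**over):
    kw = {"stabilization_minutes": 0.0, "run_minutes": 1440.0,
          "record_last_minutes": 1440.0}
    kw.update(over)
    cfg = dataclasses.replace(default_config(), **kw)
    cfg.validate()
    return cfg


@pytest.fixture(scope="module")
def short_run():
    cfg = short_cfg()
    sim = Simulation(cfg, seed=11, record_events=True)
    record = sim.run()
    return cfg, sim, record


class TestDeterminism:
    def test_same_seed_identical_trace_and_state(self):
        cfg = short_cfg(run_minutes=720.0, record_last_minutes=720.0)
        sims = [Simulation(cfg, seed=5, record_events=True) for _ in range(2)]
        for s in sims:
            s.run()
        assert sims[0].event_log == sims[1].event_log
        assert np.array_equal(sims[0].state.pos, sims[1].state.pos)
        assert np.array_equal(sims[0].state.like, sims[1].state.like)

    def test_different_seeds_differ(self):
        cfg = short_cfg(run_minutes=720.0, record_last_minutes=720.0)
        a = Simulation(cfg, seed=5, record_events=True)
        b = Simulation(cfg, seed=6, record_events=True)
        a.run()
        b.run()
        assert a.event_log != b.event_log

    def test_zero_run_minutes_no_crash(self):
        cfg = dataclasses.replace(default_config(), stabilization_minutes=60.0,
                                  run_minutes=0.0, record_last_minutes=0.0)
        record = Simulation(cfg, seed=1).run()
        assert record.n_samples == 0
        assert np.all(record.groom_minutes == 0)


class TestMovement:
    def test_speed_ten_steps_eighteen_meters(self):
        cfg = default_config()
        assert 10 * cfg.step_length == pytest.approx(18.0)

    def test_flee_increases_distance_each_step(self):
        cfg = short_cfg()
        sim = Simulation(cfg, seed=2)
        s = sim.state
        s.pos[0] = [150.0, 150.0]
        s.pos[1] = [151.0, 150.0]
        sim.update_distance(0)
        behaviors.start_move(sim, 0, behaviors.FLEE, 1)
        d_prev = sim.dist[0, 1]
        while sim.move[0] is not None:
            behaviors.movement_step(sim, 0)
            if sim.move[0] is not None:
                assert sim.dist[0, 1] > d_prev
                d_prev = sim.dist[0, 1]

    def test_approach_arrives_at_contact(self):
        cfg = short_cfg(stop_chance=0.0)
        sim = Simulation(cfg, seed=2)
        s = sim.state
        s.pos[0] = [140.0, 150.0]
        s.pos[1] = [150.0, 150.0]
        sim.update_distance(0)
        behaviors.start_move(sim, 0, behaviors.APPROACH, 1)
        for _ in range(100):
            if sim.move[0] is None:
                break
            behaviors.movement_step(sim, 0)
        assert sim.move[0] is None
        assert sim.dist[0, 1] <= cfg.interact_dist

    def test_random_walk_heading_redraw_frequency(self):
        cfg = short_cfg(stop_chance=0.0)
        sim = Simulation(cfg, seed=3)
        behaviors.start_move(sim, 0, behaviors.RANDOM_WALK, None)
        changes = 0
        trials = 2000
        for _ in range(trials):
            before = sim.state.heading[0]
            behaviors.movement_step(sim, 0)
            changes += sim.state.heading[0] != before
        assert changes / trials == pytest.approx(0.5, abs=0.05)


class TestGroomingMechanics:
    def _adjacent_sim(self):
        cfg = short_cfg()
        sim = Simulation(cfg, seed=4)
        s = sim.state
        s.pos[0] = [150.0, 150.0]
        s.pos[1] = [150.5, 150.0]
        sim.update_distance(0)
        return cfg, sim

    def test_five_minutes_of_grooming(self):
        """Receiver satisfaction 0 -> 0.5 and groomer 0 -> 0.25 after five
        minutes; the receiver's LIKE toward the groomer rises."""
        cfg, sim = self._adjacent_sim()
        s = sim.state
        s.satisfaction[:] = 0.0
        behaviors.groom(sim, 0, 1)
        sim._grooming_changed([0, 1])
        sim.refresh_contexts()
        sim.advance_to(5.0)
        assert s.satisfaction[1] == pytest.approx(0.5)
        assert s.satisfaction[0] == pytest.approx(0.25)
        assert s.psat[1, 0] == pytest.approx(0.5)
        assert s.like[1, 0] == pytest.approx(0.5)
        assert s.like[0, 1] == 0.0  # giving builds no LIKE in the giver

    def test_simultaneous_groomers_full_credit_each(self):
        """Two simultaneous groomers: the receiver's satisfaction rises as
        with one groomer, and LIKE toward each rises at the full rate."""
        cfg, sim = self._adjacent_sim()
        s = sim.state
        s.pos[2] = [149.5, 150.0]
        sim.update_distance(2)
        s.grooming[0, 1] = True
        s.grooming[2, 1] = True
        sim._grooming_changed([0, 1, 2])
        sim.refresh_contexts()
        sim.advance_to(5.0)
        assert s.satisfaction[1] == pytest.approx(0.5)
        assert s.like[1, 0] == pytest.approx(0.5)
        assert s.like[1, 2] == pytest.approx(0.5)

    def test_partner_sat_never_exceeds_satisfaction(self, short_run):
        _, sim, _ = short_run
        s = sim.state
        assert np.all(s.psat <= s.satisfaction[:, None] + 1e-12)


class TestAttackSequence:
    def _contact_sim(self, seed=0):
        cfg = short_cfg()
        sim = Simulation(cfg, seed=seed)
        s = sim.state
        s.pos[3] = [150.0, 150.0]
        s.pos[15] = [150.5, 150.0]
        sim.update_distance(3)
        sim.update_distance(15)
        return cfg, sim

    def test_win_chance_forms(self):
        assert behaviors.win_chance(0.5, 0.5) == pytest.approx(0.5)
        assert behaviors.win_chance(1.0, 0.05) == pytest.approx(1.0 / 1.05)
        assert behaviors.win_chance(0.3, 0.3, form="logistic") == 0.5

    def test_one_winner_one_loser_and_loser_flees(self):
        cfg, sim = self._contact_sim()
        out = behaviors.attack_sequence(sim, 15, 3)
        assert {out["winner"], out["loser"]} == {15, 3}
        loser = out["loser"]
        assert sim.move[loser] is not None
        assert sim.move[loser].mode == behaviors.FLEE
        assert sim.state.moving[loser]

    def test_non_escalated_attacker_wins(self):
        cfg, sim = self._contact_sim(seed=1)
        s = sim.state
        # target anxious enough that counter-attack prob toward a much
        # higher rank is essentially zero
        s.anxiety[3] = 0.9
        out = behaviors.attack_sequence(sim, 15, 3)
        assert not out["escalated"]
        assert out["winner"] == 15 and out["loser"] == 3

    def test_target_anxiety_raised_before_counter_decision(self):
        cfg, sim = self._contact_sim(seed=2)
        anx_before = sim.state.anxiety[3]
        behaviors.attack_sequence(sim, 15, 3)
        assert sim.state.anxiety[3] > anx_before


class TestTraceInvariants:
    def test_physical_interactions_require_contact(self, short_run):
        """No groom/attack beyond contact distance, no signal beyond
        personal distance, over a full event trace."""
        cfg = short_cfg()
        sim = Simulation(cfg, seed=21, record_events=True)
        s = sim.state
        end = sim.total_minutes
        while True:
            tq = sim.queue.peek_time()
            if tq > end:
                break
            act = sim.queue.pop()
            sim.advance_to(act.time)
            n_before = len(sim.event_log)
            sim.activate(act)
            for t, beh, a, r in sim.event_log[n_before:]:
                if beh in (space.GROOM, space.ATTACK):
                    assert sim.dist[a, r] <= cfg.interact_dist + 1e-9
                elif beh.endswith("signal"):
                    assert sim.dist[a, r] <= cfg.pers_dist + 1e-9

    def test_no_submission_toward_lower_ranking(self, short_run):
        _, sim, _ = short_run
        for t, beh, a, r in sim.event_log:
            if beh in (space.LEAVE, space.SUBMISSIVE_SIGNAL, space.AVOID):
                assert sim.state.dom[r] > sim.state.dom[a]

    def test_emotions_within_bounds_all_run(self, short_run):
        _, sim, _ = short_run
        s = sim.state
        for arr in (s.arousal, s.anxiety, s.satisfaction, s.like, s.psat):
            assert np.all(arr >= -1e-12) and np.all(arr <= 1 + 1e-12)

    def test_scanning_expands_view_until_next_activation(self, short_run):
        _, sim, _ = short_run
        s = sim.state
        assert np.all(s.view[s.scanning] == 360.0)
        assert np.all(s.view[~s.scanning] == 120.0)


class TestObservationBookkeeping:
    def test_grooming_conservation(self, short_run):
        """Giver minutes equal receiver minutes in the dyadic grooming
        matrix (it is a single actor->receiver account)."""
        _, _, record = short_run
        gm = record.groom_minutes
        assert gm.sum(axis=1).sum() == pytest.approx(gm.sum(axis=0).sum())

    def test_proximity_symmetric(self, short_run):
        _, _, record = short_run
        assert np.allclose(record.proximity, record.proximity.T)

    def test_sample_count(self):
        cfg = short_cfg(run_minutes=5040.0, record_last_minutes=5040.0)
        record = Simulation(cfg, seed=8).run()
        assert record.n_samples == 5040 / cfg.sample_interval_minutes == 2

    def test_hourly_rate_normalization(self):
        """21 attacks in one 42-hour interval correspond to 0.5/h."""
        from emobook.observation import Recorder
        cfg = default_config()
        rec = Recorder(cfg, 0.0, cfg.sample_interval_minutes)
        rec.on_boundary(0.0, None)
        for k in range(21):
            rec.record_event(space.ATTACK, 2, 5, float(k))
        state = initialize_group(cfg, np.random.default_rng(0))
        rec.on_boundary(cfg.sample_interval_minutes, state)
        out = rec.finalize()
        assert out.rate_matrices[space.ATTACK][2, 5] == pytest.approx(0.5)

    def test_groom_bout_merges_role_switch(self):
        """Giving then immediately receiving forms one uninterrupted bout."""
        cfg = short_cfg()
        sim = Simulation(cfg, seed=4)
        s = sim.state
        s.pos[0] = [150.0, 150.0]
        s.pos[1] = [150.5, 150.0]
        sim.update_distance(0)
        sim.advance_to(10.0)
        s.grooming[0, 1] = True
        sim._grooming_changed([0, 1])
        sim.advance_to(14.0)
        s.grooming[0, 1] = False
        s.grooming[1, 0] = True          # roles switch with no gap
        sim._grooming_changed([0, 1])
        sim.advance_to(17.0)
        s.grooming[1, 0] = False
        sim._grooming_changed([0, 1])
        assert sim.recorder.groom_bouts[0] == [pytest.approx(7.0)]
        assert sim.recorder.groom_bouts[1] == [pytest.approx(7.0)]


class TestStateRestart:
    def test_snapshot_resumes_deterministically(self):
        cfg = short_cfg(run_minutes=360.0, record_last_minutes=0.0)
        sim = Simulation(cfg, seed=13)
        sim.run()
        snap = sim.snapshot()
        clone = Simulation(cfg, seed=14, state=snap)
        assert clone.state.time == sim.state.time
        assert np.array_equal(clone.queue.pending_time,
                              sim.queue.pending_time)
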