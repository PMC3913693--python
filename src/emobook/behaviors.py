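"""Execution of selected behaviors and their side effects.

These functions mutate a running :class:`~emobook.simulation.Simulation`:
movement bouts in 3-second steps, grooming with its emotional contexts,
communicative signals with receiver reactions, rest (optionally with
scanning) and the attack / counter-attack / escalated-fight sequence with
bystander effects.  Fleeing, leaving and avoiding share one movement
mechanic and differ only in the triggering context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import actions, emotions, scheduler, space

# movement modes
APPROACH = "approach"
FLEE = "flee"
LEAVE = "leave"
AVOID = "avoid"
GROUPING = "grouping"
RANDOM_WALK = "random_walk"

AWAY_MODES = (FLEE, LEAVE, AVOID)
TOWARD_MODES = (APPROACH, GROUPING)


@dataclass
class MoveBout:
    mode: str
    target: int | None      # agent id for directed modes, None for random walk
    steps: int = 0
    steps_in_window: int = 0


def start_move(sim, ego: int, mode: str, target: int | None) -> None:
    """Begin a movement bout; the first step executes one step-time later."""
    sim.move[ego] = MoveBout(mode, target)
    sim.state.moving[ego] = True
    sim.queue.schedule(ego, sim.state.time + sim.cfg.move_step_minutes,
                       scheduler.MOVEMENT_STEP)


def end_move_bout(sim, ego: int) -> None:
    """Terminate a bout: record its distance, clear the moving flag and run
    the proximity update (dominant-within-5-m contexts for everyone)."""
    mb = sim.move[ego]
    if mb is None:
        return
    sim.recorder.record_move_bout(ego, mb.steps_in_window)
    sim.move[ego] = None
    sim.state.moving[ego] = False
    sim.refresh_contexts()


def movement_step(sim, ego: int) -> bool:
    """Execute one 3-second movement step; return True if the bout goes on.

    Directed modes re-aim at the target's current position every step;
    random walks keep or redraw the heading with equal chance.  Bouts end
    on arrival (approach/grouping at contact distance), on escaping the
    opponent's personal distance (flee/leave/avoid), when the grouping
    criteria are met again, or stochastically via the stop chance.
    """
    cfg, s = sim.cfg, sim.state
    mb = sim.move[ego]
    rng = sim.rng
    if mb.mode == RANDOM_WALK:
        if mb.steps > 0 and rng.random() < cfg.random_walk_turn_chance:
            s.heading[ego] = rng.uniform(0.0, 360.0)
    else:
        br = float(space.bearing(s.pos[ego], s.pos[mb.target], cfg.world_size))
        s.heading[ego] = br if mb.mode in TOWARD_MODES else (br + 180.0) % 360.0
    rad = np.radians(s.heading[ego])
    s.pos[ego] = (s.pos[ego] + cfg.step_length
                  * np.array([np.cos(rad), np.sin(rad)])) % cfg.world_size
    sim.update_distance(ego)
    mb.steps += 1
    if s.time >= sim.recorder.window_start:
        mb.steps_in_window += 1
    done = False
    if mb.target is not None:
        d = sim.dist[ego, mb.target]
        if mb.mode in TOWARD_MODES and d <= cfg.interact_dist:
            done = True
        elif mb.mode in AWAY_MODES and d > cfg.pers_dist:
            done = True
    if not done and mb.mode == GROUPING and not sim.grouping_needed(ego):
        done = True
    if not done and rng.random() < cfg.stop_chance:
        done = True
    if done:
        end_move_bout(sim, ego)
        return False
    return True


def rest(sim, ego: int) -> None:
    """Rest in a bout; scanning (360-degree vigilance) may accompany it,
    with a probability that rises with arousal."""
    cfg, s = sim.cfg, sim.state
    if sim.rng.random() < float(actions.p_scan(s.arousal[ego], cfg)):
        sim.begin_scan(ego)
    sim.queue.schedule(ego, s.time + sim.draw_time(cfg.rest_schedule_mean))


def grouping(sim, ego: int) -> None:
    """Rejoin the group by approaching a uniformly random other member."""
    n = sim.state.n
    j = int(sim.rng.integers(n - 1))
    if j >= ego:
        j += 1
    start_move(sim, ego, GROUPING, j)


def groom(sim, ego: int, target: int) -> None:
    """Groom the partner: both enter grooming emotion contexts, the
    receiver's partner-attributed satisfaction toward ego starts rising,
    orientations lock on, and ego re-decides after the grooming schedule
    time (7.5 min on average)."""
    s = sim.state
    s.grooming[ego, target] = True
    sim.face_each_other(ego, target)
    sim.stop_scanning(target)
    sim.queue.schedule(ego, s.time
                       + sim.draw_time(sim.cfg.groom_schedule_mean))


_SIGNAL_EVENT = {
    space.AFFILIATIVE_SIGNAL: emotions.AFFILIATIVE_SIGNAL_RECEIVED,
    space.SUBMISSIVE_SIGNAL: emotions.SUBMISSIVE_SIGNAL_RECEIVED,
    space.AGGRESSIVE_SIGNAL: emotions.AGGRESSIVE_SIGNAL_RECEIVED,
}


def send_signal(sim, ego: int, target: int, behavior: str) -> None:
    """Send a communicative signal: the receiver takes the instantaneous
    emotion effect and is activated shortly after to react."""
    cfg, s = sim.cfg, sim.state
    sim.apply_point(target, _SIGNAL_EVENT[behavior])
    sim.stop_scanning(target)
    sim.face_each_other(ego, target)
    sim.recorder.record_event(behavior, ego, target, s.time)
    sim.queue.schedule_reaction(target, s.time + cfg.reaction_delay,
                                scheduler.SIGNAL_RECEIVED)
    sim.queue.schedule(ego, s.time + sim.draw_time(cfg.action_schedule_mean))


def win_chance(dom_i: float, dom_j: float, form: str = "ratio",
               logistic_scale: float = 0.2) -> float:
    """Chance that i beats j in an escalated fight.

    The default ratio form dom_i / (dom_i + dom_j) rises with the dominance
    advantage; a logistic-in-difference alternative is available.
    """
    if form == "ratio":
        return dom_i / (dom_i + dom_j)
    return float(1.0 / (1.0 + np.exp(-(dom_i - dom_j) / logistic_scale)))


def attack_sequence(sim, attacker: int, target: int) -> dict:
    """Attack, optional counter-attack, and fight resolution.

    The target is activated immediately: its anxiety takes the
    attack-received increase *before* its counter-attack probability is
    computed, which makes counter-attacks conservative.  Without a counter
    the attacker wins outright.  An escalated fight is resolved by the win
    chance; the loser flees, the winner's anxiety drops and the loser's
    rises, and all bystanders within personal distance are startled
    (aroused, reoriented toward the counter-attacker, activated shortly).
    """
    cfg, s = sim.cfg, sim.state
    t = s.time
    sim.stop_scanning(attacker)
    sim.stop_scanning(target)
    sim.face_each_other(attacker, target)
    sim.recorder.record_event(space.ATTACK, attacker, target, t)
    sim.log_event(space.ATTACK, attacker, target)
    sim.apply_point(attacker, emotions.ATTACK_GIVEN)
    sim.apply_point(target, emotions.ATTACK_RECEIVED)
    # target's immediate response: counter-attack or not
    p_counter = float(actions.p_aggression(s.fear[target, attacker],
                                           s.anxiety[target], cfg.att_prob,
                                           cfg)) * s.arousal[target]
    escalated = sim.rng.random() < min(1.0, p_counter)
    if escalated:
        sim.recorder.record_event(space.ATTACK, target, attacker, t)
        sim.log_event(space.ATTACK, target, attacker)
        sim.apply_point(target, emotions.ATTACK_GIVEN)
        sim.apply_point(attacker, emotions.ATTACK_RECEIVED)
        w = win_chance(s.dom[attacker], s.dom[target], cfg.win_chance_form,
                       cfg.win_chance_logistic_scale)
        winner = attacker if sim.rng.random() < w else target
        # bystanders perceive the noise of the fight regardless of view
        near = np.nonzero((np.minimum(sim.dist[attacker], sim.dist[target])
                           <= cfg.pers_dist))[0]
        for b in near:
            if b == attacker or b == target:
                continue
            sim.apply_point(b, emotions.FIGHT_OBSERVED)
            sim.stop_scanning(b)
            s.heading[b] = float(space.bearing(s.pos[b], s.pos[target],
                                               cfg.world_size))
            sim.queue.schedule_reaction(b, t + cfg.reaction_delay,
                                        scheduler.FIGHT_OBSERVED)
    else:
        winner = attacker
    loser = target if winner == attacker else attacker
    sim.apply_point(winner, emotions.FIGHT_WON)
    sim.apply_point(loser, emotions.FIGHT_LOST)
    # the loser's next action is fleeing from the winner
    sim.interrupt_grooming(loser)
    start_move(sim, loser, FLEE, winner)
    sim.queue.schedule(winner, t + sim.draw_time(cfg.action_schedule_mean))
    sim.mark_context_dirty()
    return {"attacker": attacker, "target": target, "escalated": escalated,
            "winner": winner, "loser": loser}
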