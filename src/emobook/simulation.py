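"""The event-driven simulation loop.

A :class:`Simulation` owns the group state, the continuous-time event
queue and the recorder.  Processing an activation always follows the same
order: (1) advance every agent's time-dependent state (emotions,
partner-attributed satisfaction, LIKE) to the current time, (2) execute a
pending movement step if one is scheduled, (3) check the grouping
criteria, (4) otherwise select and execute one behavior.  All randomness
flows through a single seeded generator, so a (config, seed) pair fully
determines a run.
"""

from __future__ import annotations

import numpy as np

from . import _kernels, behaviors, emotions, scheduler, space
from .config import ModelConfig
from .observation import Recorder, RunRecord
from .state import GroupState, initialize_group


class Simulation:
    def __init__(self, cfg: ModelConfig, seed: int | None = None,
                 state: GroupState | None = None,
                 record_events: bool = False):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(
            cfg.rng_seed if seed is None else seed)
        self.state = state if state is not None \
            else initialize_group(cfg, self.rng)
        s = self.state
        n = s.n
        self.fear = s.fear
        self.dist = space.distance_matrix(s.pos, cfg.world_size)
        self.queue = scheduler.EventQueue(n)
        for i in range(n):
            self.queue.schedule(i, float(s.next_time[i]))
        self.move: list[behaviors.MoveBout | None] = [None] * n
        self.total_minutes = float(cfg.stabilization_minutes
                                   + cfg.run_minutes)
        self.recorder = Recorder(cfg,
                                 self.total_minutes - cfg.record_last_minutes,
                                 self.total_minutes)
        self.engaged = np.zeros(n, dtype=bool)   # in a grooming bout
        self._bout_start = np.zeros(n)
        self._psat_rate = np.full((n, n), -cfg.def_sat_dec)
        self._ctx_dirty = False
        self.event_log: list[tuple] | None = [] if record_events else None
        self.n_activations = 0
        self._ap = self._pack_action_params()

    def _pack_action_params(self) -> np.ndarray:
        """Scalar parameters of the action-selection kernel, packed in the
        order defined by the P_* indices in :mod:`emobook._kernels`."""
        cfg = self.cfg
        return np.array([
            cfg.world_size, cfg.interact_dist, cfg.pers_dist, cfg.max_dist,
            cfg.max_partners, cfg.lps, cfg.aff_motivation_floor,
            cfg.anxiety_motivation_weight, cfg.aggr_theta0,
            cfg.aggr_theta_anx_shift, cfg.aggr_scale0, cfg.aggr_scale1,
            cfg.subm_theta0, cfg.subm_theta_anx_shift, cfg.subm_scale,
            cfg.avoid_theta0, cfg.avoid_theta_anx_shift, cfg.avoid_scale,
            cfg.gg_prob, cfg.afs_prob, cfg.app_prob, cfg.att_prob,
            cfg.ags_prob, cfg.le_prob, cfg.ss_prob, cfg.av_prob,
            cfg.rndw_prob, cfg.rest_prob], dtype=float)

    # ------------------------------------------------------------------
    # state advancement
    # ------------------------------------------------------------------
    def advance_to(self, t: float) -> None:
        """Integrate all agents' emotions and attitudes up to time ``t``
        (piecewise-linear approach to the current context limits, then one
        sweep of the LIKE update with the elapsed interval)."""
        s = self.state
        dt = t - s.time
        if dt <= 0.0:
            s.time = t
            return
        self.recorder.accumulate(s.time, dt, s.grooming, self.engaged,
                                 s.scanning, s.moving)
        _kernels.sweep(dt, s.arousal, s.ar_limit, s.ar_rate,
                       s.anxiety, s.anx_limit, s.anx_rate,
                       s.satisfaction, s.sat_limit, s.sat_rate,
                       s.psat, self._psat_rate, s.like, self.cfg.lhw)
        s.time = t

    def update_distance(self, i: int) -> None:
        """Refresh row/column ``i`` of the pairwise distance matrix."""
        _kernels.update_distance_row(i, self.state.pos, self.dist,
                                     self.cfg.world_size)

    # ------------------------------------------------------------------
    # context bookkeeping
    # ------------------------------------------------------------------
    def mark_context_dirty(self) -> None:
        self._ctx_dirty = True

    def refresh_contexts(self) -> None:
        """Recompute emotion limits/rates for every agent from grooming
        roles and dominant-in-proximity perception (vectorized)."""
        cfg, s = self.cfg, self.state
        dom_near = _kernels.dominant_near(s.pos, s.heading, s.view,
                                          self.dist, s.dom, cfg.world_size,
                                          cfg.interact_dist, cfg.pers_dist,
                                          cfg.max_dist)
        (s.ar_limit, s.ar_rate, s.anx_limit, s.anx_rate,
         s.sat_limit, s.sat_rate) = emotions.context_rates(
            cfg, s.receiving, s.giving, dom_near, s.satisfaction)
        self._ctx_dirty = False

    def _grooming_changed(self, affected) -> None:
        cfg, s = self.cfg, self.state
        self._psat_rate = np.where(s.grooming.T, cfg.gr_sat_inc,
                                   -cfg.def_sat_dec)
        eng = s.grooming.any(axis=0) | s.grooming.any(axis=1)
        for a in affected:
            if eng[a] and not self.engaged[a]:
                self.engaged[a] = True
                self._bout_start[a] = s.time
            elif not eng[a] and self.engaged[a]:
                self.engaged[a] = False
                self.recorder.record_groom_bout(a, self._bout_start[a],
                                                s.time)
        self.mark_context_dirty()

    def interrupt_grooming(self, i: int) -> None:
        """Stop i's outgoing grooming (e.g. when it must flee)."""
        s = self.state
        if s.grooming[i].any():
            receivers = np.nonzero(s.grooming[i])[0]
            s.grooming[i, :] = False
            self._grooming_changed([i, *receivers])

    # ------------------------------------------------------------------
    # small helpers used by behavior executors
    # ------------------------------------------------------------------
    def draw_time(self, mean: float) -> float:
        return scheduler.draw_schedule_time(mean, self.rng,
                                            self.cfg.schedule_sd_frac,
                                            self.cfg.schedule_floor)

    def apply_point(self, i: int, event: str) -> None:
        s = self.state
        s.arousal[i], s.anxiety[i] = emotions.apply_point_effect(
            float(s.arousal[i]), float(s.anxiety[i]), event, self.cfg)

    def face_each_other(self, i: int, j: int) -> None:
        br = float(space.bearing(self.state.pos[i], self.state.pos[j],
                                 self.cfg.world_size))
        self.state.heading[i] = br
        self.state.heading[j] = (br + 180.0) % 360.0
        self.mark_context_dirty()

    def begin_scan(self, i: int) -> None:
        self.state.scanning[i] = True
        self.state.view[i] = self.cfg.max_angle
        self.mark_context_dirty()

    def stop_scanning(self, i: int) -> None:
        if self.state.scanning[i]:
            self.state.scanning[i] = False
            self.state.view[i] = self.cfg.view_angle
            self.mark_context_dirty()

    def grouping_needed(self, i: int) -> bool:
        # inline variant of space.grouping_needed (self-distance 0 counts
        # once within near_dist, hence the +1)
        row = self.dist[i]
        return bool((row <= self.cfg.near_dist).sum() < self.cfg.min_others + 1
                    or row.max() > self.cfg.far_dist)

    def log_event(self, behavior: str, actor: int,
                  target: int | None) -> None:
        if self.event_log is not None:
            self.event_log.append((round(self.state.time, 9), behavior,
                                   actor, target))

    # ------------------------------------------------------------------
    # activation handling
    # ------------------------------------------------------------------
    def activate(self, act: scheduler.Activation) -> None:
        cfg, s = self.cfg, self.state
        i = act.agent_id
        self.n_activations += 1
        self.stop_scanning(i)  # scanning lasts until the next activation
        if self.move[i] is not None:
            if act.reason == scheduler.MOVEMENT_STEP:
                if behaviors.movement_step(self, i):
                    self.queue.schedule(i, s.time + cfg.move_step_minutes,
                                        scheduler.MOVEMENT_STEP)
                    if self._ctx_dirty:
                        self.refresh_contexts()
                    return
            else:  # pre-empted mid-bout by a reaction: abort the bout
                behaviors.end_move_bout(self, i)
        # an activation ends ego's current grooming unless re-selected below
        prev_receivers = np.nonzero(s.grooming[i])[0]
        if prev_receivers.size:
            s.grooming[i, :] = False
        if self.grouping_needed(i):
            if prev_receivers.size:
                self._grooming_changed([i, *prev_receivers])
            behaviors.grouping(self, i)
            self.log_event("grouping", i, self.move[i].target)
            if self._ctx_dirty:
                self.refresh_contexts()
            return
        beh, j = self._select(i)
        self.log_event(beh, i, j)
        if beh == space.GROOM:
            s.grooming[i, j] = True
            # continuation of the same dyad keeps the bout unbroken
            changed = set([i, j, *prev_receivers])
            self._grooming_changed(sorted(changed))
            behaviors.groom(self, i, j)
        else:
            if prev_receivers.size:
                self._grooming_changed([i, *prev_receivers])
            if beh == space.REST:
                behaviors.rest(self, i)
            elif beh == space.RANDOM_WALK:
                behaviors.start_move(self, i, behaviors.RANDOM_WALK, None)
            elif beh == space.APPROACH:
                self.recorder.record_event(space.APPROACH, i, j, s.time)
                behaviors.start_move(self, i, behaviors.APPROACH, j)
            elif beh == space.LEAVE:
                self.recorder.record_event(space.LEAVE, i, j, s.time)
                behaviors.start_move(self, i, behaviors.LEAVE, j)
            elif beh == space.AVOID:
                self.recorder.record_event(space.AVOID, i, j, s.time)
                behaviors.start_move(self, i, behaviors.AVOID, j)
            elif beh == space.ATTACK:
                behaviors.attack_sequence(self, i, j)
            else:  # signals
                behaviors.send_signal(self, i, j, beh)
        # refresh every decision: the satisfaction-dependent default
        # arousal limit drifts even without discrete context changes
        self.refresh_contexts()

    # behaviors in fixed order for the flattened weight table
    _BEH_ORDER = (space.GROOM, space.AFFILIATIVE_SIGNAL, space.APPROACH,
                  space.ATTACK, space.AGGRESSIVE_SIGNAL, space.LEAVE,
                  space.SUBMISSIVE_SIGNAL, space.AVOID)

    def _select(self, i: int) -> tuple[str, int | None]:
        """Build the (behavior, partner) weight table over the candidate
        set and sample one action (same formulas as :mod:`emobook.actions`,
        evaluated in a compiled kernel)."""
        cfg, s = self.cfg, self.state
        ids, weights = _kernels.action_weights(
            i, s.pos, s.heading, s.view, self.dist[i], self.fear[i],
            s.like[i], s.moving, float(s.arousal[i]), float(s.anxiety[i]),
            float(s.satisfaction[i]), self._ap)
        total = weights.sum()
        if total <= 0.0 or not np.isfinite(total):
            return (space.REST, None)
        u = self.rng.random() * total
        idx = min(int(np.searchsorted(np.cumsum(weights), u, side="right")),
                  weights.size - 1)
        k = ids.size
        if idx >= 8 * k:
            return (space.RANDOM_WALK, None) if idx == 8 * k \
                else (space.REST, None)
        return (self._BEH_ORDER[idx // k], int(ids[idx % k]))

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------
    def run(self) -> RunRecord:
        """Run stabilization plus the recorded period and return the
        averaged observables."""
        end = self.total_minutes
        rec = self.recorder
        while True:
            tq = self.queue.peek_time()
            while rec.next_boundary <= min(tq, end):
                self.advance_to(rec.next_boundary)
                rec.on_boundary(self.state.time, self.state)
            if tq > end:
                break
            act = self.queue.pop()
            self.advance_to(act.time)
            self.activate(act)
        self.advance_to(end)
        self._flush_open_bouts()
        return rec.finalize()

    def _flush_open_bouts(self) -> None:
        s = self.state
        for a in range(s.n):
            if self.engaged[a]:
                self.recorder.record_groom_bout(a, self._bout_start[a],
                                                s.time)
            if self.move[a] is not None:
                self.recorder.record_move_bout(a,
                                               self.move[a].steps_in_window)

    # -- persistence ----------------------------------------------------
    def write_event_log(self, path) -> None:
        """Dump the recorded event trace (time, behavior, actor, target)
        as CSV; requires ``record_events=True``."""
        if self.event_log is None:
            raise ValueError("run with record_events=True to log events")
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "behavior", "actor", "target"])
            w.writerows(self.event_log)

    def snapshot(self) -> GroupState:
        """Copy of the current group state with pending activation times,
        suitable for saving and later restarts."""
        import copy
        snap = copy.deepcopy(self.state)
        snap.next_time = np.array(self.queue.pending_time)
        return snap
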