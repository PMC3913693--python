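"""Recording layer: dyadic rate matrices, state samples, bout accounting.

Only the final part of a run (the recording window) is observed.  The
window is divided into fixed intervals (3.5 days by default); dyadic
behavior counts and grooming minutes are converted to hourly rates per
interval and averaged, and individual states (emotions, LIKE, one-zero
proximity within contact distance) are sampled at each interval boundary.
Bouts (grooming, scanning, movement) are truncated at the window edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import space
from .config import MINUTES_PER_HOUR, ModelConfig

COUNT_BEHAVIORS = (space.APPROACH, space.ATTACK, space.AGGRESSIVE_SIGNAL,
                   space.AFFILIATIVE_SIGNAL, space.SUBMISSIVE_SIGNAL,
                   space.LEAVE, space.AVOID)


@dataclass
class RunRecord:
    """Averaged per-run observables produced by a :class:`Recorder`."""
    rate_matrices: dict                 # behavior -> (N, N) events per hour
    groom_minutes: np.ndarray           # (N, N) grooming min/h, actor->receiver
    like_mean: np.ndarray               # (N, N) sampled LIKE average
    proximity: np.ndarray               # (N, N) share of samples within 1 m
    arousal_mean: np.ndarray            # (N,)
    anxiety_mean: np.ndarray
    satisfaction_mean: np.ndarray
    pct_grooming: np.ndarray            # (N,) % of recorded time
    pct_scanning: np.ndarray
    pct_moving: np.ndarray
    groom_bouts: list                   # per agent: list of bout minutes
    move_bout_distances: list           # per agent: list of meters
    n_samples: int
    recording_minutes: float


class Recorder:
    """Accumulates observations over the recording window of one run."""

    def __init__(self, cfg: ModelConfig, window_start: float,
                 window_end: float):
        self.cfg = cfg
        n = cfg.n_agents
        self.n = n
        self.window_start = window_start
        self.window_end = window_end
        self.interval = cfg.sample_interval_minutes
        self.next_boundary = window_start
        self._open = False
        self._interval_start = window_start
        # per-interval accumulators
        self._counts = {b: np.zeros((n, n)) for b in COUNT_BEHAVIORS}
        self._groom_min = np.zeros((n, n))
        # collected per-interval rates
        self._rates: dict[str, list[np.ndarray]] = \
            {b: [] for b in COUNT_BEHAVIORS}
        self._groom_rates: list[np.ndarray] = []
        # samples
        self._like: list[np.ndarray] = []
        self._prox: list[np.ndarray] = []
        self._emotions: list[np.ndarray] = []
        # time budgets over the whole window
        self.groom_engaged_min = np.zeros(n)
        self.scan_min = np.zeros(n)
        self.move_min = np.zeros(n)
        # bout registries
        self.groom_bouts: list[list[float]] = [[] for _ in range(n)]
        self.move_bout_distances: list[list[float]] = [[] for _ in range(n)]

    # -- continuous accumulation --------------------------------------
    def accumulate(self, t0: float, dt: float, grooming: np.ndarray,
                   engaged: np.ndarray, scanning: np.ndarray,
                   moving: np.ndarray) -> None:
        """Attribute ``dt`` minutes of ongoing states to the tallies.

        Caller guarantees [t0, t0+dt] lies inside a single recording
        interval (boundaries are processed as scheduled events), so no
        splitting is needed here beyond clipping at the window start.
        """
        if t0 + dt <= self.window_start or t0 >= self.window_end:
            return
        lo = max(t0, self.window_start)
        hi = min(t0 + dt, self.window_end)
        d = hi - lo
        if d <= 0:
            return
        from ._kernels import accumulate_tallies
        accumulate_tallies(d, grooming, engaged, scanning, moving,
                           self._groom_min, self.groom_engaged_min,
                           self.scan_min, self.move_min)

    def record_event(self, behavior: str, actor: int, receiver: int,
                     t: float) -> None:
        if self.window_start <= t <= self.window_end:
            self._counts[behavior][actor, receiver] += 1.0

    def record_groom_bout(self, agent: int, start: float, end: float) -> None:
        lo, hi = max(start, self.window_start), min(end, self.window_end)
        if hi > lo:
            self.groom_bouts[agent].append(hi - lo)

    def record_move_bout(self, agent: int, steps_in_window: int) -> None:
        if steps_in_window > 0:
            self.move_bout_distances[agent].append(
                steps_in_window * self.cfg.step_length)

    # -- boundaries ----------------------------------------------------
    def on_boundary(self, t: float, state) -> None:
        """Handle the boundary at time ``t``: open the window on the first
        call, thereafter close the interval (rates) and take a sample."""
        if not self._open:
            self._open = True
            self._interval_start = t
        else:
            hours = (t - self._interval_start) / MINUTES_PER_HOUR
            if hours > 0:
                for b in COUNT_BEHAVIORS:
                    self._rates[b].append(self._counts[b] / hours)
                    self._counts[b] = np.zeros((self.n, self.n))
                self._groom_rates.append(self._groom_min / hours)
                self._groom_min = np.zeros((self.n, self.n))
            self._interval_start = t
            self._sample(state)
        self.next_boundary = min(t + self.interval, self.window_end)
        if t >= self.window_end:
            self.next_boundary = np.inf

    def _sample(self, state) -> None:
        self._like.append(state.like.copy())
        from .space import distance_matrix
        d = distance_matrix(state.pos, self.cfg.world_size)
        prox = (d <= self.cfg.interact_dist).astype(float)
        np.fill_diagonal(prox, 0.0)
        self._prox.append(prox)
        self._emotions.append(np.vstack([state.arousal, state.anxiety,
                                         state.satisfaction]))

    # -- finalization ---------------------------------------------------
    def finalize(self) -> RunRecord:
        n = self.n
        minutes = self.window_end - self.window_start
        def mean_of(lst, shape):
            return np.mean(lst, axis=0) if lst else np.zeros(shape)
        emo = mean_of(self._emotions, (3, n))
        pct = 100.0 / minutes if minutes > 0 else 0.0
        return RunRecord(
            rate_matrices={b: mean_of(self._rates[b], (n, n))
                           for b in COUNT_BEHAVIORS},
            groom_minutes=mean_of(self._groom_rates, (n, n)),
            like_mean=mean_of(self._like, (n, n)),
            proximity=mean_of(self._prox, (n, n)),
            arousal_mean=emo[0], anxiety_mean=emo[1],
            satisfaction_mean=emo[2],
            pct_grooming=self.groom_engaged_min * pct,
            pct_scanning=self.scan_min * pct,
            pct_moving=self.move_min * pct,
            groom_bouts=self.groom_bouts,
            move_bout_distances=self.move_bout_distances,
            n_samples=len(self._like),
            recording_minutes=minutes,
        )
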