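"""Continuous-time event queue with one pending self-activation per agent.

Activations pop in non-decreasing time order; ties break deterministically
by (time, agent id, insertion order).  Rescheduling replaces an agent's
pending activation (lazy invalidation via tokens); reaction contexts
(being attacked, receiving a signal, observing a fight) may only pull a
pending activation earlier, never push it later.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

# activation reasons
SELF_SCHEDULED = "self_scheduled"
ATTACKED = "attacked"
SIGNAL_RECEIVED = "signal_received"
FIGHT_OBSERVED = "fight_observed"
MOVEMENT_STEP = "movement_step"


def draw_schedule_time(mean: float, rng: np.random.Generator,
                       sd_frac: float = 0.05, floor: float = 0.01) -> float:
    """Sample a waiting time ~ Normal(mean, sd_frac * mean), truncated below
    at a small positive floor so waits are never zero or negative."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return max(floor, float(rng.normal(mean, sd_frac * mean)))


@dataclass(order=True)
class Activation:
    time: float
    agent_id: int
    seq: int
    reason: str = field(compare=False)
    token: int = field(compare=False)


class EventQueue:
    """Binary heap keyed on (time, agent_id, insertion order) with one live
    entry per agent; superseded entries are skipped on pop."""

    def __init__(self, n_agents: int):
        self._heap: list[Activation] = []
        self._seq = 0
        self._token = np.zeros(n_agents, dtype=np.int64)
        self.pending_time = np.full(n_agents, np.inf)

    def __len__(self) -> int:
        return len(self._heap)

    def schedule(self, agent_id: int, time: float,
                 reason: str = SELF_SCHEDULED) -> None:
        """Replace the agent's pending self-activation."""
        self._seq += 1
        self._token[agent_id] += 1
        self.pending_time[agent_id] = time
        heapq.heappush(self._heap, Activation(time, agent_id, self._seq,
                                              reason, self._token[agent_id]))

    def schedule_reaction(self, agent_id: int, time: float,
                          reason: str) -> None:
        """Pull the agent's activation earlier for a reaction; a pending
        activation that is already sooner is kept."""
        if time < self.pending_time[agent_id]:
            self.schedule(agent_id, time, reason)

    def pop(self) -> Activation:
        """Pop the next live activation (minimal time, deterministic
        tie-break).  Raises IndexError when empty."""
        while self._heap:
            act = heapq.heappop(self._heap)
            if self._token[act.agent_id] == act.token:
                self.pending_time[act.agent_id] = np.inf
                return act
        raise IndexError("pop from empty event queue")

    def peek_time(self) -> float:
        """Time of the next live activation, or +inf if none."""
        while self._heap:
            act = self._heap[0]
            if self._token[act.agent_id] == act.token:
                return act.time
            heapq.heappop(self._heap)
        return float("inf")
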