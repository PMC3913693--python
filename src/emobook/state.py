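"""Group state container and initialization.

The state of all N individuals is stored column-wise in numpy arrays so the
per-event sweep that advances every agent's emotions and attitudes is a
handful of vectorized operations regardless of group size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import emotions, space
from .attitudes import fear_matrix
from .config import ModelConfig, dominance_vector


@dataclass
class GroupState:
    """Complete, serializable state of the group at one instant."""

    dom: np.ndarray            # (N,) dominance strengths, rank order
    pos: np.ndarray            # (N, 2) torus coordinates, meters
    heading: np.ndarray        # (N,) degrees
    view: np.ndarray           # (N,) current view-cone width, degrees
    scanning: np.ndarray       # (N,) bool
    moving: np.ndarray         # (N,) bool: inside a movement bout
    arousal: np.ndarray        # (N,)
    anxiety: np.ndarray
    satisfaction: np.ndarray
    ar_limit: np.ndarray       # context-specific limits and rates
    ar_rate: np.ndarray
    anx_limit: np.ndarray
    anx_rate: np.ndarray
    sat_limit: np.ndarray
    sat_rate: np.ndarray
    like: np.ndarray           # (N, N) LIKE_ij, diagonal unused (0)
    psat: np.ndarray           # (N, N) PARTNER_SAT_ij
    grooming: np.ndarray       # (N, N) bool, [actor, receiver]
    next_time: np.ndarray      # (N,) next self-activation, minutes
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.dom.shape[0]

    @property
    def fear(self) -> np.ndarray:
        """Antisymmetric FEAR matrix (fixed for the whole run)."""
        return fear_matrix(self.dom)

    @property
    def receiving(self) -> np.ndarray:
        """Agents currently receiving grooming from anyone."""
        return self.grooming.any(axis=0)

    @property
    def giving(self) -> np.ndarray:
        """Agents currently giving grooming to anyone."""
        return self.grooming.any(axis=1)

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for name, val in self.__dict__.items():
            d[name] = val.tolist() if isinstance(val, np.ndarray) else val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupState":
        kw = {}
        for name, val in d.items():
            if isinstance(val, list):
                arr = np.asarray(val)
                if name in ("scanning", "moving", "grooming"):
                    arr = arr.astype(bool)
                else:
                    arr = arr.astype(float)
                kw[name] = arr
            else:
                kw[name] = val
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GroupState":
        return cls.from_dict(json.loads(Path(path).read_text()))


def dominant_in_proximity(state: GroupState, cfg: ModelConfig,
                          dist: np.ndarray | None = None) -> np.ndarray:
    """For each agent, whether any higher-ranking group member is perceived
    within personal distance (the arousal-raising social context)."""
    if dist is None:
        dist = space.distance_matrix(state.pos, cfg.world_size)
    n = state.n
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = space.perceives_mask(i, state.pos, state.heading, state.view,
                                    dist[i], cfg.interact_dist, cfg.max_dist,
                                    cfg.world_size)
        out[i] = bool(np.any(mask & (dist[i] <= cfg.pers_dist)
                             & (state.dom > state.dom[i])))
    return out


def refresh_context_limits(state: GroupState, cfg: ModelConfig,
                           dist: np.ndarray | None = None,
                           restlessness: bool = True) -> None:
    """Recompute every agent's emotion limits/rates from its current social
    context (grooming roles and dominant-in-proximity)."""
    dom_near = dominant_in_proximity(state, cfg, dist)
    (state.ar_limit, state.ar_rate, state.anx_limit, state.anx_rate,
     state.sat_limit, state.sat_rate) = emotions.context_rates(
        cfg, state.receiving, state.giving, dom_near,
        state.satisfaction if restlessness else None)


def initialize_group(cfg: ModelConfig, rng: np.random.Generator) -> GroupState:
    """Fresh group: positions uniform in a disc of 50 m diameter at the
    world center, random headings, neutral attitudes, baseline emotions;
    agents that already perceive a higher-ranking member within personal
    distance start with raised arousal/anxiety limits."""
    n = cfg.n_agents
    # uniform over the disc via sqrt-radius sampling
    r = cfg.init_disc_radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * np.pi
    center = cfg.world_size / 2.0
    pos = np.column_stack([center + r * np.cos(phi),
                           center + r * np.sin(phi)]) % cfg.world_size
    heading = rng.uniform(1.0, 360.0, n)
    zero = np.zeros(n)
    state = GroupState(
        dom=dominance_vector(n),
        pos=pos,
        heading=heading,
        view=np.full(n, cfg.view_angle),
        scanning=np.zeros(n, dtype=bool),
        moving=np.zeros(n, dtype=bool),
        arousal=np.full(n, cfg.def_arousal),
        anxiety=zero.copy(),
        satisfaction=zero.copy(),
        ar_limit=np.full(n, cfg.def_arousal),
        ar_rate=np.full(n, cfg.def_ar_rate),
        anx_limit=zero.copy(),
        anx_rate=np.full(n, cfg.def_anx_dec),
        sat_limit=zero.copy(),
        sat_rate=np.full(n, cfg.def_sat_dec),
        like=np.zeros((n, n)),
        psat=np.zeros((n, n)),
        grooming=np.zeros((n, n), dtype=bool),
        next_time=np.maximum(cfg.schedule_floor,
                             rng.normal(cfg.init_schedule_mean,
                                        cfg.schedule_sd_frac
                                        * cfg.init_schedule_mean, n)),
        time=0.0,
    )
    # at initialization limits equal the baseline levels, adjusted only for
    # dominant-in-proximity; the satisfaction-dependent restlessness term
    # enters from the first activation on
    refresh_context_limits(state, cfg, restlessness=False)
    return state
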