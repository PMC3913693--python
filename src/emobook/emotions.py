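"""Arousal, anxiety and satisfaction dynamics.

Each emotion variable lives in [0, 1] and moves piecewise-linearly at a
context-specific rate toward a context-specific limit, never overshooting
it.  On top of this continuous dynamic, discrete social events (attacks,
signals, fight outcomes) shift arousal and anxiety instantaneously.

Contexts are mutually exclusive per variable with the precedence
groom-receive > groom-give > dominant-in-proximity > default; receiving
grooming by several partners at once has the same effect as by one.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig

# point-event identifiers
FIGHT_OBSERVED = "fight_observed"
ATTACK_RECEIVED = "attack_received"
ATTACK_GIVEN = "attack_given"
AGGRESSIVE_SIGNAL_RECEIVED = "aggressive_signal_received"
SUBMISSIVE_SIGNAL_RECEIVED = "submissive_signal_received"
AFFILIATIVE_SIGNAL_RECEIVED = "affiliative_signal_received"
FIGHT_WON = "fight_won"
FIGHT_LOST = "fight_lost"

POINT_EVENTS = (FIGHT_OBSERVED, ATTACK_RECEIVED, ATTACK_GIVEN,
                AGGRESSIVE_SIGNAL_RECEIVED, SUBMISSIVE_SIGNAL_RECEIVED,
                AFFILIATIVE_SIGNAL_RECEIVED, FIGHT_WON, FIGHT_LOST)


def point_effect_table(cfg: ModelConfig) -> dict[str, tuple[float, float]]:
    """Instantaneous (arousal delta, anxiety delta) per event type."""
    return {
        FIGHT_OBSERVED: (cfg.ar_fight_observed, cfg.anx_fight_observed),
        ATTACK_RECEIVED: (cfg.ar_attack_received, cfg.anx_attack_received),
        ATTACK_GIVEN: (cfg.ar_attack_given, cfg.anx_attack_given),
        AGGRESSIVE_SIGNAL_RECEIVED: (cfg.ar_aggressive_signal_received,
                                     cfg.anx_aggressive_signal_received),
        SUBMISSIVE_SIGNAL_RECEIVED: (cfg.ar_submissive_signal_received,
                                     cfg.anx_submissive_signal_received),
        AFFILIATIVE_SIGNAL_RECEIVED: (cfg.ar_affiliative_signal_received,
                                      cfg.anx_affiliative_signal_received),
        FIGHT_WON: (0.0, cfg.anx_fight_won),
        FIGHT_LOST: (0.0, cfg.anx_fight_lost),
    }


def apply_point_effect(arousal: float, anxiety: float, event: str,
                       cfg: ModelConfig) -> tuple[float, float]:
    """Apply one discrete event to (arousal, anxiety) and clamp.

    Arousing events cap at 1.0.  Appeasing events (submissive or
    affiliative signals received) bring elevated arousal down toward the
    baseline, but never below it; arousal already at or below baseline is
    unaffected by them.  Anxiety is clamped to [0, 1].
    """
    table = point_effect_table(cfg)
    if event not in table:
        raise ValueError(f"unknown point event: {event!r}")
    da, dx = table[event]
    if da >= 0.0:
        arousal = min(cfg.max_arousal_limit, arousal + da)
    elif arousal > cfg.def_arousal:
        arousal = max(cfg.def_arousal, arousal + da)
    anxiety = float(np.clip(anxiety + dx, 0.0, cfg.max_anxiety))
    return arousal, anxiety


def integrate_toward(level, limit, rate, dt):
    """Move ``level`` toward ``limit`` at ``rate`` per minute for ``dt``
    minutes, saturating at the limit (no overshoot).  Works elementwise on
    arrays; exact for piecewise-constant contexts (semigroup property)."""
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be non-negative")
    step = rate * dt
    diff = limit - level
    return level + np.clip(diff, -step, step)


def context_rates(cfg: ModelConfig, receiving: np.ndarray, giving: np.ndarray,
                  dom_near: np.ndarray, satisfaction: np.ndarray | None = None
                  ) -> tuple[np.ndarray, ...]:
    """Per-agent (ar_limit, ar_rate, anx_limit, anx_rate, sat_limit,
    sat_rate) for the current social context of every agent.

    ``receiving``/``giving`` flag current grooming roles, ``dom_near``
    flags a perceived higher-ranking individual within personal distance.
    Lack of recent affiliation slightly raises the resting arousal level:
    the default arousal limit grows with (1 - satisfaction), which keeps
    unengaged individuals from settling into permanent inactivity.
    """
    n = receiving.shape[0]
    if satisfaction is None:
        ar_limit = np.full(n, cfg.def_arousal)
    else:
        ar_limit = (cfg.def_arousal
                    + cfg.low_sat_arousal_gain * (1.0 - satisfaction))
    ar_rate = np.full(n, cfg.def_ar_rate)
    anx_limit = np.full(n, cfg.def_anxiety)
    anx_rate = np.full(n, cfg.def_anx_dec)
    sat_limit = np.full(n, cfg.def_satisfaction)
    sat_rate = np.full(n, cfg.def_sat_dec)

    m = dom_near & ~receiving & ~giving
    ar_limit[m] = cfg.dom_prox_ar_limit
    ar_rate[m] = cfg.dom_prox_ar_rate
    anx_limit[m] = cfg.dom_prox_anx_limit
    anx_rate[m] = cfg.dom_prox_anx_rate

    g = giving & ~receiving
    ar_limit[g] = cfg.gg_ar_limit
    ar_rate[g] = cfg.gg_ar_rate
    anx_rate[g] = cfg.gg_anx_dec
    sat_limit[g] = cfg.max_satisfaction
    sat_rate[g] = cfg.gg_sat_inc

    r = receiving
    ar_limit[r] = cfg.gr_ar_limit
    ar_rate[r] = cfg.gr_ar_rate
    anx_rate[r] = cfg.gr_anx_dec
    sat_limit[r] = cfg.max_satisfaction
    sat_rate[r] = cfg.gr_sat_inc

    return ar_limit, ar_rate, anx_limit, anx_rate, sat_limit, sat_rate
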