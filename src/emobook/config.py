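"""Model configuration, dominance structure and group initialization.

Every constant of the simulation lives in :class:`ModelConfig`; nothing is
hard-coded in the behavioral logic.  Time is measured in minutes of active
(non-sleeping) day: 12 h = one day, 7 days = one week, 50 weeks = one year.
Space is a 300 m x 300 m torus with continuous coordinates in meters and
headings in degrees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

MINUTES_PER_HOUR = 60
DAY_MINUTES = 720        # 12 active hours
WEEK_MINUTES = 7 * DAY_MINUTES
YEAR_MINUTES = 50 * WEEK_MINUTES


@dataclass
class ModelConfig:
    """All global parameters of the social-group simulation.

    Distances are in meters, times in minutes, rates per minute, angles in
    degrees.  Behavior "probabilities" are relative selection weights: at
    every activation the weights of all eligible (behavior, partner) pairs
    are normalized and one pair is drawn.
    """

    # -- group and world ---------------------------------------------------
    n_agents: int = 20
    world_size: float = 300.0
    init_disc_radius: float = 25.0       # initial positions in a 50 m disc

    # -- timing ------------------------------------------------------------
    day_minutes: int = DAY_MINUTES
    week_days: int = 7
    year_weeks: int = 50
    stabilization_minutes: float = 21600.0
    run_minutes: float = 504000.0
    record_last_minutes: float = 252000.0
    sample_interval_minutes: float = 2520.0  # 3.5 days

    # -- perception and space ----------------------------------------------
    interact_dist: float = 1.0
    pers_dist: float = 5.0
    near_dist: float = 20.0              # grouping criterion distance
    max_dist: float = 50.0
    far_dist: float = 100.0
    min_others: int = 3
    view_angle: float = 120.0
    max_angle: float = 360.0
    max_partners: int = 10

    # -- movement ----------------------------------------------------------
    speed: float = 0.6                   # m/s
    move_step_seconds: float = 3.0
    stop_chance: float = 0.21            # per-step chance to end a bout
    random_walk_turn_chance: float = 0.5

    # -- scheduling --------------------------------------------------------
    schedule_sd_frac: float = 0.05       # SD of schedule times, 5% of mean
    schedule_floor: float = 0.01         # truncation floor, minutes
    init_schedule_mean: float = 1.0
    groom_schedule_mean: float = 7.5
    rest_schedule_mean: float = 5.0
    action_schedule_mean: float = 1.0    # after point behaviors (signals, attacks)
    reaction_delay: float = 0.1          # after received signal / observed fight

    # -- arousal dynamics --------------------------------------------------
    def_arousal: float = 0.09            # baseline level and limit
    max_arousal_limit: float = 1.0
    def_ar_rate: float = 0.02            # default approach rate, per minute
    gg_ar_limit: float = 0.05            # while giving grooming
    gg_ar_rate: float = 0.03
    gr_ar_limit: float = 0.03            # while receiving grooming
    gr_ar_rate: float = 0.05
    dom_prox_ar_limit: float = 0.5       # dominant perceived within pers_dist
    dom_prox_ar_rate: float = 0.02
    low_sat_arousal_gain: float = 0.15   # resting arousal rises as
                                         # satisfaction falls (restlessness)

    # -- anxiety dynamics --------------------------------------------------
    def_anxiety: float = 0.0
    max_anxiety: float = 1.0
    def_anx_dec: float = 0.002
    gg_anx_dec: float = 0.01
    gr_anx_dec: float = 0.02
    dom_prox_anx_limit: float = 0.25
    dom_prox_anx_rate: float = 0.002

    # -- satisfaction dynamics ---------------------------------------------
    def_satisfaction: float = 0.0
    max_satisfaction: float = 1.0
    def_sat_dec: float = 0.02
    gg_sat_inc: float = 0.05
    gr_sat_inc: float = 0.1

    # -- instantaneous (point) emotion effects ------------------------------
    # arousal deltas; aggressive events arouse, signals received appease
    ar_attack_received: float = 0.20
    ar_attack_given: float = 0.10
    ar_fight_observed: float = 0.05
    ar_aggressive_signal_received: float = 0.05
    ar_submissive_signal_received: float = -0.05
    ar_affiliative_signal_received: float = -0.05
    # anxiety deltas
    anx_attack_received: float = 0.10
    anx_attack_given: float = 0.05
    anx_fight_observed: float = 0.025
    anx_aggressive_signal_received: float = 0.025
    anx_submissive_signal_received: float = -0.02
    anx_affiliative_signal_received: float = -0.02
    anx_fight_won: float = -0.05
    anx_fight_lost: float = 0.10

    # -- attitudes -----------------------------------------------------------
    lhw: float = 720.0                   # LIKE-history weight, minutes
    lps: float = 0.0                     # LIKE-partner selectivity, [0, 1]

    # -- action-selection shape parameters -----------------------------------
    aff_motivation_floor: float = 0.3    # m0: affiliation weight at zero motivation
    anxiety_motivation_weight: float = 9.0
    aggr_theta0: float = 0.0             # aggression sigmoid midpoint at anxiety 0
    aggr_theta_anx_shift: float = -0.3   # midpoint at anxiety 1 is theta0 + shift
    aggr_scale0: float = 0.15
    aggr_scale1: float = 0.05
    subm_theta0: float = 0.5
    subm_theta_anx_shift: float = -0.3
    subm_scale: float = 0.15
    avoid_theta0: float = 0.8
    avoid_theta_anx_shift: float = -0.2
    avoid_scale: float = 0.1
    scan_mid: float = 0.62               # logistic scan probability vs arousal
    scan_slope: float = 0.13

    # -- base behavior selection weights -------------------------------------
    gg_prob: float = 1.9                 # groom
    afs_prob: float = 0.35                # affiliative signal
    app_prob: float = 6.5                # approach
    att_prob: float = 1.4               # attack
    ags_prob: float = 2.6               # aggressive signal
    le_prob: float = 0.15                # leave
    ss_prob: float = 0.3                 # submissive signal
    av_prob: float = 0.3                 # avoid
    rndw_prob: float = 0.12              # random walk
    rest_prob: float = 1.15               # rest (not scaled by arousal)

    # -- misc -----------------------------------------------------------------
    win_chance_form: str = "ratio"       # "ratio" or "logistic"
    win_chance_logistic_scale: float = 0.2
    rng_seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on inconsistent parameter settings."""
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if not (self.interact_dist < self.pers_dist < self.near_dist
                < self.max_dist < self.far_dist):
            raise ValueError("distances must satisfy interact < pers < near "
                             "< max < far")
        if not 0.0 <= self.lps <= 1.0:
            raise ValueError("lps must lie in [0, 1]")
        if self.lhw <= 0:
            raise ValueError("lhw must be positive")
        if self.record_last_minutes > self.run_minutes:
            raise ValueError("record_last_minutes cannot exceed run_minutes")
        for name in ("stop_chance", "random_walk_turn_chance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("def_arousal", "max_arousal_limit", "gg_ar_limit",
                     "gr_ar_limit", "dom_prox_ar_limit", "def_anxiety",
                     "max_anxiety", "dom_prox_anx_limit", "def_satisfaction",
                     "max_satisfaction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        rates = ("def_ar_rate", "gg_ar_rate", "gr_ar_rate", "dom_prox_ar_rate",
                 "def_anx_dec", "gg_anx_dec", "gr_anx_dec", "dom_prox_anx_rate",
                 "def_sat_dec", "gg_sat_inc", "gr_sat_inc")
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # anxiety relaxes more slowly than arousal by default
        if not self.def_anx_dec < self.def_ar_rate:
            raise ValueError("default anxiety decay must be slower than the "
                             "default arousal rate")
        if self.win_chance_form not in ("ratio", "logistic"):
            raise ValueError("win_chance_form must be 'ratio' or 'logistic'")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls.from_dict(d)

    # -- convenience ---------------------------------------------------
    @property
    def move_step_minutes(self) -> float:
        return self.move_step_seconds / 60.0

    @property
    def step_length(self) -> float:
        """Meters traveled per movement step."""
        return self.speed * self.move_step_seconds

    @property
    def recording_hours_per_interval(self) -> float:
        return self.sample_interval_minutes / MINUTES_PER_HOUR


def default_config() -> ModelConfig:
    """The standard parameterization: a 20-member group simulated for two
    years (504,000 min) after a four-week stabilization period."""
    cfg = ModelConfig()
    cfg.validate()
    return cfg


def dominance_vector(n: int) -> np.ndarray:
    """Evenly spaced dominance strengths ``i/n`` for ranks ``i = 1..n``.

    The lowest-ranking individual has strength ``1/n``, the highest 1.0.
    Dominance is fixed for the whole run.  Index 0 of the returned array is
    the lowest rank.
    """
    if n < 2:
        raise ValueError("need at least two individuals")
    return np.arange(1, n + 1, dtype=float) / n
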