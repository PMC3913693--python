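"""Behavior-and-partner probabilities and stochastic action selection.

Affiliative weights blend a partner term — a linear mixture of 1 and the
LIKE attitude controlled by the partner-selectivity LPS — with ego's
intrinsic affiliation motivation (anxiety-dominated).  Agonistic weights
are logistic in the FEAR attitude with an anxiety-dependent midpoint and
steepness: anxious individuals aggress less toward similar/higher ranks
but more toward much lower ranks, and submit/avoid at lower thresholds.
Arousal multiplies every non-rest weight, raising general activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import space
from .config import ModelConfig


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def affiliation_motivation(anxiety, satisfaction, anxiety_weight: float = 9.0):
    """Intrinsic affiliation motivation in [0, 1].

    High when anxiety is high or satisfaction low; anxiety is weighted
    ``anxiety_weight`` times more heavily than (lack of) satisfaction.
    """
    return (anxiety_weight * np.asarray(anxiety)
            + (1.0 - np.asarray(satisfaction))) / (anxiety_weight + 1.0)


def p_affiliation(like, motivation, lps, base, m0: float = 0.1):
    """Affiliative selection weight toward a partner.

    ``base * [(1-lps) + lps*like] * [m0 + (1-m0)*motivation]``: at lps = 0
    the LIKE attitude has no effect; the larger lps, the steeper the weight
    rises with LIKE.  ``m0`` keeps a floor so unmotivated affiliation stays
    possible.
    """
    partner_term = (1.0 - lps) + lps * np.asarray(like)
    return base * partner_term * (m0 + (1.0 - m0) * np.asarray(motivation))


def _theta_scale(anxiety, theta0, theta_shift, scale0, scale1):
    theta = theta0 + theta_shift * np.asarray(anxiety)
    scale = scale0 + (scale1 - scale0) * np.asarray(anxiety)
    return theta, scale


def p_aggression(fear, anxiety, base, cfg: ModelConfig | None = None):
    """Aggression weight: a decreasing sigmoid in FEAR.

    With rising anxiety the midpoint shifts left and the slope steepens,
    making aggression more risk-averse toward similar and higher ranks but
    bolder toward much lower ranks.
    """
    cfg = cfg or ModelConfig()
    theta, scale = _theta_scale(anxiety, cfg.aggr_theta0,
                                cfg.aggr_theta_anx_shift,
                                cfg.aggr_scale0, cfg.aggr_scale1)
    return base * sigmoid(-(np.asarray(fear) - theta) / scale)


def p_submission(fear, anxiety, base, cfg: ModelConfig | None = None):
    """Submission weight: increasing sigmoid in FEAR, zero for FEAR <= 0
    (submission is strictly unidirectional, up the hierarchy only)."""
    cfg = cfg or ModelConfig()
    fear = np.asarray(fear, dtype=float)
    theta = cfg.subm_theta0 + cfg.subm_theta_anx_shift * np.asarray(anxiety)
    w = base * sigmoid((fear - theta) / cfg.subm_scale)
    return np.where(fear > 0.0, w, 0.0)


def p_avoidance(fear, anxiety, base, cfg: ModelConfig | None = None):
    """Avoidance weight: like submission but with a far-right threshold, so
    only much-higher-ranking individuals are avoided."""
    cfg = cfg or ModelConfig()
    fear = np.asarray(fear, dtype=float)
    theta = cfg.avoid_theta0 + cfg.avoid_theta_anx_shift * np.asarray(anxiety)
    w = base * sigmoid((fear - theta) / cfg.avoid_scale)
    return np.where(fear > 0.0, w, 0.0)


def p_scan(arousal, cfg: ModelConfig | None = None):
    """Probability to enter scanning when resting: logistic in arousal."""
    cfg = cfg or ModelConfig()
    return sigmoid((np.asarray(arousal) - cfg.scan_mid) / cfg.scan_slope)


@dataclass
class ActionWeights:
    """Non-negative selection weights over (behavior, target) pairs plus the
    partnerless rest and random-walk options."""
    behaviors: list  # list of (behavior, target-or-None)
    weights: np.ndarray

    def normalized(self) -> np.ndarray:
        s = self.weights.sum()
        return self.weights / s if s > 0 else self.weights


_AFFILIATIVE = {space.GROOM: "gg_prob", space.AFFILIATIVE_SIGNAL: "afs_prob",
                space.APPROACH: "app_prob"}
_AGGRESSIVE = {space.ATTACK: "att_prob", space.AGGRESSIVE_SIGNAL: "ags_prob"}
_SUBMISSIVE = {space.LEAVE: "le_prob", space.SUBMISSIVE_SIGNAL: "ss_prob"}


def build_action_weights(cfg: ModelConfig, arousal: float, anxiety: float,
                         satisfaction: float, candidates: np.ndarray,
                         eligibility: list[set[str]], fear_row: np.ndarray,
                         like_row: np.ndarray) -> ActionWeights:
    """Assemble the weight table for one activated individual.

    ``eligibility[k]`` is the behavior set toward ``candidates[k]``;
    ``fear_row``/``like_row`` are ego's attitudes indexed by agent id.
    All social weights and the random-walk weight scale with arousal.
    """
    mot = float(affiliation_motivation(anxiety, satisfaction,
                                       cfg.anxiety_motivation_weight))
    pairs: list[tuple[str, int | None]] = []
    w: list[float] = []
    for k, j in enumerate(candidates):
        elig = eligibility[k]
        if not elig:
            continue
        f = float(fear_row[j])
        lk = float(like_row[j])
        for beh in elig:
            if beh in _AFFILIATIVE:
                base = getattr(cfg, _AFFILIATIVE[beh])
                wt = float(p_affiliation(lk, mot, cfg.lps, base,
                                         cfg.aff_motivation_floor))
            elif beh in _AGGRESSIVE:
                base = getattr(cfg, _AGGRESSIVE[beh])
                wt = float(p_aggression(f, anxiety, base, cfg))
            elif beh in _SUBMISSIVE:
                base = getattr(cfg, _SUBMISSIVE[beh])
                wt = float(p_submission(f, anxiety, base, cfg))
            elif beh == space.AVOID:
                wt = float(p_avoidance(f, anxiety, cfg.av_prob, cfg))
            else:  # pragma: no cover - defensive
                raise ValueError(f"unexpected behavior {beh!r}")
            pairs.append((beh, int(j)))
            w.append(wt)
    weights = np.asarray(w, dtype=float) * arousal
    pairs.append((space.RANDOM_WALK, None))
    weights = np.append(weights, cfg.rndw_prob * arousal)
    pairs.append((space.REST, None))
    weights = np.append(weights, cfg.rest_prob)
    return ActionWeights(pairs, weights)


def select_action(aw: ActionWeights, rng: np.random.Generator
                  ) -> tuple[str, int | None]:
    """Draw one (behavior, target) pair according to the weights; falls back
    to rest if every weight is zero."""
    total = aw.weights.sum()
    if total <= 0.0 or not math.isfinite(total):
        return (space.REST, None)
    u = rng.random() * total
    c = np.cumsum(aw.weights)
    idx = int(np.searchsorted(c, u, side="right"))
    idx = min(idx, len(aw.behaviors) - 1)
    return aw.behaviors[idx]
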