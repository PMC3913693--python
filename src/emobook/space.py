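"""Torus geometry, fields of view, perception and grouping rules.

The world is a square torus; all distances are minimal wrap-around Euclidean
distances and all bearings are computed on the minimal-displacement vector.
A view angle is the full width of the visual cone (120 deg means +/-60 deg
around the heading).
"""

from __future__ import annotations

import numpy as np

# behavior identifiers used across the package
GROOM = "groom"
AFFILIATIVE_SIGNAL = "affiliative_signal"
APPROACH = "approach"
ATTACK = "attack"
AGGRESSIVE_SIGNAL = "aggressive_signal"
LEAVE = "leave"
SUBMISSIVE_SIGNAL = "submissive_signal"
AVOID = "avoid"
REST = "rest"
RANDOM_WALK = "random_walk"

SOCIAL_BEHAVIORS = (GROOM, AFFILIATIVE_SIGNAL, APPROACH, ATTACK,
                    AGGRESSIVE_SIGNAL, LEAVE, SUBMISSIVE_SIGNAL, AVOID)


def torus_delta(p: np.ndarray, q: np.ndarray, world: float) -> np.ndarray:
    """Minimal displacement vector from ``p`` to ``q`` on the torus."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - world * np.round(d / world)

def torus_distance(p, q, world: float) -> float | np.ndarray:
    """Minimal wrap-around Euclidean distance between two points."""
    d = torus_delta(p, q, world)
    return np.sqrt((d * d).sum(axis=-1))

def distance_matrix(pos: np.ndarray, world: float) -> np.ndarray:
    """All pairwise torus distances for an (N, 2) position array."""
    d = pos[None, :, :] - pos[:, None, :]
    d -= world * np.round(d / world)
    return np.sqrt((d * d).sum(axis=-1))

def bearing(p, q, world: float) -> float | np.ndarray:
    """Compass-free bearing (deg, atan2 convention) from ``p`` toward ``q``."""
    d = torus_delta(p, q, world)
    return np.degrees(np.arctan2(d[..., 1], d[..., 0]))

def angle_diff(a, b):
    """Signed smallest difference a - b wrapped into (-180, 180]."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


def perceives_mask(ego: int, pos: np.ndarray, heading: np.ndarray,
                   view: np.ndarray, dist_row: np.ndarray,
                   interact_dist: float, max_dist: float,
                   world: float) -> np.ndarray:
    """Boolean mask of individuals perceived by ``ego``.

    Anyone within ``interact_dist`` is always perceived, regardless of the
    view angle; beyond that, perception requires distance <= ``max_dist``
    and a bearing within ego's current view cone.
    """
    n = pos.shape[0]
    br = bearing(pos[ego], pos, world)
    in_view = np.abs(angle_diff(br, heading[ego])) <= view[ego] / 2.0
    mask = (dist_row <= interact_dist) | ((dist_row <= max_dist) & in_view)
    mask[ego] = False
    return mask


def perceives(ego: int, other: int, pos, heading, view, world: float,
              interact_dist: float, max_dist: float) -> bool:
    """Whether ``ego`` perceives ``other`` (scalar convenience form)."""
    d = float(torus_distance(pos[ego], pos[other], world))
    if other == ego:
        return False
    if d <= interact_dist:
        return True
    if d > max_dist:
        return False
    br = float(bearing(pos[ego], pos[other], world))
    return abs(float(angle_diff(br, heading[ego]))) <= view[ego] / 2.0


def candidate_partners(ego: int, pos, heading, view, dist_row,
                       interact_dist: float, max_dist: float,
                       max_partners: int, world: float) -> np.ndarray:
    """Ids of the nearest perceived individuals, at most ``max_partners``.

    Sorted by ascending distance, ties broken by agent id.  Individuals
    within ``interact_dist`` are always in the candidate set (they are
    always perceived); the cap applies to the union.
    """
    mask = perceives_mask(ego, pos, heading, view, dist_row,
                          interact_dist, max_dist, world)
    ids = np.nonzero(mask)[0]
    if ids.size == 0:
        return ids
    order = np.lexsort((ids, dist_row[ids]))
    return ids[order][:max_partners]


def grouping_needed(ego: int, dist_row: np.ndarray, near_dist: float,
                    far_dist: float, min_others: int) -> bool:
    """Whether ego must rejoin the group.

    True when fewer than ``min_others`` group members are within
    ``near_dist`` (judged at 360 deg) or when any member is farther than
    ``far_dist``.
    """
    others = np.delete(dist_row, ego)
    return bool((others <= near_dist).sum() < min_others
                or others.max() > far_dist)


def eligible_behaviors(dist: float, target_moving: bool, fear_to_target: float,
                       interact_dist: float, pers_dist: float,
                       max_dist: float) -> set[str]:
    """The social behaviors ego may direct at a partner at distance ``dist``.

    Physical interactions (groom, attack) and leaving require contact range;
    signals require ``pers_dist``; approach works up to ``max_dist`` but not
    on partners already in contact range.  A partner executing movement can
    still be approached or avoided but not groomed, attacked or signaled.
    Submissive behaviors (leave, submissive signal, avoid) are strictly
    unidirectional: only toward higher-ranking partners (positive FEAR).
    """
    out: set[str] = set()
    if dist <= max_dist and dist > interact_dist:
        out.add(APPROACH)
    if dist <= pers_dist:
        if fear_to_target > 0.0:
            out.add(AVOID)
        if not target_moving:
            out.add(AFFILIATIVE_SIGNAL)
            out.add(AGGRESSIVE_SIGNAL)
            if fear_to_target > 0.0:
                out.add(SUBMISSIVE_SIGNAL)
    if dist <= interact_dist:
        if not target_moving:
            out.add(GROOM)
            out.add(ATTACK)
        if fear_to_target > 0.0:
            out.add(LEAVE)
    return out
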