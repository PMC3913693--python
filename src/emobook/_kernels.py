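"""Optionally JIT-compiled inner loops of the event loop.

The numpy implementations in :mod:`simulation` are the reference; these
kernels compute exactly the same quantities with explicit loops so numba
can compile them.  When numba is unavailable the pure-Python versions are
used as-is (they are identical code, just not compiled).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def sweep(dt, arousal, ar_limit, ar_rate, anxiety, anx_limit, anx_rate,
          satisfaction, sat_limit, sat_rate, psat, psat_rate, like, lhw):
    """Advance emotions, PARTNER_SAT and LIKE by ``dt`` minutes in place."""
    n = arousal.shape[0]
    w = dt / (lhw + dt)
    for i in range(n):
        step = ar_rate[i] * dt
        diff = ar_limit[i] - arousal[i]
        if diff > step:
            diff = step
        elif diff < -step:
            diff = -step
        arousal[i] += diff
        step = anx_rate[i] * dt
        diff = anx_limit[i] - anxiety[i]
        if diff > step:
            diff = step
        elif diff < -step:
            diff = -step
        anxiety[i] += diff
        step = sat_rate[i] * dt
        diff = sat_limit[i] - satisfaction[i]
        if diff > step:
            diff = step
        elif diff < -step:
            diff = -step
        satisfaction[i] += diff
    for i in range(n):
        cap = satisfaction[i]
        for j in range(n):
            ps = psat[i, j] + psat_rate[i, j] * dt
            if ps < 0.0:
                ps = 0.0
            elif ps > 1.0:
                ps = 1.0
            if ps > cap:
                ps = cap
            psat[i, j] = ps
            lk = like[i, j] + w * (ps - like[i, j])
            if ps > lk:
                lk = ps
            like[i, j] = lk


# indices into the packed action-parameter vector (see Simulation._pack)
P_WORLD, P_INTERACT, P_PERS, P_MAX_DIST, P_MAX_PARTNERS, P_LPS, \
    P_AFF_FLOOR, P_ANX_WEIGHT, P_AG_T0, P_AG_TSH, P_AG_S0, P_AG_S1, \
    P_SU_T0, P_SU_TSH, P_SU_S, P_AV_T0, P_AV_TSH, P_AV_S, \
    P_GG, P_AFS, P_APP, P_ATT, P_AGS, P_LE, P_SS, P_AV, P_RNDW, P_REST \
    = range(28)


@njit(cache=True)
def action_weights(i, pos, heading, view, dist_row, fear_row, like_row,
                   moving, arousal_i, anxiety_i, satisfaction_i, p):
    """Flattened (behavior x candidate) weight table for one activation.

    Returns (ids, weights) where weights has 8 * len(ids) + 2 entries: the
    eight social behaviors per candidate in fixed order, then random-walk
    and rest.  Mirrors the formulas in :mod:`emobook.actions`; ``p`` is the
    packed parameter vector.
    """
    world = p[P_WORLD]
    interact_dist = p[P_INTERACT]
    pers_dist = p[P_PERS]
    max_dist = p[P_MAX_DIST]
    max_partners = int(p[P_MAX_PARTNERS])
    lps = p[P_LPS]
    aff_floor = p[P_AFF_FLOOR]
    anx_weight = p[P_ANX_WEIGHT]
    aggr_theta0 = p[P_AG_T0]
    aggr_theta_shift = p[P_AG_TSH]
    aggr_scale0 = p[P_AG_S0]
    aggr_scale1 = p[P_AG_S1]
    subm_theta0 = p[P_SU_T0]
    subm_theta_shift = p[P_SU_TSH]
    subm_scale = p[P_SU_S]
    avoid_theta0 = p[P_AV_T0]
    avoid_theta_shift = p[P_AV_TSH]
    avoid_scale = p[P_AV_S]
    gg = p[P_GG]
    afs = p[P_AFS]
    app = p[P_APP]
    att = p[P_ATT]
    ags = p[P_AGS]
    le = p[P_LE]
    ss = p[P_SS]
    av = p[P_AV]
    rndw = p[P_RNDW]
    restw = p[P_REST]
    n = pos.shape[0]
    # perception mask
    perc = np.zeros(n, np.bool_)
    bear = np.empty(n)
    for j in range(n):
        if j == i:
            bear[j] = 0.0
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dx -= world * np.round(dx / world)
        dy -= world * np.round(dy / world)
        b = np.degrees(np.arctan2(dy, dx))
        bear[j] = b
        d = dist_row[j]
        if d <= interact_dist:
            perc[j] = True
        elif d <= max_dist:
            off = (b - heading[i] + 180.0) % 360.0 - 180.0
            if abs(off) <= view[i] / 2.0:
                perc[j] = True
    count = int(perc.sum())
    if count == 0:
        ids = np.empty(0, np.int64)
        w = np.empty(2)
        w[0] = rndw * arousal_i
        w[1] = restw
        return ids, w
    ids = np.nonzero(perc)[0]
    if count > max_partners:
        # nearest max_partners, ties by id (stable argsort on distance)
        order = np.argsort(dist_row[ids], kind="mergesort")
        ids = ids[order][:max_partners]
    k = ids.shape[0]
    mot = (anx_weight * anxiety_i + (1.0 - satisfaction_i)) / (anx_weight + 1.0)
    mot_term = aff_floor + (1.0 - aff_floor) * mot
    theta_a = aggr_theta0 + aggr_theta_shift * anxiety_i
    scale_a = aggr_scale0 + (aggr_scale1 - aggr_scale0) * anxiety_i
    theta_s = subm_theta0 + subm_theta_shift * anxiety_i
    theta_v = avoid_theta0 + avoid_theta_shift * anxiety_i
    w = np.zeros(8 * k + 2)
    for m in range(k):
        j = ids[m]
        d = dist_row[j]
        within1 = d <= interact_dist
        within5 = d <= pers_dist
        notmov = not moving[j]
        f = fear_row[j]
        aff = ((1.0 - lps) + lps * like_row[j]) * mot_term
        agg = 1.0 / (1.0 + np.exp((f - theta_a) / scale_a))
        sub = 1.0 / (1.0 + np.exp(-(f - theta_s) / subm_scale))
        avd = 1.0 / (1.0 + np.exp(-(f - theta_v) / avoid_scale))
        # does the receiver see the sender (required for signals)?
        back = (bear[j] + 180.0 - heading[j] + 180.0) % 360.0 - 180.0
        rsees = within1 or abs(back) <= view[j] / 2.0
        contact = within1 and notmov
        sig = within5 and notmov and rsees
        posf = f > 0.0
        if contact:
            w[0 * k + m] = gg * aff
            w[3 * k + m] = att * agg
        if sig:
            w[1 * k + m] = afs * aff
            w[4 * k + m] = ags * agg
            if posf:
                w[6 * k + m] = ss * sub
        if not within1:
            w[2 * k + m] = app * aff
        if within1 and posf:
            w[5 * k + m] = le * sub
        if within5 and posf:
            w[7 * k + m] = av * avd
    for m in range(8 * k):
        w[m] *= arousal_i
    w[8 * k] = rndw * arousal_i
    w[8 * k + 1] = restw
    return ids, w


@njit(cache=True)
def dominant_near(pos, heading, view, dist, dom, world, interact_dist,
                  pers_dist, max_dist):
    """Per-agent flag: a higher-ranking member perceived within pers_dist."""
    n = pos.shape[0]
    out = np.zeros(n, np.bool_)
    for i in range(n):
        for j in range(n):
            if j == i or dist[i, j] > pers_dist or dom[j] <= dom[i]:
                continue
            if dist[i, j] <= interact_dist:
                out[i] = True
                break
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dx -= world * np.round(dx / world)
            dy -= world * np.round(dy / world)
            b = np.degrees(np.arctan2(dy, dx))
            off = (b - heading[i] + 180.0) % 360.0 - 180.0
            if abs(off) <= view[i] / 2.0:
                out[i] = True
                break
    return out


@njit(cache=True)
def accumulate_tallies(dt, grooming, engaged, scanning, moving,
                       groom_min, engaged_min, scan_min, move_min):
    """Add ``dt`` minutes of the current ongoing states to the tallies."""
    n = engaged.shape[0]
    for i in range(n):
        if engaged[i]:
            engaged_min[i] += dt
        if scanning[i]:
            scan_min[i] += dt
        if moving[i]:
            move_min[i] += dt
        for j in range(n):
            if grooming[i, j]:
                groom_min[i, j] += dt


@njit(cache=True)
def update_distance_row(i, pos, dist, world):
    """Refresh row and column ``i`` of the pairwise distance matrix."""
    n = pos.shape[0]
    for j in range(n):
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dx -= world * np.round(dx / world)
        dy -= world * np.round(dy / world)
        d = (dx * dx + dy * dy) ** 0.5
        dist[i, j] = d
        dist[j, i] = d
    dist[i, i] = 0.0
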