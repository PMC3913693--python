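"""Partner-specific attitudes: fixed FEAR and dynamic LIKE.

FEAR_ij = dom_j - dom_i encodes the (stable) dominance relation; it is
exactly antisymmetric and never changes during a run.  LIKE_ij in [0, 1] is
the emotional bookkeeping variable: an exponentially weighted memory of the
satisfaction attributable to grooming received from partner j, tracked via
the partner-attributed satisfaction PARTNER_SAT_ij.
"""

from __future__ import annotations

import numpy as np


def fear(dom_i: float, dom_j: float) -> float:
    """FEAR attitude of i toward j: positive toward higher-ranking."""
    return dom_j - dom_i


def fear_matrix(dom: np.ndarray) -> np.ndarray:
    """Full antisymmetric FEAR matrix; entry [i, j] = dom_j - dom_i."""
    dom = np.asarray(dom, dtype=float)
    return dom[None, :] - dom[:, None]


def update_partner_sat(ps, being_groomed, dt, inc_rate, dec_rate,
                       satisfaction=None):
    """Advance PARTNER_SAT over ``dt`` minutes.

    Rises at ``inc_rate`` (the groomed individual's satisfaction increase
    rate) while the partner grooms ego, otherwise decays at ``dec_rate``;
    clamped to [0, 1] and never above ego's own general satisfaction.
    Elementwise over arrays.
    """
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be non-negative")
    rate = np.where(being_groomed, inc_rate, -dec_rate)
    out = np.clip(ps + rate * dt, 0.0, 1.0)
    if satisfaction is not None:
        out = np.minimum(out, satisfaction)
    return out


def update_like(like, ps, dt, lhw):
    """One sweep of the LIKE update.

    If the current partner-attributed satisfaction exceeds LIKE, LIKE jumps
    up to it instantly.  Otherwise LIKE relaxes toward it as the weighted
    combination (lhw * like + dt * ps) / (lhw + dt): with ps = 0 a single
    update over dt = lhw halves LIKE, which makes lhw the nominal half-life
    of an unmaintained attitude.  Elementwise over arrays.
    """
    if lhw <= 0:
        raise ValueError("lhw must be positive")
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be non-negative")
    like = np.asarray(like, dtype=float)
    ps = np.asarray(ps, dtype=float)
    decayed = like + (dt / (lhw + dt)) * (ps - like)
    out = np.where(ps > like, ps, decayed)
    if out.ndim == 0:
        return float(out)
    return out
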