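"""Group-level statistics: up/down hierarchy index, row-wise Kendall
matrix reciprocity, Shannon evenness of grooming partners, rank and
rank-distance category contrasts, and paired t-tests across runs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

SIMILAR_RANK_THRESHOLD = 0.35


def updown_index(matrix: np.ndarray, dom: np.ndarray) -> float:
    """Mean individual up/down index of a directed behavior-rate matrix.

    For each individual (excluding the top- and bottom-ranked), up_i is the
    rate directed at higher-ranking members divided by their number, down_i
    the same for lower-ranking members; the index is up/(up+down), averaged
    over individuals with a nonzero denominator.  0.5 means no rank bias,
    1.0 strictly up-hierarchy.
    """
    m = np.asarray(matrix, dtype=float)
    dom = np.asarray(dom, dtype=float)
    n = dom.shape[0]
    if n < 3:
        raise ValueError("need at least three individuals")
    order = np.argsort(dom)
    lowest, highest = order[0], order[-1]
    vals = []
    for i in range(n):
        if i == lowest or i == highest:
            continue
        hi = dom > dom[i]
        lo = dom < dom[i]
        up = m[i, hi].sum() / hi.sum()
        down = m[i, lo].sum() / lo.sum()
        if up + down > 0:
            vals.append(up / (up + down))
    if not vals:
        raise ValueError("all included individuals have zero rates")
    return float(np.mean(vals))


def _row_kendall_terms(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall concordance S and its tie-corrected maximum for one row pair."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    s = float((dx[iu] * dy[iu]).sum())
    n0 = iu[0].size
    tx = n0 - float(np.abs(dx[iu]).sum())
    ty = n0 - float(np.abs(dy[iu]).sum())
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return s, float(denom)


def tau_rw(matrix: np.ndarray) -> float:
    """Row-wise Kendall matrix correlation between a matrix and its
    transpose (dyadic reciprocity at group level).

    For each actor row the Kendall S statistic between given and received
    values over all partners is computed with tau-b tie correction; the
    group statistic is sum(S_i) / sum(max|S_i|).  Rows with all-tied values
    contribute zero to both sums; a fully tied matrix is undefined (NaN).
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least a 3x3 matrix")
    mask = ~np.eye(n, dtype=bool)
    s_sum = 0.0
    d_sum = 0.0
    for i in range(n):
        x = m[i][mask[i]]
        y = m[:, i][mask[i]]
        s, d = _row_kendall_terms(x, y)
        if d > 0:
            s_sum += s
            d_sum += d
    if d_sum == 0.0:
        return float("nan")
    return s_sum / d_sum


def shannon_evenness(row: np.ndarray, n_partners: int | None = None) -> float:
    """Buzas-Gibson evenness of one actor's grooming distribution.

    H = -sum p ln p over the actor's positive grooming shares; the evenness
    index is e^H divided by the number of possible partners, so 1 means
    grooming spread equally over every partner and 1/n_partners means a
    single exclusive partner.
    """
    row = np.asarray(row, dtype=float)
    if n_partners is None:
        n_partners = row.size
    total = row.sum()
    if total <= 0:
        raise ValueError("row sum must be positive")
    p = row[row > 0] / total
    h = float(-(p * np.log(p)).sum())
    return float(np.exp(h)) / n_partners


def group_shannon_evenness(matrix: np.ndarray) -> float:
    """Mean evenness over all individuals with positive grooming output;
    the number of possible partners is N-1."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = [shannon_evenness(m[i][mask[i]], n - 1)
            for i in range(n) if m[i][mask[i]].sum() > 0]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def rank_categories(dom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (subordinates, dominants): the lower- and higher-
    ranking halves of the group (floor/ceil split for odd sizes)."""
    dom = np.asarray(dom, dtype=float)
    n = dom.shape[0]
    order = np.argsort(dom)
    sub = np.zeros(n, dtype=bool)
    sub[order[: n // 2]] = True
    return sub, ~sub


def dyad_categories(dom: np.ndarray,
                    threshold: float = SIMILAR_RANK_THRESHOLD
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (N, N) masks (similar, distant) over directed dyads,
    diagonal excluded: similar means |dom_i - dom_j| < threshold."""
    dom = np.asarray(dom, dtype=float)
    diff = np.abs(dom[:, None] - dom[None, :])
    off = ~np.eye(dom.shape[0], dtype=bool)
    return (diff < threshold) & off, (diff >= threshold) & off


def rank_split_means(values: np.ndarray, dom: np.ndarray
                     ) -> tuple[float, float]:
    """(subordinate mean, dominant mean) of a per-individual measure."""
    sub, domi = rank_categories(dom)
    v = np.asarray(values, dtype=float)
    return float(v[sub].mean()), float(v[domi].mean())


def dyad_split_means(matrix: np.ndarray, dom: np.ndarray,
                     threshold: float = SIMILAR_RANK_THRESHOLD
                     ) -> tuple[float, float]:
    """(similar-ranking mean, distant-ranking mean) of a dyadic measure
    over directed dyads."""
    sim, dist = dyad_categories(dom, threshold)
    m = np.asarray(matrix, dtype=float)
    return float(m[sim].mean()), float(m[dist].mean())


def paired_t(values_a, values_b, alpha: float = 0.05
             ) -> tuple[float, float, str]:
    """Paired t-test with a direction label at the given significance
    level: 'A>B', 'A<B' or 'NS'."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0, "NS"
        # constant nonzero shift: a degenerate but unambiguous difference
        sign = float(np.sign(diff.mean()))
        return sign * np.inf, 0.0, "A>B" if sign > 0 else "A<B"
    t, p = sps.ttest_rel(a, b)
    direction = "NS"
    if p < alpha:
        direction = "A>B" if t > 0 else "A<B"
    return float(t), float(p), direction
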