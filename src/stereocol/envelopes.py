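"""Global rank envelopes and extreme-rank-length p-values for functional statistics.

A global envelope test asks whether an observed curve T₀ is extreme within a
reference family {T₁, …, T_m} (CSR simulations or label permutations). For
each argument j the two-sided pointwise rank of curve i is the smaller of its
rank from below and from above among all m+1 curves. Curves are then ordered
by the extreme rank length (ERL): each curve is summarised by its vector of
pointwise ranks sorted in increasing order and compared lexicographically
(smaller = more extreme), which breaks the heavy rank ties that occur when
many curves coincide (e.g. K̂ ≡ 0 at small radii).

The Monte-Carlo p-value is the fraction of curves at least as ERL-extreme as
the observed one, the observed curve included, so the test is exact under
exchangeability. The level-α global envelope is induced by the same
ordering: the ⌊α(m+1)⌋ most extreme curves are set aside and the envelope is
the pointwise min/max of the remaining curves, making "the observed curve
exits the envelope" agree with p ≤ α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["GlobalEnvelope", "global_rank_envelope"]


@dataclass
class GlobalEnvelope:
    """Result of a global rank envelope test.

    ``lo``/``hi`` bound the envelope pointwise; ``p_value`` is the
    extreme-rank-length Monte-Carlo p of the first curve (the observed one);
    ``k`` is the envelope order actually used.
    """

    lo: np.ndarray
    hi: np.ndarray
    p_value: float
    n_trimmed: int
    level: float
    n_curves: int

    def exits(self, curve: np.ndarray) -> bool:
        c = np.asarray(curve, dtype=float)
        return bool(np.any(c < self.lo - 1e-12) or np.any(c > self.hi + 1e-12))


def _pointwise_two_sided_ranks(curves: np.ndarray) -> np.ndarray:
    """(m, p) matrix of two-sided pointwise ranks (1 = most extreme)."""
    lo = rankdata(curves, axis=0, method="min")
    hi = rankdata(-curves, axis=0, method="min")
    return np.minimum(lo, hi)


def _erl_order(ranks: np.ndarray) -> np.ndarray:
    """Number of curves at-least-as-extreme (ERL lexicographic) per curve."""
    sorted_ranks = np.sort(ranks, axis=1)
    m = sorted_ranks.shape[0]
    # lexicographic order over sorted rank vectors
    order = np.lexsort(sorted_ranks.T[::-1])
    out = np.empty(m, dtype=int)
    # position in the extreme-first ordering; ties share the larger count
    pos = np.empty(m, dtype=int)
    pos[order] = np.arange(m)
    sr = sorted_ranks[order]
    # group identical rows so tied curves get identical counts
    new_group = np.any(sr[1:] != sr[:-1], axis=1)
    group_id = np.concatenate([[0], np.cumsum(new_group)])
    # count of curves in groups up to and including each group
    counts = np.bincount(group_id)
    cum = np.cumsum(counts)
    out[order] = cum[group_id]
    return out


def global_rank_envelope(curves: np.ndarray, level: float = 0.95) -> GlobalEnvelope:
    """Build a level-``level`` global rank envelope from curves (row 0 = observed).

    ``curves`` has shape (m, p): the observed curve followed by m−1 reference
    curves on a common grid.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need a 2D array with the observed plus reference curves")
    m = curves.shape[0]
    alpha = 1.0 - level
    if m < int(np.ceil(1.0 / alpha)):
        raise ValueError(f"too few curves ({m}) for a level-{level:.2f} envelope")
    ranks = _pointwise_two_sided_ranks(curves)
    n_extreme = _erl_order(ranks)
    p = float(n_extreme[0]) / m
    # ERL-induced envelope: drop the floor(alpha*m) most extreme curves
    # (whole tie groups stay together since tied curves share n_extreme)
    allowed = int(np.floor(alpha * m))
    keep = n_extreme > allowed
    if not np.any(keep):  # pathological: everything tied — keep all
        keep[:] = True
    kept = curves[keep]
    lo, hi = kept.min(axis=0), kept.max(axis=0)
    return GlobalEnvelope(lo=lo, hi=hi, p_value=p, n_trimmed=int(m - keep.sum()),
                          level=level, n_curves=m)
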