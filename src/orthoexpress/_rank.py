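"""Shared rank/AUROC primitives.

All AUROCs in this package reduce to rank statistics with the mid-rank
(Mann-Whitney) tie convention, so they live in one place.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auroc_from_rank", "mann_whitney_auroc", "rank_rows", "rank_cols"]


def auroc_from_rank(r: float, n: int) -> float:
    """Convert an ascending rank among ``n`` candidates to an AUROC.

    The candidate ranked last (``r == n``, i.e. the largest score) maps to
    1.0, the candidate ranked first to 0.0, and the middle rank to 0.5:
    ``(r - 1) / (n - 1)``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 candidates to rank, got n={n}")
    if not (1 <= r <= n):
        raise ValueError(f"rank r={r} outside 1..{n}")
    return (r - 1.0) / (n - 1.0)


def mann_whitney_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUROC of positive vs negative score groups with mid-rank ties.

    Equals U / (n_pos * n_neg) for the Mann-Whitney U statistic.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        return np.nan
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def rank_rows(m: np.ndarray) -> np.ndarray:
    """Mid-ranks along each row; NaNs are first replaced by the row median
    of the finite entries, so undefined scores land on the median rank."""
    m = np.array(m, dtype=float)
    nan_mask = ~np.isfinite(m)
    if nan_mask.any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            med = np.nanmedian(np.where(nan_mask, np.nan, m), axis=1)
        # a fully-NaN row has no median; use 0 (every entry ties)
        med = np.where(np.isfinite(med), med, 0.0)
        m[nan_mask] = np.broadcast_to(med[:, None], m.shape)[nan_mask]
    return rankdata(m, axis=1)


def rank_cols(m: np.ndarray) -> np.ndarray:
    return rank_rows(np.asarray(m).T).T
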