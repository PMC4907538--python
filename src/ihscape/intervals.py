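"""Sorted-interval primitives used throughout the pipeline.

All coordinates are 0-based, half-open (BED convention). Interval sets on a
single chromosome are represented as a pair of equal-length integer arrays
``(starts, ends)``. The :class:`Coverage` structure precomputes prefix sums
over a merged set so that "covered basepairs below position x" is a single
``searchsorted``; the permutation test issues millions of such queries per
second against a fixed track, which is why these primitives are array-based
rather than object-per-interval.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "intersect_length", "Coverage"]


def merge_intervals(starts, ends):
    """Union of an interval set: sorted, non-overlapping, non-abutting.

    Parameters
    ----------
    starts, ends : array-like of int
        Interval bounds, half-open, in any order; may overlap or touch.

    Returns
    -------
    (starts, ends) : pair of int64 arrays
        The merged set, sorted by start.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(ends <= starts):
        raise ValueError("empty or inverted interval (end <= start)")
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # an interval opens a new merged block iff it starts beyond the running max end
    running_end = np.maximum.accumulate(ends)
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > running_end[:-1]
    block_id = np.cumsum(new_block) - 1
    out_starts = starts[new_block]
    out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    del block_id
    return out_starts, out_ends


class Coverage:
    """Prefix-sum coverage of a *merged* interval set on one chromosome.

    ``covered_before(x)`` returns the number of covered basepairs in ``[0, x)``
    and vectorises over ``x``; ``overlap(starts, ends)`` gives the per-interval
    intersection length with the set.
    """

    __slots__ = ("starts", "ends", "_cum", "total")

    def __init__(self, starts, ends, merged: bool = False):
        if not merged:
            starts, ends = merge_intervals(starts, ends)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        lengths = self.ends - self.starts
        self._cum = np.concatenate(([0], np.cumsum(lengths)))
        self.total = int(self._cum[-1])

    def covered_before(self, x):
        """Covered bp in [0, x); x may be scalar or array."""
        x = np.asarray(x, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros_like(x)
        j = np.searchsorted(self.starts, x, side="right")
        base = self._cum[j]
        # only the block immediately left of x can extend past it (merged set)
        prev = j - 1
        has_prev = prev >= 0
        excess = np.where(
            has_prev,
            np.clip(self.ends[np.maximum(prev, 0)] - x, 0, None),
            0,
        )
        return base - excess

    def overlap(self, starts, ends):
        """Intersection length of each query interval with the covered set."""
        return self.covered_before(ends) - self.covered_before(starts)


def intersect_length(a_starts, a_ends, b_starts, b_ends) -> int:
    """Total bp in the intersection of two interval sets on one chromosome.

    Both sets are merged internally, so overlapping input intervals are not
    double-counted (length accounting over sets, not multisets).
    """
    a_starts, a_ends = merge_intervals(a_starts, a_ends)
    if a_starts.size == 0:
        return 0
    cov = Coverage(b_starts, b_ends)
    if cov.total == 0:
        return 0
    return int(cov.overlap(a_starts, a_ends).sum())
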