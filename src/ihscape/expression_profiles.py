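"""Expression breadth and magnitude by chromatin class.

Transcripts are attached to chromatin classes by the base containing their
TSS (half-open intervals, so a TSS exactly on a domain boundary belongs to
the domain starting there). A gene counts as expressed in a tissue when its
RPKM exceeds 3 strictly; RPKM <= 3 is silent, consistent with the FlyBase
"very low" band. Breadth is the number of tissues in which a gene is
expressed. Per-class summaries report quartiles with whiskers at the 12.5th
and 87.5th percentiles, the convention used for the published box summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RPKM_THRESHOLD = 3.0


def assign_tss_class(
    transcripts: pd.DataFrame, class_intervals: pd.DataFrame
) -> pd.Series:
    """Class label per transcript from the interval containing its TSS.

    ``transcripts`` needs columns ``chrom`` and ``tss``; ``class_intervals``
    needs ``chrom, start, end, class`` with non-overlapping intervals per
    chromosome. A TSS covered by no interval (residual gap) is labelled
    ``unassigned``.
    """
    labels = pd.Series("unassigned", index=transcripts.index, dtype=object)
    for chrom, sub in class_intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        cls = sub["class"].to_numpy(dtype=object)
        tq = transcripts[transcripts["chrom"] == chrom]
        if tq.empty:
            continue
        pos = tq["tss"].to_numpy(np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.maximum(j, 0)])
        labels.loc[tq.index[inside]] = cls[j[inside]]
    return labels


def tss_position(start: int, end: int, strand: str) -> int:
    """TSS base of a transcript span: start for '+', end-1 for '-'."""
    return int(start) if strand == "+" else int(end) - 1


def expression_breadth(
    rpkm: pd.DataFrame, threshold: float = RPKM_THRESHOLD
) -> pd.Series:
    """Tissues-expressed count per row (strictly RPKM > threshold)."""
    return (rpkm > threshold).sum(axis=1)


def expression_quartiles(values) -> dict:
    """Q1/Q2/Q3 plus 12.5th/87.5th-percentile whiskers (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty class: quartiles undefined")
    q = np.percentile(values, [12.5, 25, 50, 75, 87.5], method="linear")
    return {
        "whisker_low": float(q[0]),
        "q1": float(q[1]),
        "q2": float(q[2]),
        "q3": float(q[3]),
        "whisker_high": float(q[4]),
        "n": int(values.size),
    }


def summarize_by_class(
    transcripts: pd.DataFrame,
    rpkm: pd.DataFrame,
    class_labels: pd.Series,
    threshold: float = RPKM_THRESHOLD,
) -> pd.DataFrame:
    """Per-class breadth and expression-magnitude summary.

    ``rpkm`` is indexed like ``transcripts`` with one column per tissue.
    Magnitude is the per-transcript RPKM summed over tissues.
    """
    breadth = expression_breadth(rpkm, threshold)
    magnitude = rpkm.sum(axis=1)
    rows = []
    for cls, idx in class_labels.groupby(class_labels).groups.items():
        b = expression_quartiles(breadth.loc[idx])
        m = expression_quartiles(magnitude.loc[idx])
        row = {"class": cls, "n_transcripts": len(idx), "median_breadth": b["q2"]}
        row.update({f"breadth_{k}": v for k, v in b.items() if k != "n"})
        row.update({f"rpkm_sum_{k}": v for k, v in m.items() if k != "n"})
        rows.append(row)
    return pd.DataFrame(rows)
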