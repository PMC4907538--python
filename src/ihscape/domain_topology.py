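"""Contact topology between chromatin states and border/internal malachite.

Two questions about domain arrangement:

* which states abut which — the contact (adjacency) matrix over consecutive
  merged domains, optionally looking across short residual gaps; and
* which malachite domains sit at the edge of an IH band (border malachite, the
  transition zone toward the flanking interband) versus inside it (internal
  malachite, embedded in ruby).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chromatin_map import STATES, GenomeMap, clip_to_regions

CONTACT_STATES = STATES


def contact_matrix(
    gm: GenomeMap, gap_mode: str = "opaque", max_span: int | None = None
) -> pd.DataFrame:
    """Adjacency counts between states of consecutive merged domains.

    ``gap_mode='opaque'`` counts only directly abutting domains
    (``end == next start``); residual gaps, being runs of unassignable
    sequence longer than the fill rule tolerates, break adjacency.
    ``gap_mode='transparent'`` additionally counts pairs separated only by a
    gap of at most ``max_span`` bp. The matrix is symmetric; each unordered
    contact increments both off-diagonal cells (diagonal contacts can arise
    only in transparent mode, across a gap).
    """
    if gm.domains is None:
        raise ValueError("contact_matrix requires merged domains")
    if gap_mode not in ("opaque", "transparent"):
        raise ValueError(f"unknown gap_mode: {gap_mode!r}")
    if gap_mode == "transparent" and max_span is None:
        raise ValueError("transparent mode requires max_span")

    mat = pd.DataFrame(
        np.zeros((len(CONTACT_STATES), len(CONTACT_STATES)), dtype=np.int64),
        index=CONTACT_STATES,
        columns=CONTACT_STATES,
    )
    for _, sub in gm.domains.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        states = sub["state"].to_numpy(dtype=object)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(sub) < 2:
            continue
        sep = starts[1:] - ends[:-1]
        if gap_mode == "opaque":
            touching = sep == 0
        else:
            touching = sep <= max_span
        for a, b in zip(states[:-1][touching], states[1:][touching]):
            mat.loc[a, b] += 1
            if a != b:
                mat.loc[b, a] += 1
    return mat


def classify_malachite(
    domains: pd.DataFrame,
    ih_regions: pd.DataFrame,
    min_overlap: int = 1,
    border_tolerance: int = 0,
) -> pd.DataFrame:
    """Label each malachite domain overlapping an IH region border/internal.

    A domain is *border* iff its (whole, unclipped) span touches or crosses a
    region boundary coordinate, i.e. ``start - tol <= boundary <= end + tol``
    for either boundary; otherwise *internal*. Every malachite domain
    overlapping a region receives exactly one label.
    """
    mala = domains[domains["state"] == "malachite"]
    clipped = clip_to_regions(mala, ih_regions, min_overlap=min_overlap)
    if clipped.empty:
        return clipped.assign(label=pd.Series(dtype=str))
    reg = ih_regions.set_index("name")
    rs = reg.loc[clipped["region"], "start"].to_numpy()
    re_ = reg.loc[clipped["region"], "end"].to_numpy()
    ds = clipped["parent_start"].to_numpy() - border_tolerance
    de = clipped["parent_end"].to_numpy() + border_tolerance
    touches_start = (ds <= rs) & (rs <= de)
    touches_end = (ds <= re_) & (re_ <= de)
    label = np.where(touches_start | touches_end, "border", "internal")
    return clipped.assign(label=label)


def labeled_intervals(
    domains: pd.DataFrame,
    ih_regions: pd.DataFrame,
    min_overlap: int = 1,
    border_tolerance: int = 0,
) -> pd.DataFrame:
    """Whole-domain intervals with malachite split into border/internal.

    Returns ``chrom, start, end, class`` where malachite domains overlapping
    an IH region become ``malachite_border`` / ``malachite_internal`` and all
    other domains keep their state name. The class set partitions the mapped
    (non-gap) genome, suitable for TSS assignment.
    """
    out = domains[["chrom", "start", "end"]].copy()
    out["class"] = domains["state"].to_numpy()
    labels = classify_malachite(
        domains, ih_regions, min_overlap=min_overlap,
        border_tolerance=border_tolerance,
    )
    if not labels.empty:
        # a straddling domain labelled in two regions: border wins
        lab = (
            labels.sort_values("label")  # "border" < "internal"
            .drop_duplicates(["chrom", "parent_start", "parent_end"])
            .set_index(["chrom", "parent_start", "parent_end"])["label"]
        )
        key = pd.MultiIndex.from_arrays(
            [domains["chrom"], domains["start"], domains["end"]]
        )
        hit = key.isin(lab.index)
        out.loc[hit, "class"] = [
            f"malachite_{lab.loc[k]}" for k in key[hit]
        ]
    return out


def domain_stats(
    domains: pd.DataFrame,
    state: str,
    regions: pd.DataFrame | None = None,
    clipped: bool = False,
    min_overlap: int = 1,
) -> dict:
    """Count / mean / median length / total bp of one state's domains.

    With ``regions``, restricts to domains overlapping the regions;
    ``clipped`` selects whether lengths are measured on the clipped segments
    or the whole parent domains.
    """
    sel = domains[domains["state"] == state]
    n_regions = None
    if regions is not None:
        cl = clip_to_regions(sel, regions, min_overlap=min_overlap)
        n_regions = int(cl["region"].nunique())
        if clipped:
            lengths = (cl["end"] - cl["start"]).to_numpy()
        else:
            # a domain straddling two regions is still one domain
            uniq = cl.drop_duplicates(["chrom", "parent_start", "parent_end"])
            lengths = (uniq["parent_end"] - uniq["parent_start"]).to_numpy()
    else:
        lengths = (sel["end"] - sel["start"]).to_numpy()
    count = int(lengths.size)
    return {
        "state": state,
        "count": count,
        "mean_length": float(np.mean(lengths)) if count else float("nan"),
        "median_length": float(np.median(lengths)) if count else float("nan"),
        "total_bp": int(lengths.sum()),
        "n_regions": n_regions,
        "defined": count > 0,
    }
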