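"""Replication-timing profiles per chromatin class and the IH border gradient.

Timing probes carry a signed score (positive = early, negative = late
replication). A probe joins a chromatin class when that class's domains
cover at least half of it (``min_frac=0.5``, inclusive). Per-class score
histograms use 0.5-wide bins normalised to unit mass. Inside an IH region,
late-replicating bands replicate from the flanks inward, so timing should
fall with distance from the nearest region border; :func:`border_gradient`
quantifies this with a Spearman rank correlation and a least-squares slope
of score against border distance (kb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Coverage, merge_intervals


def assign_probe_class(
    probes: pd.DataFrame, domains: pd.DataFrame, min_frac: float = 0.5
) -> pd.Series:
    """Class per probe: the state covering >= ``min_frac`` of its length.

    At most one class can exceed half a probe strictly; at exactly 50/50 the
    tie breaks to the larger overlap first, then state order in ``domains``.
    Probes not reaching the threshold in any class are ``unassigned``.
    """
    states = list(dict.fromkeys(domains["state"]))
    labels = pd.Series("unassigned", index=probes.index, dtype=object)
    best = pd.Series(0.0, index=probes.index)
    lengths = (probes["end"] - probes["start"]).astype(float)
    for state in states:
        sub = domains[domains["state"] == state]
        covs = {
            chrom: Coverage(
                *merge_intervals(g["start"].to_numpy(), g["end"].to_numpy()),
                merged=True,
            )
            for chrom, g in sub.groupby("chrom", sort=False)
        }
        for chrom, pq in probes.groupby("chrom", sort=False):
            cov = covs.get(chrom)
            if cov is None:
                continue
            ov = cov.overlap(
                pq["start"].to_numpy(np.int64), pq["end"].to_numpy(np.int64)
            )
            frac = ov / lengths.loc[pq.index].to_numpy()
            take = (frac >= min_frac) & (frac > best.loc[pq.index].to_numpy())
            labels.loc[pq.index[take]] = state
            best.loc[pq.index[take]] = frac[take]
    return labels


def bin_timing_scores(
    scores_by_class: dict, width: float = 0.5
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-class timing-score histograms on shared bins of the given width.

    Bin edges are aligned to multiples of ``width`` and span the pooled score
    range. Densities are normalised to sum to 1 within each class.
    """
    nonempty = {k: np.asarray(v, float) for k, v in scores_by_class.items()}
    for k, v in nonempty.items():
        if v.size == 0:
            raise ValueError(f"empty class: {k!r}")
    allscores = np.concatenate(list(nonempty.values()))
    lo = np.floor(allscores.min() / width) * width
    hi = np.ceil(allscores.max() / width) * width
    if hi <= lo:
        hi = lo + width
    edges = np.arange(lo, hi + width / 2, width)
    rows = []
    for cls, v in nonempty.items():
        counts, _ = np.histogram(v, bins=edges)
        dens = counts / counts.sum()
        for i, d in enumerate(dens):
            rows.append(
                {
                    "class": cls,
                    "bin_lo": edges[i],
                    "bin_hi": edges[i + 1],
                    "count": int(counts[i]),
                    "density": float(d),
                }
            )
    return edges, pd.DataFrame(rows)


def border_gradient(probes: pd.DataFrame, region) -> dict:
    """Timing-vs-border-distance statistics for probes inside one IH region.

    Distance is from the probe midpoint to the nearest region border, in kb;
    the slope is the least-squares coefficient of score on distance (units:
    score per kb), with its standard error, plus the Spearman correlation.
    Fewer than 3 probes inside the region leaves the statistics undefined
    (``defined=False``).
    """
    start, end = int(region["start"]), int(region["end"])
    chrom = region["chrom"]
    inside = probes[
        (probes["chrom"] == chrom)
        & (probes["start"] >= start)
        & (probes["end"] <= end)
    ]
    mid = (inside["start"].to_numpy(float) + inside["end"].to_numpy(float)) / 2.0
    dist_kb = np.minimum(mid - start, end - mid) / 1000.0
    scores = inside["score"].to_numpy(float)
    out = {
        "region": region.get("name", ""),
        "n_probes": int(len(inside)),
        "defined": len(inside) >= 3,
        "spearman_rho": np.nan,
        "spearman_p": np.nan,
        "slope_per_kb": np.nan,
        "slope_se": np.nan,
        "intercept": np.nan,
    }
    if not out["defined"]:
        return out
    if np.ptp(scores) == 0 or np.ptp(dist_kb) == 0:
        out.update(spearman_rho=0.0, spearman_p=1.0, slope_per_kb=0.0, slope_se=0.0,
                   intercept=float(scores.mean()))
        return out
    rho, p = stats.spearmanr(dist_kb, scores)
    fit = stats.linregress(dist_kb, scores)
    out.update(
        spearman_rho=float(rho),
        spearman_p=float(p),
        slope_per_kb=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
    )
    return out
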