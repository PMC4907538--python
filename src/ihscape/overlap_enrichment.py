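"""Overlap accounting: profiles against reference partitions, density ratios
against annotation tracks, and scored-peak densities per chromatin state.

Tracks (insulator-protein enrichment regions, enhancers, HCNEs, polymerase
peaks) are unioned before any length accounting so overlapping ChIP regions
are not double-counted. "Overlap" between a query fragment and a track
interval means an intersection of at least 1 bp unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import Coverage, merge_intervals

MB = 1_000_000


def _per_chrom_arrays(df: pd.DataFrame):
    for chrom, sub in df.groupby("chrom", sort=False):
        yield chrom, sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)


def merge_track(track: pd.DataFrame) -> pd.DataFrame:
    """Union of a track's intervals per chromosome."""
    rows = []
    for chrom, s, e in _per_chrom_arrays(track):
        ms, me = merge_intervals(s, e)
        rows.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def total_length(df: pd.DataFrame) -> int:
    return int((df["end"] - df["start"]).sum()) if len(df) else 0


def overlap_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total bp in the intersection of two interval sets (both unioned)."""
    covs = {
        chrom: Coverage(*merge_intervals(s, e), merged=True)
        for chrom, s, e in _per_chrom_arrays(b)
    }
    total = 0
    for chrom, s, e in _per_chrom_arrays(a):
        cov = covs.get(chrom)
        if cov is None or cov.total == 0:
            continue
        ms, me = merge_intervals(s, e)
        total += int(cov.overlap(ms, me).sum())
    return total


def overlap_profile(query: pd.DataFrame, partition: pd.DataFrame) -> pd.DataFrame:
    """Fraction of query bp in each class of a genome partition.

    Partition classes must be non-overlapping (column ``class``); bp of the
    query falling in none of them is reported as ``unannotated``. Fractions
    sum to 1.
    """
    classes = list(dict.fromkeys(partition["class"]))
    query_bp = total_length(merge_track(query))
    rows = []
    accounted = 0
    for cls in classes:
        sub = partition[partition["class"] == cls]
        bp = overlap_length(query, sub[["chrom", "start", "end"]])
        accounted += bp
        rows.append({"class": cls, "bp": bp})
    rows.append({"class": "unannotated", "bp": query_bp - accounted})
    out = pd.DataFrame(rows)
    out["fraction"] = out["bp"] / query_bp if query_bp else 0.0
    return out


def density_ratio(
    query: pd.DataFrame,
    track: pd.DataFrame,
    expected_fraction: float | None = None,
    null_mean_overlap: float | None = None,
    genome_bp: int | None = None,
) -> dict:
    """Observed / expected track coverage fraction within a query class.

    observed fraction = (track bp within query) / (query bp). The expected
    fraction comes from, in order of preference: an explicit value, the mean
    overlap of the shuffle null divided by query bp, or the track's
    genome-wide density (track bp / genome bp).
    """
    query_bp = total_length(merge_track(query))
    if query_bp == 0:
        raise ValueError("query has zero length")
    track = merge_track(track)
    obs = overlap_length(query, track) / query_bp
    if expected_fraction is None:
        if null_mean_overlap is not None:
            expected_fraction = null_mean_overlap / query_bp
        elif genome_bp is not None:
            expected_fraction = total_length(track) / genome_bp
        else:
            raise ValueError(
                "provide expected_fraction, null_mean_overlap or genome_bp"
            )
    ratio = obs / expected_fraction if expected_fraction > 0 else np.inf if obs else 0.0
    return {
        "observed_fraction": obs,
        "expected_fraction": expected_fraction,
        "ratio": ratio,
        "query_bp": query_bp,
    }


def peaks_overlapping(query: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean mask over ``peaks`` rows: >=1 bp intersection with query."""
    covs = {
        chrom: Coverage(*merge_intervals(s, e), merged=True)
        for chrom, s, e in _per_chrom_arrays(query)
    }
    mask = np.zeros(len(peaks), dtype=bool)
    pos = {c: i for i, c in enumerate(peaks.index)}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        cov = covs.get(chrom)
        if cov is None:
            continue
        ov = cov.overlap(sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        mask[[pos[i] for i in sub.index]] = ov > 0
    return mask


def peak_density_by_readcount(
    peaks: pd.DataFrame,
    domains: pd.DataFrame,
    readcount_bins,
) -> pd.DataFrame:
    """Density of scored peaks per chromatin state, stratified by read count.

    ``peaks`` needs a ``score`` column (reads in the peak); ``readcount_bins``
    are ascending edges; bin i is [edge_i, edge_{i+1}). For each bin and each
    state present in ``domains``, reports the count of peaks with >=1 bp
    overlap divided by the state's total span in Mb.
    """
    if "score" not in peaks.columns or peaks["score"].isna().any():
        raise ValueError("peaks must carry a read-count score")
    edges = np.asarray(readcount_bins, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("readcount_bins must be ascending with >= 2 edges")
    states = list(dict.fromkeys(domains["state"]))
    rows = []
    for state in states:
        dom = domains[domains["state"] == state][["chrom", "start", "end"]]
        state_mb = total_length(merge_track(dom)) / MB
        hit = peaks[peaks_overlapping(dom, peaks)] if len(peaks) else peaks
        counts, _ = np.histogram(hit["score"].to_numpy(float), bins=edges)
        for i, n in enumerate(counts):
            rows.append(
                {
                    "bin_lo": edges[i],
                    "bin_hi": edges[i + 1],
                    "state": state,
                    "n_peaks": int(n),
                    "density_per_mb": n / state_mb if state_mb else np.nan,
                }
            )
    return pd.DataFrame(rows)
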