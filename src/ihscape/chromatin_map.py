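"""Fragment-level chromatin-state map: gap filling, domain merging, composition.

The input is a four-state map called on non-overlapping 200 bp fragments of
the euchromatic chromosome arms. States are named aquamarine (open,
regulatory), lazurite (gene bodies), malachite (transitional) and ruby
(repressed); the legacy colour labels cyan/blue/green/magenta are accepted and
mapped onto these. Sequence to which no state could be assigned is carried as
explicit ``gap`` fragments so that every basepair of each declared arm is
accounted for.

Processing follows the published two-step rule set:

1. *gap filling* — a gap of at most 400 bp flanked on both sides by the same
   state is relabelled to that state (one pass, no iteration to fixpoint);
2. *domain merging* — maximal runs of abutting same-state fragments become
   chromatin domains, the unit of all downstream overlap work.

Analyses of intercalary-heterochromatin (IH) bands restrict domains to a set
of named regions via :func:`clip_to_regions`; a domain belongs to a region if
it overlaps by at least ``min_overlap`` bp, while bp-exact composition uses
the clipped lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import read_bed, read_regions  # noqa: F401  (re-exported convenience)

STATES = ("aquamarine", "lazurite", "malachite", "ruby")
GAP = "gap"
LEGACY_LABELS = {
    "cyan": "aquamarine",
    "blue": "lazurite",
    "green": "malachite",
    "magenta": "ruby",
}
FRAGMENT_LENGTH = 200

FRAGMENT_COLS = ["chrom", "start", "end", "state"]
DOMAIN_COLS = ["chrom", "start", "end", "state", "n_fragments"]


def normalize_state(label: str) -> str:
    label = label.strip().lower()
    label = LEGACY_LABELS.get(label, label)
    if label not in STATES and label != GAP:
        raise ValueError(f"unknown chromatin state label: {label!r}")
    return label


@dataclass
class GenomeMap:
    """Per-chromosome fragment (and, after merging, domain) tables.

    ``fragments`` tile each declared chromosome completely: state fragments
    plus explicit gap fragments, sorted, abutting, non-overlapping.
    """

    fragments: pd.DataFrame
    chrom_sizes: dict
    domains: pd.DataFrame | None = field(default=None)

    @property
    def total_span(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def gap_bp(self) -> int:
        frag = self.fragments
        g = frag[frag["state"] == GAP]
        return int((g["end"] - g["start"]).sum())

    def state_intervals(self, state: str, chrom: str | None = None) -> pd.DataFrame:
        """Merged-domain intervals of one state (requires merge_domains)."""
        dom = self.domains if self.domains is not None else self.fragments
        sel = dom[dom["state"] == state]
        if chrom is not None:
            sel = sel[sel["chrom"] == chrom]
        return sel.reset_index(drop=True)

    def validate(self) -> None:
        frag = self.fragments
        covered = int((frag["end"] - frag["start"]).sum())
        if covered != self.total_span:
            raise ValueError(
                f"fragments cover {covered} bp but chromosome sizes sum to "
                f"{self.total_span} bp"
            )


def _coalesce_gaps(frag: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of abutting gap fragments into maximal gap fragments."""
    out = []
    for _, sub in frag.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        is_gap = (sub["state"] == GAP).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # new run whenever state changes gap<->non-gap, a non-gap appears,
        # or fragments do not abut
        prev_gap = np.roll(is_gap, 1)
        abut = np.empty(len(sub), dtype=bool)
        abut[0] = False
        abut[1:] = starts[1:] == ends[:-1]
        new_run = ~(is_gap & prev_gap & abut)
        new_run[0] = True
        run = np.cumsum(new_run) - 1
        sub = sub.assign(_run=run)
        merged = sub.groupby("_run", sort=True).agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            state=("state", "first"),
        )
        out.append(merged)
    return pd.concat(out, ignore_index=True)[FRAGMENT_COLS]


def build_map(
    fragments: pd.DataFrame,
    chrom_sizes: dict | None = None,
    fragment_length: int | None = FRAGMENT_LENGTH,
) -> GenomeMap:
    """Assemble a :class:`GenomeMap` from a fragment table.

    Uncovered stretches between the declared chromosome bounds are
    materialised as gap fragments; abutting gap fragments are coalesced.
    Non-gap fragments must be exactly ``fragment_length`` bp when that check
    is enabled (pass ``None`` to accept arbitrary lengths).
    """
    frag = fragments.copy()
    frag["state"] = frag["state"].map(normalize_state)
    frag = frag.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    for chrom, sub in frag.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        bad = np.flatnonzero(s[1:] < e[:-1])
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"overlapping fragments on {chrom}: "
                f"[{s[i]},{e[i]}) and [{s[i + 1]},{e[i + 1]})"
            )
    if fragment_length is not None:
        nong = frag[frag["state"] != GAP]
        lengths = nong["end"] - nong["start"]
        if (lengths != fragment_length).any():
            row = nong[lengths != fragment_length].iloc[0]
            raise ValueError(
                f"non-gap fragment of length {row.end - row.start} bp at "
                f"{row.chrom}:{row.start}-{row.end} "
                f"(expected {fragment_length} bp)"
            )

    if chrom_sizes is None:
        chrom_sizes = frag.groupby("chrom")["end"].max().astype(int).to_dict()

    pieces = [frag]
    for chrom, size in chrom_sizes.items():
        sub = frag[frag["chrom"] == chrom]
        holes = []
        cursor = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > cursor:
                holes.append((cursor, s))
            cursor = e
        if cursor > size:
            raise ValueError(f"fragment extends past declared size of {chrom}")
        if cursor < size:
            holes.append((cursor, size))
        if holes:
            pieces.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": [h[0] for h in holes],
                        "end": [h[1] for h in holes],
                        "state": GAP,
                    }
                )
            )
    frag = pd.concat(pieces, ignore_index=True)
    frag = frag.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    frag = _coalesce_gaps(frag)
    gm = GenomeMap(fragments=frag, chrom_sizes=dict(chrom_sizes))
    gm.validate()
    return gm


def read_state_map(
    path,
    chrom_sizes: dict | None = None,
    fragment_length: int | None = FRAGMENT_LENGTH,
) -> GenomeMap:
    """Read a 4-column (chrom, start, end, state) fragment file."""
    frag = read_bed(path, name="state")
    try:
        return build_map(frag, chrom_sizes, fragment_length)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def fill_gaps(gm: GenomeMap, max_gap: int = 400) -> GenomeMap:
    """Relabel short gaps flanked by one state on both sides.

    A gap fragment of length <= ``max_gap`` whose immediate non-gap neighbours
    on both flanks share a state takes that state. Single pass: the decision
    uses the input labels only, so the operation is idempotent. Gaps at
    chromosome ends have one flank and are never relabelled. Coordinates are
    never changed, only labels.
    """
    out = []
    for _, sub in gm.fragments.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable").reset_index(drop=True)
        states = sub["state"].to_numpy(dtype=object)
        lengths = (sub["end"] - sub["start"]).to_numpy()
        new_states = states.copy()
        # gaps were coalesced at build time, so flanking fragments are non-gap
        for i in np.flatnonzero(states == GAP):
            if i == 0 or i == len(states) - 1:
                continue
            if lengths[i] <= max_gap and states[i - 1] == states[i + 1] != GAP:
                new_states[i] = states[i - 1]
        sub = sub.assign(state=new_states)
        out.append(sub)
    frag = pd.concat(out, ignore_index=True)
    return GenomeMap(fragments=frag, chrom_sizes=dict(gm.chrom_sizes))


def merge_domains(gm: GenomeMap) -> GenomeMap:
    """Merge maximal runs of abutting same-state fragments into domains.

    Residual gaps break runs. Per-base state assignment is preserved exactly;
    ``n_fragments`` counts the constituent fragments (a relabelled gap counts
    as one fragment).
    """
    out = []
    for _, sub in gm.fragments.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        states = sub["state"].to_numpy(dtype=object)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        same = np.empty(len(sub), dtype=bool)
        same[0] = False
        same[1:] = (states[1:] == states[:-1]) & (starts[1:] == ends[:-1])
        run = np.cumsum(~same) - 1
        dom = (
            sub.assign(_run=run)
            .groupby("_run", sort=True)
            .agg(
                chrom=("chrom", "first"),
                start=("start", "min"),
                end=("end", "max"),
                state=("state", "first"),
                n_fragments=("state", "size"),
            )
        )
        out.append(dom[dom["state"] != GAP])
    domains = pd.concat(out, ignore_index=True)[DOMAIN_COLS]
    return GenomeMap(
        fragments=gm.fragments, chrom_sizes=dict(gm.chrom_sizes), domains=domains
    )


def process_map(gm: GenomeMap, max_gap: int = 400) -> GenomeMap:
    """Convenience: gap-fill then merge."""
    return merge_domains(fill_gaps(gm, max_gap=max_gap))


def clip_to_regions(
    domains: pd.DataFrame, regions: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Restrict domains to named regions.

    Returns one row per (region, overlapping domain) with clipped coordinates
    plus the parent domain's coordinates; a domain is "in" a region when the
    overlap is at least ``min_overlap`` bp.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    known = set(domains["chrom"])
    missing = set(regions["chrom"]) - known
    if missing:
        raise ValueError(f"regions on chromosomes absent from the map: {sorted(missing)}")
    rows = []
    for _, reg in regions.iterrows():
        sub = domains[domains["chrom"] == reg["chrom"]]
        cs = np.maximum(sub["start"].to_numpy(), reg["start"])
        ce = np.minimum(sub["end"].to_numpy(), reg["end"])
        keep = (ce - cs) >= min_overlap
        if not keep.any():
            continue
        sel = sub[keep]
        rows.append(
            pd.DataFrame(
                {
                    "region": reg["name"],
                    "chrom": sel["chrom"],
                    "start": cs[keep],
                    "end": ce[keep],
                    "state": sel["state"],
                    "parent_start": sel["start"],
                    "parent_end": sel["end"],
                    "n_fragments": sel.get("n_fragments", pd.Series(1, index=sel.index)),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "region", "chrom", "start", "end", "state",
                "parent_start", "parent_end", "n_fragments",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def composition(
    domains: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    include_gaps: bool = True,
    min_overlap: int = 1,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Per-state bp and fraction of the combined region span.

    With ``regions`` given, composition is over the clipped region span and
    the gap share is the span not covered by any state domain. Without
    regions, composition is genome-wide (``chrom_sizes`` required for the gap
    share). With ``include_gaps=False`` fractions are renormalised over the
    four states.
    """
    if regions is not None:
        if len(regions) == 0:
            raise ValueError("empty region set")
        clipped = clip_to_regions(domains, regions, min_overlap=min_overlap)
        span = int((regions["end"] - regions["start"]).sum())
        bp = clipped.assign(length=clipped["end"] - clipped["start"]).groupby("state")[
            "length"
        ].sum()
    else:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required for genome-wide composition")
        span = int(sum(chrom_sizes.values()))
        bp = domains.assign(length=domains["end"] - domains["start"]).groupby("state")[
            "length"
        ].sum()
    rows = []
    state_total = 0
    for state in STATES:
        v = int(bp.get(state, 0))
        state_total += v
        rows.append({"state": state, "bp": v})
    gap_bp = span - state_total
    if include_gaps:
        rows.append({"state": GAP, "bp": gap_bp})
        denom = span
    else:
        denom = state_total
    table = pd.DataFrame(rows)
    table["fraction"] = table["bp"] / denom if denom else 0.0
    return table
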