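"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of the study's inputs at desk scale:
a four-state fragment map over five chromosome arms in which large
late-replicating (IH) regions are dominated by long ruby domains interrupted
by short malachite separators and rare embedded aquamarine fragments, with
malachite forming the transition zone at every IH border; annotation tracks
with a planted fold-enrichment inside a chosen state; an RPKM matrix with
class-dependent expression breadth and level; timing probes with a planted
early-to-late gradient from IH borders inward; and scored peaks placed with
state-dependent Poisson rates.

Domain lengths are log-normal (heavy right tail: the field's observed
malachite mean ~1.6 kb sits above its median, likewise aquamarine mean ~1 kb
vs median 0.8 kb). The *malachite-buffer rule* — ruby never directly abuts
aquamarine or lazurite, malachite always intervenes — can be switched off to
produce counterexample maps for the contact-topology property tests.

All generators are deterministic given their seed, and all outputs round-trip
through the package readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin_map import FRAGMENT_LENGTH, GAP, GenomeMap, build_map, process_map
from .intervals import merge_intervals

ARM_NAMES = ("2L", "2R", "3L", "3R", "X")

# median bp / log-sd of per-state domain lengths (lengths round to 200 bp)
DEFAULT_LENGTH_PARAMS = {
    "aquamarine": (800.0, 0.65),
    "lazurite": (2000.0, 0.7),
    "malachite": (1300.0, 0.65),
    "ruby": (12000.0, 0.7),
}

# per-class expression parameters: P(expressed per tissue), log2 RPKM mean/sd
DEFAULT_EXPRESSION_PARAMS = {
    "aquamarine": {"expr_prob": 0.90, "log2_mean": 5.5, "log2_sd": 1.0},
    "lazurite": {"expr_prob": 0.60, "log2_mean": 4.5, "log2_sd": 1.0},
    "malachite_border": {"expr_prob": 0.26, "log2_mean": 3.5, "log2_sd": 1.0},
    "malachite_internal": {"expr_prob": 0.24, "log2_mean": 3.3, "log2_sd": 1.0},
    "ruby": {"expr_prob": 0.14, "log2_mean": 3.0, "log2_sd": 1.0},
}

DEFAULT_PEAK_RATES = {
    "aquamarine": 100.0,
    "lazurite": 10.0,
    "malachite": 1.0,
    "ruby": 1.0,
}


@dataclass
class MapSpec:
    """Layout of a synthetic four-state genome with embedded IH regions."""

    chrom_lengths: dict = field(
        default_factory=lambda: {arm: 2_000_000 for arm in ARM_NAMES}
    )
    length_params: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_PARAMS))
    buffer_rule: bool = True
    n_ih_regions: int = 12
    ih_length_range: tuple = (60_000, 160_000)
    ih_margin: int = 20_000
    # at an internal ruby/ruby junction inside IH: chance of an embedded
    # aquamarine or lazurite island instead of a plain malachite separator
    p_ih_aquamarine: float = 0.12
    p_ih_lazurite: float = 0.025
    gap_rate: float = 0.08
    gap_length_params: tuple = (800.0, 0.6)
    ih_gap_rate: float = 0.15
    ih_gap_length_params: tuple = (2000.0, 0.6)
    # outside-IH state preference weights
    state_weights: dict = field(
        default_factory=lambda: {
            "aquamarine": 0.28,
            "lazurite": 0.30,
            "malachite": 0.27,
            "ruby": 0.15,
        }
    )
    seed: int | None = None


@dataclass
class TrackSpec:
    """A track with planted fold-enrichment inside one state."""

    base_density: float = 0.02
    target_state: str = "aquamarine"
    fold: float = 1.0
    length_params: tuple = (400.0, 0.5)  # log-normal median bp, log-sd
    seed: int | None = None


@dataclass
class SyntheticDataset:
    genome_map: GenomeMap  # raw fragments (pre gap-fill)
    ih_regions: pd.DataFrame
    truth: dict


def _round200(x: float) -> int:
    return max(FRAGMENT_LENGTH, int(round(x / FRAGMENT_LENGTH)) * FRAGMENT_LENGTH)


def _draw_len(rng, params) -> int:
    median, sigma = params
    return _round200(median * np.exp(rng.normal(0.0, sigma)))


class _ChromBuilder:
    """Accumulates (state, length) tokens and emits 200 bp fragments."""

    def __init__(self, chrom, rng, spec):
        self.chrom = chrom
        self.rng = rng
        self.spec = spec
        self.tokens = []  # (state-or-gap, length)
        self.cursor = 0

    def add(self, state, length):
        self.tokens.append((state, int(length)))
        self.cursor += int(length)

    def maybe_gap(self, inside_ih: bool = False):
        rate = self.spec.ih_gap_rate if inside_ih else self.spec.gap_rate
        if self.rng.random() < rate:
            median, sigma = (
                self.spec.ih_gap_length_params if inside_ih
                else self.spec.gap_length_params
            )
            glen = max(100, int(round(median * np.exp(self.rng.normal(0.0, sigma)))))
            self.add(GAP, glen)

    def last_state(self):
        for state, _ in reversed(self.tokens):
            if state != GAP:
                return state
        return None

    def next_outside_state(self):
        prev = self.last_state()
        spec = self.spec
        if spec.buffer_rule and prev == "ruby":
            return "malachite"
        weights = dict(spec.state_weights)
        if prev in weights:
            weights[prev] = 0.0
        if spec.buffer_rule and prev in ("aquamarine", "lazurite"):
            weights["ruby"] = 0.0
        states = list(weights)
        w = np.array([weights[s] for s in states], dtype=float)
        w /= w.sum()
        return states[self.rng.choice(len(states), p=w)]

    def fragments(self):
        rows = []
        pos = 0
        for state, length in self.tokens:
            if state == GAP:
                rows.append((self.chrom, pos, pos + length, GAP))
            else:
                for off in range(0, length, FRAGMENT_LENGTH):
                    rows.append(
                        (self.chrom, pos + off, pos + off + FRAGMENT_LENGTH, state)
                    )
            pos += length
        return rows


def _emit_outside(builder, until):
    """Interband-like sequence up to (roughly) the target coordinate."""
    spec = builder.spec
    while builder.cursor < until:
        state = builder.next_outside_state()
        builder.add(state, _draw_len(builder.rng, spec.length_params[state]))
        if builder.cursor < until:
            builder.maybe_gap()


def _emit_ih(builder, target_len, truth):
    """One IH region: border malachite, ruby blocks, embedded islands."""
    spec = builder.spec
    rng = builder.rng
    region_start = builder.cursor
    border_len = _draw_len(rng, spec.length_params["malachite"])
    builder.add("malachite", border_len)
    truth["malachite_labels"].append((builder.chrom, region_start, "border"))
    while builder.cursor - region_start < target_len - 2 * border_len:
        builder.add("ruby", _draw_len(rng, spec.length_params["ruby"]))
        if builder.cursor - region_start >= target_len - 2 * border_len:
            break
        builder.maybe_gap(inside_ih=True)
        r = rng.random()
        if r < spec.p_ih_aquamarine + spec.p_ih_lazurite:
            island = "aquamarine" if r < spec.p_ih_aquamarine else "lazurite"
            if spec.buffer_rule:
                start = builder.cursor
                builder.add("malachite", _draw_len(rng, spec.length_params["malachite"]))
                truth["malachite_labels"].append((builder.chrom, start, "internal"))
            builder.add(island, _draw_len(rng, spec.length_params[island]))
            if island == "aquamarine":
                truth["ih_aquamarine"].append((builder.chrom, builder.cursor))
            if spec.buffer_rule:
                start = builder.cursor
                builder.add("malachite", _draw_len(rng, spec.length_params["malachite"]))
                truth["malachite_labels"].append((builder.chrom, start, "internal"))
        else:
            start = builder.cursor
            builder.add("malachite", _draw_len(rng, spec.length_params["malachite"]))
            truth["malachite_labels"].append((builder.chrom, start, "internal"))
        builder.maybe_gap(inside_ih=True)
    end_border_start = builder.cursor
    builder.add("malachite", _draw_len(rng, spec.length_params["malachite"]))
    truth["malachite_labels"].append((builder.chrom, end_border_start, "border"))
    return region_start, builder.cursor


def gen_map(spec: MapSpec | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a fragment map, IH region list and ground-truth labels."""
    spec = spec or MapSpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    lo, hi = spec.ih_length_range
    for chrom, size in spec.chrom_lengths.items():
        if hi + 2 * spec.ih_margin > size:
            raise ValueError(f"IH regions do not fit on {chrom} ({size} bp)")

    chroms = list(spec.chrom_lengths)
    per_chrom = {c: 0 for c in chroms}
    for i in range(spec.n_ih_regions):
        per_chrom[chroms[i % len(chroms)]] += 1

    truth = {"malachite_labels": [], "ih_aquamarine": []}
    frag_rows = []
    region_rows = []
    region_no = 0
    for chrom, size in spec.chrom_lengths.items():
        k = per_chrom[chrom]
        builder = _ChromBuilder(chrom, rng, spec)
        targets = sorted(
            rng.integers(spec.ih_margin, size - hi - spec.ih_margin, size=k)
        ) if k else []
        feasible = []
        prev_end = 0
        for t in targets:
            t = max(t, prev_end + spec.ih_margin)
            if t + hi + spec.ih_margin > size:
                break
            feasible.append(t)
            prev_end = t + hi
        for t in feasible:
            ih_len = int(rng.integers(lo, hi + 1))
            _emit_outside(builder, t)
            rs, re_ = _emit_ih(builder, ih_len, truth)
            region_no += 1
            region_rows.append(
                {"chrom": chrom, "start": rs, "end": re_,
                 "name": f"IH{region_no:02d}"}
            )
        _emit_outside(builder, size)
        # trim token overshoot back to the declared arm length
        rows = [r for r in builder.fragments() if r[1] < size]
        if rows and rows[-1][2] > size:
            c, s, e, st = rows[-1]
            if st == GAP:
                rows[-1] = (c, s, size, st)
            else:
                rows = [r for r in rows if r[2] <= size]
        frag_rows.extend(rows)

    frag = pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "state"])
    gm = build_map(frag, chrom_sizes=dict(spec.chrom_lengths))
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "name"])
    return SyntheticDataset(genome_map=gm, ih_regions=regions, truth=truth)


def _state_intervals(gm: GenomeMap, state: str) -> pd.DataFrame:
    if gm.domains is None:
        gm = process_map(gm)
    return gm.state_intervals(state)


def _place_in_intervals(rng, intervals: pd.DataFrame, target_bp: int, length_params):
    """Intervals sampled inside a category until merged coverage >= target."""
    if target_bp <= 0 or intervals.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    ivl = intervals.reset_index(drop=True)
    lengths = (ivl["end"] - ivl["start"]).to_numpy(float)
    w = lengths / lengths.sum()
    median, sigma = length_params
    covered = 0
    batch_rows = []
    mean_len = median * np.exp(sigma**2 / 2)
    while covered < target_bp:
        # add roughly the deficit's worth of raw length before re-merging so
        # overshoot stays within about one interval
        k = int(np.clip((target_bp - covered) / mean_len, 1, 512))
        for i in rng.choice(len(ivl), p=w, size=k):
            row = ivl.iloc[i]
            tl = max(50, int(round(median * np.exp(rng.normal(0.0, sigma)))))
            s = int(rng.integers(row["start"], row["end"]))
            e = min(s + tl, int(row["end"]))
            batch_rows.append((row["chrom"], s, e))
        df = pd.DataFrame(batch_rows, columns=["chrom", "start", "end"])
        covered = 0
        for _, sub in df.groupby("chrom"):
            ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            covered += int((me - ms).sum())
    out = []
    for chrom, sub in pd.DataFrame(
        batch_rows, columns=["chrom", "start", "end"]
    ).groupby("chrom"):
        ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        out.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    return pd.concat(out, ignore_index=True)


def gen_track(
    gm: GenomeMap, spec: TrackSpec | None = None, seed: int | None = None
) -> pd.DataFrame:
    """A merged track with coverage fold*base inside the target state, base
    elsewhere.

    With ``fold == 1`` intervals are placed uniformly along each chromosome,
    independent of the map — the null-calibration configuration. ``fold == 0``
    leaves the target state empty.
    """
    spec = spec or TrackSpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    if spec.fold * spec.base_density > 0.9:
        raise ValueError("requested coverage exceeds available sequence")
    if gm.domains is None:
        gm = process_map(gm)

    if spec.fold == 1.0:
        # uniform placement on the circle (wraparound): the track law is
        # stationary, so no position along the chromosome is privileged
        rows = []
        median, sigma = spec.length_params
        for chrom, size in gm.chrom_sizes.items():
            target = int(spec.base_density * size)
            raw = 0
            while raw < target:
                tl = max(50, int(round(median * np.exp(rng.normal(0.0, sigma)))))
                tl = min(tl, size)
                s = int(rng.integers(0, size))
                e = s + tl
                if e <= size:
                    rows.append((chrom, s, e))
                else:
                    rows.append((chrom, s, size))
                    rows.append((chrom, 0, e - size))
                raw += tl
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out = []
        for chrom, sub in df.groupby("chrom"):
            ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            out.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
        return pd.concat(out, ignore_index=True).sort_values(
            ["chrom", "start"]
        ).reset_index(drop=True)

    target_ivl = _state_intervals(gm, spec.target_state)
    if target_ivl.empty:
        raise ValueError(f"target state {spec.target_state!r} absent from map")
    target_bp = int((target_ivl["end"] - target_ivl["start"]).sum())
    other = gm.domains[gm.domains["state"] != spec.target_state]
    other_bp = int((other["end"] - other["start"]).sum())

    parts = [
        _place_in_intervals(
            rng, target_ivl[["chrom", "start", "end"]],
            int(spec.fold * spec.base_density * target_bp), spec.length_params,
        ),
        _place_in_intervals(
            rng, other[["chrom", "start", "end"]],
            int(spec.base_density * other_bp), spec.length_params,
        ),
    ]
    df = pd.concat(parts, ignore_index=True)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def place_genes(
    class_intervals: pd.DataFrame,
    n_per_class: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic genes with TSSs sampled inside labelled class intervals."""
    rng = np.random.default_rng(seed)
    rows = []
    g = 0
    for cls, sub in class_intervals.groupby("class", sort=False):
        lengths = (sub["end"] - sub["start"]).to_numpy(float)
        w = lengths / lengths.sum()
        idx = rng.choice(len(sub), size=n_per_class, p=w)
        for i in idx:
            row = sub.iloc[i]
            tss = int(rng.integers(row["start"], row["end"]))
            strand = "+" if rng.random() < 0.5 else "-"
            g += 1
            rows.append(
                {
                    "gene_id": f"G{g:05d}",
                    "transcript_id": f"G{g:05d}.1",
                    "chrom": row["chrom"],
                    "tss": tss,
                    "strand": strand,
                    "class": cls,
                }
            )
    return pd.DataFrame(rows)


def gen_expression(
    genes: pd.DataFrame,
    class_params: dict | None = None,
    n_tissues: int = 29,
    seed: int | None = None,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """RPKM matrix with planted class-dependent breadth and level.

    Per gene and tissue: expressed with the class's ``expr_prob`` (RPKM drawn
    log-normal above the threshold scale), otherwise silent with RPKM drawn
    uniformly below the threshold.
    """
    class_params = class_params or DEFAULT_EXPRESSION_PARAMS
    rng = np.random.default_rng(seed)
    cols = [f"tissue_{i + 1:02d}" for i in range(n_tissues)]
    mat = np.zeros((len(genes), n_tissues))
    for i, cls in enumerate(genes["class"]):
        p = class_params[cls]
        on = rng.random(n_tissues) < p["expr_prob"]
        expr = 2.0 ** rng.normal(p["log2_mean"], p["log2_sd"], size=n_tissues)
        expr = np.maximum(expr, threshold + 0.01)  # expressed means above cutoff
        silent = rng.uniform(0.0, threshold, size=n_tissues)
        mat[i] = np.where(on, expr, silent)
    return pd.concat(
        [genes.reset_index(drop=True), pd.DataFrame(mat, columns=cols)], axis=1
    )


def gen_probes(
    gm: GenomeMap,
    ih_regions: pd.DataFrame,
    spacing: int = 500,
    probe_len: int = 100,
    baseline: float = 1.0,
    slope_per_kb: float = 0.02,
    noise_sd: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Timing probes tiled at fixed spacing with a planted border gradient.

    Inside an IH region the score falls linearly with distance (kb) from the
    nearest region border: ``baseline - slope_per_kb * d + noise``; outside,
    the score is ``baseline + noise``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, size in gm.chrom_sizes.items():
        starts = np.arange(0, size - probe_len, spacing, dtype=np.int64)
        mids = starts + probe_len / 2.0
        score = np.full(starts.size, baseline, dtype=float)
        regs = ih_regions[ih_regions["chrom"] == chrom]
        for _, reg in regs.iterrows():
            inside = (starts >= reg["start"]) & (starts + probe_len <= reg["end"])
            d_kb = (
                np.minimum(mids[inside] - reg["start"], reg["end"] - mids[inside])
                / 1000.0
            )
            score[inside] = baseline - slope_per_kb * d_kb
        if noise_sd > 0:
            score = score + rng.normal(0.0, noise_sd, size=score.size)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + probe_len,
                    "score": score,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_peaks(
    gm: GenomeMap,
    rates_per_mb: dict | None = None,
    peak_width: int = 200,
    readcount_params: tuple = (20.0, 1.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Scored peaks Poisson-placed with state-dependent rates (per Mb)."""
    rates = rates_per_mb or DEFAULT_PEAK_RATES
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    if gm.domains is None:
        gm = process_map(gm)
    rows = []
    median, sigma = readcount_params
    for state, rate in rates.items():
        ivl = gm.state_intervals(state)
        if ivl.empty or rate == 0:
            continue
        lengths = (ivl["end"] - ivl["start"]).to_numpy(float)
        state_mb = lengths.sum() / 1e6
        n = rng.poisson(rate * state_mb)
        if n == 0:
            continue
        w = lengths / lengths.sum()
        idx = rng.choice(len(ivl), size=n, p=w)
        for i in idx:
            row = ivl.iloc[i]
            s = int(rng.integers(row["start"], row["end"]))
            e = min(s + peak_width, int(row["end"]))
            reads = int(round(median * np.exp(rng.normal(0.0, sigma)))) + 1
            rows.append((row["chrom"], s, e, reads))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "score"])
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def gen_partition(
    gm: GenomeMap, jitter: int = 400, seed: int | None = None
) -> pd.DataFrame:
    """A compactization-like 3-class reference partition derived from the map.

    Aquamarine maps to "open", lazurite/malachite to "neutral", ruby to
    "closed"; class boundaries are jittered so overlap profiles are imperfect,
    as with an independently derived partition. Classes stay non-overlapping.
    """
    rng = np.random.default_rng(seed)
    mapping = {
        "aquamarine": "open",
        "lazurite": "neutral",
        "malachite": "neutral",
        "ruby": "closed",
    }
    if gm.domains is None:
        gm = process_map(gm)
    rows = []
    for chrom, sub in gm.domains.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy(np.int64).copy()
        ends = sub["end"].to_numpy(np.int64).copy()
        cls = sub["state"].map(mapping).to_numpy(dtype=object)
        if jitter > 0 and len(sub) > 1:
            # move each shared boundary, clamped so no interval inverts even
            # when neighbouring shifts collide on a short domain
            for i in range(len(sub) - 1):
                if starts[i + 1] != ends[i]:
                    continue  # separated by a gap: boundary not shared
                lo = int(starts[i]) + 1
                hi = int(ends[i + 1]) - 1
                if hi <= lo:
                    continue
                cut = int(np.clip(ends[i] + rng.integers(-jitter, jitter + 1),
                                  lo, hi))
                ends[i] = cut
                starts[i + 1] = cut
        rows.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "class": cls}
        ))
    return pd.concat(rows, ignore_index=True)
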