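"""End-to-end orchestration: map processing through passports, plus fixtures.

``run_pipeline`` executes the full analysis from a config mapping (or YAML
file): map construction -> domain topology -> overlap/enrichment with the
domain-shuffle null -> expression breadth -> replication timing, writing
plain TSV/JSON outputs and a run log that records the seed, iteration count
and every flag that resolves a methodological choice. ``region_passport``
assembles the per-IH-region summary record (composition, malachite
subclasses, track co-occupancy of embedded aquamarine fragments, timing
gradient). ``make_fixtures`` emits a complete synthetic demo dataset in the
same file dialects the readers accept.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatin_map import (
    GAP,
    clip_to_regions,
    composition,
    process_map,
    read_state_map,
)
from .domain_topology import (
    classify_malachite,
    contact_matrix,
    labeled_intervals,
)
from .expression_profiles import assign_tss_class, summarize_by_class
from .io import read_bed, read_chrom_sizes, read_regions, write_tsv
from .overlap_enrichment import (
    density_ratio,
    merge_track,
    overlap_profile,
    peak_density_by_readcount,
    peaks_overlapping,
)
from .replication_timing import assign_probe_class, bin_timing_scores, border_gradient
from .shuffle_test import ShuffleConfig, genomewide_test

DEFAULT_READCOUNT_BINS = [1, 3, 10, 30, 100, 300, 1000, 1e9]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - rewrap with stage context
                raise StageError(name, str(err)) from err
        return wrapper
    return deco


@_stage("chromatin_map")
def _stage_map(cfg):
    sizes = read_chrom_sizes(cfg["chrom_sizes"]) if "chrom_sizes" in cfg else None
    gm = read_state_map(cfg["map"], chrom_sizes=sizes)
    gm = process_map(gm, max_gap=int(cfg.get("max_gap", 400)))
    regions = read_regions(cfg["regions"])
    return gm, regions


def run_pipeline(config, outdir) -> dict:
    """Run every stage and write TSV/JSON reports; returns output paths."""
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    iterations = int(cfg.get("iterations", 10_000))
    include_gaps = bool(cfg.get("include_gaps", True))
    min_overlap = int(cfg.get("min_overlap", 1))
    statistic = cfg.get("statistic", "length")
    gap_mode = cfg.get("gap_mode", "opaque")
    paths: dict = {}

    gm, regions = _stage_map(cfg)
    write_tsv(gm.domains, outdir / "domains.tsv")
    paths["domains"] = outdir / "domains.tsv"

    comp_ih = composition(
        gm.domains, regions, include_gaps=include_gaps, min_overlap=min_overlap
    )
    comp_gw = composition(
        gm.domains, include_gaps=include_gaps, chrom_sizes=gm.chrom_sizes
    )
    write_tsv(comp_ih, outdir / "composition_ih.tsv")
    write_tsv(comp_gw, outdir / "composition_genome.tsv")
    paths["composition_ih"] = outdir / "composition_ih.tsv"

    try:
        cm = contact_matrix(gm, gap_mode=gap_mode, max_span=cfg.get("gap_max_span"))
        cm.to_csv(outdir / "contact_matrix.tsv", sep="\t")
        labels = classify_malachite(gm.domains, regions, min_overlap=min_overlap)
        write_tsv(labels, outdir / "malachite_labels.tsv")
        classes = labeled_intervals(gm.domains, regions, min_overlap=min_overlap)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError("domain_topology", str(err)) from err
    paths["contact_matrix"] = outdir / "contact_matrix.tsv"
    paths["malachite_labels"] = outdir / "malachite_labels.tsv"

    # ---- overlap profiles against reference partitions -------------------
    profile_rows = []
    for pname, ppath in (cfg.get("partitions") or {}).items():
        try:
            part = read_bed(ppath, name="class")
            for cls in ("malachite_border", "malachite_internal", "aquamarine"):
                query = classes[classes["class"] == cls][["chrom", "start", "end"]]
                if query.empty:
                    continue
                prof = overlap_profile(query, part)
                prof.insert(0, "query", cls)
                prof.insert(0, "partition", pname)
                profile_rows.append(prof)
        except Exception as err:  # noqa: BLE001
            raise StageError("overlap_profile", f"{ppath}: {err}") from err
    if profile_rows:
        write_tsv(pd.concat(profile_rows, ignore_index=True),
                  outdir / "overlap_profiles.tsv")
        paths["overlap_profiles"] = outdir / "overlap_profiles.tsv"

    # ---- shuffle tests + density ratios per track ------------------------
    track_frames = {}
    shuffle_rows = []
    test_states = cfg.get("shuffle_states", ["aquamarine", "malachite"])
    for tname, tpath in (cfg.get("tracks") or {}).items():
        try:
            track = merge_track(read_bed(tpath))
            track_frames[tname] = track
            for state in test_states:
                dom = gm.state_intervals(state)
                per_chrom = {}
                for chrom in gm.chrom_sizes:
                    d = dom[dom["chrom"] == chrom]
                    t = track[track["chrom"] == chrom]
                    if d.empty:
                        continue
                    per_chrom[chrom] = {
                        "domain_starts": d["start"].to_numpy(),
                        "domain_ends": d["end"].to_numpy(),
                        "track_starts": t["start"].to_numpy(),
                        "track_ends": t["end"].to_numpy(),
                    }
                if not per_chrom:
                    continue
                res = genomewide_test(
                    per_chrom,
                    gm.chrom_sizes,
                    ShuffleConfig(iterations=iterations, seed=seed,
                                  statistic=statistic),
                )
                ratio = density_ratio(
                    dom[["chrom", "start", "end"]], track,
                    null_mean_overlap=res.null_mean,
                )
                row = res.as_dict()
                row.update(track=tname, state=state,
                           density_ratio=ratio["ratio"],
                           observed_fraction=ratio["observed_fraction"],
                           expected_fraction=ratio["expected_fraction"])
                shuffle_rows.append(row)
        except StageError:
            raise
        except Exception as err:  # noqa: BLE001
            raise StageError("shuffle_test", f"{tpath}: {err}") from err
    if shuffle_rows:
        write_tsv(pd.DataFrame(shuffle_rows), outdir / "shuffle_tests.tsv")
        paths["shuffle_tests"] = outdir / "shuffle_tests.tsv"

    # ---- stalled-polymerase peak densities -------------------------------
    if cfg.get("peaks"):
        try:
            peaks = read_bed(cfg["peaks"], score=True)
            bins = cfg.get("readcount_bins", DEFAULT_READCOUNT_BINS)
            dens = peak_density_by_readcount(peaks, gm.domains, bins)
            write_tsv(dens, outdir / "peak_density.tsv")
            paths["peak_density"] = outdir / "peak_density.tsv"
        except Exception as err:  # noqa: BLE001
            raise StageError("peak_density", str(err)) from err

    # ---- expression breadth and magnitude --------------------------------
    if cfg.get("expression"):
        try:
            expr = pd.read_csv(cfg["expression"], sep="\t")
            tissue_cols = [c for c in expr.columns if c.startswith("tissue_")]
            rpkm = expr[tissue_cols]
            lab = assign_tss_class(expr, classes)
            summary = summarize_by_class(
                expr, rpkm, lab, threshold=float(cfg.get("rpkm_threshold", 3.0))
            )
            write_tsv(summary, outdir / "expression_summary.tsv")
            breadth = expr[["gene_id", "transcript_id"]].copy()
            breadth["class"] = lab
            breadth["breadth"] = (rpkm > float(cfg.get("rpkm_threshold", 3.0))).sum(
                axis=1
            )
            write_tsv(breadth, outdir / "expression_breadth.tsv")
            paths["expression_summary"] = outdir / "expression_summary.tsv"
        except Exception as err:  # noqa: BLE001
            raise StageError("expression_profiles", str(err)) from err

    # ---- replication timing ----------------------------------------------
    gradients = []
    if cfg.get("probes"):
        try:
            probes = read_bed(cfg["probes"], score=True)
            pclass = assign_probe_class(probes, gm.domains)
            by_class = {
                cls: probes.loc[idx, "score"].to_numpy()
                for cls, idx in pclass.groupby(pclass).groups.items()
                if cls != "unassigned"
            }
            _, hist = bin_timing_scores(by_class, width=0.5)
            write_tsv(hist, outdir / "timing_histogram.tsv")
            for _, reg in regions.iterrows():
                gradients.append(border_gradient(probes, reg))
            write_tsv(pd.DataFrame(gradients), outdir / "timing_gradients.tsv")
            paths["timing_gradients"] = outdir / "timing_gradients.tsv"
        except Exception as err:  # noqa: BLE001
            raise StageError("replication_timing", str(err)) from err

    # ---- passports --------------------------------------------------------
    passports = [
        region_passport(
            reg, gm, regions, track_frames,
            gradients=[g for g in gradients if g["region"] == reg["name"]],
            min_overlap=min_overlap,
        )
        for _, reg in regions.iterrows()
    ]
    with open(outdir / "passports.json", "w") as fh:
        json.dump(passports, fh, indent=1, default=_jsonable)
    paths["passports"] = outdir / "passports.json"

    log = {
        "package_version": __version__,
        "seed": seed,
        "iterations": iterations,
        "flags": {
            "include_gaps": include_gaps,
            "min_overlap": min_overlap,
            "gap_mode": gap_mode,
            "statistic": statistic,
            "max_gap": int(cfg.get("max_gap", 400)),
            "rpkm_threshold": float(cfg.get("rpkm_threshold", 3.0)),
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    paths["run_log"] = outdir / "run_log.json"
    return {k: str(v) for k, v in paths.items()}


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def region_passport(
    region,
    gm,
    regions: pd.DataFrame,
    tracks: dict | None = None,
    gradients: list | None = None,
    min_overlap: int = 1,
) -> dict:
    """Structured per-region record: composition, malachite subclasses,
    aquamarine co-occupancy with tracks, and the timing gradient."""
    name = region["name"]
    if name not in set(regions["name"]):
        raise KeyError(f"unknown region name: {name!r}")
    one = regions[regions["name"] == name]
    comp = composition(gm.domains, one, include_gaps=True, min_overlap=min_overlap)
    labels = classify_malachite(gm.domains, one, min_overlap=min_overlap)
    aqua = clip_to_regions(
        gm.state_intervals("aquamarine"), one, min_overlap=min_overlap
    )
    cooc = []
    for _, frag in aqua.iterrows():
        frame = pd.DataFrame(
            {"chrom": [frag["chrom"]], "start": [frag["start"]], "end": [frag["end"]]}
        )
        hits = sorted(
            tname
            for tname, tdf in (tracks or {}).items()
            if len(tdf) and peaks_overlapping(frame, tdf).any()
        )
        cooc.append(
            {"start": int(frag["start"]), "end": int(frag["end"]), "tracks": hits}
        )
    out = {
        "region": name,
        "chrom": region["chrom"],
        "start": int(region["start"]),
        "end": int(region["end"]),
        "span_bp": int(region["end"] - region["start"]),
        "composition": {
            r["state"]: {"bp": int(r["bp"]), "fraction": float(r["fraction"])}
            for _, r in comp.iterrows()
        },
        "malachite": {
            "border": int((labels["label"] == "border").sum()),
            "internal": int((labels["label"] == "internal").sum()),
        },
        "aquamarine_fragments": cooc,
        "n_aquamarine_with_track": sum(1 for c in cooc if c["tracks"]),
    }
    if gradients:
        g = gradients[0]
        out["timing_gradient"] = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in g.items()
        }
    return out


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write a complete synthetic demo dataset plus a ready config.yaml."""
    from .synthetic_data import (
        MapSpec,
        TrackSpec,
        gen_expression,
        gen_map,
        gen_partition,
        gen_peaks,
        gen_probes,
        gen_track,
        place_genes,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731

    data = gen_map(MapSpec(), seed=sub())
    gm = process_map(data.genome_map)
    frag = data.genome_map.fragments
    frag[frag["state"] != GAP].to_csv(
        outdir / "map.bed", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {"chrom": list(gm.chrom_sizes), "size": list(gm.chrom_sizes.values())}
    ).to_csv(outdir / "chrom.sizes", sep="\t", header=False, index=False)
    data.ih_regions[["chrom", "start", "end", "name"]].to_csv(
        outdir / "ih_regions.bed", sep="\t", header=False, index=False
    )

    tracks = {
        "insulator_enriched": gen_track(
            gm, TrackSpec(base_density=0.02, target_state="aquamarine", fold=5.0),
            seed=sub(),
        ),
        "enhancer_null": gen_track(gm, TrackSpec(fold=1.0), seed=sub()),
    }
    (outdir / "tracks").mkdir(exist_ok=True)
    for tname, tdf in tracks.items():
        tdf.to_csv(outdir / "tracks" / f"{tname}.bed", sep="\t",
                   header=False, index=False)

    gen_partition(gm, seed=sub()).to_csv(
        outdir / "partition_3cm.bed", sep="\t", header=False, index=False
    )
    classes = labeled_intervals(gm.domains, data.ih_regions)
    genes = place_genes(classes[classes["class"].isin(
        ["aquamarine", "ruby", "malachite_border", "malachite_internal"]
    )], n_per_class=150, seed=sub())
    gen_expression(genes, seed=sub()).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    gen_probes(gm, data.ih_regions, seed=sub()).to_csv(
        outdir / "probes.bed", sep="\t", header=False, index=False
    )
    gen_peaks(gm, seed=sub()).to_csv(
        outdir / "peaks.bed", sep="\t", header=False, index=False
    )

    config = {
        "map": str(outdir / "map.bed"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "regions": str(outdir / "ih_regions.bed"),
        "partitions": {"3cm": str(outdir / "partition_3cm.bed")},
        "tracks": {
            t: str(outdir / "tracks" / f"{t}.bed") for t in tracks
        },
        "expression": str(outdir / "expression.tsv"),
        "probes": str(outdir / "probes.bed"),
        "peaks": str(outdir / "peaks.bed"),
        "seed": seed,
        "iterations": 2000,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return config
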