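"""Simulation studies that verify the statistical machinery end to end.

Each function sets up a synthetic scenario with known ground truth, runs the
relevant pipeline stages, and returns the measured quantity:

* exactness of the Monte-Carlo shuffle null against exhaustive enumeration on
  a toy arrangement small enough to enumerate (12 layouts);
* type-I error calibration of the permutation test under tracks placed
  independently of the map;
* recovery of a planted fold-enrichment, both as a density ratio and as
  rejection of the null;
* agreement of the Gaussian tail fallback with the empirical tail in the
  moderately far tail (the regime where the fallback replaces an empirical
  p of exactly 0 or 1);
* coverage of the replication-timing border-gradient estimate;
* enforcement of the malachite-buffer rule in the contact topology.

Problem sizes are deliberately desk-scale (single arms of 0.6-3 Mb where the
full five-arm layout is not needed) so the whole battery runs in minutes;
the statistical conclusions do not depend on genome size, only on domain and
track counts, which are kept large enough for the asymptotics each check
relies on.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .chromatin_map import process_map
from .domain_topology import contact_matrix
from .intervals import Coverage
from .overlap_enrichment import density_ratio
from .replication_timing import border_gradient
from .shuffle_test import (
    Arrangement,
    ShuffleConfig,
    decompose,
    genomewide_test,
    normal_tail_p,
    null_statistics,
    permutation_test,
    recompose,
)
from .synthetic_data import MapSpec, TrackSpec, gen_map, gen_probes, gen_track


def _spawn(seed, n):
    """Independent child seeds below 2^31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def toy_null_ks(iterations: int = 100_000, seed: int = 0) -> dict:
    """Kolmogorov distance between the MC null and the exhaustive null.

    Toy chromosome of 100 bp with 2 domains and 3 distinct spacers: exactly
    2! * 3! = 12 equally likely layouts, enumerated directly.
    """
    ds, de = [5, 45], [15, 65]  # A = {10, 20}, S = {5, 30, 35}
    chrom_len = 100
    track_s, track_e = np.array([0]), np.array([40])
    arr = decompose(ds, de, chrom_len)
    cov = Coverage(track_s, track_e)
    exact = []
    for ap in itertools.permutations(arr.domain_lengths):
        for sp in itertools.permutations(arr.spacer_lengths):
            s, e = recompose(Arrangement("toy", chrom_len,
                                         np.array(ap), np.array(sp)))
            exact.append(int(cov.overlap(s, e).sum()))
    exact = np.sort(exact)
    nulls = null_statistics(
        arr, track_s, track_e,
        ShuffleConfig(iterations=iterations), np.random.default_rng(seed),
    )
    support = np.unique(exact)
    f_exact = np.searchsorted(exact, support, side="right") / exact.size
    f_mc = np.searchsorted(np.sort(nulls), support, side="right") / nulls.size
    obs = int(cov.overlap(np.array(ds), np.array(de)).sum())
    return {
        "ks_distance": float(np.abs(f_exact - f_mc).max()),
        "exact_p_enrich": float((exact >= obs).mean()),
        "n_layouts": int(exact.size),
        "iterations": iterations,
    }


def type_one_error(
    n_replicates: int = 500,
    iterations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the enrichment test under the independence null.

    One 600 kb arm; aquamarine domains are fixed while a fresh fold-1 track
    (stationary uniform placement) is generated per replicate. The map is
    generated *without* IH regions: the permutation test's level guarantee
    presumes the observed domain order is exchangeable with its shuffles,
    and a map with planted IH structure clumps the short spacers by
    construction, which mildly inflates both tails for any implementation
    (see the methods note). A homogeneous map isolates the Monte-Carlo
    machinery, which is what this study certifies.
    """
    spec = MapSpec(chrom_lengths={"2L": 600_000}, n_ih_regions=0)
    seeds = _spawn(seed, 2 * n_replicates + 1)
    gm = process_map(gen_map(spec, seed=seeds[-1]).genome_map)
    dom = gm.state_intervals("aquamarine")
    chrom_len = gm.chrom_sizes["2L"]
    hits = 0
    p_values = []
    for i in range(n_replicates):
        track = gen_track(gm, TrackSpec(fold=1.0, base_density=0.02),
                          seed=seeds[2 * i])
        res = permutation_test(
            dom["start"].to_numpy(), dom["end"].to_numpy(),
            track["start"].to_numpy(), track["end"].to_numpy(),
            chrom_len,
            ShuffleConfig(iterations=iterations, seed=seeds[2 * i + 1]),
        )
        p_values.append(res.p_enrich)
        hits += res.p_enrich < alpha
    return {
        "rate": hits / n_replicates,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "mean_p": float(np.mean(p_values)),
    }


def planted_fold_recovery(
    fold: float = 5.0,
    base_density: float = 0.02,
    iterations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Recover a planted fold-enrichment on the five-arm default map.

    The density ratio is measured against the planted base density (the known
    ground truth); the genome-wide shuffle test must reject the null.
    """
    s_map, s_track, s_test = _spawn(seed, 3)
    gm = process_map(gen_map(seed=s_map).genome_map)
    track = gen_track(
        gm, TrackSpec(base_density=base_density, target_state="aquamarine",
                      fold=fold), seed=s_track,
    )
    dom = gm.state_intervals("aquamarine")
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
    res = genomewide_test(per_chrom, gm.chrom_sizes,
                          ShuffleConfig(iterations=iterations, seed=s_test))
    ratio = density_ratio(dom[["chrom", "start", "end"]], track,
                          expected_fraction=base_density)
    return {
        "ratio": float(ratio["ratio"]),
        "planted_fold": fold,
        "p_enrich": float(res.p_enrich),
        "method": res.method,
        "iterations": iterations,
    }


def normal_approx_agreement(
    n_cases: int = 50,
    iterations: int = 100_000,
    p_range: tuple = (1e-4, 1e-2),
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical vs Gaussian tail p in the moderately far tail.

    Each case: a fresh 3 Mb single-arm map (malachite domains, N ~ 350) and a
    fine-grained fold-1 track; the observed value is set at a null order
    statistic whose empirical p falls log-uniformly inside ``p_range``, and
    the Gaussian tail with the null sample's mean/sd is compared to it.
    """
    spec = MapSpec(chrom_lengths={"2L": 3_000_000}, n_ih_regions=6,
                   ih_length_range=(60_000, 120_000))
    rng = np.random.default_rng(seed)
    seeds = _spawn(seed + 1, 3 * n_cases)
    rows = []
    for i in range(n_cases):
        gm = process_map(gen_map(spec, seed=seeds[3 * i]).genome_map)
        dom = gm.state_intervals("malachite")
        track = gen_track(
            gm, TrackSpec(fold=1.0, base_density=0.12,
                          length_params=(120, 0.3)),
            seed=seeds[3 * i + 1],
        )
        arr = decompose(dom["start"].to_numpy(), dom["end"].to_numpy(),
                        gm.chrom_sizes["2L"])
        nulls = null_statistics(
            arr, track["start"].to_numpy(), track["end"].to_numpy(),
            ShuffleConfig(iterations=iterations),
            np.random.default_rng(seeds[3 * i + 2]),
        )
        m = nulls.size
        target_p = 10 ** rng.uniform(np.log10(p_range[0]),
                                     np.log10(p_range[1]))
        k = max(1, int(round(target_p * m)))
        obs = np.sort(nulls)[m - k]
        emp = float((nulls >= obs).sum() / m)
        gauss = normal_tail_p(obs, float(nulls.mean()),
                              float(nulls.std(ddof=1)), "enrich")
        rows.append({"case": i, "n_domains": arr.n_domains,
                     "empirical_p": emp, "normal_p": gauss,
                     "ratio": gauss / emp})
    return pd.DataFrame(rows)


def gradient_recovery(
    n_runs: int = 100,
    slope_per_kb: float = 0.02,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> dict:
    """Fraction of runs whose fitted border-gradient slope covers the truth.

    The planted score falls by ``slope_per_kb`` per kb of border distance, so
    the fitted slope should equal ``-slope_per_kb`` within 2 standard errors
    in about 95% of runs.
    """
    spec = MapSpec(chrom_lengths={"2L": 800_000}, n_ih_regions=2,
                   ih_length_range=(80_000, 150_000))
    seeds = _spawn(seed, 2 * n_runs)
    covered = 0
    for i in range(n_runs):
        data = gen_map(spec, seed=seeds[2 * i])
        p = gen_probes(data.genome_map, data.ih_regions,
                       slope_per_kb=slope_per_kb, noise_sd=noise_sd,
                       seed=seeds[2 * i + 1])
        g = border_gradient(p, data.ih_regions.iloc[0])
        if abs(g["slope_per_kb"] - (-slope_per_kb)) <= 2 * g["slope_se"]:
            covered += 1
    return {"coverage_rate": covered / n_runs, "n_runs": n_runs,
            "planted_slope_per_kb": slope_per_kb, "noise_sd": noise_sd}


def buffer_rule_contacts(n_seeds: int = 20, seed: int = 0) -> dict:
    """Forbidden ruby-aquamarine / ruby-lazurite contacts, rule on vs off."""
    spec_kw = dict(chrom_lengths={"2L": 1_000_000}, n_ih_regions=2,
                   ih_length_range=(60_000, 120_000))
    seeds = _spawn(seed, 2 * n_seeds)
    counts = {True: [], False: []}
    for i, rule in enumerate([True] * n_seeds + [False] * n_seeds):
        gm = process_map(
            gen_map(MapSpec(buffer_rule=rule, **spec_kw),
                    seed=seeds[i]).genome_map
        )
        cm = contact_matrix(gm)
        counts[rule].append(
            int(cm.loc["ruby", "aquamarine"] + cm.loc["ruby", "lazurite"])
        )
    return {"rule_on": counts[True], "rule_off": counts[False],
            "n_seeds": n_seeds}
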