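"""Generator determinism, invariants, and planted-parameter recovery hooks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ihscape.chromatin_map import GAP, STATES, process_map
from ihscape.domain_topology import contact_matrix
from ihscape.overlap_enrichment import overlap_length, total_length
from ihscape.synthetic_data import (
    MapSpec,
    TrackSpec,
    gen_map,
    gen_partition,
    gen_peaks,
    gen_probes,
    gen_track,
)


class TestGenMap:
    def test_same_seed_identical(self, small_spec):
        a = gen_map(small_spec, seed=5)
        b = gen_map(small_spec, seed=5)
        pd.testing.assert_frame_equal(a.genome_map.fragments,
                                      b.genome_map.fragments)
        pd.testing.assert_frame_equal(a.ih_regions, b.ih_regions)

    def test_fragments_tile_declared_arms(self, small_dataset):
        gm = small_dataset.genome_map
        gm.validate()
        frag = gm.fragments
        nongap = frag[frag["state"] != GAP]
        assert ((nongap["end"] - nongap["start"]) == 200).all()

    def test_ih_regions_ruby_dominated(self, default_map, default_dataset):
        from ihscape.chromatin_map import composition
        comp = composition(default_map.domains, default_dataset.ih_regions)
        frac = comp.set_index("state")["fraction"]
        assert frac["ruby"] > 0.7
        assert frac["ruby"] > frac["malachite"] > frac["aquamarine"]

    def test_infeasible_spec_rejected(self):
        spec = MapSpec(chrom_lengths={"2L": 100_000}, n_ih_regions=1,
                       ih_length_range=(90_000, 99_000))
        with pytest.raises(ValueError, match="fit"):
            gen_map(spec, seed=0)

    def test_domain_length_distribution_matches_spec(self):
        """Aquamarine domain lengths follow the configured log-normal
        (KS test against the 200 bp-rounded reference sample, n about 1e3)."""
        spec = MapSpec(chrom_lengths={c: 3_000_000 for c in ("2L", "2R")},
                       n_ih_regions=0)
        gm = process_map(gen_map(spec, seed=9).genome_map)
        lengths = gm.state_intervals("aquamarine").eval("end - start").to_numpy()
        assert len(lengths) > 300
        median, sigma = spec.length_params["aquamarine"]
        rng = np.random.default_rng(1)
        ref = np.maximum(
            np.round(median * np.exp(rng.normal(0, sigma, 20_000)) / 200), 1
        ) * 200
        ks = stats.ks_2samp(lengths, ref)
        assert ks.pvalue > 0.01


class TestBufferRule:
    def test_rule_on_forbids_ruby_open_contacts(self, default_map):
        cm = contact_matrix(default_map)
        assert cm.loc["ruby", "aquamarine"] == 0
        assert cm.loc["ruby", "lazurite"] == 0
        assert cm.loc["ruby", "malachite"] > 0

    def test_rule_off_allows_them(self):
        spec = MapSpec(buffer_rule=False)
        gm = process_map(gen_map(spec, seed=31).genome_map)
        cm = contact_matrix(gm)
        assert cm.loc["ruby", "aquamarine"] + cm.loc["ruby", "lazurite"] > 0


class TestGenTrack:
    def test_fold_zero_leaves_target_empty(self, small_map):
        track = gen_track(small_map, TrackSpec(fold=0.0, base_density=0.05,
                                               target_state="aquamarine"),
                          seed=2)
        aqua = small_map.state_intervals("aquamarine")
        assert overlap_length(aqua[["chrom", "start", "end"]], track) == 0
        assert total_length(track) > 0

    def test_planted_fold_density(self, default_map):
        base, fold = 0.02, 4.0
        track = gen_track(default_map,
                          TrackSpec(base_density=base, fold=fold,
                                    target_state="aquamarine"), seed=7)
        aqua = default_map.state_intervals("aquamarine")
        obs = overlap_length(aqua[["chrom", "start", "end"]], track)
        assert obs / total_length(aqua) == pytest.approx(fold * base, rel=0.05)

    def test_infeasible_coverage_rejected(self, small_map):
        with pytest.raises(ValueError, match="coverage"):
            gen_track(small_map, TrackSpec(base_density=0.3, fold=5.0), seed=0)

    def test_determinism(self, small_map):
        a = gen_track(small_map, TrackSpec(fold=1.0), seed=6)
        b = gen_track(small_map, TrackSpec(fold=1.0), seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestGenPeaks:
    def test_zero_rates_empty(self, small_map):
        peaks = gen_peaks(small_map, {s: 0.0 for s in STATES}, seed=1)
        assert peaks.empty

    def test_negative_rate_rejected(self, small_map):
        with pytest.raises(ValueError):
            gen_peaks(small_map, {"ruby": -1.0}, seed=1)

    def test_determinism(self, small_map):
        a = gen_peaks(small_map, seed=8)
        b = gen_peaks(small_map, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_rate_ratio_recovered(self, default_map):
        from ihscape.overlap_enrichment import peak_density_by_readcount
        peaks = gen_peaks(default_map,
                          {"aquamarine": 100.0, "ruby": 1.0}, seed=12)
        dens = peak_density_by_readcount(peaks, default_map.domains,
                                         [1, np.inf])
        d = dens.set_index("state")["density_per_mb"]
        assert d["aquamarine"] / max(d["ruby"], 1e-9) > 20

    def test_probe_and_peak_outputs_roundtrip_readers(self, tmp_path,
                                                      small_map,
                                                      small_dataset):
        from ihscape.io import read_bed
        peaks = gen_peaks(small_map, seed=3)
        probes = gen_probes(small_map, small_dataset.ih_regions, seed=3)
        for df, name in ((peaks, "peaks.bed"), (probes, "probes.bed")):
            df.to_csv(tmp_path / name, sep="\t", header=False, index=False)
            back = read_bed(tmp_path / name, score=True)
            pd.testing.assert_frame_equal(
                back, df.sort_values(["chrom", "start"]).reset_index(drop=True),
                check_dtype=False,
            )


def test_gen_partition_classes_disjoint(small_map):
    part = gen_partition(small_map, seed=5)
    for _, sub in part.groupby("chrom"):
        sub = sub.sort_values("start")
        assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()
    assert set(part["class"]) == {"open", "neutral", "closed"}
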