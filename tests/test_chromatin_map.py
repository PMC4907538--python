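"""Map construction, the 400 bp gap-fill rule, merging and composition."""

import numpy as np
import pandas as pd
import pytest

from ihscape.chromatin_map import (
    GAP,
    STATES,
    build_map,
    clip_to_regions,
    composition,
    fill_gaps,
    merge_domains,
    process_map,
    read_state_map,
)
from ihscape.io import write_bed

from conftest import frame, tile_fragments


class TestBuildAndRead:
    def test_single_record_parses(self, tmp_path):
        p = tmp_path / "map.bed"
        p.write_text("2L\t0\t200\truby\n")
        gm = read_state_map(p, chrom_sizes={"2L": 200})
        row = gm.fragments.iloc[0]
        assert (row.chrom, row.start, row.end, row.state) == ("2L", 0, 200, "ruby")

    def test_legacy_colour_labels_map_onto_current_names(self, tmp_path):
        p = tmp_path / "map.bed"
        p.write_text(
            "2L\t0\t200\tcyan\n2L\t200\t400\tblue\n"
            "2L\t400\t600\tgreen\n2L\t600\t800\tmagenta\n"
        )
        gm = read_state_map(p, chrom_sizes={"2L": 800})
        assert list(gm.fragments["state"]) == list(STATES)

    def test_overlapping_fragments_rejected(self):
        frag = frame([("2L", 0, 200, "ruby"), ("2L", 100, 300, "ruby")])
        with pytest.raises(ValueError, match="overlap"):
            build_map(frag, chrom_sizes={"2L": 400}, fragment_length=None)

    def test_unknown_state_rejected(self):
        frag = frame([("2L", 0, 200, "vermilion")])
        with pytest.raises(ValueError, match="unknown"):
            build_map(frag, chrom_sizes={"2L": 200})

    def test_uncovered_sequence_materialised_as_gaps(self):
        frag = frame([("2L", 200, 400, "ruby")])
        gm = build_map(frag, chrom_sizes={"2L": 1000})
        gaps = gm.fragments[gm.fragments["state"] == GAP]
        assert [(r.start, r.end) for r in gaps.itertuples()] == [(0, 200), (400, 1000)]
        assert gm.gap_bp == 800
        gm.validate()


class TestFillGaps:
    def make(self, gap_len, left="malachite", right="malachite"):
        frag = tile_fragments("2L", [(left, 200), ("gap", gap_len), (right, 200)])
        return build_map(frag, chrom_sizes={"2L": 400 + gap_len})

    def test_gap_at_boundary_value_filled(self):
        gm = fill_gaps(self.make(400))
        assert list(gm.fragments["state"]) == ["malachite"] * 3

    def test_gap_above_boundary_retained(self):
        gm = fill_gaps(self.make(401))
        assert list(gm.fragments["state"]) == ["malachite", GAP, "malachite"]

    def test_gap_between_different_states_retained(self):
        gm = fill_gaps(self.make(200, left="ruby", right="malachite"))
        assert list(gm.fragments["state"]) == ["ruby", GAP, "malachite"]

    def test_terminal_gap_never_filled(self):
        frag = tile_fragments("2L", [("gap", 300), ("ruby", 200), ("gap", 300)])
        gm = fill_gaps(build_map(frag, chrom_sizes={"2L": 800}))
        assert list(gm.fragments["state"]) == [GAP, "ruby", GAP]

    def test_idempotent_and_label_only(self, default_dataset):
        gm = default_dataset.genome_map
        once = fill_gaps(gm)
        twice = fill_gaps(once)
        pd.testing.assert_frame_equal(once.fragments, twice.fragments)
        # coordinates untouched, non-gap labels untouched
        assert (once.fragments[["start", "end"]].to_numpy()
                == gm.fragments[["start", "end"]].to_numpy()).all()
        nongap = gm.fragments["state"] != GAP
        assert (once.fragments.loc[nongap, "state"]
                == gm.fragments.loc[nongap, "state"]).all()


class TestMergeDomains:
    def test_run_of_three_merges(self):
        frag = tile_fragments("2L", [("ruby", 600)])
        gm = merge_domains(build_map(frag, chrom_sizes={"2L": 600}))
        dom = gm.domains.iloc[0]
        assert (dom.start, dom.end, dom.n_fragments) == (0, 600, 3)

    def test_alternating_states_do_not_merge(self):
        spans = [("ruby", 200), ("malachite", 200)] * 4
        gm = merge_domains(build_map(tile_fragments("2L", spans),
                                     chrom_sizes={"2L": 1600}))
        assert len(gm.domains) == 8
        # abutting neighbours never share a state
        same = (gm.domains["state"].iloc[1:].to_numpy()
                == gm.domains["state"].iloc[:-1].to_numpy())
        abut = (gm.domains["start"].iloc[1:].to_numpy()
                == gm.domains["end"].iloc[:-1].to_numpy())
        assert not (same & abut).any()

    def test_filled_gap_unites_runs_but_residual_gap_breaks(self, toy_map):
        # toy: ruby(600) gap(400, fillable) ruby(400) malachite aquamarine
        gm = merge_domains(fill_gaps(toy_map))
        ruby = gm.domains[gm.domains["state"] == "ruby"]
        assert [(r.start, r.end) for r in ruby.itertuples()] == [(0, 1400)]
        # an over-long gap stays and splits the run
        frag = tile_fragments("2L", [("ruby", 600), ("gap", 600), ("ruby", 400)])
        gm2 = process_map(build_map(frag, chrom_sizes={"2L": 1600}))
        assert len(gm2.domains) == 2

    def test_span_conservation(self, default_map):
        dom_bp = (default_map.domains["end"] - default_map.domains["start"]).sum()
        assert dom_bp + default_map.gap_bp == default_map.total_span

    def test_merge_preserves_per_base_states(self, small_dataset):
        gm = process_map(small_dataset.genome_map)
        filled = fill_gaps(small_dataset.genome_map)
        chrom = next(iter(gm.chrom_sizes))
        size = gm.chrom_sizes[chrom]
        by_frag = np.zeros(size, dtype=np.int16)
        by_dom = np.zeros(size, dtype=np.int16)
        code = {s: i + 1 for i, s in enumerate(STATES)}
        for r in filled.fragments.itertuples():
            if r.state != GAP:
                by_frag[r.start:r.end] = code[r.state]
        for r in gm.domains.itertuples():
            by_dom[r.start:r.end] = code[r.state]
        assert (by_frag == by_dom).all()


class TestClipAndComposition:
    def test_clip_straddling_domain(self):
        dom = frame([("2L", 100, 500, "ruby", 2)],
                    columns=["chrom", "start", "end", "state", "n_fragments"])
        reg = frame([("2L", 300, 900, "r1")],
                    columns=["chrom", "start", "end", "name"])
        out = clip_to_regions(dom, reg)
        row = out.iloc[0]
        assert (row.start, row.end) == (300, 500)
        assert (row.parent_start, row.parent_end) == (100, 500)

    def test_disjoint_domain_absent(self):
        dom = frame([("2L", 0, 200, "ruby", 1)],
                    columns=["chrom", "start", "end", "state", "n_fragments"])
        reg = frame([("2L", 500, 900, "r1")],
                    columns=["chrom", "start", "end", "name"])
        assert clip_to_regions(dom, reg).empty

    def test_region_on_unknown_chromosome_errors(self):
        dom = frame([("2L", 0, 200, "ruby", 1)],
                    columns=["chrom", "start", "end", "state", "n_fragments"])
        reg = frame([("4", 0, 100, "r1")],
                    columns=["chrom", "start", "end", "name"])
        with pytest.raises(ValueError, match="absent"):
            clip_to_regions(dom, reg)

    def test_single_ruby_region_is_all_ruby(self):
        dom = frame([("2L", 100, 500, "ruby", 2)],
                    columns=["chrom", "start", "end", "state", "n_fragments"])
        reg = frame([("2L", 100, 500, "r1")],
                    columns=["chrom", "start", "end", "name"])
        comp = composition(dom, reg)
        assert comp.loc[comp["state"] == "ruby", "fraction"].iloc[0] == 1.0

    def test_fractions_sum_to_one_and_bp_conserved(self, default_map,
                                                   default_dataset):
        comp = composition(default_map.domains, default_dataset.ih_regions)
        span = (default_dataset.ih_regions["end"]
                - default_dataset.ih_regions["start"]).sum()
        assert comp["bp"].sum() == span
        assert comp["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        no_gap = composition(default_map.domains, default_dataset.ih_regions,
                             include_gaps=False)
        assert no_gap["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_region_set_rejected(self, default_map):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        with pytest.raises(ValueError, match="empty"):
            composition(default_map.domains, empty)


def test_map_roundtrips_through_reader(tmp_path, small_dataset):
    frag = small_dataset.genome_map.fragments
    p = tmp_path / "map.bed"
    write_bed(frag[frag["state"] != GAP], p)
    gm2 = read_state_map(p, chrom_sizes=small_dataset.genome_map.chrom_sizes)
    pd.testing.assert_frame_equal(
        gm2.fragments, small_dataset.genome_map.fragments
    )
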