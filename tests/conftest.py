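import numpy as np
import pandas as pd
import pytest

from ihscape.chromatin_map import build_map, process_map
from ihscape.synthetic_data import MapSpec, gen_map


def frame(rows, columns=("chrom", "start", "end", "state")):
    return pd.DataFrame(rows, columns=list(columns))


@pytest.fixture(scope="session")
def small_spec():
    """One short arm with two IH regions: the workhorse desk-scale layout."""
    return MapSpec(
        chrom_lengths={"2L": 800_000},
        n_ih_regions=2,
        ih_length_range=(80_000, 150_000),
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return gen_map(small_spec, seed=20240)


@pytest.fixture(scope="session")
def small_map(small_dataset):
    return process_map(small_dataset.genome_map)


@pytest.fixture(scope="session")
def default_dataset():
    """The five-arm default layout emulating the study's genome structure."""
    return gen_map(seed=777)


@pytest.fixture(scope="session")
def default_map(default_dataset):
    return process_map(default_dataset.genome_map)


def tile_fragments(chrom, spans):
    """Expand (state, length) tokens into 200 bp fragments / gap records."""
    rows = []
    pos = 0
    for state, length in spans:
        if state == "gap":
            rows.append((chrom, pos, pos + length, "gap"))
        else:
            for off in range(0, length, 200):
                rows.append((chrom, pos + off, pos + off + 200, state))
        pos += length
    return frame(rows)


@pytest.fixture
def toy_map():
    """ruby(600) gap(400) ruby(400) malachite(200) aquamarine(400) on 2 kb."""
    frag = tile_fragments(
        "2L",
        [("ruby", 600), ("gap", 400), ("ruby", 400),
         ("malachite", 200), ("aquamarine", 400)],
    )
    return build_map(frag, chrom_sizes={"2L": 2000})
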