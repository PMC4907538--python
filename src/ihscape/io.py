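"""Readers and writers for the plain-text dialects the pipeline exchanges.

Everything is tab-separated BED-like text: interval tracks as BED3/BED4/BED5,
chromosome sizes as two columns, scored probes/peaks as BED with a float/int
score column. Files may carry ``#`` comment lines and a ``track``/header line.
"""

from __future__ import annotations

import pandas as pd

BED3 = ["chrom", "start", "end"]
BED4 = ["chrom", "start", "end", "name"]


def _read_tsv(path, names):
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=names,
        dtype={"chrom": str},
    )
    return df


def read_chrom_sizes(path) -> dict:
    df = _read_tsv(path, ["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_bed(path, score: bool = False, name: str | None = None) -> pd.DataFrame:
    """Read a BED3 (+ optional 4th column) interval file.

    With ``score=True`` the 4th column is parsed as a numeric ``score``;
    otherwise, with ``name`` given, as a string column of that name.
    """
    if score:
        df = _read_tsv(path, BED3 + ["score"])
        df["score"] = pd.to_numeric(df["score"])
    elif name is not None:
        df = _read_tsv(path, BED3 + [name])
        df[name] = df[name].astype(str)
    else:
        df = _read_tsv(path, BED3)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0]
        raise ValueError(f"{path}: empty or inverted interval at record {bad + 1}")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_regions(path) -> pd.DataFrame:
    """IH regions as BED4 (name = cytological band label)."""
    return read_bed(path, name="name")


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
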