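"""Readers and writers for the plain-text tables the pipeline exchanges.

All tables are TSV.  Genotype matrices have a ``locus`` first column and
one column per individual with cells AA/AB/BB/NA; anchor tables map locus
to reference chromosome and 1-based physical position.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = [
    "read_anchors",
    "write_anchors",
    "read_classes",
    "read_haplo_flags",
    "read_depths",
    "read_chromosome_lengths",
]


def read_anchors(path) -> pd.DataFrame:
    """Locus -> (ref_chrom, ref_pos) table; one top-hit anchor per locus."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "ref_chrom": str})
    required = {"locus", "ref_chrom", "ref_pos"}
    if not required <= set(df.columns):
        raise ValueError(f"anchor table needs columns {sorted(required)}")
    df["ref_pos"] = df["ref_pos"].astype(int)
    if (df["ref_pos"] < 1).any():
        raise ValueError("physical positions are 1-based; found position < 1")
    if df["locus"].duplicated().any():
        dup = df.loc[df["locus"].duplicated(), "locus"].iloc[0]
        raise ValueError(f"more than one anchor for locus {dup!r}")
    return df.set_index("locus")


def write_anchors(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_classes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str})
    return df.set_index("locus")


def read_haplo_flags(path) -> pd.DataFrame:
    """Locus -> (vesca_match, iinumae_match) boolean flags."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str})
    required = {"locus", "vesca_match", "iinumae_match"}
    if not required <= set(df.columns):
        raise ValueError(f"flag table needs columns {sorted(required)}")
    for col in ("vesca_match", "iinumae_match"):
        df[col] = df[col].map(
            {True: True, False: False, "True": True, "False": False,
             "Y": True, "N": False, 1: True, 0: False, "1": True, "0": False})
        if df[col].isna().any():
            raise ValueError(f"column {col} contains non-boolean values")
    return df.set_index("locus")


def read_depths(path) -> pd.DataFrame:
    """Locus -> (depth, label) read-depth records."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "label": str})
    required = {"locus", "depth", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"depth table needs columns {sorted(required)}")
    df["depth"] = df["depth"].astype(float)
    if (df["depth"] < 0).any():
        raise ValueError("negative read depth")
    return df.set_index("locus")


def read_chromosome_lengths(path) -> Mapping[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"ref_chrom": str})
    if not {"ref_chrom", "length"} <= set(df.columns):
        raise ValueError("length table needs columns ['ref_chrom', 'length']")
    return dict(zip(df["ref_chrom"], df["length"].astype(float)))
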