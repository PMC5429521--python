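"""Comparison of a genetic map against reference physical positions,
ancestor-haplotype flags, other maps and read-depth evidence."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "collinearity_stats",
    "coverage_ratio",
    "tally_haplosnps",
    "map_commonality",
    "depth_comparison",
    "DepthComparison",
    "expected_mutations_per_year",
]

_ROMAN = ["B_I", "B_II", "B_III", "B_IV", "B_V", "B_VI", "B_VII"]


def _anchored(locus_table: pd.DataFrame, anchors: pd.DataFrame) -> pd.DataFrame:
    joined = locus_table.join(anchors[["ref_chrom", "ref_pos"]], how="inner")
    return joined


def collinearity_stats(locus_table: pd.DataFrame,
                       anchors: pd.DataFrame,
                       min_anchors: int = 3,
                       min_segment: int = 3) -> pd.DataFrame:
    """Per-LG collinearity between map position (cM) and physical
    position (bp).

    The assigned reference chromosome is the majority vote of the LG's
    anchors; Spearman rho is reported with its orientation sign.  Inversion
    segments are maximal runs of at least ``min_segment`` consecutive loci
    (in map order, one representative physical position per map position)
    whose local physical order is reversed relative to the LG's overall
    orientation.  LGs with fewer than ``min_anchors`` anchors are flagged
    undefined.
    """
    joined = _anchored(locus_table, anchors)
    rows = []
    for lg, sub in joined.groupby("lg"):
        chrom = sub["ref_chrom"].mode().iloc[0] if len(sub) else None
        on_chrom = sub[sub["ref_chrom"] == chrom].sort_values(
            ["position_cm"], kind="mergesort")
        if len(on_chrom) < min_anchors:
            rows.append({"lg": lg, "ref_chrom": chrom, "n_anchors": len(on_chrom),
                         "rho": math.nan, "n_inversion_segments": 0,
                         "defined": False})
            continue
        rho = stats.spearmanr(on_chrom["position_cm"],
                              on_chrom["ref_pos"]).statistic
        # collapse co-located loci (bins) to one physical position
        per_pos = on_chrom.groupby("position_cm")["ref_pos"].median()
        orientation = 1.0 if not (np.isfinite(rho) and rho < 0) else -1.0
        steps = np.sign(np.diff(per_pos.to_numpy())) * orientation
        n_segments = 0
        run = 0
        for s in steps:
            if s < 0:
                run += 1
            else:
                if run >= min_segment - 1:
                    n_segments += 1
                run = 0
        if run >= min_segment - 1:
            n_segments += 1
        rows.append({"lg": lg, "ref_chrom": chrom, "n_anchors": len(on_chrom),
                     "rho": float(rho), "n_inversion_segments": n_segments,
                     "defined": True})
    return pd.DataFrame(rows).set_index("lg")


def coverage_ratio(locus_table: pd.DataFrame, anchors: pd.DataFrame,
                   chromosome_lengths: Mapping[str, float]) -> pd.DataFrame:
    """Percent of each LG's reference chromosome spanned by its anchors.

    Defined as (max anchored bp - min anchored bp) / chromosome length
    x 100, clamped to [0, 100]; LGs with fewer than two anchors report 0
    and are flagged.  Unknown chromosome lengths raise a KeyError naming
    the chromosome.
    """
    joined = _anchored(locus_table, anchors)
    rows = []
    for lg, sub in joined.groupby("lg"):
        chrom = sub["ref_chrom"].mode().iloc[0]
        on_chrom = sub[sub["ref_chrom"] == chrom]
        if chrom not in chromosome_lengths:
            raise KeyError(f"no length known for reference chromosome {chrom!r}")
        length = float(chromosome_lengths[chrom])
        if len(on_chrom) < 2:
            rows.append({"lg": lg, "ref_chrom": chrom, "coverage_pct": 0.0,
                         "n_anchors": len(on_chrom), "defined": False})
            continue
        span = float(on_chrom["ref_pos"].max() - on_chrom["ref_pos"].min())
        pct = min(max(100.0 * span / length, 0.0), 100.0)
        rows.append({"lg": lg, "ref_chrom": chrom, "coverage_pct": pct,
                     "n_anchors": len(on_chrom), "defined": True})
    return pd.DataFrame(rows).set_index("lg")


def tally_haplosnps(locus_table: pd.DataFrame,
                    flags: pd.DataFrame) -> pd.DataFrame:
    """Count ancestor-haplotype categories per LG and name LGs within HGs.

    ``flags`` is indexed by locus with boolean columns ``vesca_match`` and
    ``iinumae_match``.  Per LG the four categories Y-N / Y-Y / N-Y / N-N
    are tallied; within each HG the LG(s) with the maximum Y-N count are
    labelled ``A`` (ties: all co-candidates are flagged) and the rest
    ``B_I`` ... by descending mapped-locus count.
    """
    joined = locus_table.join(flags, how="left")
    rows = []
    for lg, sub in joined.groupby("lg"):
        flagged = sub.dropna(subset=["vesca_match", "iinumae_match"])
        v = flagged["vesca_match"].astype(bool)
        i = flagged["iinumae_match"].astype(bool)
        rows.append({
            "lg": lg,
            "hg": sub["hg"].iloc[0],
            "n_mapped": len(sub),
            "n_flagged": len(flagged),
            "Y-N": int((v & ~i).sum()),
            "Y-Y": int((v & i).sum()),
            "N-Y": int((~v & i).sum()),
            "N-N": int((~v & ~i).sum()),
        })
    out = pd.DataFrame(rows).set_index("lg")
    out["a_candidate"] = False
    out["label"] = ""
    for hg, sub in out.groupby("hg"):
        best = sub["Y-N"].max()
        a_lgs = sorted(sub.index[sub["Y-N"] == best])
        for lg in a_lgs:
            out.at[lg, "a_candidate"] = True
            out.at[lg, "label"] = "A"
        others = sub.drop(index=a_lgs).sort_values(
            ["n_mapped"], ascending=False, kind="mergesort")
        for rank, lg in enumerate(others.index):
            out.at[lg, "label"] = _ROMAN[rank] if rank < len(_ROMAN) else f"B_{rank + 1}"
    return out


def map_commonality(id_sets: Mapping[str, Iterable[str]]) -> Dict[str, object]:
    """Exact intersection cardinalities across two or more maps.

    Returns pairwise intersection counts, the count common to all maps,
    and per-map specific counts (loci found on no other map).
    """
    sets: Dict[str, Set[str]] = {k: set(v) for k, v in id_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two locus-id sets")
    if any(len(s) == 0 for s in sets.values()):
        raise ValueError("empty locus-id set")
    names = sorted(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    common_all = len(set.intersection(*sets.values()))
    specific = {}
    for a in names:
        others = set.union(*(sets[b] for b in names if b != a))
        specific[a] = len(sets[a] - others)
    return {
        "n_maps": len(names),
        "pairwise": pairwise,
        "common_all": common_all,
        "specific": specific,
        "union": len(set.union(*sets.values())),
    }


@dataclass
class DepthComparison:
    means: Dict[str, float]
    t_statistic: float
    p_value: float
    histograms: Dict[str, Tuple[np.ndarray, np.ndarray]]  # label -> (edges, freq)
    modes: Dict[str, float]
    defined: bool = True


def depth_comparison(depths: pd.DataFrame, bin_width: float = 0.1,
                     labels: Tuple[str, str] = ("PHR-like", "NMH-like")
                     ) -> DepthComparison:
    """Compare mapped-read depths between the two marker classes.

    Uses the equal-variance two-sample (Student) t-test on raw depths, and
    builds per-class histograms of depth normalized by the class mode
    (fixed ``bin_width`` on the ratio scale); single-copy loci should show
    one ratio peak near 1, homoeologous loci several.
    """
    groups = {}
    for label in labels:
        vals = depths.loc[depths["label"] == label, "depth"].to_numpy(dtype=float)
        groups[label] = vals
    if any(len(v) < 2 for v in groups.values()):
        return DepthComparison({k: math.nan for k in groups}, math.nan, math.nan,
                               {}, {}, defined=False)
    a, b = (groups[l] for l in labels)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    means = {label: float(v.mean()) for label, v in groups.items()}
    histograms = {}
    modes = {}
    for label, vals in groups.items():
        counts = np.bincount(np.round(vals).astype(int))
        mode = float(np.argmax(counts))
        if mode <= 0:
            mode = max(float(np.median(vals)), 1.0)
        ratio = vals / mode
        top = max(ratio.max(), 1.0)
        edges = np.arange(0.0, top + 2 * bin_width, bin_width)
        freq, edges = np.histogram(ratio, bins=edges)
        histograms[label] = (edges, freq)
        modes[label] = mode
    return DepthComparison(means, float(t), float(p), histograms, modes)


def expected_mutations_per_year(genome_size_bp: float,
                                rate_per_site_per_year: float = 1.5e-8) -> float:
    """Expected new point mutations per year across a genome of the given
    size at a per-site per-year substitution rate."""
    if genome_size_bp < 0 or rate_per_site_per_year < 0:
        raise ValueError("negative rate or genome size")
    return genome_size_bp * rate_per_site_per_year
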