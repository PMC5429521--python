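"""Per-locus segregation classification.

Each locus's AA/AB/BB counts are tested against the candidate segregation
ratios of the selfing design (1:2:1 codominant, 0:3:1 dominant with either
null homozygote class, 1:1, monomorphic) and assigned the compatible class
with the largest goodness-of-fit p-value.  Codominant 1:2:1 loci are the
candidate subgenome-specific markers; 3:1 loci point at homoeologous
targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .polyploid_model import (
    CANONICAL_CLASS,
    SEGREGATION_RATIOS,
    PhenotypeDistribution,
    SegregationClass,
    segregation_class,
)
from .synthetic_data import GenotypeMatrix

__all__ = [
    "LocusClassification",
    "chi2_goodness_of_fit",
    "classify_locus",
    "classify_matrix",
    "classification_report",
    "CANDIDATE_VARIANTS",
]

# Candidate classes evaluated for every locus, in tie-break priority order.
CANDIDATE_VARIANTS: Tuple[str, ...] = (
    "codominant_1_2_1",
    "dominant_AB_BB_3_1",
    "dominant_AB_AA_3_1",
    "one_to_one_AA_AB",
    "one_to_one_AB_BB",
    "monomorphic_AA",
    "monomorphic_AB",
    "monomorphic_BB",
)


@dataclass(frozen=True)
class LocusClassification:
    locus: str
    n_AA: int
    n_AB: int
    n_BB: int
    n_missing: int
    best_class: Optional[SegregationClass]
    variant: str
    chi2: float
    p_value: float
    distorted: bool
    passes_filters: bool


def _expected_probs(expected) -> np.ndarray:
    if isinstance(expected, PhenotypeDistribution):
        probs = np.array([float(expected.p_AA), float(expected.p_AB),
                          float(expected.p_BB)], dtype=float)
        total = probs.sum()
        if total <= 0:
            raise ValueError("expected distribution has no called class")
        return probs / total
    probs = np.asarray([float(p) for p in expected], dtype=float)
    if probs.size == 4:  # (AA, AB, BB, no-call): condition on a call
        probs = probs[:3]
    if probs.size != 3:
        raise ValueError("expected ratio must have three classes (AA, AB, BB)")
    if probs.sum() <= 0:
        raise ValueError("at least one expected class must be nonzero")
    return probs / probs.sum()


def chi2_goodness_of_fit(counts: Sequence[int], expected) -> Tuple[float, float]:
    """Pearson chi-square of observed (n_AA, n_AB, n_BB) against an expected
    call distribution.

    Classes with zero expected probability but nonzero observed count make
    the pattern incompatible: ``(inf, 0.0)``.  Degrees of freedom are the
    number of nonzero expected classes minus one.
    """
    obs = np.asarray(counts[:3], dtype=float)
    if (obs < 0).any():
        raise ValueError("negative counts")
    probs = _expected_probs(expected)
    n = obs.sum()
    if n == 0:
        return math.nan, math.nan
    positive = probs > 0
    if obs[~positive].sum() > 0:
        return math.inf, 0.0
    df = int(positive.sum()) - 1
    if df == 0:
        return 0.0, 1.0
    exp = probs[positive] * n
    chi2 = float(((obs[positive] - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df))


def _fit_with_allowance(obs: np.ndarray, probs: np.ndarray,
                        allowance: int) -> Tuple[float, float]:
    """Goodness of fit where up to ``allowance`` observations in
    expected-zero classes are treated as call errors and dropped from the
    conditional test; more than that makes the class incompatible."""
    positive = probs > 0
    stray = int(obs[~positive].sum())
    if stray > allowance:
        return math.inf, 0.0
    kept = obs[positive]
    n = kept.sum()
    if n == 0:
        return math.nan, math.nan
    df = int(positive.sum()) - 1
    if df == 0:
        return 0.0, 1.0
    exp = probs[positive] / probs[positive].sum() * n
    chi2 = float(((kept - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df))


def classify_locus(
    counts: Sequence[int],
    alpha: float = 0.01,
    max_missing: int = 20,
    distortion_alpha: float = 0.05,
    zero_allowance: Optional[int] = None,
    locus: str = "",
) -> LocusClassification:
    """Assign the best-fitting segregation class to one locus.

    ``counts`` is ``(n_AA, n_AB, n_BB, n_missing)``.  Among compatible
    candidate ratios the one with maximum p-value wins (ties break by the
    fixed candidate order).  ``distorted`` flags best-fit p below
    ``distortion_alpha``; ``passes_filters`` requires missing data at or
    under ``max_missing`` and goodness-of-fit p at or above ``alpha``.

    ``zero_allowance`` is the number of calls tolerated (and conditioned
    away) in classes a ratio expects to be absent, absorbing genotyping
    error at otherwise clean dominant/monomorphic loci; the default scales
    with the number of called individuals.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts[:3])
    n_missing = int(counts[3]) if len(counts) > 3 else 0
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    n_called = int(obs.sum())
    if zero_allowance is None:
        zero_allowance = max(3, round(0.03 * n_called))

    if n_called == 0:
        return LocusClassification(locus, n_aa, n_ab, n_bb, n_missing,
                                   None, "other", math.nan, math.nan,
                                   distorted=False, passes_filters=False)

    best_variant = None
    best = (-1.0, math.inf)  # (p, chi2)
    for variant in CANDIDATE_VARIANTS:
        probs = _expected_probs(SEGREGATION_RATIOS[variant])
        chi2, p = _fit_with_allowance(obs, probs, zero_allowance)
        if not math.isfinite(chi2):
            continue
        if p > best[0] + 1e-15:
            best = (p, chi2)
            best_variant = variant

    if best_variant is None:  # cannot happen: 1:2:1 is always compatible
        return LocusClassification(locus, n_aa, n_ab, n_bb, n_missing,
                                   None, "other", math.inf, 0.0,
                                   distorted=True, passes_filters=False)
    p, chi2 = best
    passes = (n_missing <= max_missing) and (p >= alpha)
    return LocusClassification(
        locus, n_aa, n_ab, n_bb, n_missing,
        segregation_class(best_variant), best_variant, chi2, p,
        distorted=p < distortion_alpha, passes_filters=passes,
    )


def classify_matrix(
    matrix: GenotypeMatrix,
    alpha: float = 0.01,
    max_missing: int = 20,
    distortion_alpha: float = 0.05,
    zero_allowance: Optional[int] = None,
) -> pd.DataFrame:
    """Classify every locus of a genotype matrix.

    Returns a frame indexed by locus with columns ``n_AA, n_AB, n_BB,
    n_missing, class, variant, chi2, p, distorted, passes_filters``.
    """
    counts = matrix.counts()
    rows = []
    for locus, row in counts.iterrows():
        c = classify_locus(
            (row["n_AA"], row["n_AB"], row["n_BB"], row["n_missing"]),
            alpha=alpha, max_missing=max_missing,
            distortion_alpha=distortion_alpha, zero_allowance=zero_allowance,
            locus=str(locus),
        )
        rows.append({
            "locus": c.locus,
            "n_AA": c.n_AA, "n_AB": c.n_AB, "n_BB": c.n_BB,
            "n_missing": c.n_missing,
            "class": CANONICAL_CLASS.get(c.variant, "other"),
            "variant": c.variant,
            "chi2": c.chi2, "p": c.p_value,
            "distorted": c.distorted, "passes_filters": c.passes_filters,
        })
    if not rows:
        return pd.DataFrame(
            columns=["locus", "n_AA", "n_AB", "n_BB", "n_missing", "class",
                     "variant", "chi2", "p", "distorted", "passes_filters"]
        ).set_index("locus")
    return pd.DataFrame(rows).set_index("locus")


def classification_report(classes: pd.DataFrame) -> pd.DataFrame:
    """Summary counts and percentages per segregation class."""
    if len(classes) == 0:
        return pd.DataFrame(columns=["class", "count", "percent"]).set_index("class")
    grouped = classes.groupby("class").size().sort_values(ascending=False)
    out = pd.DataFrame({
        "count": grouped,
        "percent": 100.0 * grouped / grouped.sum(),
    })
    out.index.name = "class"
    return out
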