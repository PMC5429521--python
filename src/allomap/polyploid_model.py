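"""Exact disomic-inheritance combinatorics for allo-polyploid loci.

A locus is described by the allele state of the eight parental homologs,
grouped into four subgenome pairs.  At meiosis each subgenome forms a
bivalent and transmits one of its two homologs with probability 1/2,
independently of the other subgenomes; homoeologous chromosomes never pair.
Observed biallelic calls are dosage blind: an offspring carrying at least
one A and one B allele anywhere across its homologs reads AB, all-A reads
AA, all-B reads BB, and no allele at all gives no call.

All probabilities are computed by exact enumeration with rational
arithmetic and only converted to floats at the boundary, so every returned
probability is a dyadic rational represented exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Dict, Iterator, Optional, Tuple

__all__ = [
    "ALLELES",
    "ConfigurationError",
    "AlleleConfiguration",
    "GameteDistribution",
    "PhenotypeDistribution",
    "SegregationClass",
    "SEGREGATION_RATIOS",
    "CANONICAL_CLASS",
    "gamete_distribution",
    "expected_segregation",
    "is_subgenome_specific",
    "classify_distribution",
    "all_valid_configurations",
]

ALLELES = ("A", "B", "O")


class ConfigurationError(ValueError):
    """Raised for malformed homolog-allele configuration strings."""


@dataclass(frozen=True)
class AlleleConfiguration:
    """Allele state of the eight parental homologs of one locus.

    Parameters
    ----------
    homolog_alleles:
        Eight symbols over ``{A, B, O}``; positions ``2k`` and ``2k+1``
        are the two homologs of subgenome ``k``.  Within a subgenome pair
        either both symbols are ``O`` (locus absent from that subgenome)
        or both are non-``O``.
    """

    homolog_alleles: Tuple[str, ...]

    N_SUBGENOMES = 4

    def __post_init__(self) -> None:
        alleles = tuple(self.homolog_alleles)
        object.__setattr__(self, "homolog_alleles", alleles)
        n = 2 * self.N_SUBGENOMES
        if len(alleles) != n:
            raise ConfigurationError(
                f"configuration {''.join(alleles)!r} has length "
                f"{len(alleles)}, expected {n}"
            )
        for sym in alleles:
            if sym not in ALLELES:
                raise ConfigurationError(
                    f"invalid allele symbol {sym!r}; must be one of {ALLELES}"
                )
        for k, (a, b) in enumerate(self.pairs, start=1):
            if (a == "O") != (b == "O"):
                raise ConfigurationError(
                    f"subgenome {k} mixes a null with a non-null allele "
                    f"({a}{b}); a locus is either present in a subgenome "
                    "or absent from it"
                )
        if all(a == "O" for a in alleles):
            raise ConfigurationError("configuration has no non-null allele")

    @classmethod
    def from_string(cls, label: str) -> "AlleleConfiguration":
        return cls(tuple(label))

    @property
    def label(self) -> str:
        return "".join(self.homolog_alleles)

    @property
    def pairs(self) -> Tuple[Tuple[str, str], ...]:
        a = self.homolog_alleles
        return tuple((a[2 * k], a[2 * k + 1]) for k in range(self.N_SUBGENOMES))

    @property
    def present_subgenomes(self) -> Tuple[int, ...]:
        """0-based indices of subgenomes carrying the locus."""
        return tuple(k for k, (a, _) in enumerate(self.pairs) if a != "O")

    @property
    def heterozygous_subgenomes(self) -> Tuple[int, ...]:
        return tuple(k for k, (a, b) in enumerate(self.pairs) if a != b and a != "O")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _as_config(config) -> AlleleConfiguration:
    if isinstance(config, AlleleConfiguration):
        return config
    return AlleleConfiguration.from_string(str(config))


@dataclass(frozen=True)
class GameteDistribution:
    """Distribution over gamete allele tuples (one symbol per subgenome)."""

    outcomes: Dict[Tuple[str, ...], Fraction]

    def __post_init__(self) -> None:
        total = sum(self.outcomes.values())
        if total != 1:
            raise ValueError(f"gamete probabilities sum to {total}, not 1")

    def items(self) -> Iterator[Tuple[Tuple[str, ...], Fraction]]:
        return iter(self.outcomes.items())

    def as_floats(self) -> Dict[Tuple[str, ...], float]:
        return {g: float(p) for g, p in self.outcomes.items()}


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Probabilities of the collapsed biallelic call of an offspring."""

    p_AA: Fraction
    p_AB: Fraction
    p_BB: Fraction
    p_null: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        for p in (self.p_AA, self.p_AB, self.p_BB, self.p_null):
            if p < 0:
                raise ValueError("negative phenotype probability")
        total = self.p_AA + self.p_AB + self.p_BB + self.p_null
        if total != 1:
            raise ValueError(f"phenotype probabilities sum to {total}, not 1")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (float(self.p_AA), float(self.p_AB), float(self.p_BB), float(self.p_null))

    def ratio(self, num: str, den: str) -> float:
        """Odds of one call class against another, e.g. ``ratio('AB', 'AA')``."""
        values = {"AA": self.p_AA, "AB": self.p_AB, "BB": self.p_BB, "null": self.p_null}
        return float(Fraction(values[num], values[den]))


def gamete_distribution(config) -> GameteDistribution:
    """Enumerate the gametes of one parent under disomic inheritance.

    Each subgenome transmits one of its two homolog alleles with
    probability 1/2, independently across subgenomes; the 2^4 homolog
    choices are enumerated exactly.
    """
    cfg = _as_config(config)
    pairs = cfg.pairs
    outcomes: Dict[Tuple[str, ...], Fraction] = {}
    n = cfg.N_SUBGENOMES
    unit = Fraction(1, 2**n)
    for choice in product((0, 1), repeat=n):
        gamete = tuple(pairs[k][choice[k]] for k in range(n))
        outcomes[gamete] = outcomes.get(gamete, Fraction(0)) + unit
    return GameteDistribution(outcomes)


def _collapse_call(alleles: Tuple[str, ...]) -> str:
    has_a = "A" in alleles
    has_b = "B" in alleles
    if has_a and has_b:
        return "AB"
    if has_a:
        return "AA"
    if has_b:
        return "BB"
    return "null"


def expected_segregation(maternal, paternal=None) -> PhenotypeDistribution:
    """Expected offspring call distribution for a cross (or selfing).

    Convolves the two parental gamete distributions and collapses each
    offspring's combined allele set to an AA/AB/BB/no-call phenotype.
    Selfing is the ``paternal is None`` (or identical-configuration) case.
    The result is exact.
    """
    mat = _as_config(maternal)
    pat = mat if paternal is None else _as_config(paternal)
    gm = gamete_distribution(mat)
    gp = gamete_distribution(pat) if pat is not mat else gm
    probs = {"AA": Fraction(0), "AB": Fraction(0), "BB": Fraction(0), "null": Fraction(0)}
    for g1, p1 in gm.items():
        for g2, p2 in gp.items():
            probs[_collapse_call(g1 + g2)] += p1 * p2
    return PhenotypeDistribution(probs["AA"], probs["AB"], probs["BB"], probs["null"])


def is_subgenome_specific(config) -> bool:
    """True iff the marker target exists in exactly one subgenome."""
    return len(_as_config(config).present_subgenomes) == 1


# Named segregation ratios (AA, AB, BB, no-call) used throughout the
# pipeline.  Keys are class *variants*; CANONICAL_CLASS maps them onto the
# coarse class names used in reports.
SEGREGATION_RATIOS: Dict[str, Tuple[Fraction, Fraction, Fraction, Fraction]] = {
    "codominant_1_2_1": (Fraction(1, 4), Fraction(1, 2), Fraction(1, 4), Fraction(0)),
    "dominant_AB_BB_3_1": (Fraction(0), Fraction(3, 4), Fraction(1, 4), Fraction(0)),
    "dominant_AB_AA_3_1": (Fraction(1, 4), Fraction(3, 4), Fraction(0), Fraction(0)),
    "one_to_one_AA_AB": (Fraction(1, 2), Fraction(1, 2), Fraction(0), Fraction(0)),
    "one_to_one_AB_BB": (Fraction(0), Fraction(1, 2), Fraction(1, 2), Fraction(0)),
    "monomorphic_AA": (Fraction(1), Fraction(0), Fraction(0), Fraction(0)),
    "monomorphic_AB": (Fraction(0), Fraction(1), Fraction(0), Fraction(0)),
    "monomorphic_BB": (Fraction(0), Fraction(0), Fraction(1), Fraction(0)),
}

CANONICAL_CLASS: Dict[str, str] = {
    "codominant_1_2_1": "codominant_1_2_1",
    "dominant_AB_BB_3_1": "dominant_AB_BB_3_1",
    "dominant_AB_AA_3_1": "dominant_AB_AA_3_1",
    "one_to_one_AA_AB": "one_to_one",
    "one_to_one_AB_BB": "one_to_one",
    "monomorphic_AA": "monomorphic",
    "monomorphic_AB": "monomorphic",
    "monomorphic_BB": "monomorphic",
}


@dataclass(frozen=True)
class SegregationClass:
    """A named expected segregation pattern."""

    name: str
    expected_ratio: PhenotypeDistribution
    variant: str = ""

    def __post_init__(self) -> None:
        if self.variant in SEGREGATION_RATIOS:
            expect = PhenotypeDistribution(*SEGREGATION_RATIOS[self.variant])
            if expect != self.expected_ratio:
                raise ValueError(
                    f"expected ratio inconsistent with variant {self.variant!r}"
                )


def segregation_class(variant: str) -> SegregationClass:
    """Build the :class:`SegregationClass` for a named ratio variant."""
    ratio = PhenotypeDistribution(*SEGREGATION_RATIOS[variant])
    return SegregationClass(CANONICAL_CLASS[variant], ratio, variant)


def classify_distribution(dist: PhenotypeDistribution) -> Optional[SegregationClass]:
    """Match an exact phenotype distribution to a named segregation class.

    Returns ``None`` when the distribution matches no registered ratio
    (callers report such loci as ``other``).
    """
    key = (dist.p_AA, dist.p_AB, dist.p_BB, dist.p_null)
    for variant, ratio in SEGREGATION_RATIOS.items():
        if key == ratio:
            return segregation_class(variant)
    return None


def all_valid_configurations() -> Iterator[AlleleConfiguration]:
    """Enumerate every valid configuration (pairs over AA/AB/BB/OO)."""
    pair_states = ("AA", "AB", "BA", "BB", "OO")
    for combo in product(pair_states, repeat=AlleleConfiguration.N_SUBGENOMES):
        if all(p == "OO" for p in combo):
            continue
        yield AlleleConfiguration.from_string("".join(combo))
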