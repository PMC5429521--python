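"""Simulation of an allo-octoploid selfing (S1) or cross (F1) mapping
population with fully known truth.

The simulated parent carries four diploid subgenomes.  Each chromosome
belongs to one subgenome and one homoeologous group (HG); at meiosis every
chromosome pair recombines internally with Poisson crossovers and no
interference (Haldane model) while homoeologous chromosomes never exchange.
Each locus sits on exactly one chromosome (the subgenome whose copy can
segregate) and owns an :class:`~allomap.polyploid_model.AlleleConfiguration`
describing all eight parental homologs; homozygous copies in other
subgenomes contribute constant alleles to the collapsed call.

Everything is driven by ``numpy.random.default_rng`` seeds and is
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .polyploid_model import (
    AlleleConfiguration,
    CANONICAL_CLASS,
    classify_distribution,
    expected_segregation,
    is_subgenome_specific,
)

__all__ = [
    "CALL_CODES",
    "CODE_CALLS",
    "GenotypeMatrix",
    "Chromosome",
    "Locus",
    "SimulatedGenome",
    "SimulationConfig",
    "default_genome",
    "simulate_gametes",
    "simulate_meiosis",
    "simulate_population",
    "emulate_array_classes",
    "simulate_depths",
]

CALL_CODES = {"AA": 0, "AB": 1, "BB": 2, "NA": -1}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Observed calls for loci x individuals.

    ``calls`` is an int8 array with codes 0=AA, 1=AB, 2=BB, -1=missing.
    """

    loci: List[str]
    individuals: List[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.loci)} loci x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.calls, list(CODE_CALLS))
        if bad.any():
            raise ValueError("calls contain symbols outside {AA, AB, BB, NA}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(locus) from None

    def row(self, locus: str) -> np.ndarray:
        return self.calls[self.locus_index(locus)]

    def counts(self) -> pd.DataFrame:
        """Per-locus counts of AA/AB/BB/missing calls."""
        out = {
            "n_AA": (self.calls == 0).sum(axis=1),
            "n_AB": (self.calls == 1).sum(axis=1),
            "n_BB": (self.calls == 2).sum(axis=1),
            "n_missing": (self.calls == MISSING).sum(axis=1),
        }
        return pd.DataFrame(out, index=pd.Index(self.loci, name="locus"))

    def subset(self, loci: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeMatrix(list(loci), list(self.individuals), self.calls[idx].copy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.loci), list(self.individuals), self.calls.copy())

    def to_dataframe(self) -> pd.DataFrame:
        symbols = np.array([CODE_CALLS[c] for c in sorted(CODE_CALLS)])
        # codes -1..2 -> index 0..3 via +1
        lookup = np.array(["NA", "AA", "AB", "BB"])
        data = lookup[self.calls + 1]
        return pd.DataFrame(data, index=pd.Index(self.loci, name="locus"),
                            columns=self.individuals)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        arr = df.to_numpy(dtype=object)
        codes = np.full(arr.shape, MISSING, dtype=np.int8)
        for sym, code in CALL_CODES.items():
            codes[arr == sym] = code
        known = np.isin(arr, list(CALL_CODES)) | pd.isna(arr)
        if not known.all():
            bad = sorted(set(arr[~known].tolist()))
            raise ValueError(f"unknown call symbols in matrix: {bad}")
        return cls([str(i) for i in df.index], [str(c) for c in df.columns], codes)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls.from_dataframe(df)


@dataclass(frozen=True)
class Chromosome:
    name: str
    subgenome: int          # 0-based subgenome index
    hg: int                 # 1-based homoeologous group id
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_cm < 0:
            raise ValueError("negative chromosome length")


@dataclass(frozen=True)
class Locus:
    name: str
    chrom: str
    pos_cm: float
    config: AlleleConfiguration
    phase: int = 0          # homolog index (0/1) carrying the A allele
    ref_chrom: Optional[str] = None
    ref_pos: Optional[int] = None


@dataclass
class SimulatedGenome:
    """A parental genome with known locus configurations and positions."""

    chromosomes: List[Chromosome]
    loci: List[Locus]
    n_subgenomes: int = 4

    def __post_init__(self) -> None:
        by_name = {c.name: c for c in self.chromosomes}
        if len(by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus ids")
        for loc in self.loci:
            chrom = by_name.get(loc.chrom)
            if chrom is None:
                raise ValueError(f"locus {loc.name} on unknown chromosome {loc.chrom}")
            if not 0 <= loc.pos_cm <= chrom.length_cm:
                raise ValueError(
                    f"locus {loc.name} at {loc.pos_cm} cM outside chromosome "
                    f"{chrom.name} of length {chrom.length_cm} cM"
                )
            pair = loc.config.pairs[chrom.subgenome]
            if pair[0] == "O":
                raise ValueError(
                    f"locus {loc.name} configuration {loc.config.label} is null "
                    f"in its own subgenome {chrom.subgenome}"
                )
            for k in loc.config.heterozygous_subgenomes:
                if k != chrom.subgenome:
                    raise ValueError(
                        f"locus {loc.name} is heterozygous in subgenome {k} "
                        "but placed on a different subgenome; multi-het "
                        "configurations are not simulated"
                    )

    @property
    def chromosome_map(self) -> Dict[str, Chromosome]:
        return {c.name: c for c in self.chromosomes}

    def loci_by_chromosome(self) -> Dict[str, List[Locus]]:
        out: Dict[str, List[Locus]] = {c.name: [] for c in self.chromosomes}
        for loc in self.loci:
            out[loc.chrom].append(loc)
        for name in out:
            out[name].sort(key=lambda l: (l.pos_cm, l.name))
        return out

    def truth_table(self) -> pd.DataFrame:
        """Per-locus truth: configuration, class, position, anchors."""
        chrom_map = self.chromosome_map
        rows = []
        for loc in self.loci:
            chrom = chrom_map[loc.chrom]
            dist = expected_segregation(loc.config)
            klass = classify_distribution(dist)
            rows.append({
                "locus": loc.name,
                "config": loc.config.label,
                "true_class": klass.variant if klass is not None else "other",
                "subgenome_specific": is_subgenome_specific(loc.config),
                "chrom": loc.chrom,
                "subgenome": chrom.subgenome,
                "hg": chrom.hg,
                "pos_cm": loc.pos_cm,
                "phase": loc.phase,
                "ref_chrom": loc.ref_chrom,
                "ref_pos": loc.ref_pos,
            })
        return pd.DataFrame(rows).set_index("locus")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated population."""

    n_individuals: int = 164
    error_rate: float = 0.005
    missing_rate: float = 0.02
    seed: int = 0
    population_type: str = "S1"
    fraction_specific: float = 0.7

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        for name in ("error_rate", "missing_rate", "fraction_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.population_type not in ("S1", "F1"):
            raise ValueError("population_type must be 'S1' or 'F1'")


def _random_config(rng: np.random.Generator, subgenome: int, n_subgenomes: int,
                   specific: bool, monomorphic: bool = False) -> AlleleConfiguration:
    """Draw a locus configuration heterozygous (or homozygous) in one subgenome."""
    pairs = ["OO"] * n_subgenomes
    if monomorphic:
        pairs[subgenome] = "AA" if rng.random() < 0.5 else "BB"
    else:
        pairs[subgenome] = "AB"
    if not specific:
        others = [k for k in range(n_subgenomes) if k != subgenome]
        n_extra = int(rng.integers(1, n_subgenomes))  # 1..3 extra subgenomes
        for k in rng.permutation(others)[:n_extra]:
            pairs[k] = "BB"
    return AlleleConfiguration.from_string("".join(pairs))


def default_genome(
    n_hg: int = 7,
    n_subgenomes: int = 4,
    loci_per_chrom: int = 36,
    chrom_length_cm: float = 70.0,
    fraction_specific: float = 0.7,
    fraction_monomorphic: float = 0.0,
    bp_per_cm: int = 400_000,
    ref_mode: str = "per_hg",
    inversions: Optional[Sequence[Tuple[str, float, float]]] = None,
    dropouts: Optional[Sequence[Tuple[str, float, float]]] = None,
    seed: int = 0,
) -> SimulatedGenome:
    """Build a structured test genome: ``n_hg`` homoeologous groups times
    ``n_subgenomes`` chromosomes with evenly spaced loci.

    ``ref_mode`` controls reference anchoring: ``"per_hg"`` maps all
    chromosomes of one HG onto a shared reference chromosome (a diploid
    relative), ``"per_chromosome"`` gives each chromosome its own.
    ``inversions`` / ``dropouts`` are ``(chrom_name, start_cm, end_cm)``
    windows whose anchor order is reversed / whose loci are removed,
    emulating structural variation between subgenomes.
    """
    rng = np.random.default_rng(seed)
    inversions = list(inversions or [])
    dropouts = list(dropouts or [])
    chromosomes: List[Chromosome] = []
    loci: List[Locus] = []
    for hg in range(1, n_hg + 1):
        for sub in range(n_subgenomes):
            cname = f"chr{hg}{chr(ord('a') + sub)}"
            chromosomes.append(Chromosome(cname, sub, hg, chrom_length_cm))
            ref_chrom = f"ref{hg}" if ref_mode == "per_hg" else f"ref_{cname}"
            step = chrom_length_cm / max(loci_per_chrom - 1, 1)
            inv_windows = [(a, b) for (c, a, b) in inversions if c == cname]
            drop_windows = [(a, b) for (c, a, b) in dropouts if c == cname]
            for i in range(loci_per_chrom):
                pos = i * step
                if any(a <= pos <= b for (a, b) in drop_windows):
                    continue
                specific = bool(rng.random() < fraction_specific)
                mono = bool(rng.random() < fraction_monomorphic)
                config = _random_config(rng, sub, n_subgenomes, specific, mono)
                ref_cm = pos
                for (a, b) in inv_windows:
                    if a <= pos <= b:
                        ref_cm = a + b - pos  # mirror inside the window
                        break
                # tiny subgenome offset keeps shared-reference positions distinct
                ref_pos = int(round(ref_cm * bp_per_cm)) * 10 + sub + 1
                loci.append(Locus(
                    name=f"L{hg}{chr(ord('a') + sub)}_{i:03d}",
                    chrom=cname,
                    pos_cm=pos,
                    config=config,
                    phase=int(rng.integers(2)),
                    ref_chrom=ref_chrom,
                    ref_pos=ref_pos,
                ))
    return SimulatedGenome(chromosomes, loci, n_subgenomes)


def simulate_gametes(length_cm: float, positions_cm: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n`` gamete haplotypes along one chromosome.

    Crossover counts are Poisson(length/100), breakpoints uniform, no
    interference.  Returns an ``(n, len(positions))`` array of homolog
    indices (0/1) carried by each gamete at each position.
    """
    positions = np.asarray(positions_cm, dtype=float)
    n_loci = positions.size
    if n_loci == 0:
        return np.zeros((n, 0), dtype=np.int8)
    start = rng.integers(0, 2, size=n)
    n_breaks = rng.poisson(length_cm / 100.0, size=n)
    out = np.empty((n, n_loci), dtype=np.int8)
    kmax = int(n_breaks.max()) if n > 0 else 0
    if kmax == 0:
        out[:] = start[:, None]
        return out
    # uniform breakpoints, padded to kmax and masked beyond each gamete's count
    u = rng.uniform(0.0, length_cm, size=(n, kmax))
    valid = np.arange(kmax)[None, :] < n_breaks[:, None]
    # number of breakpoints to the left of each locus
    crossings = ((u[:, :, None] <= positions[None, None, :]) & valid[:, :, None]).sum(axis=1)
    out[:] = (start[:, None] + crossings) % 2
    return out


def simulate_meiosis(genome: SimulatedGenome, seed: int) -> Dict[str, np.ndarray]:
    """One gamete of the parent: per chromosome, the homolog index carried
    at each locus position (loci in chromosome order)."""
    rng = np.random.default_rng(seed)
    by_chrom = genome.loci_by_chromosome()
    chrom_map = genome.chromosome_map
    gamete: Dict[str, np.ndarray] = {}
    for cname, locs in by_chrom.items():
        positions = np.array([l.pos_cm for l in locs])
        gamete[cname] = simulate_gametes(chrom_map[cname].length_cm, positions, 1, rng)[0]
    return gamete


def _locus_gamete_allele_codes(locus: Locus, subgenome: int,
                               homologs: np.ndarray) -> np.ndarray:
    """Allele (0=A, 1=B) transmitted at this locus for each gamete, given the
    homolog indices carried by the gametes on the locus's own chromosome."""
    a, b = locus.config.pairs[subgenome]
    if a == b:
        return np.full(homologs.shape, 0 if a == "A" else 1, dtype=np.int8)
    # heterozygous: homolog `phase` carries A
    return np.where(homologs == locus.phase, 0, 1).astype(np.int8)


def _constant_contribution(locus: Locus, own_subgenome: int) -> Tuple[bool, bool]:
    """(carries A, carries B) from homozygous copies in other subgenomes."""
    has_a = has_b = False
    for k, (x, _) in enumerate(locus.config.pairs):
        if k == own_subgenome or x == "O":
            continue
        if x == "A":
            has_a = True
        else:
            has_b = True
    return has_a, has_b


def simulate_population(
    genome: SimulatedGenome,
    config: SimulationConfig,
    paternal_genome: Optional[SimulatedGenome] = None,
    return_gametes: bool = False,
):
    """Simulate the mapping population and return ``(matrix, truth)``.

    Selfing (``S1``) draws both gametes of every individual from ``genome``;
    ``F1`` requires ``paternal_genome`` with identical locus layout.  True
    calls are collapsed with the dosage-blind model, then perturbed by the
    genotyping-error and missing-data rates.

    With ``return_gametes`` a third element is returned: per chromosome the
    two (n x loci) homolog-index arrays actually transmitted, from which
    realized recombinant fractions (the finite population's own genetic
    lengths) can be computed.
    """
    if config.population_type == "F1":
        if paternal_genome is None:
            raise ValueError("F1 population requested without a paternal genome")
        if [l.name for l in paternal_genome.loci] != [l.name for l in genome.loci]:
            raise ValueError("parental genomes disagree on locus layout")
    else:
        paternal_genome = genome

    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    by_chrom = genome.loci_by_chromosome()
    by_chrom_p = paternal_genome.loci_by_chromosome()
    chrom_map = genome.chromosome_map

    locus_order = [l.name for l in genome.loci]
    locus_row = {name: i for i, name in enumerate(locus_order)}
    calls = np.empty((len(locus_order), n), dtype=np.int8)

    gamete_record: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for cname, locs in by_chrom.items():
        chrom = chrom_map[cname]
        positions = np.array([l.pos_cm for l in locs])
        g_m = simulate_gametes(chrom.length_cm, positions, n, rng)
        locs_p = by_chrom_p[cname]
        g_p = simulate_gametes(chrom.length_cm, positions, n, rng)
        gamete_record[cname] = (g_m, g_p)
        for j, loc in enumerate(locs):
            loc_p = locs_p[j]
            am = _locus_gamete_allele_codes(loc, chrom.subgenome, g_m[:, j])
            ap = _locus_gamete_allele_codes(loc_p, chrom.subgenome, g_p[:, j])
            has_a = (am == 0) | (ap == 0)
            has_b = (am == 1) | (ap == 1)
            ca, cb = _constant_contribution(loc, chrom.subgenome)
            cap, cbp = _constant_contribution(loc_p, chrom.subgenome)
            has_a |= ca or cap
            has_b |= cb or cbp
            row = np.where(has_a & has_b, 1, np.where(has_a, 0, 2)).astype(np.int8)
            calls[locus_row[loc.name]] = row

    if config.error_rate > 0:
        err = rng.random(calls.shape) < config.error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    individuals = [f"ind{i:04d}" for i in range(1, n + 1)]
    matrix = GenotypeMatrix(locus_order, individuals, calls)
    truth = genome.truth_table().loc[locus_order]
    if return_gametes:
        return matrix, truth, gamete_record
    return matrix, truth


def realized_lengths_cm(genome: SimulatedGenome,
                        gamete_record: Mapping[str, Tuple[np.ndarray, np.ndarray]],
                        loci_subset: Optional[Sequence[str]] = None
                        ) -> Dict[str, float]:
    """Realized genetic length per chromosome of a simulated population.

    Sums Haldane-transformed realized recombinant fractions between
    consecutive loci over all transmitted gametes — the genetic length the
    finite population actually carries, as opposed to the chromosome's
    nominal length parameter.  ``loci_subset`` restricts the span to those
    loci (e.g. the ones that ended up mapped).
    """
    keep = set(loci_subset) if loci_subset is not None else None
    out: Dict[str, float] = {}
    for cname, locs in genome.loci_by_chromosome().items():
        g_m, g_p = gamete_record[cname]
        gametes = np.vstack([g_m, g_p])
        cols = [j for j, l in enumerate(locs) if keep is None or l.name in keep]
        if len(cols) < 2:
            out[cname] = 0.0
            continue
        sub = gametes[:, cols]
        r = (np.diff(sub, axis=1) != 0).mean(axis=0)
        r = np.clip(r, 0.0, 0.4999)
        out[cname] = float((-50.0 * np.log(1.0 - 2.0 * r)).sum())
    return out


def emulate_array_classes(matrix: GenotypeMatrix,
                          call_rate_threshold: float = 0.97) -> pd.Series:
    """Label each locus with the genotyping-array cluster class implied by
    its observed calls: low call rate first (CRBT), then three clusters
    (PHR), heterozygote plus a single homozygote (NMH), one cluster (MHR);
    anything else is ``other``."""
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    counts = matrix.counts()
    n = matrix.n_individuals
    labels = []
    for _, row in counts.iterrows():
        call_rate = 1.0 - row["n_missing"] / n
        observed = {c for c in ("AA", "AB", "BB") if row[f"n_{c}"] > 0}
        if call_rate < call_rate_threshold:
            labels.append("CRBT")
        elif observed == {"AA", "AB", "BB"}:
            labels.append("PHR")
        elif observed in ({"AA", "AB"}, {"BB", "AB"}):
            labels.append("NMH")
        elif len(observed) == 1:
            labels.append("MHR")
        else:
            labels.append("other")
    return pd.Series(labels, index=counts.index, name="array_class")


def simulate_depths(truth: pd.DataFrame, mean_depth: float = 50.0,
                    seed: int = 0) -> pd.DataFrame:
    """Per-locus mapped-read depths: Poisson(k * mean_depth) where k is the
    number of subgenomes carrying the locus, so single-copy loci show one
    depth mode and homoeologous loci a mixture of higher modes."""
    rng = np.random.default_rng(seed)
    k = truth["config"].map(
        lambda c: len(AlleleConfiguration.from_string(c).present_subgenomes)
    ).to_numpy()
    depth = rng.poisson(k * mean_depth)
    label = np.where(k == 1, "PHR-like", "NMH-like")
    return pd.DataFrame(
        {"depth": depth, "label": label, "n_subgenomes_present": k},
        index=truth.index,
    )
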