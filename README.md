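# allomap

Discrimination of candidate subgenome-specific loci and de novo linkage-map
construction for allo-octoploid selfing (S1) populations.

An allo-octoploid carries four diploid subgenomes that pair as bivalents at
meiosis. A marker whose target exists in exactly one subgenome segregates
1:2:1 (AA:AB:BB) when a heterozygous parent is selfed, whereas a marker
hitting homoeologous copies collapses to a 3:1 (AB:BB) dominant pattern.
`allomap` implements this logic end to end:

- **`allomap.polyploid_model`** — exact gamete enumeration under disomic
  inheritance, expected offspring segregation for selfing or crossing, and
  subgenome-specificity of 8-homolog allele configurations (strings such as
  `ABOOOOOO`, `ABBBOOOO`; `O` is a null allele).
- **`allomap.synthetic_data`** — a meiosis/population simulator (Poisson
  crossovers, no interference, homoeologs never exchange) with genotyping
  error, missing data, structural-variant injection, genotyping-array
  cluster-class emulation (PHR/NMH/MHR/CRBT) and read-depth simulation; the
  simulated truth makes every later stage testable by parameter recovery.
- **`allomap.classification`** — per-locus chi-square classification into
  codominant 1:2:1 (candidate subgenome-specific), dominant 3:1
  (homoeologous), 1:1, and monomorphic classes, with missing-data and
  distortion filters.
- **`allomap.linkage_mapping`** — two-point recombination fractions by EM
  over the F2-design joint class probabilities (codominant and dominant
  markers, both phases), LOD grouping, coupling-phase conversion, greedy
  SARF ordering with ripple, Haldane distances, co-segregation bins,
  solitary-missing imputation, and placement of dominant loci by nearest
  anchored physical position.
- **`allomap.genome_comparison`** — collinearity and inversion-segment
  detection against reference anchors, chromosome coverage, ancestor
  haploSNP tallies with per-group "A" assignment, cross-map commonality
  counts, and read-depth comparison between marker classes.

## Command line

```sh
# simulate an S1 population (7 HGs x 4 subgenomes by default)
allomap simulate --config sim.yaml --out-prefix run --seed 1

# classify loci by segregation pattern
allomap classify --genotypes run.genotypes.tsv --alpha 0.01 --max-missing 20 \
    --out classes.tsv

# build linkage groups and an ordered map
allomap map --genotypes run.genotypes.tsv --classes classes.tsv \
    --anchors run.anchors.tsv --lod 2.0 --max-rf 0.4 --out map.tsv

# compare the map against reference positions
allomap compare --map map.tsv --anchors run.anchors.tsv --out report/
```

All files are TSV: genotype matrices are loci x individuals with cells
`AA`/`AB`/`BB`/`NA`; anchor tables map locus to reference chromosome and
1-based physical position.

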