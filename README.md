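# phylocorridor

Landscape-phylogeography toolkit for intraspecific sequence and
microsatellite data. It answers two linked questions about a species
sampled across many populations:

1. **Is there phylogeographic structure?** — do mutationally close
   haplotypes co-occur geographically, i.e. is the ordered
   differentiation coefficient N<sub>ST</sub> larger than the unordered
   G<sub>ST</sub>?
2. **Where did gene flow run?** — which landscape features acted as
   dispersal corridors connecting the populations that share (or nearly
   share) haplotypes?

It is aimed at phylogeographers who have an aligned haplotype matrix, a
population table, optionally codominant microsatellite genotypes, and a
habitat-suitability raster (e.g. an SDM's logistic output), and who want
the classical analysis chain — diversity statistics, a permutation test,
a median-joining network, a corridor map — as one reproducible, tested
pipeline instead of four GUI programs.

## What it computes

**Diversity and differentiation (sequence markers).** Per-population gene
diversity h<sub>k</sub> = n<sub>k</sub>/(n<sub>k</sub>−1)·(1−Σp²),
within-population mean h<sub>S</sub>, total diversity h<sub>T</sub> with
the matching small-sample correction, and
G<sub>ST</sub> = (h<sub>T</sub>−h<sub>S</sub>)/h<sub>T</sub>. The ordered
analogues weight haplotype pairs by mutational distance d<sub>ij</sub>
(Hamming on the indel-stripped alignment by default), giving
v<sub>S</sub>, v<sub>T</sub> and
N<sub>ST</sub> = (v<sub>T</sub>−v<sub>S</sub>)/v<sub>T</sub>.
Phylogeographic structure is tested by permuting haplotype labels on the
distance matrix: N<sub>ST</sub> is recomputed per permutation
(G<sub>ST</sub> is invariant), and a one-sided p-value and standardised
difference U are reported.

**Microsatellites.** Rarefied allelic richness AR(g), observed and
unbiased expected heterozygosity H<sub>O</sub>/H<sub>E</sub>, the
Weir–Cockerham within-population inbreeding coefficient F<sub>IS</sub>,
and multilocus Nei G<sub>ST</sub>.

**Median-joining network.** The Bandelt median-joining construction
(ε-relaxed minimum spanning networks plus per-site majority median
vectors, deterministic tie-breaking), from which the package derives all
population pairs linked by *shared* haplotypes or *sister* haplotypes
(one mutational step apart in the network).

**Categorical least-cost-path (CLCP) corridors.** Suitability is
inverted to a dispersal-cost layer (cost = max(1−s, floor)); for every
qualifying population pair the corridor surface
V = CD<sub>a</sub> + CD<sub>b</sub> (sum of accumulated-cost surfaces
from the two endpoints) is classified into its lowest 1% / 2% / 5%
(classes 3/2/1, nested), and the per-pair classes are summed into a
population-connectivity map — the hotter a cell, the more corridors
stack on it.

**Synthetic test bed.** A generator produces suitability landscapes with
a planted east–west corridor band, haplotype chains with pairwise
distance |i−j|, population samples with tunable ordered structure (a
discretized normal over haplotype indices; ∞ = panmixia), and diploid
microsatellite genotypes under Hardy–Weinberg with inbreeding f — so
calibration, power, parameter recovery and corridor recovery are all
measurable against known truth.

## Worked example

Simulate a structured dataset (8 populations along a planted corridor,
8-haplotype chain, spread σ = 1), then run the statistics:

```bash
phylocorridor simulate --out-dir demo --n-pops 8 --n-ind 20 \
    --n-haplotypes 8 --structure-sigma 1.0 --n-rows 40 --n-cols 120 --seed 42
phylocorridor stats --fasta demo/haplotypes.fasta --pops demo/populations.tsv \
    --ssr demo/ssr_genotypes.tsv --n-perm 999 --seed 42
```

```
Haplotype diversity and differentiation
----------------------------------------
populations used          8
hS (within-population)    0.7020
hT (total)                0.8733
GST                       0.1962
vS (ordered, within)      1.0270
vT (ordered, total)       2.4824
NST                       0.5863
Phylogeographic structure test (haplotype-label permutation)
------------------------------------------------------------
NST (observed)   0.5863
GST (observed)   0.1962
permutations     999 (seed 42)
permuted NST     0.1973 +/- 0.0872
U                4.461
one-sided p      0.0010
```

N<sub>ST</sub> (0.586) far exceeds G<sub>ST</sub> (0.196) and the
permutation p-value is at its floor (1/1000): neighbouring populations
carry mutationally close haplotypes, exactly the ordered structure the
generator planted. The microsatellite block of the same run reports
per-population AR/H<sub>E</sub>/H<sub>O</sub>/F<sub>IS</sub> and a
multilocus G<sub>ST</sub> of −0.001 — no nuclear differentiation, as
expected since the simulated allele frequencies are shared.

Build the network and the corridor map:

```bash
phylocorridor network --fasta demo/haplotypes.fasta --pops demo/populations.tsv \
    --out-prefix demo/net
phylocorridor corridor --suitability demo/suitability.asc \
    --pairs demo/net_pairs.tsv --pops demo/populations.tsv --out-prefix demo/corr
```

```
Median-joining network (epsilon = 0)
--------------------------------------------
observed haplotypes  8
median vectors       0
edges                7
network cost (MST)   7
27 linked population pairs
Corridor map (quantile mode, fractions (0.01, 0.02, 0.05))
--------------------------------------------------------
pairs summed     27
pairs skipped    0
max cell value   48
```

The chain of 8 haplotypes forms a 7-edge path (no median vectors
needed); 27 population pairs are linked by shared or sister haplotypes,
and their summed corridor classes peak (cell value 48) inside the
planted band — `demo/corr_summed.asc` is an ESRI ASCII grid you can drop
into any GIS. `phylocorridor run --config run.toml` chains all stages
and writes a manifest that reproduces the run bit-for-bit.

The package also ships a 38-population diversity table as a worked
fixture (`phylocorridor.io.load_table1()`); its summary operation
reproduces the table's printed means over the 33 microsatellite-genotyped
populations (AR 3.66, H<sub>E</sub> 0.512, H<sub>O</sub> 0.597,
F<sub>IS</sub> −0.201).

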