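# Methods

`phylocorridor` implements a landscape-phylogeography pipeline for
intraspecific sequence and microsatellite data: diversity and
differentiation statistics with a permutation test for phylogeographic
structure, median-joining haplotype networks, and categorical
least-cost-path (CLCP) reconstruction of dispersal corridors from a
habitat-suitability raster. This note documents the estimators, the
algorithmic and numerical choices, and what the synthetic test bed does
and does not establish.

## Haplotype diversity and differentiation

For `K` populations with sample sizes `n_k` and haplotype frequencies
`p_ki`, within-population gene diversity uses the small-sample-corrected
estimator

    h_k = n_k / (n_k - 1) * (1 - Σ_i p_ki²)

and `hS` is the unweighted mean of `h_k` over populations (the
HAPLONST/PERMUT convention; a sample-size-weighted variant is available
via `weighted=True`). Total diversity applies the matching correction

    hT = 1 - Σ_i x̄_i² + hS / (ñ · s)

where `x̄_i` is the unweighted mean of `p_ki` over the `s` included
populations and `ñ` their harmonic mean sample size. We use the
harmonic-mean form of the correction because it makes the estimators
exactly self-consistent: `hS` computed on the pooled sample equals `hT`
computed on the same pooling (asserted to 1e-12 in the tests).
Unordered differentiation is `GST = (hT - hS) / hT`.

The ordered analogues `v_k`, `vS`, `vT` replace `1 - Σ p²` by the
frequency-weighted mean pairwise mutational distance `Σ_ij p_ki p_kj d_ij`,
and `NST = (vT - vS) / vT`. The default ordered distance `d_ij` is the
Hamming distance on the indel-stripped alignment; in the intraspecific
regime where haplotypes differ by single substitutions this equals the
number of mutational steps. A network-path distance
(`HaploNetwork`-contracted distance) is available but non-default, because
the Hamming choice is reproducible without a network. When all
off-diagonal distances are equal, `Σ_ij p_i p_j d_ij = d·(1 - Σ p²)` in
both the within- and total-diversity terms, so NST reduces to GST exactly
(machine precision), which the tests assert.

Populations with a single sampled copy carry no unbiased `h_k`; they are
excluded from all population means, recorded in the result, and a warning
is emitted. Fully monomorphic data yield `hT = 0`; GST/NST are then
reported as explicitly undefined (`None` plus a flag), never as silent
NaNs.

### Permutation test for phylogeographic structure

Phylogeographic structure means mutationally close haplotypes co-occur
geographically, i.e. NST exceeds GST. The null distribution is built by
jointly permuting rows and columns of the distance matrix (equivalently,
permuting haplotype labels on the distances) and recomputing NST; GST is
invariant under this permutation. The one-sided p-value uses the
`(b + 1) / (n_perm + 1)` correction; `U` is reported as the
permutation-standardised difference (observed NST minus permutation mean,
over permutation SD). The p-value, not U, is the decision criterion;
default `n_perm = 999`, and fewer than 99 permutations is rejected as
meaningless. The seed is always recorded in the result.

Calibration and power are measured, not assumed: under the panmictic
generator (10 populations × 20 copies, 8 haplotypes, 199 permutations,
500 replicates) the rejection rate at α = 0.05 must fall inside the
binomial 99% CI around 0.05 and the null p-values must pass a KS
uniformity check; under planted ordered structure (below) the test must
reject in ≥ 80% of 100 replicates at 999 permutations. Both are part of
the acceptance suite and are recomputed by `scripts/acceptance.py`.

## Microsatellite statistics

* **Allelic richness** is rarefied:
  `AR(g) = Σ_a [1 - C(N - N_a, g) / C(N, g)]` per locus and population,
  averaged over loci; `g = "auto"` uses the smallest per-population,
  per-locus genotyped gene-copy count. AR is monotone in `g` and equals
  the observed allele count at `g = N` (both asserted).
* **HE** is Nei's unbiased estimator `2n/(2n-1) · (1 - Σ p_a²)` averaged
  over genotyped loci; **HO** the observed heterozygote proportion.
  Missing genotypes are excluded locus-wise; a population with no
  genotyped locus is carried as explicitly absent (NaN), never zero.
* **FIS** defaults to the Weir & Cockerham within-population `f`
  (variance components `b`, `c` summed over alleles and loci before the
  ratio — the FSTAT convention). The simple `1 - HO/HE` variant is
  selectable (`fis_estimator="nei"`). The default recovers a simulated
  `f = 0.3` within 0.02 at 10,000 individuals.
* **Multilocus GST** parallels the haploid estimators with gene copies
  `2n`: per locus, `HS` is the unweighted population mean of unbiased
  gene diversity and `HT = 1 - Σ x̄² + HS/(2 ñ s)`; `HS`, `HT` are
  averaged over loci before forming `(HT - HS)/HT`.

The packaged 38-population table ships with explicit absent records for
the five populations without microsatellite data; its summary operation
reports unweighted means of the AR/HE/HO/FIS columns over the 33
populations with data, rounded to the printed precision. The two
sequence-diversity "total" cells of that table are total diversities
computed from raw sequence data and are not reproducible from the
per-population values, so they are outside the summary's contract.

## Median-joining networks

The construction iterates to a fixed point: (1) build the ε-relaxed
minimum spanning network over the current node set — edge `(u, v)` is
feasible iff `d(u, v) ≤ L(u, v) + ε`, with `L` the single-linkage level
at which the components of `u` and `v` first merge; (2) for each node
triplet with at least two feasible links, propose the per-site majority
consensus, and add all proposals whose connection cost
`d(u,m) + d(v,m) + d(w,m)` is within ε of the round minimum. Median
vectors with degree < 3 are obsolete and deleted; a deleted median is
never re-proposed (guaranteeing termination). All candidate orderings are
lexicographic in node label, so the topology is deterministic. ε defaults
to 0 (the usual choice for intraspecific data) and is recorded in output
metadata.

Two deliberate simplifications: a site at which all three triplet members
disagree generates no candidate (no full quasi-median expansion), and no
maximum-parsimony post-cleaning is applied. With single-step intraspecific
data such ties are rare and the omission is conservative.

`minimal_connection_cost()` reports the cheapest subtree of the produced
network that spans all observed haplotypes (an exact Dreyfus–Wagner
dynamic program over terminal subsets, limited to ≤ 14 observed
haplotypes). This — not the total edge weight, which also counts
redundant tie edges — is the quantity compared against an exhaustive
minimal-network (Steiner) search in the acceptance suite: on a fixed
random family of 50 datasets (≤ 6 haplotypes, ≤ 6 segregating sites;
single-step mutation trees and random binary hypercube corners) the two
agree exactly.

**Shared and sister pairs.** Population pair (A, B) qualifies for
corridor reconstruction iff some haplotype is sampled in both (shared) or
some haplotype of A and some of B are exactly one mutational step apart
along the network, medians included (sister). The step threshold is a
parameter (`sister_distance`); haplotype-level links are collapsed to
unique population pairs before corridor summation, so a pair contributes
one corridor regardless of how many haplotypes link it.

## Categorical least-cost-path corridors

Suitability `s ∈ [0, 1]` is inverted to dispersal cost
`max(1 - s, floor)` with `floor = 1e-3`; the floor keeps costs strictly
positive so zero-cost plateaus cannot make least-cost paths degenerate.
Cost distance follows standard GIS semantics on the 8-connected grid:
stepping between adjacent cells costs the mean of the two cell costs
times the cell size (times √2 diagonally); NODATA cells are impassable.
The accumulated-cost solver is Dijkstra's algorithm on the sparse lattice
graph and is checked cell-for-cell against exhaustive path enumeration on
random 4×4 grids.

For a pair of population cells the corridor value of every cell is
`V = CD_a + CD_b`; its minimum `c*` is the least-cost-path cost and is
attained exactly on the path. Classification is nested — class 3 = lowest
1% of `V`, class 2 = lowest 2%, class 1 = lowest 5% — with two
interpretations of "lowest x%": `"quantile"` (default; thresholds at the
1st/2nd/5th percentiles of the defined `V` distribution, per pair) and
`"relative"` (thresholds at `c*(1 + f)`). The mode and fractions are
always written into output metadata. Threshold comparisons carry a 1e-9
relative tolerance because the least-cost path is a plateau of cells with
`V = c*`; bit-for-bit ties there would otherwise make the classification
sensitive to float rounding (and break exact invariance under uniform
cost scaling, which the tests require in quantile mode). Per-pair class
rasters are summed cell-wise into the connectivity map; unreachable pairs
(NODATA barriers) are skipped and recorded.

Populations are mapped to the nearest defined cell; a population more
than one cell from any defined cell is an error, because silently
snapping across a barrier would corrupt corridors. Coordinates are
treated as planar; for geographic grids an optional cosine-latitude
scaling of the x-axis would be the next refinement, but at subtropical
extents the distortion is secondary to the method's own threshold
ambiguity, so it is not applied.

## Synthetic test bed

The generator plants known structure so every stage has ground truth:

* **Landscape**: an east–west band of suitability 0.9 (rows
  `center ± half_width`, default 7 rows of a 50 × 200 grid) on a 0.1
  background, plus independent Gaussian noise (default SD 0.02) clipped
  to [0, 1]. Clipping (rather than re-sampling) slightly biases strata
  means at extreme levels; the corridor tests use interior levels where
  this is irrelevant.
* **Haplotype chain**: haplotype `i+1` differs from haplotype `i` at one
  previously unmutated site, so pairwise mutational distance is exactly
  `|i - j|` — the cleanest possible "ordered" structure.
* **Population sampling**: population `k` of `K` draws haplotype indices
  from a discretized normal centred at `k/(K-1) · (H-1)` with spread
  `structure_sigma`; `structure_sigma = inf` is the panmixia sentinel
  (uniform draws, the null of the permutation test). A discretized-normal
  assignment is used instead of a coalescent because the NST/GST contrast
  only requires controlling the correlation between haplotype identity,
  mutational distance and geography; a coalescent would add machinery
  without adding testability.
* **Microsatellites**: with probability `f` an individual is autozygous
  (one allele drawn and doubled), otherwise two independent draws —
  `P(aa) = p² + f·p(1-p)`, `P(ab) = (1-f)·2 p_a p_b` — so the expected
  heterozygote deficit equals `f` exactly.

**Choice of the ordered-structure spread.** The power scenario uses
`structure_sigma = 1.0`. A much tighter spread (e.g. 0.25) makes every
population monomorphic for its own haplotype, and then NST ≡ GST ≡ 1 with
a permutation-invariant NST (the within-population ordered diversity is
identically zero), so the test has no power by construction — the
interesting alternative is the one where populations are polymorphic but
neighbouring populations share mutationally close haplotypes, which
`sigma = 1` realises (each population carries mostly three adjacent chain
haplotypes).

All generators are bit-reproducible for a fixed seed.

**What passing does and does not show.** The synthetic bed verifies the
estimators, the test calibration, and the geometry of the corridor logic
under known truth. Real datasets add features the generator does not
emulate: recombination and homoplasy in sequences (networks with loops),
null alleles and genotyping dropout in microsatellites, anisotropic and
multi-scale landscape structure, and geographic coordinate distortion.
Passing here validates the machinery, not any biological conclusion drawn
from a particular dataset.

## Problem sizes and runtime choices

The acceptance computations use: 500 null replicates at 199 permutations
and 100 structured replicates at 999 permutations (10 populations × 20
copies each); 200 random 4×4 grids for the cost-distance oracle; a
50-case family for the network oracle; 10,000 individuals for parameter
recovery; and a 50 × 200 planted-band grid with 5 populations (10 pairs)
for corridor recovery. These sizes give Monte-Carlo error comfortably
below every acceptance tolerance while keeping a full run in well under a
minute on one core.

## Known limitations

* The NST/GST machinery assumes the haplotype distance matrix is known
  without error; alignment or distance mis-specification propagates
  directly into NST.
* The median-joining implementation omits full quasi-median generation
  and MP cleaning; for data with extensive homoplasy the produced network
  can be a proper supergraph or (rarely) miss globally optimal median
  placements — the greedy median-selection step is inherently heuristic.
* Quantile-mode corridor classes depend on the raster extent (percentiles
  are taken over the analysed window); relative mode is extent-free but
  depends on the fraction parameters differently. Both are recorded in
  metadata so runs are comparable.
* Corridor geometry is planar; no geodesic correction is applied.
* The Weir & Cockerham `f` is the within-population component only; no
  hierarchical F-statistics (FST/FIT across populations) are computed.
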