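"""Synthetic landscapes and genetic data with known, tunable structure.

Every downstream stage (diversity statistics, the NST/GST permutation test,
network building, corridor reconstruction) is exercised against data whose
ground truth is planted here:

* :func:`make_landscape` builds a suitability raster containing an
  east-west high-suitability band (a planted dispersal corridor) on a
  low-suitability background, plus optional clipped Gaussian noise.
* :func:`make_haplotype_chain` builds haplotypes one new mutation apart, so
  the pairwise mutational distance between haplotypes ``i`` and ``j`` is
  exactly ``|i - j|``.
* :func:`sample_populations` draws per-population haplotype counts either
  panmictically (uniform over haplotypes, no structure of any kind) or with
  ordered spatial structure: population ``k`` samples haplotype indices from
  a discretized normal whose mean increases linearly along the corridor, so
  that nearby populations carry similar, mutationally close haplotypes.
* :func:`simulate_ssr` draws diploid microsatellite genotypes under
  Hardy-Weinberg with an optional inbreeding coefficient ``f``:
  with probability ``f`` an individual is autozygous (one allele drawn and
  doubled), otherwise both alleles are drawn independently, giving
  ``P(aa) = p_a^2 + f p_a (1 - p_a)`` and
  ``P(ab) = (1 - f) 2 p_a p_b`` for ``a != b``.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    MISSING_ALLELE,
    ConfigurationError,
    HaplotypeDataset,
    SSRGenotypes,
)
from .raster import SuitabilityRaster

__all__ = [
    "PANMIXIA",
    "LandscapeConfig",
    "GeneticSimConfig",
    "make_landscape",
    "make_haplotype_chain",
    "default_population_positions",
    "sample_populations",
    "uniform_allele_freqs",
    "simulate_ssr",
]

#: Sentinel for ``structure_sigma`` meaning "no spatial structure at all".
PANMIXIA = math.inf

_BASES = np.array(list("ACGT"))


@dataclass
class LandscapeConfig:
    """Parameters of the planted-corridor suitability landscape.

    The band spans every column of rows
    ``band_row_center - band_half_width .. band_row_center + band_half_width``
    (inclusive) at mean suitability ``band_suitability``; everything else
    sits at ``background_suitability``.  ``noise_sd`` adds independent
    Gaussian noise clipped back into [0, 1].
    """

    n_rows: int = 50
    n_cols: int = 200
    cell_size: float = 1.0
    band_row_center: int = 25
    band_half_width: int = 3
    band_suitability: float = 0.9
    background_suitability: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not 0 <= self.background_suitability < self.band_suitability <= 1:
            raise ConfigurationError(
                "need 0 <= background_suitability < band_suitability <= 1"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.band_half_width < 0:
            raise ConfigurationError("band_half_width must be non-negative")
        if (
            self.band_row_center - self.band_half_width < 0
            or self.band_row_center + self.band_half_width >= self.n_rows
        ):
            raise ConfigurationError("band rows must lie fully inside the grid")

    def band_rows(self) -> np.ndarray:
        return np.arange(
            self.band_row_center - self.band_half_width,
            self.band_row_center + self.band_half_width + 1,
        )


@dataclass
class GeneticSimConfig:
    """Parameters of the genetic generator.

    ``structure_sigma`` is the spread (in haplotype-index units) of the
    discretized normal used by :func:`sample_populations`;
    :data:`PANMIXIA` (infinity) draws uniformly instead.
    """

    n_pops: int = 10
    n_ind_per_pop: int = 20
    n_haplotypes: int = 8
    seq_length: int = 40
    structure_sigma: float = PANMIXIA
    ssr_n_loci: int = 6
    ssr_alleles_per_locus: int = 8
    inbreeding_f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_ind_per_pop, self.n_haplotypes) < 1:
            raise ConfigurationError("counts must be at least 1")
        if self.n_haplotypes > self.seq_length:
            raise ConfigurationError(
                "n_haplotypes must not exceed seq_length (one fresh site "
                "is consumed per mutation step)"
            )
        if not (self.structure_sigma > 0):  # rejects <= 0 and NaN
            raise ConfigurationError("structure_sigma must be positive (inf = panmixia)")
        if min(self.ssr_n_loci, self.ssr_alleles_per_locus) < 1:
            raise ConfigurationError("SSR counts must be at least 1")
        if not 0 <= self.inbreeding_f <= 1:
            raise ConfigurationError("inbreeding_f must lie in [0, 1]")


def make_landscape(config: LandscapeConfig) -> SuitabilityRaster:
    """Build the planted-corridor suitability raster."""
    rng = np.random.default_rng(config.seed)
    values = np.full(
        (config.n_rows, config.n_cols), config.background_suitability, dtype=float
    )
    values[config.band_rows(), :] = config.band_suitability
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        values = np.clip(values, 0.0, 1.0)
    return SuitabilityRaster(values=values, cell_size=config.cell_size)


def make_haplotype_chain(
    n_haplotypes: int, seq_length: int, seed: int = 0
) -> HaplotypeDataset:
    """Build a chain of haplotypes one mutation apart.

    Haplotype ``i+1`` equals haplotype ``i`` except at one site never
    mutated before, so the Hamming distance between haplotypes ``i`` and
    ``j`` is exactly ``|i - j|``.  The returned dataset carries a single
    placeholder population sampling one copy of each haplotype; callers
    normally re-sample counts with :func:`sample_populations`.
    """
    if n_haplotypes < 1:
        raise ConfigurationError("n_haplotypes must be at least 1")
    if n_haplotypes > seq_length:
        raise ConfigurationError("n_haplotypes must not exceed seq_length")
    rng = np.random.default_rng(seed)
    base = rng.choice(_BASES, size=seq_length)
    sites = rng.permutation(seq_length)[: n_haplotypes - 1]
    ids = [f"H{i + 1}" for i in range(n_haplotypes)]
    seqs: dict[str, str] = {ids[0]: "".join(base)}
    current = base.copy()
    for step, site in enumerate(sites, start=1):
        alternatives = [b for b in _BASES if b != current[site]]
        current[site] = rng.choice(alternatives)
        seqs[ids[step]] = "".join(current)
    counts = np.ones((1, n_haplotypes), dtype=int)
    return HaplotypeDataset(
        haplotype_ids=ids, sequences=seqs, counts=counts, pop_ids=["chain"]
    )


def default_population_positions(
    landscape: LandscapeConfig, n_pops: int, off_band: bool = False
) -> list[tuple[int, int]]:
    """Evenly spaced (row, col) population positions along the band center.

    With ``off_band=True`` the populations are placed on the background
    instead (a negative control), as far from the band as the grid allows.
    """
    cols = np.linspace(0, landscape.n_cols - 1, n_pops).round().astype(int)
    if off_band:
        lo = landscape.band_row_center - landscape.band_half_width
        hi = landscape.band_row_center + landscape.band_half_width
        row = 0 if lo >= landscape.n_rows - 1 - hi else landscape.n_rows - 1
    else:
        row = landscape.band_row_center
    return [(int(row), int(c)) for c in cols]


def sample_populations(
    chain: HaplotypeDataset,
    config: GeneticSimConfig,
    pop_positions: list[tuple[int, int]] | None = None,
    cell_size: float = 1.0,
) -> HaplotypeDataset:
    """Draw per-population haplotype counts with tunable ordered structure.

    Population ``k`` (of ``K``) draws each of its ``n_ind_per_pop`` copies
    from a discretized normal over haplotype indices centred at
    ``k / (K - 1) * (H - 1)`` with spread ``structure_sigma``; with
    ``structure_sigma = PANMIXIA`` all populations draw uniformly over all
    haplotypes.  ``pop_positions`` (row, col cell indices) become planar
    coordinates; by default populations are spread along a line.
    """
    rng = np.random.default_rng(config.seed)
    n_hap = chain.n_haplotypes
    K = config.n_pops
    if pop_positions is None:
        pop_positions = [(0, c) for c in np.linspace(0, max(K - 1, 1), K).round().astype(int)]
    if len(pop_positions) != K:
        raise ConfigurationError("pop_positions must give one cell per population")
    idx = np.arange(n_hap)
    counts = np.empty((K, n_hap), dtype=int)
    for k in range(K):
        if math.isinf(config.structure_sigma):
            weights = np.full(n_hap, 1.0 / n_hap)
        else:
            center = 0.0 if K == 1 else k / (K - 1) * (n_hap - 1)
            z = (idx - center) / config.structure_sigma
            weights = np.exp(-0.5 * z * z)
            weights /= weights.sum()
        counts[k] = rng.multinomial(config.n_ind_per_pop, weights)
    coords = np.array(
        [[(c + 0.5) * cell_size, (r + 0.5) * cell_size] for r, c in pop_positions]
    )
    return HaplotypeDataset(
        haplotype_ids=list(chain.haplotype_ids),
        sequences=dict(chain.sequences),
        counts=counts,
        pop_ids=[f"P{k + 1}" for k in range(K)],
        pop_coords=coords,
    )


def uniform_allele_freqs(config: GeneticSimConfig) -> list[np.ndarray]:
    """Equal allele frequencies at every locus (shared by all populations)."""
    return [
        np.full(config.ssr_alleles_per_locus, 1.0 / config.ssr_alleles_per_locus)
        for _ in range(config.ssr_n_loci)
    ]


def simulate_ssr(
    config: GeneticSimConfig,
    per_pop_allele_freqs: object | None = None,
    missing_rate: float = 0.0,
    allele_size_start: int = 100,
    allele_size_step: int = 2,
) -> SSRGenotypes:
    """Draw diploid microsatellite genotypes under HW with inbreeding ``f``.

    ``per_pop_allele_freqs`` is either a sequence of per-locus frequency
    vectors shared by all populations, or a nested sequence indexed
    ``[population][locus]``; ``None`` means uniform frequencies.  Allele
    "sizes" are reported as ``allele_size_start + i * allele_size_step`` for
    allele index ``i`` (microsatellite fragment-length convention).
    """
    rng = np.random.default_rng(config.seed)
    freqs = _normalize_freqs(per_pop_allele_freqs, config)
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must lie in [0, 1)")

    pop_ids: list[str] = []
    individual_ids: list[str] = []
    alleles = np.empty((config.n_pops * config.n_ind_per_pop, config.ssr_n_loci, 2), int)
    row = 0
    for k in range(config.n_pops):
        for i in range(config.n_ind_per_pop):
            pop_ids.append(f"P{k + 1}")
            individual_ids.append(f"P{k + 1}_I{i + 1}")
            for locus in range(config.ssr_n_loci):
                p = freqs[k][locus]
                if config.inbreeding_f > 0 and rng.random() < config.inbreeding_f:
                    a = rng.choice(len(p), p=p)
                    pair = (a, a)
                else:
                    pair = tuple(rng.choice(len(p), size=2, p=p))
                sizes = tuple(allele_size_start + a * allele_size_step for a in pair)
                if missing_rate > 0 and rng.random() < missing_rate:
                    sizes = (MISSING_ALLELE, MISSING_ALLELE)
                alleles[row, locus] = sizes
            row += 1
    locus_names = [f"L{j + 1}" for j in range(config.ssr_n_loci)]
    return SSRGenotypes(
        pop_ids=pop_ids,
        individual_ids=individual_ids,
        locus_names=locus_names,
        alleles=alleles,
    )


def _normalize_freqs(
    per_pop_allele_freqs: object | None, config: GeneticSimConfig
) -> list[list[np.ndarray]]:
    """Validate and broadcast allele frequencies to [population][locus]."""
    if per_pop_allele_freqs is None:
        shared = uniform_allele_freqs(config)
        return [shared] * config.n_pops
    seq = list(per_pop_allele_freqs)  # type: ignore[call-overload]
    if seq and np.ndim(seq[0]) == 1:  # per-locus, shared by all populations
        loci = [_check_freq(v) for v in seq]
        if len(loci) != config.ssr_n_loci:
            raise ConfigurationError("need one frequency vector per locus")
        return [loci] * config.n_pops
    if len(seq) != config.n_pops:
        raise ConfigurationError("need frequencies for every population")
    out = []
    for pop_freqs in seq:
        loci = [_check_freq(v) for v in pop_freqs]
        if len(loci) != config.ssr_n_loci:
            raise ConfigurationError("need one frequency vector per locus")
        out.append(loci)
    return out


def _check_freq(v: object) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size == 0 or (arr < 0).any() or not math.isclose(
        arr.sum(), 1.0, abs_tol=1e-8
    ):
        raise ConfigurationError("allele frequencies must be a 1-D vector summing to 1")
    return arr / arr.sum()
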