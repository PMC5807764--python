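"""Core in-memory containers shared across the pipeline.

Sequence-based statistics operate on a :class:`HaplotypeDataset` (aligned
haplotype sequences plus a populations x haplotypes count matrix), ordered
statistics additionally need a :class:`DistanceMatrix`, and microsatellite
summaries operate on :class:`SSRGenotypes`.  Raster containers live in
:mod:`phylocorridor.raster`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhylocorridorError",
    "ConfigurationError",
    "InputError",
    "HaplotypeDataset",
    "DistanceMatrix",
    "SSRGenotypes",
    "MISSING_ALLELE",
]


class PhylocorridorError(Exception):
    """Base class for package errors."""


class ConfigurationError(PhylocorridorError):
    """A configuration value is out of its documented range."""


class InputError(PhylocorridorError):
    """Input data are malformed or inconsistent."""


VALID_BASES = frozenset("ACGT")

#: Sentinel for a missing allele call (both alleles of a genotype are
#: missing together; a half-missing genotype is rejected on construction).
MISSING_ALLELE = -9


@dataclass
class HaplotypeDataset:
    """Aligned haplotypes plus per-population sample counts.

    Parameters
    ----------
    haplotype_ids : list of str
        Labels of the distinct haplotypes, e.g. ``["H1", "H2", ...]``.
    sequences : dict
        ``haplotype_id -> aligned sequence`` over ``{A, C, G, T}``.  Indel
        columns are expected to have been removed already; all sequences
        must share one aligned length.  May be empty for count-only use
        (unordered statistics need no sequences).
    counts : ndarray
        ``(n_populations, n_haplotypes)`` non-negative integer matrix of
        sampled copies.
    pop_ids : list of str
        Population labels, one per counts row.
    pop_coords : ndarray or None
        ``(n_populations, 2)`` array of ``(x, y)`` (or lon, lat) positions.
    """

    haplotype_ids: list[str]
    sequences: dict[str, str]
    counts: np.ndarray
    pop_ids: list[str]
    pop_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D populations x haplotypes matrix")
        if self.counts.shape[1] != len(self.haplotype_ids):
            raise InputError(
                f"counts has {self.counts.shape[1]} haplotype columns but "
                f"{len(self.haplotype_ids)} haplotype ids were given"
            )
        if self.counts.shape[0] != len(self.pop_ids):
            raise InputError("counts rows and pop_ids disagree")
        if (self.counts < 0).any():
            raise InputError("haplotype counts must be non-negative")
        if (self.counts.sum(axis=1) < 1).any():
            raise InputError("every population must have at least one sampled copy")
        if self.sequences:
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                raise InputError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
            bad = {h for h, s in self.sequences.items() if not set(s) <= VALID_BASES}
            if bad:
                raise InputError(
                    "sequences contain non-ACGT characters (ambiguity codes and "
                    f"gaps are not allowed): {sorted(bad)}"
                )
            sampled = set(np.asarray(self.haplotype_ids)[self.counts.sum(axis=0) > 0])
            missing = sampled - set(self.sequences)
            if missing:
                raise InputError(f"sampled haplotypes lack sequences: {sorted(missing)}")
        if self.pop_coords is not None:
            self.pop_coords = np.asarray(self.pop_coords, dtype=float)
            if self.pop_coords.shape != (len(self.pop_ids), 2):
                raise InputError("pop_coords must be (n_populations, 2)")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_sizes(self) -> np.ndarray:
        """Per-population number of sampled copies ``n_k``."""
        return self.counts.sum(axis=1)

    @property
    def alignment_length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    def frequencies(self) -> np.ndarray:
        """Per-population haplotype frequencies ``p_ki`` (rows sum to 1)."""
        n = self.sample_sizes.astype(float)
        return self.counts / n[:, None]

    def pooled(self) -> "HaplotypeDataset":
        """Collapse all populations into a single pooled population."""
        return HaplotypeDataset(
            haplotype_ids=list(self.haplotype_ids),
            sequences=dict(self.sequences),
            counts=self.counts.sum(axis=0, keepdims=True),
            pop_ids=["pooled"],
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (populations x haplotypes)."""
        return pd.DataFrame(self.counts, index=self.pop_ids, columns=self.haplotype_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between labelled haplotypes."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise InputError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise InputError("distances must be non-negative")

    def reindex(self, labels: list[str]) -> "DistanceMatrix":
        """Reorder/subset to the given labels."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), d=self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class SSRGenotypes:
    """Codominant diploid genotypes: individuals x loci x 2 allele calls.

    Allele calls are integers (e.g. fragment sizes); :data:`MISSING_ALLELE`
    marks a missing genotype, and both calls of an individual-locus genotype
    must be missing together.
    """

    pop_ids: list[str]
    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray  # (n_individuals, n_loci, 2)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        n_ind = len(self.individual_ids)
        if len(self.pop_ids) != n_ind:
            raise InputError("pop_ids must give one population per individual")
        if self.alleles.shape != (n_ind, len(self.locus_names), 2):
            raise InputError("alleles must be (n_individuals, n_loci, 2)")
        miss = self.alleles == MISSING_ALLELE
        if (miss[..., 0] != miss[..., 1]).any():
            raise InputError("both alleles of a genotype must be missing together")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        """Distinct population ids in order of first appearance."""
        return list(dict.fromkeys(self.pop_ids))

    def population_mask(self, pop: str) -> np.ndarray:
        return np.asarray([p == pop for p in self.pop_ids])

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean mask of missing genotypes."""
        return self.alleles[..., 0] == MISSING_ALLELE

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "pop_id": self.pop_ids,
            "individual_id": self.individual_ids,
        }
        for j, locus in enumerate(self.locus_names):
            data[f"{locus}_1"] = self.alleles[:, j, 0]
            data[f"{locus}_2"] = self.alleles[:, j, 1]
        return pd.DataFrame(data)
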