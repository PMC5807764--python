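"""Haplotype and microsatellite diversity and differentiation statistics.

Sequence markers
----------------
Within-population gene diversity uses the small-sample-corrected estimator

    h_k = n_k / (n_k - 1) * (1 - sum_i p_ki^2),

``hS`` is the (by default unweighted) mean of ``h_k`` over populations with
``n_k >= 2``, and total diversity applies the matching correction

    hT = 1 - sum_i xbar_i^2 + hS / (n_tilde * s),

with ``xbar_i`` the unweighted mean of ``p_ki`` over the ``s`` included
populations and ``n_tilde`` their harmonic mean sample size.  Unordered
differentiation is ``GST = (hT - hS) / hT``.  The ordered analogues replace
``1 - sum p^2`` by the frequency-weighted mean pairwise mutational distance
``sum_ij p_ki p_kj d_ij`` (giving ``v_k``, ``vS``, ``vT`` and
``NST = (vT - vS) / vT``).  When every pair of distinct haplotypes is
equidistant, NST reduces to GST exactly.

Phylogeographic structure is tested by permuting haplotype labels on the
distance matrix: permutation leaves GST untouched but destroys any
association between mutational closeness and geographic co-occurrence, so
``NST_obs`` in the upper tail of the permuted NST distribution indicates
that related haplotypes co-occur.  ``U`` is the permutation-standardised
difference; the p-value (with the +1 correction) is the decision criterion.

Microsatellites
---------------
Rarefied allelic richness, observed/unbiased expected heterozygosity, the
Weir & Cockerham within-population inbreeding coefficient f (FSTAT's FIS
convention; a plain ``1 - HO/HE`` variant is selectable), and multilocus
Nei differentiation GST across populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING_ALLELE,
    ConfigurationError,
    DistanceMatrix,
    HaplotypeDataset,
    InputError,
)

__all__ = [
    "DiversityResult",
    "StructureTestResult",
    "SSRDiversityResult",
    "hamming_distances",
    "uniform_distances",
    "haplotype_diversity",
    "nst_gst_test",
    "allele_counts",
    "allelic_richness",
    "heterozygosity_and_fis",
    "multilocus_gst",
]


# ---------------------------------------------------------------------------
# distances


def hamming_distances(dataset: HaplotypeDataset) -> DistanceMatrix:
    """Pairwise Hamming distances between the dataset's haplotypes.

    This is the default "ordered" distance: on an indel-stripped alignment
    of closely related haplotypes it equals the number of mutational steps.
    """
    if not dataset.sequences:
        raise InputError("hamming_distances requires aligned sequences")
    labels = list(dataset.haplotype_ids)
    arrs = [np.frombuffer(dataset.sequences[h].encode(), dtype="S1") for h in labels]
    mat = np.stack(arrs)
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(labels=labels, d=d)


def uniform_distances(dataset: HaplotypeDataset) -> DistanceMatrix:
    """All distinct haplotypes at distance 1 (makes NST collapse to GST)."""
    n = dataset.n_haplotypes
    d = np.ones((n, n)) - np.eye(n)
    return DistanceMatrix(labels=list(dataset.haplotype_ids), d=d)


# ---------------------------------------------------------------------------
# haplotype diversity


@dataclass
class DiversityResult:
    """hS/hT/GST (and vS/vT/NST when distances were supplied)."""

    h_k: pd.Series
    hS: float
    hT: float
    GST: float | None
    vS: float | None = None
    vT: float | None = None
    NST: float | None = None
    excluded_pops: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Haplotype diversity and differentiation", "-" * 40]
        lines.append(f"populations used          {len(self.h_k) - len(self.excluded_pops)}")
        if self.excluded_pops:
            lines.append(f"excluded (n_k = 1)        {', '.join(self.excluded_pops)}")
        lines.append(f"hS (within-population)    {self.hS:.4f}")
        lines.append(f"hT (total)                {self.hT:.4f}")
        lines.append(
            "GST                       "
            + (f"{self.GST:.4f}" if self.GST is not None else "undefined")
        )
        if self.vS is not None:
            lines.append(f"vS (ordered, within)      {self.vS:.4f}")
            lines.append(f"vT (ordered, total)       {self.vT:.4f}")
            lines.append(
                "NST                       "
                + (f"{self.NST:.4f}" if self.NST is not None else "undefined")
            )
        for flag in self.flags:
            lines.append(f"note: {flag}")
        return "\n".join(lines)


def _diversity_components(
    counts: np.ndarray, d: np.ndarray | None
) -> tuple[np.ndarray, float, float, np.ndarray | None]:
    """Per-population diversities and the total-diversity correction inputs.

    Returns (h_k over included populations, hS, hT, v_k) for the given
    count matrix (rows already restricted to n_k >= 2 populations).
    """
    n = counts.sum(axis=1).astype(float)
    p = counts / n[:, None]
    s = counts.shape[0]
    n_tilde = s / (1.0 / n).sum()  # harmonic mean
    corr = n / (n - 1.0)

    h_k = corr * (1.0 - (p**2).sum(axis=1))
    hS = h_k.mean()
    xbar = p.mean(axis=0)
    hT = 1.0 - (xbar**2).sum() + hS / (n_tilde * s)

    v_k = None
    if d is not None:
        v_k = corr * np.einsum("ki,ij,kj->k", p, d, p)
    return h_k, float(hS), float(hT), v_k


def haplotype_diversity(
    dataset: HaplotypeDataset,
    distances: DistanceMatrix | None = None,
    weighted: bool = False,
) -> DiversityResult:
    """Estimate hS, hT, GST (and vS, vT, NST when distances are given).

    Populations with a single sampled copy carry no unbiased within-
    population diversity and are excluded (and recorded).  ``weighted=True``
    weights the population means by sample size instead of the default
    unweighted (HAPLONST/PERMUT) convention.
    """
    n_all = dataset.sample_sizes
    include = n_all >= 2
    excluded = [p for p, ok in zip(dataset.pop_ids, include) if not ok]
    if excluded:
        warnings.warn(
            f"populations with n_k = 1 excluded from diversity estimation: {excluded}",
            stacklevel=2,
        )
    counts = dataset.counts[include]
    if counts.shape[0] == 0:
        raise InputError("no population has n_k >= 2; diversity is not estimable")

    d = None
    if distances is not None:
        d = distances.reindex(list(dataset.haplotype_ids)).d

    flags: list[str] = []
    if weighted:
        h_k, hS, hT, v_k = _weighted_components(counts, d)
    else:
        h_k, hS, hT, v_k = _diversity_components(counts, d)

    GST: float | None
    if hT > 1e-12:
        GST = float((hT - hS) / hT)
    else:
        GST = None
        flags.append("all populations monomorphic for one haplotype: GST undefined")

    vS = vT = NST = None
    if d is not None:
        n = counts.sum(axis=1).astype(float)
        p = counts / n[:, None]
        s = counts.shape[0]
        n_tilde = s / (1.0 / n).sum()
        vS = float(np.mean(v_k)) if not weighted else float(np.average(v_k, weights=n))
        xbar = p.mean(axis=0) if not weighted else np.average(p, axis=0, weights=n)
        vT = float(xbar @ d @ xbar + vS / (n_tilde * s))
        if vT > 1e-12:
            NST = float((vT - vS) / vT)
        else:
            flags.append("total ordered diversity is zero: NST undefined")

    included_ids = [p for p, ok in zip(dataset.pop_ids, include) if ok]
    h_series = pd.Series(np.nan, index=dataset.pop_ids, name="h_k")
    h_series.loc[included_ids] = h_k
    return DiversityResult(
        h_k=h_series, hS=hS, hT=hT, GST=GST, vS=vS, vT=vT, NST=NST,
        excluded_pops=excluded, flags=flags,
    )


def _weighted_components(counts, d):
    """Sample-size-weighted variant of the population means."""
    n = counts.sum(axis=1).astype(float)
    p = counts / n[:, None]
    s = counts.shape[0]
    n_tilde = s / (1.0 / n).sum()
    corr = n / (n - 1.0)
    h_k = corr * (1.0 - (p**2).sum(axis=1))
    hS = float(np.average(h_k, weights=n))
    xbar = np.average(p, axis=0, weights=n)
    hT = float(1.0 - (xbar**2).sum() + hS / (n_tilde * s))
    v_k = None
    if d is not None:
        v_k = corr * np.einsum("ki,ij,kj->k", p, d, p)
    return h_k, hS, hT, v_k


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class StructureTestResult:
    """Permutation test of NST against its haplotype-label-permuted null."""

    NST_obs: float
    GST_obs: float
    n_perm: int
    p_value: float
    U: float
    perm_mean: float
    perm_sd: float
    seed: int

    def summary(self) -> str:
        return (
            "Phylogeographic structure test (haplotype-label permutation)\n"
            + "-" * 60
            + f"\nNST (observed)   {self.NST_obs:.4f}"
            + f"\nGST (observed)   {self.GST_obs:.4f}"
            + f"\npermutations     {self.n_perm} (seed {self.seed})"
            + f"\npermuted NST     {self.perm_mean:.4f} +/- {self.perm_sd:.4f}"
            + f"\nU                {self.U:.3f}"
            + f"\none-sided p      {self.p_value:.4f}"
        )


def nst_gst_test(
    dataset: HaplotypeDataset,
    distances: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> StructureTestResult:
    """Test NST > GST by permuting haplotype labels on the distance matrix.

    Rows/columns of ``d`` are permuted jointly, NST recomputed each time
    (GST is invariant), and the one-sided p-value reported with the
    ``(b + 1) / (n_perm + 1)`` correction.  ``U`` is the observed NST minus
    the permutation mean, over the permutation standard deviation.
    """
    if n_perm < 99:
        raise ConfigurationError("n_perm < 99 makes the test meaningless")
    res = haplotype_diversity(dataset, distances)
    if res.NST is None or res.GST is None:
        raise InputError("NST/GST are undefined for these data; cannot test")

    include = dataset.sample_sizes >= 2
    counts = dataset.counts[include]
    d = distances.reindex(list(dataset.haplotype_ids)).d
    n = counts.sum(axis=1).astype(float)
    p = counts / n[:, None]
    s = counts.shape[0]
    n_tilde = s / (1.0 / n).sum()
    corr = n / (n - 1.0)
    xbar = p.mean(axis=0)

    rng = np.random.default_rng(seed)
    H = d.shape[0]
    nst_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(H)
        dp = d[np.ix_(perm, perm)]
        v_k = corr * np.einsum("ki,ij,kj->k", p, dp, p)
        vS = v_k.mean()
        vT = xbar @ dp @ xbar + vS / (n_tilde * s)
        nst_perm[b] = (vT - vS) / vT if vT > 1e-12 else 0.0

    obs = res.NST
    b_ge = int(np.sum(nst_perm >= obs - 1e-12))
    p_value = (b_ge + 1) / (n_perm + 1)
    sd = float(nst_perm.std(ddof=1))
    U = float((obs - nst_perm.mean()) / sd) if sd > 0 else float("nan")
    return StructureTestResult(
        NST_obs=float(obs), GST_obs=float(res.GST), n_perm=n_perm,
        p_value=float(p_value), U=U, perm_mean=float(nst_perm.mean()),
        perm_sd=sd, seed=seed,
    )


# ---------------------------------------------------------------------------
# microsatellites


def allele_counts(genotypes, pop: str, locus_index: int) -> dict[int, int]:
    """Counts of each allele (gene copies) in one population at one locus."""
    mask = genotypes.population_mask(pop)
    calls = genotypes.alleles[mask, locus_index, :].ravel()
    calls = calls[calls != MISSING_ALLELE]
    values, counts = np.unique(calls, return_counts=True)
    return dict(zip(values.tolist(), counts.tolist()))


def _rarefied_richness(counts: dict[int, int], g: int) -> float:
    """AR(g) = sum_a [1 - C(N - N_a, g) / C(N, g)] for one locus."""
    N = sum(counts.values())
    denom = math.comb(N, g)
    return float(
        sum(1.0 - math.comb(N - Na, g) / denom for Na in counts.values())
    )


def allelic_richness(
    genotypes, g: int | str = "auto"
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Rarefied allelic richness per population (mean over loci) and per locus.

    ``g`` is the rarefaction size in gene copies; ``"auto"`` uses the
    smallest per-population, per-locus genotyped gene-copy count (the FSTAT
    convention).  Returns ``(per_population_mean, per_locus_table, g)``.
    """
    pops = genotypes.populations
    copy_counts = []
    tables: dict[str, dict[str, dict[int, int]]] = {}
    for pop in pops:
        tables[pop] = {}
        for j, locus in enumerate(genotypes.locus_names):
            cnt = allele_counts(genotypes, pop, j)
            tables[pop][locus] = cnt
            N = sum(cnt.values())
            if N > 0:
                copy_counts.append(N)
    if not copy_counts:
        raise InputError("no genotyped locus in any population")
    if g == "auto":
        g = min(copy_counts)
    g = int(g)
    if g < 1:
        raise ConfigurationError("rarefaction size g must be at least 1")
    if g > min(copy_counts):
        raise ConfigurationError(
            f"g = {g} exceeds the smallest genotyped gene-copy count ({min(copy_counts)})"
        )
    per_locus = pd.DataFrame(np.nan, index=pops, columns=genotypes.locus_names)
    for pop in pops:
        for locus, cnt in tables[pop].items():
            if cnt:
                per_locus.loc[pop, locus] = _rarefied_richness(cnt, g)
    per_pop = per_locus.mean(axis=1, skipna=True).rename("AR")
    return per_pop, per_locus, g


@dataclass
class SSRDiversityResult:
    """Per-population microsatellite summaries (NaN = marker data absent)."""

    table: pd.DataFrame  # columns: n, AR, HE, HO, FIS
    g: int
    GST_multilocus: float | None
    fis_estimator: str

    def summary(self) -> str:
        lines = [
            f"Microsatellite diversity (AR rarefied to g = {self.g} gene copies, "
            f"FIS: {self.fis_estimator})",
            "-" * 72,
            self.table.round({"AR": 2, "HE": 3, "HO": 3, "FIS": 3}).to_string(),
        ]
        if self.GST_multilocus is not None:
            lines.append(f"multilocus GST = {self.GST_multilocus:.3f}")
        return "\n".join(lines)


def heterozygosity_and_fis(
    genotypes, g: int | str = "auto", fis_estimator: str = "wc"
) -> SSRDiversityResult:
    """Per-population AR, HE, HO and FIS, plus the multilocus GST.

    HE is Nei's unbiased estimator ``2n/(2n-1) * (1 - sum p_a^2)`` averaged
    over genotyped loci; HO the observed proportion of heterozygotes.  FIS
    defaults to the Weir & Cockerham within-population f with variance
    components summed over alleles and loci (``fis_estimator="wc"``); the
    simple ``1 - HO/HE`` ratio of locus means is available as
    ``fis_estimator="nei"``.
    """
    if fis_estimator not in {"wc", "nei"}:
        raise ConfigurationError("fis_estimator must be 'wc' or 'nei'")
    pops = genotypes.populations
    miss = genotypes.missing_mask()
    rows = []
    for pop in pops:
        mask = genotypes.population_mask(pop)
        he_loci, ho_loci = [], []
        b_sum = c_sum = 0.0
        n_ind_used = 0
        for j in range(genotypes.n_loci):
            calls = genotypes.alleles[mask, j, :]
            ok = ~miss[mask, j]
            calls = calls[ok]
            n = calls.shape[0]
            if n == 0:
                continue
            n_ind_used = max(n_ind_used, n)
            het = calls[:, 0] != calls[:, 1]
            ho = float(het.mean())
            values, cnts = np.unique(calls.ravel(), return_counts=True)
            p = cnts / (2.0 * n)
            he = 2.0 * n / (2.0 * n - 1.0) * (1.0 - float((p**2).sum()))
            ho_loci.append(ho)
            he_loci.append(he)
            if n > 1:
                for a, pa in zip(values, p):
                    hbar = float((het & (np.any(calls == a, axis=1))).mean())
                    b = n / (n - 1.0) * (pa * (1 - pa) - (2 * n - 1) / (4.0 * n) * hbar)
                    c = hbar / 2.0
                    b_sum += b
                    c_sum += c
        if not ho_loci:
            rows.append((pop, 0, np.nan, np.nan, np.nan))
            continue
        HO = float(np.mean(ho_loci))
        HE = float(np.nanmean(he_loci))
        if fis_estimator == "wc":
            FIS = 1.0 - c_sum / (b_sum + c_sum) if (b_sum + c_sum) > 0 else float("nan")
        else:
            FIS = 1.0 - HO / HE if HE > 0 else float("nan")
        rows.append((pop, n_ind_used, HE, HO, FIS))

    ar_pop, _, g_used = allelic_richness(genotypes, g=g)
    table = pd.DataFrame(
        rows, columns=["pop", "n", "HE", "HO", "FIS"]
    ).set_index("pop")
    table.insert(1, "AR", ar_pop)
    gst = multilocus_gst(genotypes) if len(pops) >= 2 else None
    return SSRDiversityResult(
        table=table, g=g_used, GST_multilocus=gst, fis_estimator=fis_estimator
    )


def multilocus_gst(genotypes) -> float | None:
    """Nei's multilocus GST = (HT - HS) / HT with HS, HT averaged over loci.

    HS per locus is the unweighted mean over populations of the unbiased
    within-population gene diversity; HT applies the matching small-sample
    correction ``HS / (2 n_tilde s)`` to the diversity of the mean allele
    frequencies.  Returns None (undefined) for monomorphic data.
    """
    pops = genotypes.populations
    if len(pops) < 2:
        raise InputError("multilocus GST needs at least 2 populations")
    miss = genotypes.missing_mask()
    hs_loci, ht_loci = [], []
    for j in range(genotypes.n_loci):
        freqs, sizes = [], []
        alleles_all: set[int] = set()
        for pop in pops:
            mask = genotypes.population_mask(pop)
            calls = genotypes.alleles[mask, j, :][~miss[mask, j]]
            n = calls.shape[0]
            if n < 2:
                continue
            values, cnts = np.unique(calls.ravel(), return_counts=True)
            freqs.append(dict(zip(values.tolist(), (cnts / (2.0 * n)).tolist())))
            sizes.append(n)
            alleles_all.update(values.tolist())
        if len(sizes) < 2:
            continue
        order = sorted(alleles_all)
        P = np.array([[f.get(a, 0.0) for a in order] for f in freqs])
        n_arr = np.asarray(sizes, dtype=float)
        s = len(sizes)
        n_tilde = s / (1.0 / n_arr).sum()
        corr = 2.0 * n_arr / (2.0 * n_arr - 1.0)
        h_k = corr * (1.0 - (P**2).sum(axis=1))
        HS = float(h_k.mean())
        xbar = P.mean(axis=0)
        HT = float(1.0 - (xbar**2).sum() + HS / (2.0 * n_tilde * s))
        hs_loci.append(HS)
        ht_loci.append(HT)
    if not ht_loci:
        warnings.warn("no locus is genotyped in at least two populations; GST undefined",
                      stacklevel=2)
        return None
    HS_bar = float(np.mean(hs_loci))
    HT_bar = float(np.mean(ht_loci))
    if HT_bar <= 1e-12:
        return None
    return float((HT_bar - HS_bar) / HT_bar)
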