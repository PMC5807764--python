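"""File formats and the packaged per-population worked-example table.

Formats
-------
* aligned haplotypes: FASTA (uppercased on read; ambiguity codes rejected)
* population table: TSV with columns ``pop_id, lat, lon, individual_id,
  haplotype_id`` ('#' comments; "NA" or the en-dash "–" mark absent values
  on read, "NA" on write)
* microsatellite genotypes: TSV with ``pop_id, individual_id`` then two
  columns per locus (``<locus>_1``, ``<locus>_2``)
* rasters: ESRI ASCII grid (see :mod:`phylocorridor.raster`)
* networks: GraphML plus a plain-text edge list
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    MISSING_ALLELE,
    HaplotypeDataset,
    InputError,
    SSRGenotypes,
)
from .network import HaploNetwork, PairList

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_population_table",
    "write_population_table",
    "read_haplotype_data",
    "write_haplotype_data",
    "read_ssr_table",
    "write_ssr_table",
    "write_network",
    "write_pairs",
    "load_table1",
    "summarize_table1",
]

NA_TOKENS = {"NA", "–", "-", ""}
VALID_BASES = set("ACGT")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read aligned sequences; uppercases and rejects ambiguity codes."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        bad = set(s) - VALID_BASES
        if bad:
            raise InputError(
                f"sequence {rec.id!r} contains unsupported characters {sorted(bad)}; "
                "only unambiguous A/C/G/T (indels already stripped) are accepted"
            )
        if rec.id in seqs:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = s
    if not seqs:
        raise InputError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=h, description="") for h, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# population table (per-individual haplotype assignments)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, encoding="utf-8"
    )


def read_population_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV of per-individual haplotype assignments."""
    df = _read_tsv(path)
    required = {"pop_id", "lat", "lon", "individual_id", "haplotype_id"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"population table is missing columns: {sorted(missing)}")
    df["lat"] = pd.to_numeric(df["lat"])
    df["lon"] = pd.to_numeric(df["lon"])
    return df


def write_population_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_haplotype_data(fasta: str | Path, pop_table: str | Path) -> HaplotypeDataset:
    """Assemble a :class:`HaplotypeDataset` from FASTA + population TSV."""
    seqs = read_fasta(fasta)
    df = read_population_table(pop_table)
    unknown = set(df["haplotype_id"]) - set(seqs)
    if unknown:
        raise InputError(f"haplotypes in the table lack sequences: {sorted(unknown)}")
    pops = list(dict.fromkeys(df["pop_id"]))
    haps = list(seqs)
    counts = np.zeros((len(pops), len(haps)), dtype=int)
    tab = df.groupby(["pop_id", "haplotype_id"]).size()
    for (pop, hap), n in tab.items():
        counts[pops.index(pop), haps.index(hap)] = n
    coords = (
        df.groupby("pop_id")[["lon", "lat"]].first().loc[pops].to_numpy(dtype=float)
    )
    return HaplotypeDataset(
        haplotype_ids=haps, sequences=seqs, counts=counts, pop_ids=pops,
        pop_coords=coords,
    )


def write_haplotype_data(
    dataset: HaplotypeDataset, fasta: str | Path, pop_table: str | Path
) -> None:
    """Write FASTA plus a per-individual population table."""
    write_fasta(dataset.sequences, fasta)
    rows = []
    for k, pop in enumerate(dataset.pop_ids):
        lon, lat = (
            dataset.pop_coords[k] if dataset.pop_coords is not None else (np.nan, np.nan)
        )
        i = 0
        for h, c in zip(dataset.haplotype_ids, dataset.counts[k]):
            for _ in range(int(c)):
                i += 1
                rows.append((pop, lat, lon, f"{pop}_I{i}", h))
    df = pd.DataFrame(rows, columns=["pop_id", "lat", "lon", "individual_id", "haplotype_id"])
    write_population_table(df, pop_table)


# ---------------------------------------------------------------------------
# SSR genotypes


def read_ssr_table(path: str | Path) -> SSRGenotypes:
    df = _read_tsv(path)
    if not {"pop_id", "individual_id"} <= set(df.columns):
        raise InputError("SSR table needs pop_id and individual_id columns")
    locus_cols = [c for c in df.columns if c not in ("pop_id", "individual_id")]
    if len(locus_cols) % 2 != 0:
        raise InputError("SSR table must have two allele columns per locus")
    loci = []
    for a, b in zip(locus_cols[::2], locus_cols[1::2]):
        if a[:-2] != b[:-2] or not (a.endswith("_1") and b.endswith("_2")):
            raise InputError(f"locus columns must pair as <locus>_1/<locus>_2; got {a}, {b}")
        loci.append(a[:-2])
    n = len(df)
    alleles = np.empty((n, len(loci), 2), dtype=int)
    for j, locus in enumerate(loci):
        for t, col in enumerate((f"{locus}_1", f"{locus}_2")):
            vals = df[col].str.strip()
            alleles[:, j, t] = [
                MISSING_ALLELE if v in NA_TOKENS else int(v) for v in vals
            ]
    return SSRGenotypes(
        pop_ids=list(df["pop_id"]),
        individual_ids=list(df["individual_id"]),
        locus_names=loci,
        alleles=alleles,
    )


def write_ssr_table(genotypes: SSRGenotypes, path: str | Path) -> None:
    df = genotypes.to_frame()
    df = df.replace(MISSING_ALLELE, "NA")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network / pair outputs


def write_network(network: HaploNetwork, graphml: str | Path, edge_list: str | Path) -> None:
    """Emit GraphML plus a plain-text edge list."""
    G = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        G.add_node(
            node,
            seq=data.get("seq", ""),
            is_median=bool(data.get("is_median", False)),
            frequency=int(network.node_frequencies.get(node, 0)),
        )
    for u, v, w in network.graph.edges(data="weight"):
        G.add_edge(u, v, weight=int(w))
    nx.write_graphml(G, str(graphml))
    network.edge_list().to_csv(edge_list, sep="\t", index=False)


def write_pairs(pairs: PairList, path: str | Path) -> None:
    pairs.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged worked-example fixture


def load_table1() -> pd.DataFrame:
    """Load the packaged 38-population diversity table.

    Absent marker values are NaN (never zero); ``code`` is the population
    number (1-38).
    """
    ref = importlib.resources.files("phylocorridor.data") / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(
            path, sep="\t", comment="#", na_values=["NA", "–", "-"],
            keep_default_na=False, encoding="utf-8",
        )
    if len(df) != 38 or df["code"].nunique() != 38:
        raise InputError("packaged table must have 38 uniquely coded populations")
    return df


def summarize_table1(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Unweighted means of AR, HE, HO, FIS over populations with nSSR data.

    Rounded to the column's printed precision (2, 3, 3, 3 decimals).  The
    within-population sequence-diversity columns are deliberately excluded:
    their table-wide "total" entries are total diversities computed from
    raw sequence data, not column means, and cannot be reproduced from the
    per-population values.
    """
    if df is None:
        df = load_table1()
    with_ssr = df.dropna(subset=["AR", "HE", "HO", "FIS"])
    if len(with_ssr) == 0:
        raise InputError("no population has microsatellite data to summarize")
    return {
        "n_populations": int(len(with_ssr)),
        "AR_mean": round(float(with_ssr["AR"].mean()), 2),
        "HE_mean": round(float(with_ssr["HE"].mean()), 3),
        "HO_mean": round(float(with_ssr["HO"].mean()), 3),
        "FIS_mean": round(float(with_ssr["FIS"].mean()), 3),
    }
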