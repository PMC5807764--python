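"""End-to-end orchestration: stats -> network -> pairs -> corridor.

:func:`run_pipeline` consumes a :class:`RunConfig`, executes whichever
stages its inputs allow, writes all outputs plus a machine-readable run
manifest (inputs with checksums, the effective configuration, package
version), and returns the in-memory results.  Re-running with the same
config reproduces the outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .corridor import invert_suitability, snap_population_cells, summed_corridor
from .datatypes import InputError, PhylocorridorError
from .diversity import hamming_distances, haplotype_diversity, heterozygosity_and_fis, nst_gst_test
from .io import (
    read_haplotype_data,
    read_ssr_table,
    write_network,
    write_pairs,
)
from .network import extract_pairs, median_joining
from .raster import SuitabilityRaster, read_ascii_grid, write_ascii_grid

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(PhylocorridorError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run (serialized to the manifest)."""

    fasta: str | None = None
    pop_table: str | None = None
    ssr_table: str | None = None
    suitability: str | None = None
    marker: str = "haplotype"
    n_perm: int = 999
    seed: int = 0
    g: str | int = "auto"
    fis_estimator: str = "wc"
    weighted: bool = False
    epsilon: int = 0
    sister_distance: float = 1.0
    fractions: tuple[float, float, float] = (0.01, 0.02, 0.05)
    mode: str = "quantile"
    floor: float = 1e-3
    out_dir: str = "phylocorridor_out"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        return d


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages the config's inputs allow; write outputs + manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    outputs: list[str] = []
    inputs: dict[str, str] = {}

    dataset = None
    if config.fasta and config.pop_table:
        try:
            dataset = read_haplotype_data(config.fasta, config.pop_table)
            inputs["fasta"] = _sha256(config.fasta)
            inputs["pop_table"] = _sha256(config.pop_table)
        except Exception as err:
            raise PipelineStageError("read_haplotypes", err) from err

    if dataset is not None:
        try:
            distances = hamming_distances(dataset)
            div = haplotype_diversity(dataset, distances, weighted=config.weighted)
            results["diversity"] = div
            div_path = out_dir / "diversity.tsv"
            div.h_k.to_frame().to_csv(div_path, sep="\t", na_rep="NA")
            stats = {
                "hS": div.hS, "hT": div.hT, "GST": div.GST,
                "vS": div.vS, "vT": div.vT, "NST": div.NST,
                "excluded_pops": div.excluded_pops, "flags": div.flags,
            }
            if dataset.n_populations >= 2 and div.NST is not None:
                test = nst_gst_test(
                    dataset, distances, n_perm=config.n_perm, seed=config.seed
                )
                results["structure_test"] = test
                stats.update(
                    {"p_value": test.p_value, "U": test.U, "n_perm": test.n_perm}
                )
            (out_dir / "diversity.json").write_text(json.dumps(stats, indent=2))
            outputs += ["diversity.tsv", "diversity.json"]
        except Exception as err:
            raise PipelineStageError("diversity", err) from err

        try:
            network = median_joining(dataset, epsilon=config.epsilon)
            results["network"] = network
            write_network(network, out_dir / "network.graphml", out_dir / "network_edges.tsv")
            pairs = extract_pairs(dataset, network, sister_distance=config.sister_distance)
            results["pairs"] = pairs
            write_pairs(pairs, out_dir / "pairs.tsv")
            outputs += ["network.graphml", "network_edges.tsv", "pairs.tsv"]
        except Exception as err:
            raise PipelineStageError("network", err) from err

    if config.ssr_table:
        try:
            genotypes = read_ssr_table(config.ssr_table)
            inputs["ssr_table"] = _sha256(config.ssr_table)
            ssr = heterozygosity_and_fis(
                genotypes, g=config.g, fis_estimator=config.fis_estimator
            )
            results["ssr"] = ssr
            ssr.table.to_csv(out_dir / "ssr_diversity.tsv", sep="\t", na_rep="NA")
            (out_dir / "ssr_diversity.json").write_text(
                json.dumps(
                    {"g": ssr.g, "GST_multilocus": ssr.GST_multilocus,
                     "fis_estimator": ssr.fis_estimator},
                    indent=2,
                )
            )
            outputs += ["ssr_diversity.tsv", "ssr_diversity.json"]
        except Exception as err:
            raise PipelineStageError("ssr", err) from err

    if config.suitability:
        if "pairs" not in results:
            raise PipelineStageError(
                "corridor", InputError("corridor stage needs haplotype inputs to derive pairs")
            )
        try:
            suit = read_ascii_grid(config.suitability, SuitabilityRaster)
            inputs["suitability"] = _sha256(config.suitability)
            cost = invert_suitability(suit, floor=config.floor)
            coords = {
                p: tuple(xy) for p, xy in zip(dataset.pop_ids, dataset.pop_coords)
            }
            cells = snap_population_cells(cost, coords)
            cmap = summed_corridor(
                cost, results["pairs"], cells,
                fractions=config.fractions, mode=config.mode,
            )
            results["corridor"] = cmap
            write_ascii_grid(cmap.summed, out_dir / "corridor_summed.asc")
            (out_dir / "corridor_metadata.json").write_text(
                json.dumps(cmap.metadata(), indent=2)
            )
            outputs += ["corridor_summed.asc", "corridor_metadata.json"]
        except Exception as err:
            raise PipelineStageError("corridor", err) from err

    manifest = {
        "package": "phylocorridor",
        "version": __version__,
        "config": config.to_dict(),
        "inputs_sha256": inputs,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
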