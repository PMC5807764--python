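"""Categorical least-cost-path (CLCP) dispersal-corridor reconstruction.

The habitat-suitability raster is inverted into a dispersal-cost (friction)
layer, ``cost = max(1 - suitability, floor)``.  For a pair of population
cells the corridor value of every cell is ``V = CD_a + CD_b``, the sum of
the accumulated least costs from each endpoint; its minimum ``c*`` is the
least-cost-path cost and is attained exactly on the least-cost path.  Each
pair's corridor is classified into nested categories — class 3 = lowest 1%
of V, class 2 = lowest 2%, class 1 = lowest 5% (quantile mode; "relative"
mode thresholds at ``c* (1 + f)`` instead) — and the per-pair class rasters
are summed over all qualifying pairs into the population-connectivity map:
the hotter the cell, the more corridors stack on it.

Cost distance uses standard GIS semantics on the 8-connected grid: moving
between adjacent cells costs the mean of the two cell costs times the cell
size (times sqrt(2) diagonally); NODATA cells are impassable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .datatypes import ConfigurationError, InputError
from .network import PairList
from .raster import CostRaster, Raster, SuitabilityRaster

__all__ = [
    "UnreachablePairError",
    "invert_suitability",
    "cost_distance",
    "pair_corridor",
    "summed_corridor",
    "snap_population_cells",
    "CorridorMap",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.01, 0.02, 0.05)
_SQRT2 = float(np.sqrt(2.0))


class UnreachablePairError(InputError):
    """The two endpoint cells are separated by a NODATA barrier."""


def invert_suitability(raster: SuitabilityRaster, floor: float = 1e-3) -> CostRaster:
    """Invert suitability into dispersal cost: ``max(1 - s, floor)``.

    The floor keeps every defined cell strictly positive so that zero-cost
    plateaus cannot collapse path uniqueness.
    """
    if floor <= 0:
        raise ConfigurationError("cost floor must be positive")
    cost = np.maximum(1.0 - raster.values, floor)
    cost = np.where(np.isnan(raster.values), np.nan, cost)
    return CostRaster(
        values=cost, cell_size=raster.cell_size, origin=raster.origin, nodata=raster.nodata
    )


def _lattice_graph(cost: CostRaster) -> sparse.csr_matrix:
    """Sparse 8-connected lattice with average-cost edge weights."""
    vals = cost.values
    n_rows, n_cols = vals.shape
    n = n_rows * n_cols
    defined = ~np.isnan(vals)
    rows_i, cols_i, weights = [], [], []
    # only right / down-right / down / down-left offsets: each undirected
    # edge appears once, dijkstra is run on the symmetrized graph
    offsets = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2))
    for dr, dc, mult in offsets:
        r0 = slice(0, n_rows - dr)
        r1 = slice(dr, n_rows)
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        c1 = slice(max(0, dc), n_cols + min(0, dc))
        ok = defined[r0, c0] & defined[r1, c1]
        w = 0.5 * (vals[r0, c0] + vals[r1, c1]) * cost.cell_size * mult
        src = (np.arange(n).reshape(n_rows, n_cols))[r0, c0][ok]
        dst = (np.arange(n).reshape(n_rows, n_cols))[r1, c1][ok]
        rows_i.append(src)
        cols_i.append(dst)
        weights.append(w[ok])
    data = np.concatenate(weights) if weights else np.empty(0)
    i = np.concatenate(rows_i) if rows_i else np.empty(0, int)
    j = np.concatenate(cols_i) if cols_i else np.empty(0, int)
    g = sparse.coo_matrix((data, (i, j)), shape=(n, n))
    return (g + g.T).tocsr()


def cost_distance(
    cost: CostRaster, sources: list[tuple[int, int]] | tuple[int, int]
) -> Raster:
    """Accumulated least cost from a source cell set to every cell.

    Returns a raster of accumulated costs (0 at the sources, ``inf`` for
    cells unreachable without crossing NODATA, NaN on NODATA cells).
    """
    if isinstance(sources, tuple) and len(sources) == 2 and isinstance(sources[0], int):
        sources = [sources]  # type: ignore[list-item]
    n_rows, n_cols = cost.shape
    idx = []
    for r, c in sources:  # type: ignore[union-attr]
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise InputError(f"source cell {(r, c)} lies outside the grid")
        if np.isnan(cost.values[r, c]):
            raise InputError(f"source cell {(r, c)} is NODATA")
        idx.append(r * n_cols + c)
    graph = _lattice_graph(cost)
    acc = dijkstra(graph, directed=False, indices=idx, min_only=len(idx) > 1)
    if acc.ndim == 2:
        acc = acc.min(axis=0)
    acc = acc.reshape(n_rows, n_cols)
    acc = np.where(np.isnan(cost.values), np.nan, acc)
    return Raster(
        values=acc, cell_size=cost.cell_size, origin=cost.origin, nodata=cost.nodata
    )


def _classify(V: np.ndarray, c_star: float, fractions, mode: str) -> np.ndarray:
    finite = np.isfinite(V)
    classes = np.zeros(V.shape, dtype=int)
    fr = sorted(fractions)
    if mode == "quantile":
        thresholds = np.quantile(V[finite], fr)
    elif mode == "relative":
        thresholds = [c_star * (1.0 + f) for f in fr]
    else:
        raise ConfigurationError("mode must be 'quantile' or 'relative'")
    # nested: lowest 5% -> 1, lowest 2% -> 2, lowest 1% -> 3.  The LCP
    # itself is a plateau of cells with V == c*, so threshold comparisons
    # carry a relative tolerance to keep ties robust to float rounding
    # (and the classification invariant under uniform cost scaling).
    for rank, thr in enumerate(reversed(list(thresholds)), start=1):
        tol = 1e-9 * max(abs(thr), abs(c_star), 1e-30)
        classes[finite & (V <= thr + tol)] = rank
    return classes


def pair_corridor(
    cost: CostRaster,
    cell_a: tuple[int, int],
    cell_b: tuple[int, int],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    mode: str = "quantile",
) -> tuple[np.ndarray, float]:
    """Classified corridor raster for one population pair, plus LCP cost.

    Returns ``(classes, c_star)`` where ``classes`` holds {0, 1, 2, 3} per
    cell and ``c_star`` is the least-cost-path cost between the endpoints.
    """
    if len(fractions) != 3 or not all(0 < f < 1 for f in fractions):
        raise ConfigurationError("fractions must be three values in (0, 1)")
    cd_a = cost_distance(cost, cell_a).values
    cd_b = cost_distance(cost, cell_b).values
    V = cd_a + cd_b
    finite = np.isfinite(V)
    if not finite.any() or not np.isfinite(V[cell_a]) or not np.isfinite(V[cell_b]):
        raise UnreachablePairError(
            f"cells {cell_a} and {cell_b} are mutually unreachable (NODATA barrier)"
        )
    c_star = float(np.nanmin(np.where(finite, V, np.nan)))
    classes = _classify(V, c_star, fractions, mode)
    return classes, c_star


@dataclass
class CorridorMap:
    """Summed categorical corridor surface plus per-pair metadata."""

    summed: Raster
    per_pair: dict[tuple[str, str], np.ndarray]
    lcp_costs: dict[tuple[str, str], float]
    skipped_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    mode: str = "quantile"

    def metadata(self) -> dict:
        return {
            "mode": self.mode,
            "fractions": list(self.fractions),
            "n_pairs": len(self.per_pair),
            "pairs": ["|".join(p) for p in sorted(self.per_pair)],
            "skipped_pairs": [list(t) for t in self.skipped_pairs],
            "lcp_costs": {"|".join(k): v for k, v in sorted(self.lcp_costs.items())},
        }

    def summary(self) -> str:
        vals = self.summed.values
        return (
            f"Corridor map ({self.mode} mode, fractions {self.fractions})\n"
            + "-" * 56
            + f"\npairs summed     {len(self.per_pair)}"
            + f"\npairs skipped    {len(self.skipped_pairs)}"
            + f"\nmax cell value   {int(np.nanmax(vals)) if vals.size else 0}"
        )


def snap_population_cells(
    raster: Raster, coords: dict[str, tuple[float, float]]
) -> dict[str, tuple[int, int]]:
    """Map population (x, y) coordinates to their nearest defined cell.

    A population whose nearest defined cell is more than one cell away is
    rejected: silently snapping across a barrier would corrupt corridors.
    """
    cells = {}
    defined = raster.defined_mask()
    for pop, (x, y) in coords.items():
        r, c = raster.nearest_cell(x, y)
        if defined[r, c]:
            cells[pop] = (r, c)
            continue
        window = defined[
            max(0, r - 1) : r + 2, max(0, c - 1) : c + 2
        ]
        if not window.any():
            raise InputError(
                f"population {pop!r} is more than one cell from any defined cell"
            )
        rr, cc = np.argwhere(defined[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2])[0]
        cells[pop] = (max(0, r - 1) + int(rr), max(0, c - 1) + int(cc))
    return cells


def summed_corridor(
    cost: CostRaster,
    pairs: PairList | list[tuple[str, str]],
    pop_cells: dict[str, tuple[int, int]],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    mode: str = "quantile",
    keep_per_pair: bool = True,
) -> CorridorMap:
    """Sum per-pair corridor classes into the population-connectivity map.

    Haplotype-level links are collapsed to unique population pairs first: a
    pair contributes once no matter how many haplotypes connect it.
    Unreachable pairs are skipped and recorded.
    """
    if isinstance(pairs, PairList):
        pop_pairs = pairs.population_pairs()
    else:
        pop_pairs = list(pairs)
    unique_pairs = sorted({tuple(sorted(p)) for p in pop_pairs})
    missing = [p for pair in unique_pairs for p in pair if p not in pop_cells]
    if missing:
        raise InputError(f"populations without a mapped cell: {sorted(set(missing))}")

    summed = np.zeros(cost.shape, dtype=int)
    per_pair: dict[tuple[str, str], np.ndarray] = {}
    lcp_costs: dict[tuple[str, str], float] = {}
    skipped: list[tuple[str, str, str]] = []
    for a, b in unique_pairs:
        try:
            classes, c_star = pair_corridor(
                cost, pop_cells[a], pop_cells[b], fractions=fractions, mode=mode
            )
        except UnreachablePairError as err:
            skipped.append((a, b, str(err)))
            continue
        summed += classes
        lcp_costs[(a, b)] = c_star
        if keep_per_pair:
            per_pair[(a, b)] = classes
        else:
            per_pair[(a, b)] = np.empty(0, dtype=int)
    if not unique_pairs:
        warnings.warn("empty pair list: corridor map is all zero", stacklevel=2)
    out = Raster(
        values=summed.astype(float),
        cell_size=cost.cell_size,
        origin=cost.origin,
        nodata=cost.nodata,
    )
    out.values[np.isnan(cost.values)] = np.nan
    return CorridorMap(
        summed=out,
        per_pair=per_pair,
        lcp_costs=lcp_costs,
        skipped_pairs=skipped,
        fractions=tuple(fractions),
        mode=mode,
    )
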