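"""Median-joining haplotype networks and shared/sister population pairs.

The median-joining (MJ) construction iterates two steps to a fixed point:

1. build the epsilon-relaxed minimum-spanning network (MSN) over the
   current node set — the union of all edges ``(u, v)`` whose Hamming
   distance does not exceed the single-linkage connection level of ``u``
   and ``v`` by more than ``epsilon``;
2. for every triplet of nodes of which at least two pairs are MSN edges,
   propose the per-site majority consensus ("median vector"); among
   proposals not already in the node set, add all whose connection cost
   ``d(u,m) + d(v,m) + d(w,m)`` is within ``epsilon`` of the round minimum.

Median vectors that end up with degree < 3 are obsolete (they lie on a
path that the observed nodes already realise) and are deleted.  All
candidate orderings are lexicographic in node label, so the topology is
deterministic.  A site at which all three triplet members disagree has no
majority and the triplet proposes nothing — with intraspecific data where
haplotypes differ by single steps such ties are rare and skipping them is
conservative.

"Sister" haplotypes are observed haplotypes at contracted network distance
exactly 1 (shortest weighted path, possibly through median vectors).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, HaplotypeDataset, InputError

__all__ = [
    "HaploNetwork",
    "PopulationPair",
    "PairList",
    "median_joining",
    "contracted_distance",
    "extract_pairs",
]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(
    labels: list[str], seqs: dict[str, str], epsilon: int
) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u, v) is feasible iff d(u, v) <= L(u, v) + epsilon, where
    L(u, v) is the single-linkage level at which the components of u and v
    first merge in a Kruskal sweep that adds ALL tied edges per level.
    """
    n = len(labels)
    if n <= 1:
        return []
    pairs = {
        (labels[i], labels[j]): _hamming(seqs[labels[i]], seqs[labels[j]])
        for i in range(n)
        for j in range(i + 1, n)
    }
    # single-linkage merge levels via level-by-level union-find
    parent = {l: l for l in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merge_level: dict[tuple[str, str], int] = {}
    for level in sorted(set(pairs.values())):
        # union all pairs at this level, then record every pair that has
        # just become connected
        for (u, v), duv in sorted(pairs.items()):
            if duv == level:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
        for (u, v) in pairs:
            if (u, v) not in merge_level and find(u) == find(v):
                merge_level[(u, v)] = level
    edges = [
        (u, v, duv)
        for (u, v), duv in sorted(pairs.items())
        if duv <= merge_level[(u, v)] + epsilon
    ]
    return edges


@dataclass
class HaploNetwork:
    """The MJ network: observed haplotypes plus retained median vectors."""

    graph: nx.Graph
    observed: list[str]
    medians: list[str]
    node_frequencies: dict[str, int]
    epsilon: int = 0

    def total_cost(self) -> float:
        """Weight of a minimum spanning tree of the network's node set.

        With optimally placed median vectors this equals the cost of the
        minimal (Steiner) connection of the observed haplotypes.
        """
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return float(sum(w for _, _, w in mst.edges(data="weight")))

    def minimal_connection_cost(self) -> float:
        """Cost of the cheapest subtree of the network spanning all observed
        haplotypes (median vectors used only where they help).

        Computed exactly by a Dreyfus-Wagner dynamic program over terminal
        subsets, so it is limited to networks with at most 14 observed
        haplotypes; this is the quantity to compare against an exhaustive
        minimal-network search.
        """
        terminals = self.observed
        if len(terminals) > 14:
            raise InputError("exact minimal connection is limited to <= 14 observed haplotypes")
        if len(terminals) <= 1:
            return 0.0
        nodes = list(self.graph.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        dist = np.full((n, n), np.inf)
        for src, lengths in nx.all_pairs_dijkstra_path_length(self.graph, weight="weight"):
            for dst, w in lengths.items():
                dist[index[src], index[dst]] = w
        k = len(terminals)
        dp: dict[frozenset[int], np.ndarray] = {
            frozenset([i]): dist[index[t]].copy() for i, t in enumerate(terminals)
        }
        for size in range(2, k + 1):
            for subset in itertools.combinations(range(k), size):
                S = frozenset(subset)
                arr = np.full(n, np.inf)
                seen: set[frozenset[int]] = set()
                for r in range(1, size):
                    for sub in itertools.combinations(sorted(S), r):
                        half = frozenset(sub)
                        rest = S - half
                        if half in seen or rest in seen:
                            continue
                        seen.add(half)
                        arr = np.minimum(arr, dp[half] + dp[rest])
                dp[S] = (arr[None, :] + dist).min(axis=1)
        full = frozenset(range(k))
        return float(min(dp[full][index[t]] for t in terminals))

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (u, v, int(w), self.graph.nodes[u]["is_median"], self.graph.nodes[v]["is_median"])
            for u, v, w in sorted(self.graph.edges(data="weight"))
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "weight", "median1", "median2"])

    def summary(self) -> str:
        return (
            f"Median-joining network (epsilon = {self.epsilon})\n"
            + "-" * 44
            + f"\nobserved haplotypes  {len(self.observed)}"
            + f"\nmedian vectors       {len(self.medians)}"
            + f"\nedges                {self.graph.number_of_edges()}"
            + f"\nnetwork cost (MST)   {self.total_cost():.0f}"
        )


def _majority_median(a: str, b: str, c: str) -> str | None:
    """Per-site majority consensus; None when some site is a 3-way tie."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


def median_joining(dataset: HaplotypeDataset, epsilon: int = 0) -> HaploNetwork:
    """Build the median-joining network of the dataset's haplotypes."""
    if epsilon < 0:
        raise InputError("epsilon must be non-negative")
    observed = [
        h for h, tot in zip(dataset.haplotype_ids, dataset.counts.sum(axis=0)) if tot > 0
    ]
    if not observed:
        raise InputError("dataset has no sampled haplotype")
    if not dataset.sequences:
        raise InputError("median_joining requires aligned sequences")
    seqs = {h: dataset.sequences[h] for h in observed}
    # collapse duplicate sequences (same haplotype sequence under two ids)
    freq = dict(
        zip(dataset.haplotype_ids, (int(x) for x in dataset.counts.sum(axis=0)))
    )

    labels = sorted(seqs)
    banned: set[str] = set()
    median_count = 0
    for _ in range(100):  # fixed point is reached in a handful of rounds
        labels, seqs, dropped = _drop_obsolete(labels, seqs, epsilon)
        banned.update(dropped)  # a deleted median is never proposed again
        edges = _msn_edges(labels, seqs, epsilon)
        G = nx.Graph()
        G.add_nodes_from(labels)
        G.add_weighted_edges_from(edges)
        candidates: dict[str, int] = {}
        for u, v, w in itertools.combinations(sorted(labels), 3):
            n_links = sum(G.has_edge(a, b) for a, b in ((u, v), (u, w), (v, w)))
            if n_links < 2:
                continue
            m = _majority_median(seqs[u], seqs[v], seqs[w])
            if m is None or m in seqs.values() or m in banned:
                continue
            lam = _hamming(seqs[u], m) + _hamming(seqs[v], m) + _hamming(seqs[w], m)
            if m not in candidates or lam < candidates[m]:
                candidates[m] = lam
        if not candidates:
            break
        lam_min = min(candidates.values())
        added = False
        for m_seq in sorted(s for s, lam in candidates.items() if lam <= lam_min + epsilon):
            median_count += 1
            label = f"mv{median_count}"
            labels.append(label)
            seqs[label] = m_seq
            added = True
        if not added:
            break

    labels, seqs, _ = _drop_obsolete(labels, seqs, epsilon)
    edges = _msn_edges(labels, seqs, epsilon)
    G = nx.Graph()
    for l in labels:
        G.add_node(l, seq=seqs[l], is_median=l.startswith("mv"))
    G.add_weighted_edges_from(edges)
    obs_final = [l for l in labels if not l.startswith("mv")]
    med_final = [l for l in labels if l.startswith("mv")]
    return HaploNetwork(
        graph=G,
        observed=obs_final,
        medians=med_final,
        node_frequencies={h: freq.get(h, 0) for h in obs_final},
        epsilon=epsilon,
    )


def _drop_obsolete(
    labels: list[str], seqs: dict[str, str], epsilon: int
) -> tuple[list[str], dict[str, str], set[str]]:
    """Iteratively delete median vectors with MSN degree < 3."""
    labels = list(labels)
    seqs = dict(seqs)
    dropped: set[str] = set()
    while True:
        edges = _msn_edges(labels, seqs, epsilon)
        deg = {l: 0 for l in labels}
        for u, v, _ in edges:
            deg[u] += 1
            deg[v] += 1
        drop = [l for l in labels if l.startswith("mv") and deg[l] < 3]
        if not drop:
            return labels, seqs, dropped
        for l in drop:
            labels.remove(l)
            dropped.add(seqs.pop(l))


def contracted_distance(network: HaploNetwork, h1: str, h2: str) -> float:
    """Shortest weighted path between two observed haplotypes.

    The path may pass through median vectors; edge weights (mutational
    steps) are summed.
    """
    for h in (h1, h2):
        if h not in network.observed:
            raise InputError(f"haplotype {h!r} is not an observed node of the network")
    return float(nx.shortest_path_length(network.graph, h1, h2, weight="weight"))


@dataclass
class PopulationPair:
    """An unordered population pair linked by shared or sister haplotypes."""

    pop_a: str
    pop_b: str
    relations: list[tuple[str, str, str]] = field(default_factory=list)
    # each relation: (kind, haplotype_in_a, haplotype_in_b); kind in
    # {"shared", "sister"}; for "shared" both haplotypes are the same id.

    @property
    def kinds(self) -> set[str]:
        return {k for k, _, _ in self.relations}


@dataclass
class PairList:
    """All population pairs connected through shared or sister haplotypes."""

    pairs: list[PopulationPair]
    sister_distance: float = 1.0

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def population_pairs(self) -> list[tuple[str, str]]:
        return [(p.pop_a, p.pop_b) for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.pop_a, p.pop_b, kind, ha, hb)
            for p in self.pairs
            for kind, ha, hb in p.relations
        ]
        return pd.DataFrame(rows, columns=["pop_a", "pop_b", "relation", "hap_a", "hap_b"])


def extract_pairs(
    dataset: HaplotypeDataset,
    network: HaploNetwork,
    sister_distance: float = 1.0,
) -> PairList:
    """Population pairs linked by shared or sister haplotypes.

    A pair (A, B) is included iff some haplotype has nonzero count in both
    populations ("shared"), or some haplotype of A and some haplotype of B
    are within ``sister_distance`` mutational steps in the network
    ("sister", default exactly one step).
    """
    counts = dataset.counts
    pops = dataset.pop_ids
    haps = list(dataset.haplotype_ids)
    # contracted distances among observed haplotypes present in the network
    present = [h for h in haps if h in network.observed]
    dist = {}
    for h in present:
        lengths = nx.single_source_dijkstra_path_length(network.graph, h, weight="weight")
        for h2 in present:
            dist[(h, h2)] = lengths.get(h2, np.inf)

    pairs: list[PopulationPair] = []
    for a, b in itertools.combinations(range(len(pops)), 2):
        relations: list[tuple[str, str, str]] = []
        in_a = [h for h, c in zip(haps, counts[a]) if c > 0]
        in_b = [h for h, c in zip(haps, counts[b]) if c > 0]
        for h in in_a:
            if h in in_b:
                relations.append(("shared", h, h))
        for ha in in_a:
            for hb in in_b:
                if ha == hb:
                    continue
                d = dist.get((ha, hb))
                if d is not None and 0 < d <= sister_distance:
                    relations.append(("sister", ha, hb))
        if relations:
            pairs.append(PopulationPair(pop_a=pops[a], pop_b=pops[b], relations=relations))
    return PairList(pairs=pairs, sister_distance=sister_distance)
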