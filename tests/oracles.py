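"""Independent oracles used to validate the package's algorithms.

Everything here is deliberately written without the package's own
implementations (and without scipy graph routines): plain-Python exhaustive
or dynamic-programming computations that are obviously correct on small
inputs.
"""

from __future__ import annotations

import itertools

import numpy as np

SQRT2 = 2.0**0.5


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def steiner_cost(terminals: list[str]) -> int:
    """Exact minimal-network (Steiner tree) cost of a haplotype set.

    Dreyfus-Wagner dynamic program over the product graph of per-site
    observed states; the unit-weight Hamming metric is its shortest-path
    metric, and an optimal Steiner point can always be chosen sitewise
    among observed states.
    """
    terminals = list(dict.fromkeys(terminals))
    k = len(terminals)
    if k <= 1:
        return 0
    L = len(terminals[0])
    states = [sorted({t[i] for t in terminals}) for i in range(L)]
    nodes = ["".join(p) for p in itertools.product(*states)]
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.array([[hamming(u, v) for v in nodes] for u in nodes], dtype=float)
    dp: dict[frozenset, np.ndarray] = {
        frozenset([i]): dist[idx[t]].copy() for i, t in enumerate(terminals)
    }
    for size in range(2, k + 1):
        for subset in itertools.combinations(range(k), size):
            S = frozenset(subset)
            arr = np.full(n, np.inf)
            seen: set[frozenset] = set()
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
    return int(round(min(dp[full][idx[t]] for t in terminals)))


def grid_accumulated_costs(values: np.ndarray, cell_size: float = 1.0) -> np.ndarray:
    """All-pairs accumulated least costs on an 8-connected cost grid.

    Depth-first enumeration of paths with pruning of provably dominated
    prefixes (a prefix costing at least the best known cost to its head
    cannot lead to a better path, since step costs are positive).
    Returns an (n_cells, n_cells) matrix in row-major cell order; NaN
    cells are impassable.
    """
    n_rows, n_cols = values.shape
    n = n_rows * n_cols
    result = np.full((n, n), np.inf)

    def neighbors(r: int, c: int):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and not np.isnan(values[rr, cc]):
                    mult = SQRT2 if dr and dc else 1.0
                    step = 0.5 * (values[r, c] + values[rr, cc]) * cell_size * mult
                    yield rr, cc, step

    for sr in range(n_rows):
        for sc in range(n_cols):
            if np.isnan(values[sr, sc]):
                continue
            src = sr * n_cols + sc
            best = np.full(n, np.inf)
            best[src] = 0.0
            stack = [(sr, sc, 0.0)]
            while stack:
                r, c, acc = stack.pop()
                for rr, cc, step in neighbors(r, c):
                    new = acc + step
                    j = rr * n_cols + cc
                    if new < best[j] - 1e-12:
                        best[j] = new
                        stack.append((rr, cc, new))
            result[src] = best
    return result


def shortest_network_path(edges: list[tuple[str, str, float]], a: str, b: str) -> float:
    """Minimum-weight simple path by exhaustive enumeration."""
    adjacency: dict[str, list[tuple[str, float]]] = {}
    for u, v, w in edges:
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))
    best = np.inf

    def walk(node: str, seen: frozenset, acc: float) -> None:
        nonlocal best
        if node == b:
            best = min(best, acc)
            return
        for nxt, w in adjacency.get(node, []):
            if nxt not in seen and acc + w < best:
                walk(nxt, seen | {nxt}, acc + w)

    walk(a, frozenset([a]), 0.0)
    return float(best)


# ---------------------------------------------------------------------------
# random dataset families (shared by tests and the acceptance script)


def random_mutation_tree(rng: np.random.Generator) -> list[str]:
    """Haplotypes generated by single-site mutations on a random tree."""
    n = int(rng.integers(3, 7))
    L = int(rng.integers(max(3, n - 1), 7))
    base = "".join(rng.choice(list("AC"), L))
    seqs = [base]
    sites = list(rng.permutation(L)[: n - 1])
    for site in sites:
        parent = seqs[int(rng.integers(0, len(seqs)))]
        flip = {"A": "C", "C": "A"}[parent[site]]
        seqs.append(parent[:site] + flip + parent[site + 1 :])
    return list(dict.fromkeys(seqs))


def random_corner_set(rng: np.random.Generator) -> list[str]:
    """Distinct random corners of a small binary sequence hypercube."""
    L = int(rng.integers(3, 6))
    n = int(rng.integers(3, 6))
    corners: set[str] = set()
    while len(corners) < n:
        corners.add("".join(rng.choice(list("AT"), L)))
    return sorted(corners)


def mjn_oracle_family(seed: int, n_cases: int = 50) -> list[list[str]]:
    """The fixed random family for the network-vs-minimal-network check."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        if i % 2 == 0:
            cases.append(random_mutation_tree(rng))
        else:
            cases.append(random_corner_set(rng))
    return cases
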