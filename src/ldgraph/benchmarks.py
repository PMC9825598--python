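"""Planted-structure generators and search oracles for validating the
block-model machinery.

These are first-class package functions (not test fixtures): the acceptance
script and the test suite both drive them. Each generator plants known
community structure into a two-layer graph so that recovery, description-
length optimality and layer separation can be scored against ground truth.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .sbm import BlockState, LayeredGraph, anneal


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _er_edges(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    i, j = np.triu_indices(n, k=1)
    keep = rng.random(len(i)) < p
    return np.column_stack([i[keep], j[keep]])


def _pair_index(bi: np.ndarray, bj: np.ndarray, n_blocks: int) -> np.ndarray:
    lo = np.minimum(bi, bj)
    hi = np.maximum(bi, bj)
    return lo * n_blocks + hi


def planted_partition_graph(n_nodes: int = 120, n_blocks: int = 3,
                            p_in: float = 0.25, p_out: float = 0.05,
                            weight_sd: float = 0.05, separation: float = 1.0,
                            seed: int = 0) -> tuple[LayeredGraph, np.ndarray]:
    """Assortative graph with block-structured Gaussian weights.

    Nodes are split into equal blocks; edges appear with probability ``p_in``
    within and ``p_out`` between blocks. Each unordered block pair gets a
    distinct layer-A mean, spread across [0.1, 0.9] and shrunk toward 0.5 by
    ``1 - separation``; layer-C counts are uninformative Poisson(4) draws.
    Returns the graph and the planted node labels.
    """
    rng = np.random.default_rng(seed)
    b = np.arange(n_nodes) * n_blocks // n_nodes
    i, j = np.triu_indices(n_nodes, k=1)
    within = b[i] == b[j]
    keep = rng.random(len(i)) < np.where(within, p_in, p_out)
    edges = np.column_stack([i[keep], j[keep]])
    n_pairs = n_blocks * (n_blocks + 1) // 2
    base = np.linspace(0.1, 0.9, n_pairs)
    mu_table = np.full(n_blocks * n_blocks, np.nan)
    k = 0
    for r in range(n_blocks):
        for s in range(r, n_blocks):
            mu_table[r * n_blocks + s] = base[k]
            k += 1
    mu = mu_table[_pair_index(b[edges[:, 0]], b[edges[:, 1]], n_blocks)]
    mu = 0.5 + separation * (mu - 0.5)
    w = np.clip(rng.normal(mu, weight_sd), 0.0, 1.0)
    c = rng.poisson(4.0, size=len(edges))
    return LayeredGraph(n_nodes, edges, w, c), b


def layer_distinct_graph(n_nodes: int = 90, seed: int = 0
                         ) -> tuple[LayeredGraph, np.ndarray, np.ndarray]:
    """Two-layer graph whose layers carry *different* planted partitions.

    Edges are uniform Erdos-Renyi (the structure term is uninformative).
    Layer-A means follow a contiguous 3-block partition; layer-C Poisson
    rates follow a modulo-3 partition that cuts across it. Only a layered
    model can describe both patterns with one node partition per-layer
    likelihood; shuffling values across layers destroys them.
    """
    rng = np.random.default_rng(seed)
    edges = _er_edges(n_nodes, 0.12, rng)
    b_a = np.arange(n_nodes) * 3 // n_nodes
    b_c = np.arange(n_nodes) % 3
    n_blocks = 3
    pidx_a = _pair_index(b_a[edges[:, 0]], b_a[edges[:, 1]], n_blocks)
    mu = np.linspace(0.1, 0.9, 6)[_dense_pair(pidx_a, n_blocks)]
    w = np.clip(rng.normal(mu, 0.04), 0.0, 1.0)
    lam = np.array([2.0, 6.0, 14.0, 6.0, 14.0, 2.0])[
        _dense_pair(_pair_index(b_c[edges[:, 0]], b_c[edges[:, 1]], n_blocks),
                    n_blocks)]
    c = rng.poisson(lam)
    return LayeredGraph(n_nodes, edges, w, c), b_a, b_c


def _dense_pair(pidx: np.ndarray, n_blocks: int) -> np.ndarray:
    """Map lo*n+hi pair codes to dense 0..n(n+1)/2-1 indices."""
    table = {}
    k = 0
    for r in range(n_blocks):
        for s in range(r, n_blocks):
            table[r * n_blocks + s] = k
            k += 1
    return np.array([table[int(x)] for x in pidx])


def exchangeable_graph(n_nodes: int = 90, lam: float = 5.0, seed: int = 0
                       ) -> LayeredGraph:
    """Two-layer graph with no layer-specific structure: both per-edge values
    are independent Poisson(lam) draws, the layer-A copy min-max cast into
    [0, 1]. Swapping layers changes nothing in distribution."""
    rng = np.random.default_rng(seed)
    edges = _er_edges(n_nodes, 0.12, rng)
    c1 = rng.poisson(lam, size=len(edges))
    c2 = rng.poisson(lam, size=len(edges))
    lo, hi = c1.min(), c1.max()
    w = (np.asarray(c2, float) - lo) / (hi - lo) if hi > lo else np.full(len(edges), 0.5)
    w = np.clip(w, 0.0, 1.0)
    return LayeredGraph(n_nodes, edges, w, c1)


def random_small_graph(seed: int, n_min: int = 4, n_max: int = 8) -> LayeredGraph:
    """Random connected-ish two-layer graph with at most ``n_max`` nodes, for
    exhaustive-search comparison."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        edges = _er_edges(n, 0.5, rng)
        if len(edges) >= 1:
            break
    w = rng.uniform(0.0, 1.0, size=len(edges))
    c = rng.poisson(3.0, size=len(edges))
    return LayeredGraph(n, edges, w, c)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def set_partitions(n: int) -> Iterator[np.ndarray]:
    """All set partitions of n items as restricted-growth label strings."""
    labels = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)
    yield labels.copy()
    while True:
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]
        yield labels.copy()


def exhaustive_min_sigma(graph: LayeredGraph) -> tuple[float, np.ndarray]:
    """Global minimum description length over every partition (brute force;
    only feasible for small graphs)."""
    if graph.n_nodes > 10:
        raise ValueError("exhaustive search is limited to <= 10 nodes")
    best = np.inf
    best_b = None
    for b in set_partitions(graph.n_nodes):
        s = BlockState(graph, b).sigma
        if s < best:
            best = s
            best_b = b
    return best, best_b


# ---------------------------------------------------------------------------
# benchmark drivers
# ---------------------------------------------------------------------------

def dl_oracle_benchmark(n_graphs: int = 50, seed: int = 0, tol: float = 1e-6,
                        wait: int = 50, max_sweeps_per_stage: int = 150) -> dict:
    """Annealed Sigma vs the exhaustive minimum on random small graphs.

    Returns the fraction of graphs where annealing attains the global
    minimum and the count where it (impossibly, if correct) undercuts it.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_graphs)
    matches = 0
    undercuts = 0
    for s in seeds:
        s = int(s) % (2 ** 31)
        g = random_small_graph(s)
        opt, _ = exhaustive_min_sigma(g)
        fit = anneal(g, wait=wait, seed=s,
                     max_sweeps_per_stage=max_sweeps_per_stage)
        if fit.sigma < opt - tol:
            undercuts += 1
        if abs(fit.sigma - opt) <= tol:
            matches += 1
    return {"n_graphs": n_graphs, "match_rate": matches / n_graphs,
            "undercuts": undercuts}


def planted_recovery_benchmark(n_seeds: int = 20, seed: int = 0,
                               ari_threshold: float = 0.9,
                               separation: float = 1.0,
                               wait: int = 30,
                               max_sweeps_per_stage: int = 100) -> dict:
    """Partition recovery on strongly separated 3-block planted graphs."""
    from .evaluate import adjusted_rand

    seeds = np.random.SeedSequence(seed).generate_state(n_seeds)
    aris = []
    for s in seeds:
        s = int(s) % (2 ** 31)
        g, truth = planted_partition_graph(separation=separation, seed=s)
        fit = anneal(g, wait=wait, seed=s,
                     max_sweeps_per_stage=max_sweeps_per_stage)
        aris.append(adjusted_rand(fit.b, truth))
    aris = np.asarray(aris)
    return {"n_seeds": n_seeds, "aris": aris.tolist(),
            "mean_ari": float(aris.mean()),
            "n_success": int((aris >= ari_threshold).sum())}


def layer_separation_benchmark(n_seeds: int = 20, seed: int = 0,
                               mode: str = "distinct", wait: int = 15,
                               max_sweeps_per_stage: int = 60) -> dict:
    """Layered-vs-randomised-null description-length differences across
    seeded planted graphs (mode 'distinct') or exchangeable-weight graphs
    (mode 'exchangeable')."""
    from .sbm import fit_and_compare

    seeds = np.random.SeedSequence(seed).generate_state(n_seeds)
    deltas = []
    for s in seeds:
        s = int(s) % (2 ** 31)
        if mode == "distinct":
            g, _, _ = layer_distinct_graph(seed=s)
        elif mode == "exchangeable":
            g = exchangeable_graph(seed=s)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        _, _, cmp = fit_and_compare(g, seed=s, wait=wait,
                                    max_sweeps_per_stage=max_sweeps_per_stage)
        deltas.append(cmp.delta)
    deltas = np.asarray(deltas)
    return {"n_seeds": n_seeds, "deltas": deltas.tolist(),
            "mean_delta": float(deltas.mean()),
            "sd_delta": float(deltas.std(ddof=1)),
            "n_positive": int((deltas > 0).sum())}
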