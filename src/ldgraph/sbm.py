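"""Flat degree-corrected stochastic block model with two edge-weight layers.

The model scores a node partition ``b`` of a weighted graph by a total
description length (in nats)

    Sigma = S_struct + S_part + S_A + S_C

* ``S_struct``: microcanonical degree-corrected structure term,
  ``E - 1/2 * sum_rs e_rs ln(e_rs / (e_r e_s))`` with the diagonal counted
  twice (``sum_rs e_rs = 2E``);
* ``S_part``: complexity penalty ``E*h(zeta) + N ln B`` with
  ``zeta = B(B+1)/(2E)`` and ``h(x) = (1+x)ln(1+x) - x ln x``;
* ``S_A``: minus log marginal likelihood of the real-valued deficit weights
  within each block pair under a Normal-Inverse-Gamma conjugate model
  (mu0=0.5, kappa0=1, a0=1, b0=0.1);
* ``S_C``: minus log marginal likelihood of the integer co-occurrence counts
  within each block pair under a Gamma-Poisson conjugate model
  (alpha0=1, beta0=1).

Lower Sigma means a more plausible model; differences between fits give
posterior odds. Inference is single-node Metropolis moves on Sigma with
simulated annealing (inverse temperature 1 -> 10, record-breaking plateau
criterion), optionally preceded by agglomerative merging from singletons.

Confining each weight type to its own layer and comparing against a fit in
which the two values of every edge are randomly shuffled across layers tests
whether deficit-driven and co-occurrence-driven structure are genuinely
distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import SubstrateMap
from .graphs import LesionGraph, NodeTable

# conjugate hyperparameters (weights live in [0,1]; counts are small integers)
MU0, K0, A0, B0 = 0.5, 1.0, 1.0, 0.1
ALPHA0, BETA0 = 1.0, 1.0
CAT_ALPHA = 1.0

_LN2PI = math.log(2.0 * math.pi)
_lgamma = math.lgamma


class SBMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# layered graph container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayeredGraph:
    """Undirected graph with a Gaussian layer (A), an optional Poisson layer
    (C) and an optional categorical layer (E), all on the same edge set."""

    n_nodes: int
    edges: np.ndarray            # (E, 2) int, i < j
    weight_A: np.ndarray         # (E,) float in [0, 1]
    count_C: Optional[np.ndarray] = None   # (E,) int >= 0
    cat_E: Optional[np.ndarray] = None     # (E,) int category ids
    # raw per-edge values and swap mask, kept so layer randomisation is an
    # involution (see randomize_layers)
    raw_A: Optional[np.ndarray] = None
    raw_C: Optional[np.ndarray] = None
    swap_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(e) and ((e[:, 0] >= e[:, 1]).any() or e.min() < 0 or e.max() >= self.n_nodes):
            raise SBMError("edges must be canonical i<j pairs over 0..n_nodes-1")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "weight_A", np.asarray(self.weight_A, dtype=float))
        if self.count_C is not None:
            c = np.asarray(self.count_C, dtype=np.int64)
            if (c < 0).any():
                raise SBMError("counts must be >= 0")
            object.__setattr__(self, "count_C", c)
        if len(self.weight_A) != len(e):
            raise SBMError("layer A must cover every edge")
        if self.count_C is not None and len(self.count_C) != len(e):
            raise SBMError("layer C must cover every edge")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @classmethod
    def from_lesion_graph(cls, g: LesionGraph, with_aetiology: bool = False
                          ) -> "LayeredGraph":
        return cls(n_nodes=g.n_nodes, edges=g.edges.pairs,
                   weight_A=g.deficit_weight, count_C=g.cooccurrence,
                   cat_E=(g.aetiology_weight if with_aetiology else None))


# ---------------------------------------------------------------------------
# conjugate log-marginals
# ---------------------------------------------------------------------------

def _ln_nig(n: float, s: float, ss: float) -> float:
    """Log marginal of n observations (sum s, sum of squares ss) under the
    Normal-Inverse-Gamma prior."""
    if n == 0:
        return 0.0
    kn = K0 + n
    an = A0 + 0.5 * n
    xbar = s / n
    scatter = ss - n * xbar * xbar
    if scatter < 0.0:  # numerical cancellation guard
        scatter = 0.0
    bn = B0 + 0.5 * scatter + K0 * n * (xbar - MU0) ** 2 / (2.0 * kn)
    return (_lgamma(an) - _lgamma(A0) + A0 * math.log(B0) - an * math.log(bn)
            + 0.5 * (math.log(K0) - math.log(kn)) - 0.5 * n * _LN2PI)


def _ln_gp(n: float, s: float) -> float:
    """Log marginal of n Poisson counts with sum s under a Gamma prior,
    excluding the partition-invariant -sum ln(c!) term (added globally)."""
    if n == 0:
        return 0.0
    return (_lgamma(ALPHA0 + s) - _lgamma(ALPHA0) + ALPHA0 * math.log(BETA0)
            - (ALPHA0 + s) * math.log(BETA0 + n))


def _ln_cat(counts: np.ndarray) -> float:
    """Dirichlet-multinomial log marginal for an ordered category sequence."""
    n = counts.sum()
    if n == 0:
        return 0.0
    k = len(counts)
    out = _lgamma(k * CAT_ALPHA) - _lgamma(n + k * CAT_ALPHA)
    for c in counts:
        out += _lgamma(c + CAT_ALPHA) - _lgamma(CAT_ALPHA)
    return out


def _h(x: float) -> float:
    if x <= 0.0:
        return 0.0
    return (1.0 + x) * math.log1p(x) - x * math.log(x)


# ---------------------------------------------------------------------------
# block state with incremental sufficient statistics
# ---------------------------------------------------------------------------

class BlockState:
    """Node partition plus per-block-pair sufficient statistics and Sigma.

    Statistics per unordered block pair (r <= s): edge count m, layer-A sum
    and sum of squares, layer-C sum (and categorical counts when present).
    All updates are incremental; :meth:`recount` rebuilds from scratch for
    audits.
    """

    def __init__(self, graph: LayeredGraph, b: Sequence[int]):
        b = np.asarray(b, dtype=np.int64)
        if len(b) != graph.n_nodes:
            raise SBMError("partition must assign every node")
        if (b < 0).any():
            raise SBMError("block labels must be non-negative")
        self.g = graph
        self.b = b.copy()
        self._n_cat = (int(graph.cat_E.max()) + 1) if graph.cat_E is not None else 0
        self._build_adjacency()
        self._build_stats()
        self._sigma = self._full_sigma()

    # -- construction -----------------------------------------------------

    def _build_adjacency(self) -> None:
        g = self.g
        e = g.edges
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        eid = np.concatenate([np.arange(len(e)), np.arange(len(e))])
        order = np.argsort(src, kind="stable")
        self._nbr = dst[order]
        self._nbr_eid = eid[order]
        self._indptr = np.searchsorted(src[order], np.arange(g.n_nodes + 1))
        self.degree = np.diff(self._indptr)
        has_c = g.count_C is not None
        self._const_lfact = (float(np.sum([_lgamma(c + 1.0) for c in g.count_C]))
                             if has_c else 0.0)

    def _build_stats(self) -> None:
        g, b = self.g, self.b
        self.stats: dict[tuple[int, int], np.ndarray] = {}
        self.cat_stats: dict[tuple[int, int], np.ndarray] = {}
        self.pairs_of: dict[int, set] = {}
        self.n_r: dict[int, int] = {}
        self.e_r: dict[int, int] = {}
        for v in range(g.n_nodes):
            self.n_r[b[v]] = self.n_r.get(b[v], 0) + 1
            self.e_r[b[v]] = self.e_r.get(b[v], 0) + int(self.degree[v])
        w, c = g.weight_A, g.count_C
        for i, (u, v) in enumerate(g.edges):
            key = _pkey(b[u], b[v])
            st = self.stats.get(key)
            if st is None:
                st = np.zeros(4)
                self.stats[key] = st
                self.pairs_of.setdefault(key[0], set()).add(key)
                self.pairs_of.setdefault(key[1], set()).add(key)
            st[0] += 1.0
            st[1] += w[i]
            st[2] += w[i] * w[i]
            if c is not None:
                st[3] += c[i]
            if self._n_cat:
                cs = self.cat_stats.get(key)
                if cs is None:
                    cs = np.zeros(self._n_cat)
                    self.cat_stats[key] = cs
                cs[g.cat_E[i]] += 1
        self._next_label = int(b.max()) + 1

    # -- Sigma ------------------------------------------------------------

    @property
    def B(self) -> int:
        return len(self.n_r)

    @property
    def sigma(self) -> float:
        return self._sigma

    def _pair_terms(self, key: tuple[int, int], st: np.ndarray) -> float:
        """Structure (m-part) + weight-marginal contribution of one pair."""
        m = st[0]
        if m == 0.0:
            return 0.0
        if key[0] == key[1]:
            out = -m * math.log(2.0 * m)
        else:
            out = -m * math.log(m)
        out -= _ln_nig(m, st[1], st[2])
        if self.g.count_C is not None:
            out -= _ln_gp(m, st[3])
        if self._n_cat:
            out -= _ln_cat(self.cat_stats[key])
        return out

    def _part_term(self, B: int) -> float:
        g = self.g
        E = g.n_edges
        if E == 0:
            return g.n_nodes * math.log(B) if B > 1 else 0.0
        zeta = B * (B + 1) / (2.0 * E)
        return E * _h(zeta) + g.n_nodes * math.log(B)

    def _full_sigma(self) -> float:
        br = self.sigma_breakdown()
        return br["structure"] + br["partition"] + br["layer_A"] + br["layer_C"] \
            + br.get("layer_E", 0.0)

    def sigma_breakdown(self) -> dict:
        """Per-term description length (nats)."""
        g = self.g
        E = g.n_edges
        s_struct = float(E)
        for key, st in self.stats.items():
            m = st[0]
            if m > 0:
                s_struct += (-m * math.log(2.0 * m) if key[0] == key[1]
                             else -m * math.log(m))
        for e in self.e_r.values():
            if e > 0:
                s_struct += e * math.log(e)
        s_a = -sum(_ln_nig(st[0], st[1], st[2]) for st in self.stats.values())
        if g.count_C is not None:
            s_c = self._const_lfact - sum(_ln_gp(st[0], st[3])
                                          for st in self.stats.values())
        else:
            s_c = 0.0
        out = {"structure": s_struct, "partition": self._part_term(self.B),
               "layer_A": float(s_a), "layer_C": float(s_c)}
        if self._n_cat:
            out["layer_E"] = -sum(_ln_cat(cs) for cs in self.cat_stats.values())
        if not all(math.isfinite(v) for v in out.values()):
            raise SBMError(f"non-finite description length term: {out}")
        return out

    def recount(self) -> float:
        """Sigma rebuilt from scratch (audit path, independent of the
        incremental bookkeeping)."""
        return BlockState(self.g, self.b).sigma

    # -- incremental moves ------------------------------------------------

    def _neighbour_groups(self, v: int):
        lo, hi = self._indptr[v], self._indptr[v + 1]
        nbrs = self._nbr[lo:hi]
        eids = self._nbr_eid[lo:hi]
        t = self.b[nbrs]
        if len(t) == 0:
            return [], None
        labels, inv = np.unique(t, return_inverse=True)
        w = self.g.weight_A[eids]
        d = np.bincount(inv).astype(float)
        ws = np.bincount(inv, weights=w)
        wss = np.bincount(inv, weights=w * w)
        if self.g.count_C is not None:
            cs = np.bincount(inv, weights=self.g.count_C[eids].astype(float))
        else:
            cs = np.zeros(len(labels))
        cats = None
        if self._n_cat:
            cats = np.zeros((len(labels), self._n_cat))
            np.add.at(cats, (inv, self.g.cat_E[eids]), 1.0)
        return list(zip(labels.tolist(), d, ws, wss, cs)), cats

    def _move_changes(self, v: int, s: int):
        """Per-pair stat deltas induced by moving v from its block to s."""
        r = int(self.b[v])
        groups, cats = self._neighbour_groups(v)
        changes: dict[tuple[int, int], np.ndarray] = {}
        cat_changes: dict[tuple[int, int], np.ndarray] = {}

        def add(key, vec, cvec):
            acc = changes.get(key)
            if acc is None:
                changes[key] = vec.copy()
            else:
                acc += vec
            if cvec is not None:
                cacc = cat_changes.get(key)
                if cacc is None:
                    cat_changes[key] = cvec.copy()
                else:
                    cacc += cvec

        for gi, (t, d, ws, wss, cs) in enumerate(groups):
            vec = np.array([d, ws, wss, cs])
            cvec = cats[gi] if cats is not None else None
            if t == r:
                old, new = _pkey(r, r), _pkey(r, s)
            elif t == s:
                old, new = _pkey(r, s), _pkey(s, s)
            else:
                old, new = _pkey(r, t), _pkey(s, t)
            add(old, -vec, -cvec if cvec is not None else None)
            add(new, vec, cvec)
        return r, changes, cat_changes

    def move_delta(self, v: int, s: int) -> float:
        """Exact Sigma change if node v moved to block s (s may be fresh)."""
        r = int(self.b[v])
        if s == r:
            return 0.0
        _, changes, cat_changes = self._move_changes(v, s)
        delta = 0.0
        zeros4 = np.zeros(4)
        saved_cats = {}
        for key, ch in changes.items():
            st0 = self.stats.get(key, zeros4)
            if self._n_cat:
                cs0 = self.cat_stats.get(key, np.zeros(self._n_cat))
                saved_cats[key] = cs0
                self.cat_stats[key] = cs0 + cat_changes.get(key, 0)
            st1 = st0 + ch
            if self._n_cat:
                old_term = self._pair_terms_with_cat(key, st0, saved_cats[key])
                new_term = self._pair_terms_with_cat(key, st1, self.cat_stats[key])
                delta += new_term - old_term
            else:
                delta += self._pair_terms(key, st1) - self._pair_terms(key, st0)
        if self._n_cat:
            for key, cs0 in saved_cats.items():
                self.cat_stats[key] = cs0
        k = int(self.degree[v])
        er0, es0 = self.e_r[r], self.e_r.get(s, 0)
        er1, es1 = er0 - k, es0 + k
        for e0, e1 in ((er0, er1), (es0, es1)):
            if e0 > 0:
                delta -= e0 * math.log(e0)
            if e1 > 0:
                delta += e1 * math.log(e1)
        b_new = self.B + (0 if s in self.n_r else 1) - (1 if self.n_r[r] == 1 else 0)
        if b_new != self.B:
            delta += self._part_term(b_new) - self._part_term(self.B)
        return delta

    def _pair_terms_with_cat(self, key, st, cs) -> float:
        m = st[0]
        if m == 0.0:
            return 0.0
        out = (-m * math.log(2.0 * m) if key[0] == key[1] else -m * math.log(m))
        out -= _ln_nig(m, st[1], st[2])
        if self.g.count_C is not None:
            out -= _ln_gp(m, st[3])
        out -= _ln_cat(cs)
        return out

    def apply_move(self, v: int, s: int, delta: Optional[float] = None) -> None:
        r = int(self.b[v])
        if s == r:
            return
        if delta is None:
            delta = self.move_delta(v, s)
        _, changes, cat_changes = self._move_changes(v, s)
        for key, ch in changes.items():
            st = self.stats.get(key)
            if st is None:
                st = np.zeros(4)
                self.stats[key] = st
                self.pairs_of.setdefault(key[0], set()).add(key)
                self.pairs_of.setdefault(key[1], set()).add(key)
            st += ch
            if self._n_cat and key in cat_changes:
                cs = self.cat_stats.setdefault(key, np.zeros(self._n_cat))
                cs += cat_changes[key]
            if st[0] <= 1e-9:
                del self.stats[key]
                self.cat_stats.pop(key, None)
                self.pairs_of[key[0]].discard(key)
                self.pairs_of[key[1]].discard(key)
        k = int(self.degree[v])
        self.e_r[r] -= k
        self.e_r[s] = self.e_r.get(s, 0) + k
        self.n_r[r] -= 1
        self.n_r[s] = self.n_r.get(s, 0) + 1
        if self.n_r[r] == 0:
            del self.n_r[r]
            self.e_r.pop(r, None)
        self.b[v] = s
        self._next_label = max(self._next_label, s + 1)
        self._sigma += delta

    def merge_delta(self, r: int, s: int) -> float:
        """Sigma change if blocks r and s were merged (into one block)."""
        if r == s or r not in self.n_r or s not in self.n_r:
            raise SBMError("merge requires two distinct nonempty blocks")
        zeros4 = np.zeros(4)
        zc = np.zeros(self._n_cat) if self._n_cat else None
        get = self.stats.get
        getc = self.cat_stats.get

        def term(key, st, cs):
            if self._n_cat:
                return self._pair_terms_with_cat(key, st, cs)
            return self._pair_terms(key, st)

        delta = 0.0
        others = set()
        for key in self.pairs_of.get(r, ()) | self.pairs_of.get(s, ()):
            a, bb = key
            t = bb if a in (r, s) else a
            if t in (r, s):
                continue
            others.add(t)
        # off-diagonal pairs with third blocks
        for t in others:
            kr, ks = _pkey(r, t), _pkey(s, t)
            st_r, st_s = get(kr, zeros4), get(ks, zeros4)
            cs_r = getc(kr, zc) if self._n_cat else None
            cs_s = getc(ks, zc) if self._n_cat else None
            merged = st_r + st_s
            mc = (cs_r + cs_s) if self._n_cat else None
            delta += term(kr, merged, mc) - term(kr, st_r, cs_r) - term(ks, st_s, cs_s)
        # internal pairs
        krr, kss, krs = _pkey(r, r), _pkey(s, s), _pkey(r, s)
        st = get(krr, zeros4) + get(kss, zeros4) + get(krs, zeros4)
        if self._n_cat:
            mc = getc(krr, zc) + getc(kss, zc) + getc(krs, zc)
        else:
            mc = None
        delta += term(krr, st, mc)
        delta -= term(krr, get(krr, zeros4), getc(krr, zc) if self._n_cat else None)
        delta -= term(kss, get(kss, zeros4), getc(kss, zc) if self._n_cat else None)
        delta -= term(krs, get(krs, zeros4), getc(krs, zc) if self._n_cat else None)
        # e_r terms
        er, es = self.e_r[r], self.e_r[s]
        for e0 in (er, es):
            if e0 > 0:
                delta -= e0 * math.log(e0)
        if er + es > 0:
            delta += (er + es) * math.log(er + es)
        delta += self._part_term(self.B - 1) - self._part_term(self.B)
        return delta

    def apply_merge(self, r: int, s: int) -> None:
        """Merge block s into r (stats rebuilt; used during initialisation)."""
        self.b[self.b == s] = r
        self._build_stats()
        self._sigma = self._full_sigma()


def _pkey(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def description_length(graph: LayeredGraph, b: Sequence[int]) -> dict:
    """Total description length of partition ``b`` with per-term breakdown."""
    state = BlockState(graph, b)
    out = state.sigma_breakdown()
    out["total"] = state.sigma
    return out


def init_partition(graph: LayeredGraph, mode: str = "singletons_merge",
                   seed: int = 0, B: int = 10) -> BlockState:
    """Initial state: greedy agglomeration from singletons, or a random
    assignment into ``B`` blocks."""
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    if mode == "random_B":
        return BlockState(graph, rng.integers(0, max(1, B), size=n))
    if mode != "singletons_merge":
        raise SBMError(f"unknown init mode {mode!r}")
    state = BlockState(graph, np.arange(n))
    while True:
        candidates = []
        seen = set()
        for key in list(state.stats.keys()):
            r, s = key
            if r == s or key in seen:
                continue
            seen.add(key)
            d = state.merge_delta(r, s)
            if d < -1e-12:
                candidates.append((d, r, s))
        if not candidates:
            break
        candidates.sort()
        merged = set()
        any_applied = False
        for d, r, s in candidates:
            if r in merged or s in merged:
                continue
            if state.merge_delta(r, s) < -1e-12:
                state.apply_merge(r, s)
                merged.update((r, s))
                any_applied = True
        if not any_applied:
            break
    return state


def mcmc_sweep(state: BlockState, beta: float, rng: np.random.Generator) -> int:
    """One Metropolis pass over all nodes in random order.

    Proposals: with probability 0.9 the block of a uniformly chosen
    neighbour; otherwise a uniform choice among existing blocks plus one
    fresh block. Acceptance min(1, exp(-beta*delta)). Returns the number of
    accepted moves.
    """
    if beta <= 0:
        raise SBMError("beta must be > 0")
    accepted = 0
    order = rng.permutation(state.g.n_nodes)
    for v in order:
        lo, hi = state._indptr[v], state._indptr[v + 1]
        if hi > lo and rng.random() < 0.9:
            nbr = state._nbr[lo + rng.integers(hi - lo)]
            target = int(state.b[nbr])
        else:
            labels = list(state.n_r.keys())
            labels.append(state._next_label)
            target = int(labels[rng.integers(len(labels))])
        if target == state.b[v]:
            continue
        delta = state.move_delta(v, target)
        if delta <= 0 or rng.random() < math.exp(-beta * delta):
            state.apply_move(v, target, delta)
            accepted += 1
    return accepted


def geometric_schedule(beta_min: float = 1.0, beta_max: float = 10.0,
                       n_steps: int = 10) -> np.ndarray:
    return np.geomspace(beta_min, beta_max, n_steps)


def anneal(graph: LayeredGraph, beta_schedule: Optional[np.ndarray] = None,
           wait: int = 100, seed: int = 0, init: str = "singletons_merge",
           init_B: int = 10, max_sweeps_per_stage: int = 1000) -> BlockState:
    """Simulated-annealing fit: sweep along an increasing inverse-temperature
    schedule, at each stage until no new record-low Sigma occurs for ``wait``
    consecutive sweeps; return the best state observed."""
    if wait < 1:
        raise SBMError("wait must be >= 1")
    if beta_schedule is None:
        beta_schedule = geometric_schedule()
    beta_schedule = np.asarray(beta_schedule, dtype=float)
    if (np.diff(beta_schedule) < 0).any() or beta_schedule[0] <= 0:
        raise SBMError("beta schedule must be positive and non-decreasing")
    rng = np.random.default_rng(seed)
    state = init_partition(graph, mode=init, seed=seed, B=init_B)
    best_sigma = state.sigma
    best_b = state.b.copy()
    for beta in beta_schedule:
        since_record = 0
        sweeps = 0
        while since_record < wait and sweeps < max_sweeps_per_stage:
            mcmc_sweep(state, float(beta), rng)
            sweeps += 1
            if state.sigma < best_sigma - 1e-9:
                best_sigma = state.sigma
                best_b = state.b.copy()
                since_record = 0
            else:
                since_record += 1
    best = BlockState(graph, _relabel_dense(best_b))
    return best


def _relabel_dense(b: np.ndarray) -> np.ndarray:
    _, inv = np.unique(b, return_inverse=True)
    return inv


# ---------------------------------------------------------------------------
# layer randomisation and model comparison
# ---------------------------------------------------------------------------

def _cast_count_to_real(c: np.ndarray, cmin: float, cmax: float) -> np.ndarray:
    if cmax - cmin < 1e-300:
        return np.full(np.shape(c), 0.5)
    return (np.asarray(c, float) - cmin) / (cmax - cmin)


def _cast_real_to_count(w: np.ndarray, cmin: float, cmax: float) -> np.ndarray:
    return np.round(np.asarray(w, float) * (cmax - cmin) + cmin).astype(np.int64)


def randomize_layers(graph: LayeredGraph, seed: int = 0) -> LayeredGraph:
    """Null construction: per edge, with probability 1/2, swap which layer
    each of its two weight values occupies.

    Because the layers have different supports, swapped-in values are cast
    rank-preservingly: counts are min-max mapped into [0, 1], reals are
    mapped back into the original count range and rounded. The raw values
    and the accumulated swap mask are retained, so applying the operation
    twice with the same seed restores the original graph exactly.
    """
    if graph.count_C is None:
        raise SBMError("layer randomisation requires both layers")
    rng = np.random.default_rng(seed)
    flip = rng.random(graph.n_edges) < 0.5
    raw_a = graph.raw_A if graph.raw_A is not None else graph.weight_A
    raw_c = graph.raw_C if graph.raw_C is not None else graph.count_C
    mask = flip if graph.swap_mask is None else (flip ^ graph.swap_mask)
    cmin, cmax = float(raw_c.min()), float(raw_c.max())
    eff_a = np.where(mask, _cast_count_to_real(raw_c, cmin, cmax), raw_a)
    eff_c = np.where(mask, _cast_real_to_count(raw_a, cmin, cmax), raw_c)
    return LayeredGraph(graph.n_nodes, graph.edges, eff_a, eff_c,
                        cat_E=graph.cat_E, raw_A=raw_a, raw_C=raw_c,
                        swap_mask=mask)


@dataclass(frozen=True)
class ModelComparison:
    """Layered vs layer-randomised description lengths (nats)."""

    sigma_layered: float
    sigma_null: float

    @property
    def delta(self) -> float:
        return self.sigma_null - self.sigma_layered

    @property
    def log10_posterior_odds(self) -> float:
        return self.delta / math.log(10.0)


def fit_and_compare(graph: LayeredGraph, seed: int = 0,
                    **anneal_kwargs) -> tuple[BlockState, BlockState, ModelComparison]:
    """Fit the layered graph and its layer-randomised null with an identical
    protocol and compare description lengths."""
    ss = np.random.SeedSequence(seed).generate_state(3)
    layered = anneal(graph, seed=int(ss[0]) % (2 ** 31), **anneal_kwargs)
    null_graph = randomize_layers(graph, seed=int(ss[1]) % (2 ** 31))
    null = anneal(null_graph, seed=int(ss[2]) % (2 ** 31), **anneal_kwargs)
    cmp = ModelComparison(sigma_layered=layered.sigma, sigma_null=null.sigma)
    if not (math.isfinite(cmp.sigma_layered) and math.isfinite(cmp.sigma_null)):
        raise SBMError("non-finite description length in model comparison")
    return layered, null, cmp


# ---------------------------------------------------------------------------
# back-projection
# ---------------------------------------------------------------------------

def _layer_values(graph: LayeredGraph, layer: str) -> np.ndarray:
    if layer == "A":
        return graph.weight_A
    if layer == "C":
        if graph.count_C is None:
            raise SBMError("graph has no count layer")
        return graph.count_C.astype(float)
    raise SBMError(f"unknown layer {layer!r}")


def _node_values(graph: LayeredGraph, b: np.ndarray, vals: np.ndarray,
                 aggregation: str) -> np.ndarray:
    n = graph.n_nodes
    e = graph.edges
    if aggregation == "node_mean_incident":
        tot = np.zeros(n)
        cnt = np.zeros(n)
        np.add.at(tot, e[:, 0], vals)
        np.add.at(tot, e[:, 1], vals)
        np.add.at(cnt, e[:, 0], 1)
        np.add.at(cnt, e[:, 1], 1)
        out = np.zeros(n)
        nz = cnt > 0
        out[nz] = tot[nz] / cnt[nz]
        return out
    if aggregation == "block_mean":
        internal = b[e[:, 0]] == b[e[:, 1]]
        labels = np.unique(b)
        out = np.zeros(n)
        for r in labels:
            sel = internal & (b[e[:, 0]] == r)
            out[b == r] = vals[sel].mean() if sel.any() else 0.0
        return out
    raise SBMError(f"unknown aggregation {aggregation!r}")


def backproject(state: BlockState, nodes: NodeTable, layer: str = "A",
                aggregation: str = "node_mean_incident",
                bootstrap: int = 0, seed: int = 0):
    """Project community edge weights back onto the brain grid.

    Each node's voxel receives either the mean weight of its incident edges
    or its block's mean internal edge weight; other voxels are 0. With
    ``bootstrap`` > 0, edges are resampled with replacement and 2.5/97.5
    percentile maps are returned alongside the mean map.
    """
    graph = state.g
    if len(nodes) != graph.n_nodes:
        raise SBMError("node table does not match graph order")
    vals = _layer_values(graph, layer)
    grid = nodes.grid

    def to_map(node_vals: np.ndarray) -> SubstrateMap:
        data = np.zeros(grid.shape)
        data[tuple(nodes.voxel_indices.T)] = node_vals
        return SubstrateMap(data, grid, kind="inferred")

    mean_map = to_map(_node_values(graph, state.b, vals, aggregation))
    if bootstrap <= 0:
        return mean_map
    rng = np.random.default_rng(seed)
    boots = np.empty((bootstrap, graph.n_nodes))
    for i in range(bootstrap):
        idx = rng.integers(0, graph.n_edges, size=graph.n_edges)
        sub = LayeredGraph(graph.n_nodes, graph.edges[idx], graph.weight_A[idx],
                           None if graph.count_C is None else graph.count_C[idx])
        # resampled edge list may break i<j after indexing identical rows; it
        # does not (rows are reused verbatim), so construction is safe
        boots[i] = _node_values(sub, state.b, _layer_values(sub, layer), aggregation)
    lo = to_map(np.percentile(boots, 2.5, axis=0))
    hi = to_map(np.percentile(boots, 97.5, axis=0))
    return mean_map, lo, hi
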