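"""Network-based statistics on per-patient lesion edge vectors.

Per edge, damage (both endpoint voxels lesioned) is regressed on the deficit
score with nuisance covariates; edges whose t-statistic for the score
coefficient crosses a primary threshold are grouped into connected
components, and the size (edge count) of each component is referred to a
permutation null of the maximum component size, giving component-wise
family-wise error control.

Permutation follows the Freedman-Lane scheme: residuals of the nuisance-only
model of each edge outcome are permuted with a single shared patient
permutation per iteration (preserving inter-edge dependence), added back to
the nuisance fit, and the full model refitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .cohort import PatientRecord

_T_CAP = 1e12  # stand-in for an infinite t on perfectly fitted edges


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class GLMSpec:
    """Edge-wise GLM and permutation settings."""

    predictor: str = "score"
    nuisance: tuple[str, ...] = ("age", "nart")
    t_threshold: float = 3.1
    n_permutations: int = 1000
    alpha: float = 0.05
    #: 'negative' keeps t <= -threshold (damage associated with lower score),
    #: 'positive' keeps t >= threshold, 'two_sided' keeps |t| >= threshold
    sign: str = "negative"
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 100:
            raise DesignError("n_permutations must be >= 100")
        if not (0.0 < self.alpha < 1.0):
            raise DesignError("alpha must be in (0, 1)")
        if self.t_threshold <= 0:
            raise DesignError("t_threshold must be > 0")
        if self.sign not in ("negative", "positive", "two_sided"):
            raise DesignError(f"unknown sign {self.sign!r}")


@dataclass
class NBSResult:
    """Edge statistics, suprathreshold components and their FWER p-values."""

    t_stat: np.ndarray               # (E,)
    edges: np.ndarray                # (E, 2) node pairs
    supra_edges: np.ndarray          # indices into edges
    component_label: np.ndarray      # per supra edge, contiguous 0..K-1
    component_sizes: np.ndarray      # (K,) edge counts
    component_pfwer: np.ndarray      # (K,)
    null_max_sizes: np.ndarray       # (P,)
    spec: GLMSpec

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    def significant_components(self, alpha: Optional[float] = None) -> np.ndarray:
        a = self.spec.alpha if alpha is None else alpha
        return np.where(self.component_pfwer <= a)[0]

    def significant_nodes(self, alpha: Optional[float] = None) -> np.ndarray:
        """Node ids incident to any edge of a significant component."""
        sig = self.significant_components(alpha)
        if len(sig) == 0:
            return np.empty(0, dtype=np.int64)
        keep = np.isin(self.component_label, sig)
        return np.unique(self.edges[self.supra_edges[keep]])

    def significant_edges(self, alpha: Optional[float] = None) -> np.ndarray:
        sig = self.significant_components(alpha)
        if len(sig) == 0:
            return np.empty(0, dtype=np.int64)
        return self.supra_edges[np.isin(self.component_label, sig)]


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def design_columns(records: Sequence[PatientRecord], names: Sequence[str],
                   extra: Optional[dict] = None) -> np.ndarray:
    cols = []
    for name in names:
        if extra and name in extra:
            cols.append(np.asarray(extra[name], dtype=float))
        else:
            cols.append(np.array([getattr(r, name) for r in records], dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(records), 0))


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # find a minimal offending column by dropping one at a time
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise DesignError(f"design is rank-deficient; column {names[j]!r} "
                                  "is collinear with the others")
        raise DesignError("design is rank-deficient")


def _residual_projector(Z: np.ndarray) -> np.ndarray:
    """M = I - Z (Z'Z)^-1 Z' (annihilator of the nuisance space)."""
    n = Z.shape[0]
    return np.eye(n) - Z @ np.linalg.pinv(Z)


def _t_from_residualized(xt: np.ndarray, Yt: np.ndarray, df: int) -> np.ndarray:
    """t-statistics of the predictor coefficient from residualised predictor
    xt (n,) and residualised outcomes Yt (n, E), via Frisch-Waugh-Lovell."""
    xx = float(xt @ xt)
    num = xt @ Yt                       # (E,)
    yy = np.einsum("ij,ij->j", Yt, Yt)  # (E,)
    beta = num / xx
    rss = yy - num * num / xx
    rss = np.maximum(rss, 0.0)
    zero_var = yy <= 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / xx)
        t = beta / se
    t = np.where(zero_var, 0.0, t)
    t = np.nan_to_num(t, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP)
    return np.clip(t, -_T_CAP, _T_CAP)


def edge_glm(edge_matrix: np.ndarray, records: Sequence[PatientRecord],
             spec: GLMSpec) -> np.ndarray:
    """Per-edge t of the predictor coefficient: OLS of edge damage on
    [intercept, predictor, nuisance]. Zero-damage-variance edges get t = 0."""
    Y = np.asarray(edge_matrix, dtype=float)
    n = Y.shape[0]
    p = 2 + len(spec.nuisance)
    if n < p + 2:
        raise DesignError(f"need at least {p + 2} patients, got {n}")
    x = design_columns(records, [spec.predictor])[:, 0]
    if np.ptp(x) == 0:
        raise DesignError(f"predictor {spec.predictor!r} has zero variance")
    Z = np.column_stack([np.ones(n), design_columns(records, spec.nuisance)])
    _check_design(np.column_stack([Z, x]),
                  ["intercept", *spec.nuisance, spec.predictor])
    M = _residual_projector(Z)
    return _t_from_residualized(M @ x, M @ Y, n - p)


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def _apply_sign(t: np.ndarray, threshold: float, sign: str) -> np.ndarray:
    if sign == "negative":
        return t <= -threshold
    if sign == "positive":
        return t >= threshold
    return np.abs(t) >= threshold


def suprathreshold_components(t_stat: np.ndarray, edges: np.ndarray,
                              t_threshold: float, sign: str = "negative"
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group suprathreshold edges into node-sharing connected components.

    Returns (supra edge indices, per-edge component labels, component edge
    counts). Components are labelled 0..K-1 by their smallest member node, so
    labelling is deterministic.
    """
    if sign not in ("negative", "positive", "two_sided"):
        raise DesignError(f"unknown sign {sign!r}")
    supra = np.where(_apply_sign(np.asarray(t_stat), t_threshold, sign))[0]
    if len(supra) == 0:
        return supra, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    sub = edges[supra]
    nodes, inv = np.unique(sub, return_inverse=True)
    inv = inv.reshape(sub.shape)
    n = len(nodes)
    adj = coo_matrix((np.ones(len(sub)), (inv[:, 0], inv[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    # deterministic relabelling by smallest member node id
    min_node = {}
    for local, lab in enumerate(labels):
        min_node[lab] = min(min_node.get(lab, np.inf), nodes[local])
    order = sorted(min_node, key=lambda lab: min_node[lab])
    remap = {lab: k for k, lab in enumerate(order)}
    edge_labels = np.array([remap[labels[i]] for i in inv[:, 0]], dtype=np.int64)
    sizes = np.bincount(edge_labels, minlength=len(order)).astype(np.int64)
    return supra, edge_labels, sizes


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def nbs_inference(edge_matrix: np.ndarray, records: Sequence[PatientRecord],
                  spec: GLMSpec, edges: Optional[np.ndarray] = None) -> NBSResult:
    """Freedman-Lane permutation test of suprathreshold component size.

    A single patient permutation per iteration is shared across all edges;
    the component p-value is (1 + #{perm max size >= observed}) / (P + 1),
    so the observed statistic is a member of its own null and p is never 0.
    """
    Y = np.asarray(edge_matrix, dtype=float)
    n, n_edges = Y.shape
    if edges is None:
        raise DesignError("edge endpoint pairs are required for components")
    edges = np.asarray(edges, dtype=np.int64)
    if len(edges) != n_edges:
        raise DesignError("edge pair list does not match edge matrix")

    t_obs = edge_glm(Y, records, spec)
    supra, labels, sizes = suprathreshold_components(
        t_obs, edges, spec.t_threshold, spec.sign)

    x = design_columns(records, [spec.predictor])[:, 0]
    Z = np.column_stack([np.ones(n), design_columns(records, spec.nuisance)])
    M = _residual_projector(Z)
    xt = M @ x
    R = M @ Y                      # nuisance-model residuals of every edge
    df = n - (2 + len(spec.nuisance))

    rng = np.random.default_rng(spec.seed)
    P = spec.n_permutations
    null_max = np.zeros(P, dtype=np.int64)
    for it in range(P):
        perm = rng.permutation(n)
        # Y* = Z fit + permuted residuals; after re-residualising only the
        # permuted-residual part survives (M annihilates the nuisance fit)
        Yt = M @ R[perm]
        t_perm = _t_from_residualized(xt, Yt, df)
        _, _, perm_sizes = suprathreshold_components(
            t_perm, edges, spec.t_threshold, spec.sign)
        null_max[it] = perm_sizes.max() if len(perm_sizes) else 0

    if len(sizes):
        exceed = (null_max[None, :] >= sizes[:, None]).sum(axis=1)
        pfwer = (1.0 + exceed) / (P + 1.0)
    else:
        pfwer = np.empty(0)
    return NBSResult(t_stat=t_obs, edges=edges, supra_edges=supra,
                     component_label=labels, component_sizes=sizes,
                     component_pfwer=pfwer, null_max_sizes=null_max, spec=spec)


# ---------------------------------------------------------------------------
# community summary and patient-level features
# ---------------------------------------------------------------------------

def summarize_network_communities(result: NBSResult, seed: int = 0,
                                  alpha: Optional[float] = None,
                                  **anneal_kwargs) -> dict:
    """Partition the significant network with the single-layer Gaussian-weight
    block model, |t| (min-max rescaled) as edge weights.

    Returns {'nodes': node ids, 'blocks': per-node block labels,
    'sigma': description length}.
    """
    from .sbm import LayeredGraph, anneal  # local import to avoid cycle

    sig_edges = result.significant_edges(alpha)
    if len(sig_edges) == 0:
        raise DesignError("no significant network to summarise")
    pairs = result.edges[sig_edges]
    tvals = np.abs(result.t_stat[sig_edges])
    lo, hi = tvals.min(), tvals.max()
    w = np.full_like(tvals, 0.5) if hi - lo < 1e-12 else (tvals - lo) / (hi - lo)
    nodes, inv = np.unique(pairs, return_inverse=True)
    local = inv.reshape(pairs.shape)
    lo_, hi_ = np.minimum(local[:, 0], local[:, 1]), np.maximum(local[:, 0], local[:, 1])
    graph = LayeredGraph(len(nodes), np.column_stack([lo_, hi_]), w)
    state = anneal(graph, seed=seed, **anneal_kwargs)
    return {"nodes": nodes, "blocks": state.b.copy(), "sigma": state.sigma}


def extract_network_features(patient_nodes: np.ndarray, result: NBSResult,
                             alpha: Optional[float] = None) -> tuple[int, int]:
    """(overlap indicator, shared node count) between a patient's lesioned
    nodes and the significant network."""
    net = set(result.significant_nodes(alpha).tolist())
    shared = sum(1 for v in np.asarray(patient_nodes).ravel() if int(v) in net)
    return (1 if shared > 0 else 0), shared
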