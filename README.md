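# ldgraph

Graph lesion-deficit mapping on synthetic cohorts: a layered, weighted
stochastic block model that separates deficit-driven from pathology-driven
network structure, alongside network-based-statistic (NBS) and
mass-univariate (VLSM) baselines.

## The problem

Lesion-deficit mapping infers which brain regions a behavioural deficit
causally depends on, from patients' binary lesion masks and their scores.
Its central confound is *lesion co-occurrence*: pathology anatomy (vascular
territories, tumour growth patterns) damages sets of voxels together, so a
region can correlate with a deficit merely because it is habitually injured
alongside the true substrate. Mass-univariate voxel statistics cannot tell
the two apart.

`ldgraph` treats the cohort as a weighted, undirected graph: voxels are
nodes, spatially adjacent voxels are edges, and every edge carries two
weights accumulated across patients —

* a **co-occurrence count** `c_e`: the number of patients in whom both
  endpoint voxels were lesioned (modelled as Poisson), and
* an **adjusted deficit weight** `w_e ∈ [0, 1]`: the mean, over those
  patients, of NART/score — premorbid ability over attained score, so larger
  means a worse deficit relative to expectation — min–max rescaled across
  edges (modelled as Gaussian).

A flat degree-corrected stochastic block model assigns nodes to blocks `b`
and scores the fit by a total description length (nats)

```
Sigma(b) = S_struct + S_part + S_A + S_C
S_struct = E − ½ Σ_rs e_rs ln(e_rs / e_r e_s)
S_part   = E·h(ζ) + N ln B,   ζ = B(B+1)/2E,  h(x) = (1+x)ln(1+x) − x ln x
S_A, S_C = − Σ_rs ln m(weights in block pair rs)
```

where the per-block-pair weight marginals `m(·)` are conjugate
(Normal–Inverse-Gamma for the deficit layer, Gamma–Poisson for the counts),
so move deltas are exact. Inference is single-node Metropolis moves with
simulated annealing (inverse temperature 1 → 10, plateau criterion on
record-breaking events). Confining each weight type to its own layer and
comparing `Sigma` against a fit in which the two values of every edge are
randomly shuffled across layers (`delta = Sigma_null − Sigma_layered`,
posterior odds `10^{delta/ln 10}`) tests whether deficit and co-occurrence
structure are genuinely distinct. Community weights are back-projected to
the brain as localisation maps.

Because no patient data are distributable, the package ships a first-class
synthetic cohort generator: territory-like brain subdivisions with
stroke branches grown inside them (and, in confound mode, mirrored across a
coupled territory pair — one vascular trunk supplying two disjoint
regions), blob-like tumours, planted substrate clusters, and deficit scores
generated from lesion∩substrate overlap plus covariate effects and Gaussian
noise.

## Worked example

```python
import numpy as np
from ldgraph import (CohortConfig, SubstrateSpec, DeficitParams, make_grid,
                     sample_lesion_cohort, make_ground_truth,
                     simulate_cohort_deficits, enumerate_nodes,
                     spatial_adjacency_edges, assemble_group_graph,
                     filter_graph, fit_and_compare, backproject, dice)
from ldgraph.sbm import LayeredGraph

grid = make_grid((14, 16, 14))
cfg = CohortConfig(n_patients=48, aetiology_mix=0.55, n_territories=4,
                   substrate_spec=SubstrateSpec(1, (3.0,), territory=0),
                   deficit_params=DeficitParams(sigma=2.0),
                   stroke_territory_pairing=True, seed=1)
masks, records = sample_lesion_cohort(cfg, grid)
gt = make_ground_truth(cfg, grid, seed=2)
records = simulate_cohort_deficits(masks, records, gt, cfg.deficit_params, 3)

nodes = enumerate_nodes(masks, grid, "lesioned_anywhere")
graph = filter_graph(assemble_group_graph(
    masks, records, nodes, spatial_adjacency_edges(nodes, 26)))
layered, null, cmp = fit_and_compare(
    LayeredGraph.from_lesion_graph(graph), seed=4, wait=15,
    max_sweeps_per_stage=80)
print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges")
print(f"delta = {cmp.delta:.1f} nats, log10 odds = {cmp.log10_posterior_odds:.1f}")
m = backproject(layered, graph.nodes, layer="A")
print(f"Dice vs planted substrate: "
      f"{dice(m, gt, ('top_k', int((gt.data > 0).sum()))):.2f}")
```

prints

```
graph: 345 nodes, 1222 edges
delta = 882.1 nats, log10 odds = 383.1
Dice vs planted substrate: 0.46
```

The positive `delta` says the layered model describes the cohort far more
economically than one in which deficit and co-occurrence values are shuffled
across layers — the two kinds of structure are distinguishable — and the
back-projected deficit layer localises the planted substrate despite every
stroke damaging a causally empty mirror territory alongside it.

A command-line interface mirrors the stages:
`ldgraph simulate | build-graph | nbs | sbm | vlsm | evaluate`
(each takes `--seed` and `--out`; see `ldgraph --help`).

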