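# Methods

## Model

The package localises the substrate of a behavioural deficit from a cohort
of binary lesion masks and per-patient scores, treating the cohort as a
weighted graph rather than a collection of independent voxels. Nodes are
retained voxels of a common template grid; edges join spatially adjacent
voxels (26-neighbourhood by default; 6 and 18 are available). Each edge
carries two weights: the co-occurrence count `c_e` (patients lesioning both
endpoints) and the adjusted deficit weight `w_e`, the mean over those
patients of NART/max(score, 0.5), min–max rescaled to [0, 1] across edges.
The floor of 0.5 on the score caps the weight of floor-scoring patients at
2×NART and guards the division; the mean (rather than a sum) keeps `w_e`
informative beyond what `c_e` already carries. The alternative algebraic
reading of the adjusted weight, 1/(score·NART), is selectable.

A flat, degree-corrected stochastic block model scores a partition `b` by a
description length in nats:

* structure: `E − ½ Σ_rs e_rs ln(e_rs/(e_r e_s))`, with the diagonal of the
  block-pair edge-count matrix counted twice (`Σ_rs e_rs = 2E`);
* partition complexity: `E·h(ζ) + N ln B`, `ζ = B(B+1)/2E`,
  `h(x) = (1+x)ln(1+x) − x ln x`;
* weight layers: per block pair, minus the log marginal likelihood of its
  weights under a conjugate model — Normal–Inverse-Gamma for the deficit
  layer (`μ0=0.5, κ0=1, a0=1, b0=0.1`, i.e. centred on the middle of the
  rescaled range, weakly informative) and Gamma–Poisson for the counts
  (`α0=β0=1`). An optional categorical layer (lesion aetiology) uses a
  Dirichlet-multinomial marginal with `α=1`; it is off by default, and when
  enabled its extra description length can be compared against the simpler
  model the same way as any other fit.

Conjugacy makes every single-node move delta exact and cheap; the test
suite audits incremental deltas against full recounts at 1e-8. The model is
deliberately *flat* (single-level): the scientific claims exercised here —
layer separation and community recovery — do not require a nested
hierarchy, and a flat partition keeps the search space exhaustively
checkable at small sizes.

## Inference

Fitting starts from greedy agglomeration (singleton blocks, batched
best-first merges while the description length falls) and continues with
single-node Metropolis sweeps under simulated annealing: 10 geometric
inverse-temperature steps from 1 to 10, each stage ending when no new
record-low description length has occurred for a `wait` of consecutive
sweeps (default 100; benchmarks use 15–50 as their problem-size choice,
with a per-stage sweep cap as a hard bound). Proposals move a node to a
uniformly chosen neighbour's block with probability 0.9, otherwise to a
uniform existing-or-fresh block. The best state ever observed is returned.
The sampler has no split move, so it can under-segment when the structure
term is uninformative and only weights carry signal; the planted-partition
benchmarks run in regimes where agglomeration stops appropriately.

Layer separation is tested by refitting after shuffling, per edge with
probability ½, which layer each of its two values occupies. Because the
layers have different supports, swapped-in counts are min–max cast to
[0, 1] and swapped-in reals are rounded back into the count range; raw
values and the accumulated swap mask are retained, making the operation an
exact involution. `delta = Sigma_null − Sigma_layered > 0` favours the
layered description; `log10` posterior odds are `delta/ln 10`. (For the
kind of data this models, published entropy differences on real cohorts are
in the 10^5-nat range; note that a printed odds exponent of ~3×10^5 is
consistent with `delta/ln 10` only up to a conversion that the source
material leaves unclear, so this package reports delta in nats and
`delta/ln 10` and nothing else.)

Localisation maps are back-projections: each node's voxel receives the mean
weight of its incident edges in a layer (`node_mean_incident`) or its
block's mean internal weight (`block_mean`); bootstrap over edges gives
2.5/97.5 percentile maps.

## Baselines

*NBS*: per-patient binary edge vectors on the complete pair set of retained
voxels; per edge, OLS of damage on [intercept, score, age, NART]; edges
with t beyond a primary threshold (default 3.1, one-sided negative — damage
associated with worse scores — configurable) form node-sharing connected
components whose sizes are referred to a Freedman–Lane permutation null of
the maximum component size (nuisance-model residuals of the edge outcomes,
one shared patient permutation per iteration). p = (1+x)/(P+1), so the
observed statistic is a member of its own null. The significant network can
be summarised by the single-layer Gaussian block model with |t| weights.

*VLSM/PLSM*: per voxel or cubic parcel (units below a minimum damaged-
patient count are excluded, default 10), OLS of score on [intercept,
damage, age, NART, lesion volume]; Freedman–Lane max-|t| permutation FWER.
The deficit score is the outcome here and damage the predictor, following
mass-univariate convention, whereas NBS models damage as the outcome;
the asymmetry mirrors the respective methods' standard usage. Both
permutation loops are vectorised linear algebra (via the
Frisch–Waugh–Lovell residualisation), which is what makes 200-replicate
calibration studies affordable; statsmodels OLS serves as the independent
oracle for the t-statistics in the tests.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
brain anatomy. The brain is an ellipsoid inscribed in the grid. Territories
are Voronoi cells of farthest-point-sampled seeds — compact, reproducible
stand-ins for vascular territories. Stroke lesions are unions of 1–3
contiguous randomly grown branches inside one territory, so same-territory
lesions overlap; in the two-territory confound mode, each stroke's
territory-0 branch is copied through a fixed nearest-neighbour map into
territory 1, modelling a single vascular trunk supplying two disjoint
regions and enforcing repeated co-occurrence of the same voxel pairs —
a coupling that lesion volume cannot explain away. Tumours are ellipsoidal
blobs with smoothed boundary noise placed anywhere in the brain. Substrates
are unions of 1–3 spherical clusters, optionally confined to one territory
(clipped to it) or straddling the 0–1 boundary. Deficits follow
`score = clamp(s_max − γ·s_max·|L∩GT|/|GT| − β_age(age−50) + ε, 0, s_max)`,
`ε ~ N(0, σ²)` — the simplest model linking overlap to deficit, with the
overlap fraction recorded per patient for audit. NART ~ N(100, 10²)
truncated positive and age ~ U(20, 80) only feed covariate adjustment.
Scores are left continuous rather than integer-valued.

Defaults are study conditions, chosen once: benchmark cohorts of 48
patients (55% stroke), 4 territories on a 14×16×14 grid, branches of
40–90 voxels, tumour semi-axes 2–3.5 voxels, γ=0.9, σ=2.0 (matching the
2–3-point within-group dispersion a 0–12 matrix-reasoning score shows in
patient cohorts), β_age=0.03. What the generator does *not* emulate —
registration error, partial-volume effects, realistic vascular atlases, MRI
intensities, non-linear deficit models — bounds what passing tests show:
they validate the inferential machinery under the stated assumptions, not
performance on real patient data.

## Benchmarks and their design choices

* **Description-length oracle**: on 50 random ≤8-node two-layer graphs,
  annealed Sigma is compared with the exhaustive minimum over all set
  partitions (Bell(8)=4140); it must never undercut and matches ≥95% of
  runs (the sampler is stochastic, perfection is not claimed).
* **Planted recovery**: 120 nodes, 3 equal blocks, edge probabilities
  0.25/0.05, distinct per-block-pair Gaussian means (sd 0.05), uninformative
  Poisson counts; ARI ≥ 0.9 expected in ≥18/20 seeds. Recovery degrades
  monotonically as the weight separation is annealed to zero.
* **Layer separation**: layers carrying *different* planted partitions
  (contiguous-thirds vs modulo-3) on a uniform random graph give
  reliably positive delta; two i.i.d. Poisson layers (one min–max cast)
  give deltas scattered about zero.
* **FWER calibration**: 200 simulated global-null cohorts (scores drawn
  independently of lesions), 500 permutations; the family-wise
  false-positive rate at α=0.05 must be compatible with the binomial 95%
  interval. The NBS null cohorts use deliberately large lesions so the
  coarse edge space is well covered — with sparse damage the max-component
  null is massively tied and the test is only conservative, which is
  validity of a degenerate kind, not evidence the machinery works. The NBS
  primary threshold in this audit is 1.7 for the same reason: a smoother
  size distribution resolves the tail.
* **Confound benchmark**: six domains (distinct substrate configurations,
  all confined to territory 0) under mirrored-stroke confounding. Both
  methods are thresholded at the planted substrate's volume (top-k with
  k=|GT|, identical for both, so the comparison is threshold-free);
  the VLSM map is ranked by signed −t because its permutation p-values are
  heavily tied and rank poorly. SBM-vs-VLSM Dice differences are summarised
  by an exact two-sided sign test. A separate sharper configuration
  (n=72, σ=1, γ=1) checks that VLSM marks causally empty territory-1 voxels
  FWER-significant in a majority of seeds — the mislocalisation the graph
  model is built to resist. The SBM's advantage under these conditions
  comes from spatial pooling across incident edges and from the dilution of
  mirrored-territory weights by the second pathology; with low-noise scores
  and abundant patients, voxel-wise regression catches up, as expected.

## Degenerate inputs and numerical choices

Empty block pairs contribute zero to weight terms (`0·ln 0 ≡ 0`
throughout). A constant weight vector min–max rescales to 0.5. Cancellation
in the Gaussian scatter is clamped at zero. Zero-damage-variance edges and
units get t = 0; perfectly fitted ones are capped at ±1e12 rather than
±inf. Degree quantile filtering keeps ties (≥). All stochastic operations
take explicit seeds; derived seeds come from `SeedSequence` spawning and
stay below 2³¹. Problem sizes in tests and the acceptance script are the
package's own desk-scale choices and are stated next to each benchmark.

## Known limitations

The sampler lacks split and merge-split moves, so weight-only structure on
uninformative graphs can be missed from a collapsed state. The flat model
cannot express nested communities. The adjusted deficit weight is
heavy-tailed by construction (premorbid/attained ratio); block- and
node-level averaging, the bootstrap maps, and the count-layer filter are
the mitigations. GraphML round-trips node/edge attributes only; per-patient
edge vectors are recomputed from masks rather than stored.
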