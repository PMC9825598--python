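"""Synthetic lesion cohorts with planted deficit substrates.

Generates the inputs a lesion-deficit study provides — per-patient binary
lesion masks in a common template space plus a behaviour table — with the
statistical structure the downstream graph analyses assume:

* *stroke* lesions are unions of contiguous branches grown inside one of a
  small library of fixed, territory-like brain subdivisions, so that the same
  voxel pairs are damaged together across patients (the lesion co-occurrence
  confound enforced in reality by the vascular tree);
* *tumour* lesions are ellipsoidal blobs with roughened boundaries placed
  anywhere in the brain, a pathology with different spatial statistics;
* the deficit score of each patient is generated from the overlap between
  their lesion and a planted substrate map, plus covariate effects and
  Gaussian noise, then clamped to the score range.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .grid import GeometryError, GridSpec


class ConfigurationError(ValueError):
    """Raised when a cohort configuration cannot be realised on the grid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeficitParams:
    """Parameters of the overlap-to-deficit model.

    score = clamp(s_max - gamma * s_max * overlap_fraction
                  - beta_age * (age - 50) + Normal(0, sigma^2), 0, s_max)
    """

    s_max: float = 12.0
    gamma: float = 0.8
    sigma: float = 1.5
    beta_age: float = 0.03

    def __post_init__(self):
        if self.s_max <= 0:
            raise ConfigurationError("s_max must be > 0")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass(frozen=True)
class SubstrateSpec:
    """Number, size and placement of planted substrate clusters."""

    n_clusters: int = 1
    radii: tuple[float, ...] = (3.0,)
    #: place every cluster inside this territory (index into the territory
    #: library); None = anywhere in the brain
    territory: Optional[int] = None
    #: force the first cluster to straddle a territory boundary, reproducing
    #: the co-occurrence confound in its sharpest form
    confound_mode: bool = False

    def __post_init__(self):
        if self.n_clusters < 1 or self.n_clusters > 3:
            raise ConfigurationError("n_clusters must be between 1 and 3")
        if len(self.radii) != self.n_clusters:
            raise ConfigurationError("one radius per cluster required")
        if any(r <= 0 for r in self.radii):
            raise ConfigurationError("cluster radii must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 64
    #: fraction of patients with stroke aetiology (the rest are tumours)
    aetiology_mix: float = 0.6
    n_territories: int = 4
    substrate_spec: SubstrateSpec = field(default_factory=SubstrateSpec)
    deficit_params: DeficitParams = field(default_factory=DeficitParams)
    #: when True every stroke damages territories 0 and 1 jointly — the
    #: two-territory confound condition
    stroke_territory_pairing: bool = False
    #: range of voxels per stroke branch
    branch_size: tuple[int, int] = (25, 60)
    #: range of tumour semi-axis lengths in voxels
    tumour_radius: tuple[float, float] = (1.5, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not (0.0 <= self.aetiology_mix <= 1.0):
            raise ConfigurationError("aetiology_mix must be in [0, 1]")
        if self.n_territories < 1:
            raise ConfigurationError("n_territories must be >= 1")


@dataclass(frozen=True)
class LesionMask:
    """Binary 3-D lesion mask for one patient on a shared grid."""

    patient_id: str
    data: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise GeometryError("mask data shape does not match grid")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("lesion mask must be binary")
        if data.sum() == 0:
            raise ValueError("lesion mask must contain at least one voxel")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def volume(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class PatientRecord:
    """Behavioural record: deficit score, premorbid index, age, aetiology."""

    patient_id: str
    score: float
    nart: float
    age: float
    aetiology: str
    #: |lesion ∩ substrate| / |substrate|, recorded for audit when the score
    #: was simulated; None for placeholder records
    overlap_fraction: Optional[float] = None

    def __post_init__(self):
        if self.nart <= 0:
            raise ValueError("nart must be > 0")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.aetiology not in ("stroke", "tumour"):
            raise ValueError(f"unknown aetiology {self.aetiology!r}")


@dataclass(frozen=True)
class SubstrateMap:
    """Voxel-wise scalar map: planted ground truth or inferred localisation."""

    data: np.ndarray
    grid: GridSpec
    kind: str = "ground_truth"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise GeometryError("map shape does not match grid")
        if not np.isfinite(data).all():
            raise ValueError("substrate map must be finite")
        if (data < 0).any():
            raise ValueError("substrate map must be non-negative")
        if self.kind not in ("ground_truth", "inferred"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        object.__setattr__(self, "data", data)


# ---------------------------------------------------------------------------
# territory library
# ---------------------------------------------------------------------------

def territory_labels(grid: GridSpec, n_territories: int, seed: int) -> np.ndarray:
    """Partition the in-brain voxels into territory-like regions.

    Seed points are picked by greedy farthest-point sampling over the brain
    voxels (first seed chosen at random) and each brain voxel is assigned to
    its nearest seed, giving compact Voronoi-style regions. Returns an int
    array with -1 outside the brain and territory ids 0..n-1 inside.
    """
    brain = grid.brain_mask()
    coords = np.argwhere(brain).astype(float)
    if len(coords) < 10 * n_territories:
        raise ConfigurationError(
            f"grid too small for {n_territories} territories ({len(coords)} brain voxels)"
        )
    rng = np.random.default_rng(seed)
    seeds = [coords[rng.integers(len(coords))]]
    d = np.linalg.norm(coords - seeds[0], axis=1)
    for _ in range(1, n_territories):
        seeds.append(coords[int(np.argmax(d))])
        d = np.minimum(d, np.linalg.norm(coords - seeds[-1], axis=1))
    seeds = np.asarray(seeds)
    dist = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    assign = np.argmin(dist, axis=1)
    labels = np.full(grid.shape, -1, dtype=np.int32)
    labels[tuple(coords.astype(int).T)] = assign
    return labels


def _grow_region(allowed: np.ndarray, start: tuple[int, int, int], size: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Grow a contiguous region of ~`size` voxels from `start` inside `allowed`.

    Randomised breadth-first growth over the 6-neighbourhood; contiguity is
    guaranteed, the exact size only if `allowed` is large enough.
    """
    shape = allowed.shape
    region = np.zeros(shape, dtype=bool)
    frontier = [start]
    region[start] = True
    count = 1
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while frontier and count < size:
        i = rng.integers(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        neigh = [(v[0] + o[0], v[1] + o[1], v[2] + o[2]) for o in offsets]
        rng.shuffle(neigh)
        for w in neigh:
            if count >= size:
                break
            if all(0 <= w[a] < shape[a] for a in range(3)) and allowed[w] and not region[w]:
                region[w] = True
                frontier.append(w)
                count += 1
    return region


def _stroke_lesion(territories: np.ndarray, territory_ids: Sequence[int],
                   branch_size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    lesion = np.zeros(territories.shape, dtype=bool)
    for tid in territory_ids:
        allowed = territories == tid
        voxels = np.argwhere(allowed)
        if len(voxels) == 0:
            raise ConfigurationError(f"territory {tid} is empty")
        start = tuple(voxels[rng.integers(len(voxels))])
        size = int(rng.integers(branch_size[0], branch_size[1] + 1))
        lesion |= _grow_region(allowed, start, size, rng)
    return lesion


def _mirror_map(territories: np.ndarray, src: int, dst: int) -> dict:
    """Fixed spatial correspondence from territory ``src`` voxels to their
    nearest counterparts in territory ``dst`` (after centroid alignment).

    Models a single vascular trunk supplying two disjoint regions: occlusion
    damages corresponding voxels in both, enforcing repeated co-occurrence of
    the same voxel pairs across patients.
    """
    from scipy.spatial import cKDTree

    a = np.argwhere(territories == src)
    b = np.argwhere(territories == dst)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("mirror territories must be non-empty")
    shift = b.mean(axis=0) - a.mean(axis=0)
    tree = cKDTree(b)
    _, idx = tree.query(a + shift)
    return {tuple(v): tuple(b[i]) for v, i in zip(a, idx)}


def _tumour_lesion(brain: np.ndarray, radius_range: tuple[float, float],
                   rng: np.random.Generator) -> np.ndarray:
    shape = brain.shape
    voxels = np.argwhere(brain)
    for _ in range(50):
        centre = voxels[rng.integers(len(voxels))].astype(float)
        radii = rng.uniform(radius_range[0], radius_range[1], size=3)
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
        # roughen the boundary with smoothed noise so tumours are blob-like,
        # not perfect ellipsoids
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.2)
        lesion = (d2 + 0.6 * noise <= 1.0) & brain
        if lesion.any():
            return lesion
    raise ConfigurationError("failed to place a non-empty tumour lesion")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_lesion_cohort(config: CohortConfig, grid: GridSpec
                         ) -> tuple[list[LesionMask], list[PatientRecord]]:
    """Sample lesion masks and covariate records for one cohort.

    Scores in the returned records are placeholders at ``s_max`` (no deficit);
    :func:`simulate_deficit` assigns real scores once a ground-truth substrate
    exists. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    brain = grid.brain_mask()
    territories = territory_labels(grid, config.n_territories, config.seed)
    mirror = None
    if config.stroke_territory_pairing:
        if config.n_territories < 2:
            raise ConfigurationError("territory pairing needs >= 2 territories")
        mirror = _mirror_map(territories, 0, 1)

    n_stroke = int(round(config.aetiology_mix * config.n_patients))
    aetiologies = ["stroke"] * n_stroke + ["tumour"] * (config.n_patients - n_stroke)

    masks: list[LesionMask] = []
    records: list[PatientRecord] = []
    for p, aet in enumerate(aetiologies):
        pid = f"sub-{p:04d}"
        if aet == "stroke":
            if config.stroke_territory_pairing:
                # one branch in territory 0, co-damaged mirror in territory 1
                data = _stroke_lesion(territories, [0], config.branch_size, rng)
                for v in np.argwhere(data):
                    data[mirror[tuple(v)]] = True
            else:
                t = int(rng.integers(config.n_territories))
                n_branches = int(rng.integers(1, 4))
                tids = [t] * n_branches
                data = _stroke_lesion(territories, tids, config.branch_size, rng)
        else:
            data = _tumour_lesion(brain, config.tumour_radius, rng)
        masks.append(LesionMask(pid, data.astype(np.uint8), grid))

        nart = 0.0
        while nart <= 0:
            nart = rng.normal(100.0, 10.0)
        age = rng.uniform(20.0, 80.0)
        records.append(PatientRecord(pid, score=config.deficit_params.s_max,
                                     nart=float(nart), age=float(age), aetiology=aet))
    return masks, records


def _sphere(shape, centre, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return d2 <= radius ** 2


def make_ground_truth(config: CohortConfig, grid: GridSpec, seed: int) -> SubstrateMap:
    """Plant a binary substrate: a union of 1-3 compact spherical clusters.

    Placement honours ``substrate_spec``: clusters can be confined to one
    territory, or (confound mode) the first cluster is centred on a voxel of
    the boundary between territories 0 and 1 so that it straddles regions with
    coupled damage.
    """
    spec = config.substrate_spec
    brain = grid.brain_mask()
    rng = np.random.default_rng(seed)
    territories = territory_labels(grid, config.n_territories, config.seed)

    if spec.territory is not None:
        allowed = territories == spec.territory
    else:
        allowed = brain
    if not allowed.any():
        raise ConfigurationError("no candidate voxels for substrate placement")
    candidates = np.argwhere(allowed)

    gt = np.zeros(grid.shape, dtype=bool)
    for k in range(spec.n_clusters):
        if k == 0 and spec.confound_mode:
            # boundary voxels of territory 0 facing territory 1
            t0 = territories == 0
            dil = ndimage.binary_dilation(territories == 1)
            boundary = np.argwhere(t0 & dil)
            if len(boundary) == 0:
                raise ConfigurationError("territories 0 and 1 share no boundary")
            centre = boundary[rng.integers(len(boundary))].astype(float)
        else:
            centre = candidates[rng.integers(len(candidates))].astype(float)
        cluster = _sphere(grid.shape, centre, spec.radii[k]) & brain
        if spec.territory is not None and not spec.confound_mode:
            # confine the substrate strictly to the designated territory so
            # that coupled neighbouring territories carry no causal voxels
            cluster &= allowed
        gt |= cluster
    if not gt.any():
        raise ConfigurationError("planted substrate is empty")
    return SubstrateMap(gt.astype(float), grid, kind="ground_truth")


def overlap_fraction(mask: LesionMask, gt: SubstrateMap) -> float:
    """|lesion ∩ substrate| / |substrate| on binarised maps."""
    if mask.grid != gt.grid:
        raise GeometryError("mask and substrate are on different grids")
    gt_bin = gt.data > 0
    n_gt = int(gt_bin.sum())
    if n_gt == 0:
        raise ValueError("substrate map is empty")
    return float((mask.data.astype(bool) & gt_bin).sum()) / n_gt


def simulate_deficit(mask: LesionMask, gt: SubstrateMap, record: PatientRecord,
                     params: DeficitParams, seed: int) -> PatientRecord:
    """Generate a deficit score from lesion-substrate overlap.

    score = clamp(s_max - gamma*s_max*overlap - beta_age*(age-50) + eps,
    0, s_max) with eps ~ Normal(0, sigma^2). The overlap fraction is stored on
    the returned record for audit.
    """
    frac = overlap_fraction(mask, gt)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
    raw = (params.s_max - params.gamma * params.s_max * frac
           - params.beta_age * (record.age - 50.0) + eps)
    score = float(np.clip(raw, 0.0, params.s_max))
    return replace(record, score=score, overlap_fraction=frac)


def simulate_cohort_deficits(masks: Sequence[LesionMask], records: Sequence[PatientRecord],
                             gt: SubstrateMap, params: DeficitParams, seed: int
                             ) -> list[PatientRecord]:
    """Apply :func:`simulate_deficit` across a cohort with per-patient subseeds."""
    seeds = np.random.SeedSequence(seed).generate_state(len(masks))
    return [simulate_deficit(m, gt, r, params, int(s) % (2 ** 31))
            for m, r, s in zip(masks, records, seeds)]
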