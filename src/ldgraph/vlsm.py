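"""Mass-univariate lesion-symptom mapping baseline (VLSM/PLSM).

Per spatial unit (voxel or cubic parcel), the deficit score is regressed on
unit damage with nuisance covariates (age, premorbid index, total lesion
volume); the damage t-statistic is referred to a Freedman-Lane permutation
null of the maximum |t| across units, giving family-wise error corrected
p-values. Units damaged in fewer than a minimum number of patients are
excluded before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import LesionMask, PatientRecord, SubstrateMap
from .grid import GridSpec
from .nbs import (DesignError, GLMSpec, _check_design, _residual_projector,
                  design_columns)


@dataclass
class UnitMatrix:
    """Patients x units binary damage matrix plus the unit -> voxel registry."""

    damage: np.ndarray              # (n_patients, n_units) uint8
    unit_voxels: list[np.ndarray]   # per unit, (k, 3) voxel indices
    grid: GridSpec
    min_patients: int
    excluded_units: int = 0

    @property
    def n_units(self) -> int:
        return self.damage.shape[1]


@dataclass
class VLSMResult:
    """Per-unit t and FWER p from the max-|t| permutation null."""

    t_stat: np.ndarray
    pfwer: np.ndarray
    null_max_abs_t: np.ndarray
    alpha: float
    n_permutations: int

    def significant_units(self, alpha: Optional[float] = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        return np.where(self.pfwer <= a)[0]


def build_unit_matrix(masks: Sequence[LesionMask], unit_scheme: str = "voxel",
                      min_patients: int = 10, parcel_size: int = 2) -> UnitMatrix:
    """Build the damage matrix.

    ``unit_scheme='voxel'`` uses single in-brain voxels;
    ``'cube_parcels'`` tiles the grid with ``parcel_size``-voxel cubes. A unit
    is damaged for a patient iff it contains >= 1 lesioned voxel; units
    damaged in fewer than ``min_patients`` patients are dropped.
    """
    grid = masks[0].grid
    brain = grid.brain_mask()
    if unit_scheme == "voxel":
        voxels = np.argwhere(brain)
        unit_voxels = [voxels[i:i + 1] for i in range(len(voxels))]
        flat = np.ravel_multi_index(tuple(voxels.T), grid.shape)
        dmg = np.stack([m.data.ravel()[flat] for m in masks]).astype(np.uint8)
    elif unit_scheme == "cube_parcels":
        k = parcel_size
        unit_voxels = []
        cols = []
        for i0 in range(0, grid.shape[0], k):
            for j0 in range(0, grid.shape[1], k):
                for k0 in range(0, grid.shape[2], k):
                    block_idx = np.array([(i, j, kk)
                                          for i in range(i0, min(i0 + k, grid.shape[0]))
                                          for j in range(j0, min(j0 + k, grid.shape[1]))
                                          for kk in range(k0, min(k0 + k, grid.shape[2]))])
                    inb = brain[tuple(block_idx.T)]
                    if not inb.any():
                        continue
                    block_idx = block_idx[inb]
                    unit_voxels.append(block_idx)
                    flat = np.ravel_multi_index(tuple(block_idx.T), grid.shape)
                    cols.append(np.array([m.data.ravel()[flat].any() for m in masks],
                                         dtype=np.uint8))
        dmg = np.column_stack(cols) if cols else np.empty((len(masks), 0), dtype=np.uint8)
    else:
        raise DesignError(f"unknown unit scheme {unit_scheme!r}")

    counts = dmg.sum(axis=0)
    keep = counts >= min_patients
    if not keep.any():
        raise DesignError("every unit fell below the minimum patient count")
    return UnitMatrix(damage=dmg[:, keep],
                      unit_voxels=[uv for uv, k_ in zip(unit_voxels, keep) if k_],
                      grid=grid, min_patients=min_patients,
                      excluded_units=int((~keep).sum()))


def vlsm_inference(unit_matrix: UnitMatrix, records: Sequence[PatientRecord],
                   spec: GLMSpec, lesion_volume: Optional[np.ndarray] = None
                   ) -> VLSMResult:
    """OLS of score on [intercept, damage, nuisance (+ lesion volume)] per
    unit; Freedman-Lane max-|t| permutation FWER.

    Here the deficit score is the outcome and damage the tested predictor
    (mass-univariate convention); total lesion volume is added as a nuisance
    covariate when supplied.
    """
    D = unit_matrix.damage.astype(float)
    n, n_units = D.shape
    if len(records) != n:
        raise DesignError("one record per patient required")
    y = design_columns(records, [spec.predictor])[:, 0]
    nuis = design_columns(records, spec.nuisance)
    names = ["intercept", *spec.nuisance]
    if lesion_volume is not None:
        nuis = np.column_stack([nuis, np.asarray(lesion_volume, dtype=float)])
        names.append("lesion_volume")
    Z = np.column_stack([np.ones(n), nuis])
    _check_design(Z, names)
    p = Z.shape[1] + 1
    if n < p + 2:
        raise DesignError(f"need at least {p + 2} patients, got {n}")
    df = n - p

    M = _residual_projector(Z)
    Dt = M @ D                      # residualised damage, fixed across perms
    dd = np.einsum("ij,ij->j", Dt, Dt)
    zero = dd <= 1e-30

    def unit_ts(yt: np.ndarray) -> np.ndarray:
        num = Dt.T @ yt
        yy = float(yt @ yt)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = num / dd
            rss = np.maximum(yy - num * num / dd, 0.0)
            t = beta / np.sqrt(rss / df / dd)
        return np.where(zero, 0.0, np.nan_to_num(t, posinf=1e12, neginf=-1e12))

    yt_obs = M @ y
    t_obs = unit_ts(yt_obs)

    # Freedman-Lane: permute nuisance-model residuals of the score
    resid = yt_obs                  # = y - Z fit
    rng = np.random.default_rng(spec.seed)
    P = spec.n_permutations
    null_max = np.zeros(P)
    for it in range(P):
        perm = rng.permutation(n)
        yt = M @ resid[perm]
        null_max[it] = np.abs(unit_ts(yt)).max()

    exceed = (null_max[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)
    pfwer = (1.0 + exceed) / (P + 1.0)
    return VLSMResult(t_stat=t_obs, pfwer=pfwer, null_max_abs_t=null_max,
                      alpha=spec.alpha, n_permutations=P)


def vlsm_map(result: VLSMResult, unit_matrix: UnitMatrix
             ) -> tuple[SubstrateMap, np.ndarray]:
    """Voxel map of -ln p per unit, plus the binary significance mask at
    alpha. Voxels of excluded units stay 0."""
    data = np.zeros(unit_matrix.grid.shape)
    sigmask = np.zeros(unit_matrix.grid.shape, dtype=bool)
    for u, voxels in enumerate(unit_matrix.unit_voxels):
        idx = tuple(voxels.T)
        data[idx] = -np.log(result.pfwer[u])
        if result.pfwer[u] <= result.alpha:
            sigmask[idx] = True
    return SubstrateMap(data, unit_matrix.grid, kind="inferred"), sigmask
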