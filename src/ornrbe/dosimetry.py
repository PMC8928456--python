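"""Cumulative dose-volume and dose-LET-volume histograms and DVH indices.

Indices (VxGy, D0.01cc, Dmean) are computed exactly from sorted voxels, not
from a binned curve; the histogram grids are for presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DoseLETSampleSet

__all__ = [
    "DVHCurve",
    "DVHIndexSet",
    "DLVHSurface",
    "DlvhContour",
    "compute_dvh",
    "dvh_indices",
    "compute_dlvh",
    "dlvh_contour",
    "index_table",
    "INDEX_NAMES",
]

INDEX_NAMES = ("v40", "v50", "v60", "v70", "v75", "d001cc", "dmean")

#: dose levels (Gy[RBE]) of the volume indices, in table order
VOLUME_INDEX_LEVELS = {"v40": 40.0, "v50": 50.0, "v60": 60.0, "v70": 70.0, "v75": 75.0}


@dataclass(frozen=True)
class DVHCurve:
    dose_grid: np.ndarray  # ascending Gy[RBE]
    cumulative_volume: np.ndarray  # cc with dose >= grid value
    total_volume: float


@dataclass(frozen=True)
class DVHIndexSet:
    v40: float
    v50: float
    v60: float
    v70: float
    v75: float
    d001cc: Optional[float]  # None when total volume < 0.01 cc
    dmean: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INDEX_NAMES}


@dataclass(frozen=True)
class DLVHSurface:
    dose_grid: np.ndarray
    let_grid: np.ndarray
    volume_fraction: np.ndarray  # shape (len(dose_grid), len(let_grid))
    total_volume: float


@dataclass(frozen=True)
class DlvhContour:
    percent: float
    points: list  # (dose, let) where the volume fraction crosses percent/100


def volume_at_dose(samples: DoseLETSampleSet, dose: float) -> float:
    """Absolute volume (cc) receiving at least ``dose`` Gy[RBE]."""
    return float(samples.volumes[samples.doses >= dose].sum())


def compute_dvh(samples: DoseLETSampleSet, dose_resolution: float = 1.0) -> DVHCurve:
    """Cumulative DVH on a regular grid of spacing ``dose_resolution``."""
    if dose_resolution <= 0:
        raise ValueError("dose_resolution must be > 0")
    max_dose = float(samples.doses.max())
    n_bins = int(np.ceil(max_dose / dose_resolution)) + 1
    grid = np.arange(n_bins + 1) * dose_resolution
    order = np.argsort(samples.doses)
    sorted_doses = samples.doses[order]
    cum_below = np.concatenate([[0.0], np.cumsum(samples.volumes[order])])
    # volume with dose >= g: total minus volume of voxels with dose < g
    idx = np.searchsorted(sorted_doses, grid, side="left")
    cumulative = samples.total_volume - cum_below[idx]
    return DVHCurve(dose_grid=grid, cumulative_volume=cumulative, total_volume=samples.total_volume)


def dvh_indices(samples: DoseLETSampleSet) -> DVHIndexSet:
    """Exact DVH indices from the voxel set.

    D0.01cc is resolved at voxel granularity: voxels are sorted by
    descending dose and the dose of the voxel in which the accumulated
    volume first reaches 0.01 cc is reported (no sub-voxel interpolation).
    """
    vols = {
        name: volume_at_dose(samples, level)
        for name, level in VOLUME_INDEX_LEVELS.items()
    }
    dmean = float(np.average(samples.doses, weights=samples.volumes))
    if samples.total_volume < 0.01:
        d001 = None
    else:
        order = np.argsort(-samples.doses, kind="stable")
        cum = np.cumsum(samples.volumes[order])
        hit = int(np.searchsorted(cum, 0.01 - 1e-12, side="left"))
        d001 = float(samples.doses[order][hit])
    return DVHIndexSet(d001cc=d001, dmean=dmean, **vols)


def compute_dlvh(
    samples: DoseLETSampleSet,
    dose_grid: Sequence[float] | None = None,
    let_grid: Sequence[float] | None = None,
) -> DLVHSurface:
    """Joint cumulative histogram: fraction of volume with dose >= d AND LET >= l.

    Defaults: 1 Gy dose grid from 0 to max dose, 0.25 keV/um LET grid from
    0 to max LET. Photon sample sets (all-zero LET) are allowed; the
    surface then collapses to the DVH at l = 0.
    """
    if dose_grid is None:
        dose_grid = np.arange(0.0, float(samples.doses.max()) + 1.0, 1.0)
    if let_grid is None:
        top = float(samples.lets.max())
        let_grid = np.arange(0.0, top + 0.25, 0.25) if top > 0 else np.array([0.0])
    dose_grid = np.asarray(dose_grid, float)
    let_grid = np.asarray(let_grid, float)
    if np.any(np.diff(dose_grid) <= 0) or (let_grid.size > 1 and np.any(np.diff(let_grid) <= 0)):
        raise ValueError("grids must be strictly ascending")

    # 2-D cumulative count via a binned histogram + suffix sums
    d_idx = np.searchsorted(dose_grid, samples.doses, side="right") - 1
    l_idx = np.searchsorted(let_grid, samples.lets, side="right") - 1
    nd, nl = dose_grid.size, let_grid.size
    acc = np.zeros((nd + 1, nl + 1))
    valid = (d_idx >= 0) & (l_idx >= 0)
    np.add.at(acc, (d_idx[valid], l_idx[valid]), samples.volumes[valid])
    suffix = np.flip(np.cumsum(np.flip(np.cumsum(np.flip(acc, 0), axis=0), 1), axis=1), (0, 1))
    frac = np.clip(suffix[:nd, :nl] / samples.total_volume, 0.0, 1.0)
    return DLVHSurface(
        dose_grid=dose_grid,
        let_grid=let_grid,
        volume_fraction=frac,
        total_volume=samples.total_volume,
    )


def dlvh_volume_fraction(samples: DoseLETSampleSet, dose: float, let: float) -> float:
    """Exact voxel-level evaluation of the joint exceedance fraction."""
    mask = (samples.doses >= dose) & (samples.lets >= let)
    return float(samples.volumes[mask].sum()) / samples.total_volume


def dlvh_contour(surface: DLVHSurface, percent: float) -> DlvhContour:
    """Iso-volume contour DLx%: at each dose-grid value, the largest LET
    with volume fraction >= percent/100, linearly interpolated between LET
    grid points; doses where the level is not attained are omitted."""
    if not (0.0 < percent < 100.0):
        raise ValueError(f"percent must be in (0, 100), got {percent}")
    level = percent / 100.0
    points = []
    lg = surface.let_grid
    for i, d in enumerate(surface.dose_grid):
        col = surface.volume_fraction[i]
        if col[0] < level:
            continue  # level not attained in this dose column
        # col is non-increasing in LET; find last index with col >= level
        j = int(np.searchsorted(-col, -level, side="right")) - 1
        if j >= lg.size - 1 or col[j] == level:
            let_val = float(lg[min(j, lg.size - 1)])
        else:
            # interpolate between grid points j and j+1
            c0, c1 = col[j], col[j + 1]
            if c0 == c1:
                let_val = float(lg[j])
            else:
                t = (c0 - level) / (c0 - c1)
                let_val = float(lg[j] + t * (lg[j + 1] - lg[j]))
        points.append((float(d), let_val))
    return DlvhContour(percent=percent, points=points)


def index_table(
    records, samples: Sequence[DoseLETSampleSet]
) -> pd.DataFrame:
    """Per-patient DVH index table (patient_id, modality, orn, v40..v75,
    d001cc, dmean)."""
    by_id = {s.patient_id: s for s in samples}
    rows = []
    for r in records:
        idx = dvh_indices(by_id[r.patient_id])
        row = {"patient_id": r.patient_id, "modality": r.modality, "orn": int(r.orn)}
        row.update(idx.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
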