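"""Boltzmann-averaged excess chemical potential (WT) from fine-grid
water occupancy.

A 1 A cube centered on the reference position is divided into fine
cubic voxels of edge ``a`` (default 0.005 A, giving 200^3 = 8,000,000
voxels).  Each voxel's WT follows from its observed density,

    WT(dV) = -kT ln( c / (F * dV * rho_bulk) ),

with c the water count over F frames.  The site-level value is the
Boltzmann average over the densest ``top_fraction`` of the voxels
(default 1%, n = 80,000):

    WT(V) = -kT ln( (1/n) * sum_selected exp(-WT(dV)/kT) )
          = -kT ln( S / (n * F * dV * rho_bulk) ),

where S is the summed count in the selected voxels.  Zero-count voxels
inside the selection contribute nothing to S, which keeps WT finite
whenever the cube holds at least one observation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    ThermoParams,
    ValidationError,
    WaterTrajectory,
    WTResult,
)
from .sitefinder import PredictedSite

__all__ = [
    "FineGrid",
    "bin_fine_grid",
    "voxel_wt",
    "boltzmann_wt",
    "score_sites",
]

logger = logging.getLogger(__name__)


@dataclass
class FineGrid:
    """Sparse-friendly fine occupancy grid around one reference point.

    ``counts`` is stored flat (C order over ``dims``); voxels are
    half-open boxes of edge ``voxel_edge`` tiling the cube
    [reference - half_extent, reference + half_extent).
    """

    reference: np.ndarray
    half_extent: float
    voxel_edge: float
    dims: tuple[int, int, int]
    counts: np.ndarray
    n_frames: int

    @property
    def total_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def dV(self) -> float:
        """Voxel volume in A^3."""
        return self.voxel_edge**3


def bin_fine_grid(
    traj: WaterTrajectory,
    reference,
    half_extent: float = 0.5,
    voxel_edge: float = 0.005,
) -> FineGrid:
    """Bin all water-oxygen observations falling in the cube
    [reference - h, reference + h) into half-open fine voxels."""
    if half_extent <= 0 or voxel_edge <= 0:
        raise ValidationError("half_extent and voxel_edge must be > 0")
    reference = np.asarray(reference, dtype=np.float64)
    n_per_axis = int(round(2 * half_extent / voxel_edge))
    if n_per_axis < 1:
        raise ValidationError("voxel_edge larger than the cube")
    dims = (n_per_axis,) * 3
    points = traj.stacked()
    lo = reference - half_extent
    idx = np.floor((points - lo) / voxel_edge).astype(np.int64)
    mask = np.all((idx >= 0) & (idx < n_per_axis), axis=1)
    idx = idx[mask]
    total = n_per_axis**3
    if len(idx):
        flat = np.ravel_multi_index(tuple(idx.T), dims)
        counts = np.bincount(flat, minlength=total)
    else:
        counts = np.zeros(total, dtype=np.int64)
    return FineGrid(
        reference=reference,
        half_extent=float(half_extent),
        voxel_edge=float(voxel_edge),
        dims=dims,
        counts=counts,
        n_frames=traj.n_frames,
    )


def voxel_wt(
    count: int, n_frames: int, dV: float, thermo: ThermoParams
) -> float:
    """Per-voxel WT from a raw occupancy count; +inf for empty voxels
    (an empty voxel contributes 0 to any Boltzmann sum)."""
    if n_frames < 1 or dV <= 0:
        raise ValidationError("need n_frames >= 1 and dV > 0")
    if count == 0:
        return math.inf
    rho = count / (n_frames * dV)
    return -thermo.kT * math.log(rho / thermo.rho_bulk)


def boltzmann_wt(
    grid: FineGrid,
    thermo: ThermoParams,
    top_fraction: float = 0.01,
) -> WTResult:
    """Boltzmann-average WT over the densest *top_fraction* of voxels.

    Selection is by count; equal counts contribute identically, so any
    tie at the selection boundary leaves the result unchanged.  When
    fewer than n voxels are occupied, zero-count voxels pad the
    selection and contribute 0 to the sum (the denominator stays n,
    matching the fixed selected sub-volume).
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError("top_fraction must be in (0, 1]")
    total = grid.total_voxels
    n = int(round(top_fraction * total))
    if n < 1:
        raise ValidationError("selection is empty: top_fraction too small")
    counts = grid.counts
    nnz = int(np.count_nonzero(counts))
    if nnz == 0:
        raise ValidationError("all-zero fine grid: WT undefined")
    if nnz <= n:
        S = int(counts.sum())
    else:
        S = int(np.partition(counts, total - n)[total - n:].sum())
    denom = n * grid.n_frames * grid.dV * thermo.rho_bulk
    wt = -thermo.kT * math.log(S / denom)
    return WTResult(
        reference=grid.reference,
        wt=wt,
        n_selected_voxels=n,
        total_selected_count=S,
        density_ratio=math.exp(-wt / thermo.kT),
    )


def score_sites(
    traj: WaterTrajectory,
    sites: list[PredictedSite],
    thermo: ThermoParams,
    half_extent: float = 0.5,
    voxel_edge: float = 0.005,
    top_fraction: float = 0.01,
) -> list[PredictedSite]:
    """Score each site's cube center with :func:`boltzmann_wt` and
    return new sites sorted ascending by WT (most favorable first),
    with rank 1..N assigned.

    Sites whose fine cube holds no observation are dropped with a
    warning.
    """
    scored: list[PredictedSite] = []
    for site in sites:
        grid = bin_fine_grid(
            traj, site.cube_center,
            half_extent=half_extent, voxel_edge=voxel_edge,
        )
        if not np.any(grid.counts):
            logger.warning(
                "dropping site at %s: empty fine grid", site.cube_center
            )
            continue
        result = boltzmann_wt(grid, thermo, top_fraction=top_fraction)
        scored.append(
            replace(site, wt=result.wt, density_ratio=result.density_ratio)
        )
    scored.sort(key=lambda s: s.wt)  # stable: preserves input order on ties
    return [replace(s, rank=i) for i, s in enumerate(scored, start=1)]
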