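"""Candidate hydration sites from a coarse water-occupancy grid.

Water-oxygen observations within the first hydration shell of the
solute are binned on a 0.1 A voxel grid accumulated over all frames.  A
sliding 10x10x10 window (a 1 A cube) sums the occupancy, and windows
are picked greedily in descending count subject to mutual and
solute-distance exclusion, giving the 1 A regions that hold the most
water.  Each accepted cube contributes a predicted site: the cube
center is the reference position for WT scoring and the mean of the
member water positions is the predicted water position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import SoluteStructure, ValidationError, WaterTrajectory

__all__ = [
    "CoarseGrid",
    "PredictedSite",
    "accumulate_coarse_grid",
    "window_sums",
    "select_sites",
    "site_mean_position",
    "find_sites",
]


@dataclass
class CoarseGrid:
    """Integer occupancy counts on a regular voxel lattice.

    Voxels are half-open boxes [origin + i*a, origin + (i+1)*a) per
    axis; ``counts`` has shape ``dims`` and sums to the number of
    binned observations.
    """

    origin: np.ndarray
    voxel_edge: float
    counts: np.ndarray

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.counts.shape)


@dataclass
class PredictedSite:
    """A candidate hydration site from one accepted 1 A cube."""

    cube_center: np.ndarray
    window_count: int
    mean_position: np.ndarray | None = None
    wt: float | None = None
    density_ratio: float | None = None
    rank: int | None = None


def accumulate_coarse_grid(
    traj: WaterTrajectory,
    solute: SoluteStructure | None,
    shell: float = 3.25,
    voxel_edge: float = 0.1,
    padding: float | None = None,
) -> CoarseGrid:
    """Bin in-shell water-oxygen observations from every frame.

    Only waters whose minimum distance to any solute atom is <= *shell*
    are counted.  With ``solute=None`` (synthetic box setups) no shell
    filter is applied and the grid spans the water bounding box.
    The grid spans the solute bounding box extended by *padding*
    (default shell + 1 A), which must be >= shell so no in-shell water
    falls outside.
    """
    if voxel_edge <= 0:
        raise ValidationError("voxel_edge must be > 0")
    points = traj.stacked()
    if len(points) == 0:
        raise ValidationError("trajectory contains no water positions")
    if solute is not None:
        if len(solute) == 0:
            raise ValidationError("solute must be non-empty")
        if padding is None:
            padding = shell + 1.0
        dist, _ = cKDTree(solute.coords).query(points)
        points = points[dist <= shell]
        lo = solute.coords.min(axis=0) - padding
        hi = solute.coords.max(axis=0) + padding
    else:
        if padding is None:
            padding = 1.0
        lo = points.min(axis=0) - padding
        hi = points.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / voxel_edge).astype(int), 1)
    if len(points):
        idx = np.floor((points - lo) / voxel_edge).astype(int)
        if np.any(idx < 0) or np.any(idx >= dims):
            raise RuntimeError(
                "in-shell water outside the grid: padding too small"
            )
        flat = np.ravel_multi_index(tuple(idx.T), tuple(dims))
        counts = np.bincount(flat, minlength=int(np.prod(dims)))
    else:
        counts = np.zeros(int(np.prod(dims)), dtype=np.int64)
    return CoarseGrid(
        origin=lo, voxel_edge=float(voxel_edge),
        counts=counts.reshape(tuple(dims)).astype(np.int64),
    )


def window_sums(grid: CoarseGrid, window: int = 10) -> np.ndarray:
    """Exact integer sums over every window^3 block (stride 1).

    Output index (i, j, k) is the block whose lowest-index corner is
    voxel (i, j, k); computed with an integer summed-area table, so the
    result is bit-identical to direct summation.
    """
    c = grid.counts
    if any(window > d for d in c.shape):
        raise ValidationError(
            f"window {window} exceeds grid dims {c.shape}"
        )
    sat = np.zeros(tuple(d + 1 for d in c.shape), dtype=np.int64)
    sat[1:, 1:, 1:] = c
    sat = sat.cumsum(axis=0).cumsum(axis=1).cumsum(axis=2)
    w = window
    return (
        sat[w:, w:, w:]
        - sat[:-w, w:, w:] - sat[w:, :-w, w:] - sat[w:, w:, :-w]
        + sat[:-w, :-w, w:] + sat[:-w, w:, :-w] + sat[w:, :-w, :-w]
        - sat[:-w, :-w, :-w]
    )


def select_sites(
    field: np.ndarray,
    grid: CoarseGrid,
    solute: SoluteStructure | None = None,
    min_separation: float = 2.25,
    min_solute_dist: float = 2.25,
    max_sites: int | None = None,
) -> list[PredictedSite]:
    """Greedy non-maximum suppression over window sums.

    Windows are visited in descending count (ties by lexicographic
    lowest-corner index, so the result is platform-independent); a
    window is accepted iff its geometric center is >= *min_separation*
    from every accepted center and >= *min_solute_dist* from every
    solute atom.  Stops at *max_sites* or when counts reach zero.
    """
    window = grid.counts.shape[0] - field.shape[0] + 1
    flat = field.ravel()
    nz = np.flatnonzero(flat)
    if len(nz) == 0:
        return []
    # stable argsort on -count leaves equal counts in ascending flat
    # (= lexicographic corner) order
    order = nz[np.argsort(-flat[nz], kind="stable")]
    corners = np.column_stack(np.unravel_index(order, field.shape))
    centers = grid.origin + (corners + window / 2.0) * grid.voxel_edge
    counts = flat[order]

    if solute is not None and len(solute):
        # one batched query instead of a tree lookup per candidate
        sd, _ = cKDTree(solute.coords).query(centers)
        keep = sd >= min_solute_dist
        centers, counts = centers[keep], counts[keep]
    accepted: list[PredictedSite] = []
    accepted_centers: list[np.ndarray] = []
    for center, count in zip(centers, counts):
        if max_sites is not None and len(accepted) >= max_sites:
            break
        if accepted_centers:
            d = np.linalg.norm(np.asarray(accepted_centers) - center, axis=1)
            if np.any(d < min_separation):
                continue
        accepted.append(PredictedSite(cube_center=center, window_count=int(count)))
        accepted_centers.append(center)
    return accepted


def site_mean_position(
    traj: WaterTrajectory,
    site: PredictedSite,
    half_extent: float = 0.5,
) -> np.ndarray:
    """Mean of all water-oxygen positions (pooled over frames) inside
    the axis-aligned cube [center - h, center + h) of the site.

    The result is stored on the site and returned.
    """
    points = traj.stacked()
    lo = site.cube_center - half_extent
    hi = site.cube_center + half_extent
    mask = np.all((points >= lo) & (points < hi), axis=1)
    if not mask.any():
        raise ValidationError(
            "no waters inside the site cube; the site should not have "
            "been selected"
        )
    site.mean_position = points[mask].mean(axis=0)
    return site.mean_position


def find_sites(
    traj: WaterTrajectory,
    solute: SoluteStructure | None,
    shell: float = 3.25,
    voxel_edge: float = 0.1,
    window: int = 10,
    min_separation: float = 2.25,
    min_solute_dist: float = 2.25,
    max_sites: int | None = None,
) -> list[PredictedSite]:
    """Full site-finding pipeline: grid -> window sums -> greedy
    selection -> mean positions."""
    grid = accumulate_coarse_grid(
        traj, solute, shell=shell, voxel_edge=voxel_edge
    )
    field = window_sums(grid, window=window)
    sites = select_sites(
        field, grid, solute,
        min_separation=min_separation,
        min_solute_dist=min_solute_dist,
        max_sites=max_sites,
    )
    for s in sites:
        site_mean_position(traj, s, half_extent=window * voxel_edge / 2.0)
    return sites
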