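"""3D occupancy density grids of aligned ligand positions.

Counts are stored as raw integers (one increment per selected bead per
frame) so grids from replicate runs merge exactly; normalization to
occupancy (counts / n_frames) happens only at export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityGrid",
    "accumulate_density",
    "merge_grids",
    "threshold_and_project",
    "write_opendx",
]

DEFAULT_VOXEL_NM = 0.1


@dataclass
class DensityGrid:
    """Integer occupancy counts on an axis-aligned voxel grid (nm units)."""

    origin: np.ndarray  # (3,)
    voxel_nm: float
    counts: np.ndarray  # (nx, ny, nz) int64
    n_frames: int
    selection: str = ""
    out_of_bounds: int = 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def total_observations(self) -> int:
        return int(self.counts.sum()) + int(self.out_of_bounds)

    def occupancy(self) -> np.ndarray:
        """Counts normalized per frame (mean occupancy per voxel)."""
        return self.counts / max(self.n_frames, 1)

    def compatible_with(self, other: "DensityGrid") -> bool:
        return (self.counts.shape == other.counts.shape
                and np.allclose(self.origin, other.origin)
                and np.isclose(self.voxel_nm, other.voxel_nm))


def accumulate_density(positions: np.ndarray, origin, extent_nm,
                       voxel_nm: float = DEFAULT_VOXEL_NM, n_frames: int | None = None,
                       selection: str = "head") -> DensityGrid:
    """Histogram bead-frame observations into a voxel grid.

    ``positions`` is an (n_obs, 3) array of already-aligned coordinates (one
    row per selected bead per frame); observations outside ``origin +
    extent`` are tallied separately as out-of-bounds.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel edge must be > 0")
    origin = np.asarray(origin, dtype=float)
    extent = np.asarray(extent_nm, dtype=float)
    if np.any(extent <= 0):
        raise ValueError("extent must be positive along every axis")
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    shape = np.maximum(np.ceil(extent / voxel_nm - 1e-9).astype(int), 1)
    edges = [origin[k] + voxel_nm * np.arange(shape[k] + 1) for k in range(3)]
    inb = np.all((pts >= origin) & (pts < origin + shape * voxel_nm), axis=1)
    hist, _ = np.histogramdd(pts[inb], bins=edges)
    counts = hist.astype(np.int64)
    if n_frames is None:
        n_frames = len(pts)
    return DensityGrid(origin=origin, voxel_nm=float(voxel_nm), counts=counts,
                       n_frames=int(n_frames), selection=selection,
                       out_of_bounds=int(len(pts) - inb.sum()))


def accumulate_density_trajectory(traj, role_map, origin, extent_nm,
                                  voxel_nm: float = DEFAULT_VOXEL_NM,
                                  selection: str = "head") -> DensityGrid:
    """Accumulate head-bead centroids of every ligand across all frames."""
    paths = [traj.head_path(role_map, lig) for lig in role_map.ligands]
    if not paths:
        pts = np.empty((0, 3))
    else:
        pts = np.concatenate(paths, axis=0)
    return accumulate_density(pts, origin, extent_nm, voxel_nm,
                              n_frames=traj.n_frames, selection=selection)


def merge_grids(grids) -> DensityGrid:
    """Sum counts and frame totals of compatible grids (order-invariant)."""
    grids = list(grids)
    if not grids:
        raise ValueError("no grids to merge")
    first = grids[0]
    for g in grids[1:]:
        if not first.compatible_with(g):
            raise ValueError("grids have mismatched origin/extent/voxel")
    return DensityGrid(
        origin=first.origin.copy(), voxel_nm=first.voxel_nm,
        counts=np.sum([g.counts for g in grids], axis=0),
        n_frames=sum(g.n_frames for g in grids),
        selection=first.selection,
        out_of_bounds=sum(g.out_of_bounds for g in grids))


def threshold_and_project(grid: DensityGrid, level: float, axis: int = 2
                          ) -> tuple[np.ndarray, int]:
    """Threshold the grid and project it.

    Voxels with count >= level are retained; the return value is the
    maximum-intensity projection of the retained counts along ``axis`` and
    the number of 26-connected components of the retained voxel set.
    """
    if level < 0:
        raise ValueError("threshold level must be >= 0")
    keep = grid.counts >= max(level, 1e-300) if level > 0 else grid.counts > 0
    retained = np.where(keep, grid.counts, 0)
    projection = retained.max(axis=axis) if retained.size else retained.sum(axis=axis)
    _, n_components = ndimage.label(keep, structure=np.ones((3, 3, 3), dtype=int))
    return projection, int(n_components)


def write_opendx(grid: DensityGrid, path, normalize: bool = True) -> None:
    """Write the grid as an OpenDX scalar field readable by molecular viewers."""
    data = grid.occupancy() if normalize else grid.counts.astype(float)
    nx, ny, nz = data.shape
    d = grid.voxel_nm
    lines = [
        f"# occupancy density ({grid.selection}); counts normalized per frame: {normalize}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {d:.6f} 0 0",
        f"delta 0 {d:.6f} 0",
        f"delta 0 0 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {data.size} data follows",
    ]
    flat = data.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
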