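"""Trajectory input: bead tagging, unwrapping, alignment and trimming.

Internal units are nm and ns throughout.  Two dialects are supported: a
plain tabular TSV format (columns ``frame_time_ns, bead_id, x_nm, y_nm,
z_nm, box_x, box_y, box_z``) read natively, and structure+trajectory pairs
(PDB/GRO + XTC/DCD/multi-model PDB) read through MDAnalysis, whose native
Angstrom/ps units are converted on load.

Only beads named by the :class:`RoleMap` are kept.  Ligand bead paths are
unwrapped with per-bead minimum-image continuity between consecutive frames;
protein reference beads are assumed whole and never unwrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "RoleMap",
    "LigandRoles",
    "Frame",
    "Trajectory",
    "read_trajectory",
    "align_frames",
    "discard_equilibration",
]

DEFAULT_EQUILIBRATION_NS = 1000.0

TABULAR_COLUMNS = ["frame_time_ns", "bead_id", "x_nm", "y_nm", "z_nm",
                   "box_x", "box_y", "box_z"]


class TrajectoryError(ValueError):
    pass


@dataclass(frozen=True)
class LigandRoles:
    head_beads: tuple[str, ...]
    tail_beads: tuple[str, ...] = ()  # ordered head-proximal to terminal
    species: str = "PLQ"  # PLQ | PLQol

    def __post_init__(self):
        object.__setattr__(self, "head_beads", tuple(self.head_beads))
        object.__setattr__(self, "tail_beads", tuple(self.tail_beads))
        if not self.head_beads:
            raise TrajectoryError("ligand needs at least one head bead")
        overlap = set(self.head_beads) & set(self.tail_beads)
        if overlap:
            raise TrajectoryError(f"head and tail bead sets overlap: {sorted(overlap)}")
        if self.species not in ("PLQ", "PLQol"):
            raise TrajectoryError(f"unknown ligand species {self.species!r}")


@dataclass(frozen=True)
class RoleMap:
    """Assignment of beads to ligand head/tail and protein-reference roles."""

    ligands: Mapping[str, LigandRoles]
    protein_reference: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "ligands", dict(self.ligands))
        object.__setattr__(self, "protein_reference", tuple(self.protein_reference))

    @property
    def all_beads(self) -> list[str]:
        beads: list[str] = []
        for roles in self.ligands.values():
            beads.extend(roles.head_beads)
            beads.extend(roles.tail_beads)
        beads.extend(self.protein_reference)
        return beads

    @property
    def ligand_beads(self) -> list[str]:
        beads: list[str] = []
        for roles in self.ligands.values():
            beads.extend(roles.head_beads)
            beads.extend(roles.tail_beads)
        return beads

    @classmethod
    def from_config(cls, cfg: Mapping) -> "RoleMap":
        ligands = {
            str(name): LigandRoles(
                head_beads=[str(b) for b in spec["head_beads"]],
                tail_beads=[str(b) for b in spec.get("tail_beads", [])],
                species=spec.get("species", "PLQ"),
            )
            for name, spec in cfg.get("ligands", {}).items()
        }
        return cls(ligands=ligands,
                   protein_reference=[str(b) for b in cfg.get("protein_reference", [])])

    def to_config(self) -> dict:
        return {
            "ligands": {
                name: {"species": r.species,
                       "head_beads": list(r.head_beads),
                       "tail_beads": list(r.tail_beads)}
                for name, r in self.ligands.items()
            },
            "protein_reference": list(self.protein_reference),
        }

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


@dataclass(frozen=True)
class Frame:
    """Single-frame view: time (ns), positions (nm) and box edges (nm)."""

    time: float
    positions: np.ndarray  # (n_beads, 3)
    box: np.ndarray  # (3,)


@dataclass
class Trajectory:
    """Time-ordered tagged-bead coordinates in a periodic orthorhombic box."""

    times: np.ndarray  # (F,) ns, strictly increasing
    positions: np.ndarray  # (F, B, 3) nm
    box: np.ndarray  # (F, 3) nm
    bead_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions)
        self.box = np.asarray(self.box, dtype=float)
        self.bead_ids = tuple(self.bead_ids)
        if self.positions.ndim != 3 or self.positions.shape[0] != len(self.times):
            raise TrajectoryError("positions must have shape (n_frames, n_beads, 3)")
        if self.positions.shape[1] != len(self.bead_ids):
            raise TrajectoryError("bead_ids length must match positions")
        bad = np.flatnonzero(np.diff(self.times) <= 0)
        if bad.size:
            raise TrajectoryError(f"times not strictly increasing at frame index {bad[0] + 1}")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("non-finite coordinates in trajectory")
        if np.any(self.box <= 0):
            raise TrajectoryError("box edges must be > 0")
        self._index = {b: i for i, b in enumerate(self.bead_ids)}

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return len(self.bead_ids)

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.positions[i], self.box[i])

    def bead_index(self, bead: str) -> int:
        try:
            return self._index[bead]
        except KeyError:
            raise TrajectoryError(f"bead {bead!r} not in trajectory") from None

    def bead_path(self, bead: str) -> np.ndarray:
        return self.positions[:, self.bead_index(bead), :]

    def centroid_path(self, beads: Sequence[str]) -> np.ndarray:
        idx = [self.bead_index(b) for b in beads]
        return self.positions[:, idx, :].mean(axis=1)

    def head_path(self, role_map: RoleMap, ligand: str) -> np.ndarray:
        return self.centroid_path(role_map.ligands[ligand].head_beads)

    def tail_path(self, role_map: RoleMap, ligand: str) -> np.ndarray | None:
        tails = role_map.ligands[ligand].tail_beads
        if not tails:
            return None
        return self.centroid_path(tails)


# ---------------------------------------------------------------------------
# reading

def _read_tabular(path, role_map: RoleMap) -> Trajectory:
    df = pd.read_csv(path, sep="\t", dtype={"bead_id": str})
    missing_cols = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrajectoryError(f"tabular trajectory {path} missing columns {missing_cols}")
    wanted = role_map.all_beads
    present = set(df["bead_id"].unique())
    absent = [b for b in wanted if b not in present]
    if absent:
        raise TrajectoryError(f"role map beads not found in trajectory: {absent}")
    df = df[df["bead_id"].isin(set(wanted))]
    times_file_order = df["frame_time_ns"].drop_duplicates().to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times_file_order) <= 0)
    if bad.size:
        raise TrajectoryError(f"times not strictly increasing at frame index {bad[0] + 1}")
    times = times_file_order
    wide = df.pivot_table(index="frame_time_ns", columns="bead_id",
                          values=["x_nm", "y_nm", "z_nm"], aggfunc="first")
    for b in wanted:
        for ax in ("x_nm", "y_nm", "z_nm"):
            if wide[(ax, b)].isna().any():
                raise TrajectoryError(f"bead {b!r} missing from some frames")
    F, B = len(times), len(wanted)
    positions = np.empty((F, B, 3))
    for j, b in enumerate(wanted):
        for k, ax in enumerate(("x_nm", "y_nm", "z_nm")):
            positions[:, j, k] = wide[(ax, b)].to_numpy()
    box = (df.drop_duplicates("frame_time_ns").sort_values("frame_time_ns")
           [["box_x", "box_y", "box_z"]].to_numpy(dtype=float))
    return Trajectory(times=times, positions=positions, box=box, bead_ids=wanted,
                      metadata={"source": str(path), "format": "tabular"})


def _resolve_mda_bead(universe, bead: str):
    """Resolve a bead id against an MDAnalysis Universe.

    Accepted forms: a unique atom name, ``resid:name``, or ``index:<i>``.
    """
    import MDAnalysis as mda  # noqa: F401  (deferred import)

    if bead.startswith("index:"):
        i = int(bead.split(":", 1)[1])
        if i < 0 or i >= len(universe.atoms):
            return None
        return universe.atoms[i]
    if ":" in bead:
        resid, name = bead.split(":", 1)
        sel = universe.select_atoms(f"resid {int(resid)} and name {name}")
    else:
        sel = universe.select_atoms(f"name {bead}")
    if len(sel) != 1:
        return None
    return sel[0]


def _read_mdanalysis(structure_path, trajectory_path, role_map: RoleMap) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = (mda.Universe(str(structure_path), str(trajectory_path))
                    if trajectory_path else mda.Universe(str(structure_path)))
    wanted = role_map.all_beads
    atoms, absent = [], []
    for bead in wanted:
        atom = _resolve_mda_bead(universe, bead)
        (absent if atom is None else atoms).append(bead if atom is None else atom)
    if absent:
        raise TrajectoryError(f"role map beads not found in trajectory: {absent}")
    group = mda.AtomGroup(atoms)
    times, positions, box = [], [], []
    for ts in universe.trajectory:
        times.append(ts.time / 1000.0)  # ps -> ns
        positions.append(group.positions / 10.0)  # A -> nm
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise TrajectoryError("trajectory frame lacks box dimensions")
        box.append(np.asarray(dims[:3], dtype=float) / 10.0)
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise TrajectoryError(f"times not strictly increasing at frame index {bad}")
    return Trajectory(times=times, positions=np.asarray(positions), box=np.asarray(box),
                      bead_ids=wanted,
                      metadata={"source": str(trajectory_path or structure_path),
                                "format": "mdanalysis"})


def _unwrap_ligands(traj: Trajectory, role_map: RoleMap) -> None:
    """Make each ligand bead's path continuous across periodic boundaries.

    In-place; per-bead minimum image between consecutive frames.  Protein
    reference beads are assumed whole and left untouched.
    """
    if traj.n_frames < 2:
        return
    idx = [traj.bead_index(b) for b in role_map.ligand_beads]
    if not idx:
        return
    pos = traj.positions[:, idx, :].astype(float)
    disp = np.diff(pos, axis=0)
    boxes = traj.box[1:, None, :]
    disp -= boxes * np.round(disp / boxes)
    pos[1:] = pos[0] + np.cumsum(disp, axis=0)
    traj.positions = traj.positions.astype(float, copy=True)
    traj.positions[:, idx, :] = pos


def wrap_into_box(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map coordinates back into [0, box) per axis (inverse of unwrapping)."""
    return np.mod(points, box)


def read_trajectory(structure_path, trajectory_path, role_map: RoleMap) -> Trajectory:
    """Read a trajectory, keep role-mapped beads, convert units, unwrap ligands."""
    traj_path = Path(trajectory_path) if trajectory_path else None
    if traj_path is not None and traj_path.suffix.lower() in (".tsv", ".txt"):
        traj = _read_tabular(traj_path, role_map)
    else:
        traj = _read_mdanalysis(structure_path, trajectory_path, role_map)
    _unwrap_ligands(traj, role_map)
    return traj


# ---------------------------------------------------------------------------
# alignment and trimming

def _check_reference(ref: np.ndarray) -> None:
    if len(ref) < 3:
        raise TrajectoryError("alignment needs >= 3 protein reference beads")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise TrajectoryError("protein reference beads are collinear")


def align_frames(traj: Trajectory, reference_positions: np.ndarray | Mapping[str, Sequence[float]],
                 role_map: RoleMap) -> Trajectory:
    """Rigid-body least-squares superposition of every frame onto a reference.

    The optimal rotation+translation is fit on the protein-reference beads
    (Kabsch, via quaternion-free SVD in scipy) and applied to all beads.
    """
    ref_beads = list(role_map.protein_reference)
    if isinstance(reference_positions, Mapping):
        ref = np.array([reference_positions[b] for b in ref_beads], dtype=float)
    else:
        ref = np.asarray(reference_positions, dtype=float)
        if ref.shape != (len(ref_beads), 3):
            raise TrajectoryError("reference positions must match protein_reference beads")
    _check_reference(ref)
    idx = [traj.bead_index(b) for b in ref_beads]
    ref_centroid = ref.mean(axis=0)
    ref_centered = ref - ref_centroid
    out = np.empty_like(traj.positions, dtype=float)
    for f in range(traj.n_frames):
        mobile = traj.positions[f, idx, :].astype(float)
        mob_centroid = mobile.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mobile - mob_centroid)
        out[f] = rot.apply(traj.positions[f].astype(float) - mob_centroid) + ref_centroid
    meta = dict(traj.metadata)
    meta["aligned"] = True
    return Trajectory(times=traj.times.copy(), positions=out, box=traj.box.copy(),
                      bead_ids=traj.bead_ids, metadata=meta)


def discard_equilibration(traj: Trajectory, t_eq_ns: float = DEFAULT_EQUILIBRATION_NS) -> Trajectory:
    """Drop all frames with time < ``t_eq_ns``."""
    if t_eq_ns < 0:
        raise TrajectoryError("t_eq_ns must be >= 0")
    keep = traj.times >= t_eq_ns
    if not np.any(keep):
        raise TrajectoryError(
            f"discarding {t_eq_ns} ns removes all {traj.n_frames} frames "
            f"(trajectory ends at {traj.times[-1]} ns)")
    meta = dict(traj.metadata)
    meta["equilibration_discarded_ns"] = float(traj.times[keep][0] - traj.times[0])
    return Trajectory(times=traj.times[keep], positions=traj.positions[keep],
                      box=traj.box[keep], bead_ids=traj.bead_ids, metadata=meta)
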