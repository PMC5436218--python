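import numpy as np
import pytest

from plqex.geometry import GeometryModel
from plqex.synthetic_data import toy_geometry
from plqex.trajio import LigandRoles, RoleMap, Trajectory


@pytest.fixture(scope="session")
def toy_model() -> GeometryModel:
    """Two-monomer, three-channel toy geometry (4 nm slab, midplane z=5)."""
    return toy_geometry(2)


def make_trace(model, labels, dt_ns=0.5, z=None, ligand="lig"):
    """StateTrace from a list of label strings (no hysteresis applied)."""
    from plqex.events import StateTrace

    codes = np.array([model.code(lab) for lab in labels], dtype=np.int16)
    times = np.arange(len(labels)) * dt_ns
    if z is None:
        z = np.full(len(labels), model.midplane)
    return StateTrace(ligand=ligand, times=times, codes=codes,
                      leaflets=np.zeros(len(labels), dtype=np.int8),
                      z=np.asarray(z, float), model=model)


def traj_from_paths(times, bead_paths: dict, box=(24.0, 12.0, 10.0)) -> Trajectory:
    """Trajectory from {bead_id: (F, 3) array}."""
    bead_ids = list(bead_paths)
    positions = np.stack([np.asarray(bead_paths[b], float) for b in bead_ids], axis=1)
    F = len(times)
    return Trajectory(times=np.asarray(times, float), positions=positions,
                      box=np.tile(np.asarray(box, float), (F, 1)), bead_ids=bead_ids)


def simple_role_map(n_tails=2) -> RoleMap:
    tails = tuple(f"T{j}" for j in range(1, n_tails + 1))
    return RoleMap(ligands={"lig": LigandRoles(head_beads=("H",), tail_beads=tails)},
                   protein_reference=("R0", "R1", "R2", "R3"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
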