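"""Reading and writing structures and trajectories.

Single structures and multi-model PDB trajectories go through gemmi (cell
parameters come from the CRYST1 record; HOH/WAT residues are split out as
water sites). Binary trajectory formats (XTC/DCD) are loaded through
MDAnalysis when it is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .core import Topology, TrajectoryEnsemble
from .lattice import UnitCell

__all__ = [
    "ReferenceStructure",
    "read_pdb",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "load_trajectory",
]

_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}


@dataclass
class ReferenceStructure:
    """A reference crystal structure: protein, waters, and cell."""

    coords: np.ndarray
    topology: Topology
    cell: UnitCell | None
    water_coords: np.ndarray  # oxygen positions, (n_waters, 3)
    water_b: np.ndarray  # experimental B per water


def read_pdb(path: str) -> ReferenceStructure:
    """Read a PDB file; protein and water atoms are separated."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = UnitCell(
            st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma,
        )
    coords, resid, resname, atomname, element = [], [], [], [], []
    wat, wat_b = [], []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                for atom in res:
                    if atom.element.name == "O":
                        wat.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        wat_b.append(atom.b_iso)
                continue
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                resid.append(res.seqid.num)
                resname.append(res.name)
                atomname.append(atom.name)
                element.append(atom.element.name)
    top = Topology(
        np.array(resid, dtype=int),
        np.array(resname, dtype=object),
        np.array(atomname, dtype=object),
        np.array(element, dtype=object),
    )
    return ReferenceStructure(
        np.array(coords, dtype=float),
        top,
        cell,
        np.array(wat, dtype=float).reshape(-1, 3),
        np.array(wat_b, dtype=float),
    )


def _chain_ids():
    import itertools
    import string

    letters = string.ascii_uppercase + string.ascii_lowercase + string.digits
    yield from letters
    for a, b in itertools.product(letters, repeat=2):
        yield a + b


def write_multimodel_pdb(
    path: str,
    ens: TrajectoryEnsemble,
    cell: UnitCell | None = None,
) -> None:
    """Write an ensemble as a multi-model PDB (one model per frame).

    Chains are written as separate chain IDs inside each model; the cell
    goes to CRYST1 when given.
    """
    st = gemmi.Structure()
    if cell is not None:
        st.cell = gemmi.UnitCell(
            cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma
        )
        st.spacegroup_hm = "C 1 2 1"
    top = ens.topology
    for fi in range(ens.n_frames):
        model = gemmi.Model(fi + 1)
        ids = _chain_ids()
        for ci in range(ens.n_chains):
            chain = gemmi.Chain(next(ids))
            cur_res = None
            cur_id = None
            for ai in range(ens.n_atoms):
                rid = int(top.resid[ai])
                if cur_id != rid:
                    cur_res = gemmi.Residue()
                    cur_res.name = str(top.resname[ai])
                    cur_res.seqid = gemmi.SeqId(rid, " ")
                    chain.add_residue(cur_res)
                    cur_res = chain[-1]
                    cur_id = rid
                atom = gemmi.Atom()
                atom.name = str(top.atomname[ai])
                atom.element = gemmi.Element(str(top.element[ai]))
                x, y, z = ens.coords[ci, fi, ai]
                atom.pos = gemmi.Position(x, y, z)
                cur_res.add_atom(atom)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def read_multimodel_pdb(
    path: str, frame_interval_ns: float = 1.0
) -> TrajectoryEnsemble:
    """Read a multi-model PDB written per frame into an ensemble."""
    st = gemmi.read_structure(str(path))
    frames = []
    top = None
    for model in st:
        chains = []
        for chain in model:
            coords, resid, resname, atomname, element = [], [], [], [], []
            for res in chain:
                if res.name in _WATER_NAMES:
                    continue
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    resid.append(res.seqid.num)
                    resname.append(res.name)
                    atomname.append(atom.name)
                    element.append(atom.element.name)
            chains.append(np.array(coords))
            if top is None:
                top = Topology(
                    np.array(resid, dtype=int),
                    np.array(resname, dtype=object),
                    np.array(atomname, dtype=object),
                    np.array(element, dtype=object),
                )
        frames.append(np.array(chains))
    coords = np.stack(frames, axis=1)  # (chains, frames, atoms, 3)
    times = frame_interval_ns * np.arange(1, coords.shape[1] + 1)
    return TrajectoryEnsemble(coords, top, times)


def load_trajectory(
    traj_path: str,
    top_path: str,
    frame_interval_ns: float | None = None,
) -> TrajectoryEnsemble:
    """Load an XTC/DCD trajectory plus topology through MDAnalysis.

    Chains are split by segment/chain ID; every chain must share one
    topology.
    """
    import MDAnalysis as mda  # deferred: optional heavy dependency

    u = mda.Universe(str(top_path), str(traj_path))
    protein = u.select_atoms("protein")
    segids = sorted(set(protein.segids))
    groups = [protein.select_atoms(f"segid {s}") for s in segids]
    n_atoms = len(groups[0])
    if any(len(g) != n_atoms for g in groups):
        raise ValueError("all chains must share one topology")
    g0 = groups[0]
    top = Topology(
        np.array(g0.resids, dtype=int),
        np.array(g0.resnames, dtype=object),
        np.array(g0.names, dtype=object),
        np.array([t[0] if t else "C" for t in g0.types], dtype=object),
    )
    n_frames = len(u.trajectory)
    coords = np.empty((len(groups), n_frames, n_atoms, 3))
    cells = np.empty((n_frames, 3, 3))
    times = np.empty(n_frames)
    for fi, ts in enumerate(u.trajectory):
        for ci, g in enumerate(groups):
            coords[ci, fi] = g.positions
        cells[fi] = (
            mda.lib.mdamath.triclinic_vectors(ts.dimensions).T
            if ts.dimensions is not None
            else np.eye(3)
        )
        times[fi] = ts.time / 1000.0  # ps -> ns
    if frame_interval_ns is not None:
        times = frame_interval_ns * np.arange(1, n_frames + 1)
    elif not np.all(np.diff(times) > 0):
        times = np.arange(1, n_frames + 1, dtype=float)
    return TrajectoryEnsemble(coords, top, times, cell_per_frame=cells)
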