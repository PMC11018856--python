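"""Core containers for crystal-trajectory analysis.

A :class:`TrajectoryEnsemble` holds per-chain, per-frame coordinates of a
crystal supercell (or any collection of chains sharing one topology) and is
the universal input of every analysis operation in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Average atomic masses (u) for mass-weighted centers of mass.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


@dataclass
class Topology:
    """Per-atom metadata shared by every chain of an ensemble.

    Parameters
    ----------
    resid : (n_atoms,) int array
        Residue index of each atom (reference numbering).
    resname : (n_atoms,) str array
        Three-letter residue name.
    atomname : (n_atoms,) str array
        PDB atom name (``CA``, ``CB``, ...).
    element : (n_atoms,) str array
        Element symbol; hydrogens are excluded from heavy-atom selections.
    """

    resid: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    element: np.ndarray

    def __post_init__(self) -> None:
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atomname = np.asarray(self.atomname, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        n = len(self.resid)
        if not (len(self.resname) == len(self.atomname) == len(self.element) == n):
            raise ValueError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.resid)

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.resid)

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask selecting non-hydrogen atoms."""
        return np.array([e.upper() != "H" for e in self.element], dtype=bool)

    @property
    def calpha(self) -> np.ndarray:
        """Boolean mask selecting C-alpha atoms."""
        return np.array([a == "CA" for a in self.atomname], dtype=bool)

    @property
    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(str(e).upper(), 12.011) for e in self.element]
        )

    def selection_mask(self, selection: str) -> np.ndarray:
        if selection == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if selection == "heavy":
            return self.heavy
        if selection == "calpha":
            return self.calpha
        raise ValueError(
            f"unknown selection {selection!r}; expected 'all', 'heavy' or 'calpha'"
        )


@dataclass
class TrajectoryEnsemble:
    """Per-chain, per-frame coordinates with shared topology.

    Attributes
    ----------
    coords : (n_chains, n_frames, n_atoms, 3) float array, Angstrom
    topology : Topology
        One topology shared by every chain.
    frame_times : (n_frames,) float array, ns, strictly increasing.
    replica_id : identifier of the simulation replica this ensemble came from.
    cell_per_frame : optional (n_frames, 3, 3) array
        Box (cell) matrix per frame for NPT trajectories whose box reshapes;
        columns are cell vectors in Angstrom.
    sites : optional list
        Lattice-site assignment of each chain, fixed at construction time
        (see :mod:`xtalmd.lattice`).
    """

    coords: np.ndarray
    topology: Topology
    frame_times: np.ndarray
    replica_id: int | str = 0
    cell_per_frame: np.ndarray | None = None
    sites: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[-1] != 3:
            raise ValueError(
                "coords must have shape (n_chains, n_frames, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[2] != self.topology.n_atoms:
            raise ValueError("coords atom axis does not match topology")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.coords.shape[1],):
            raise ValueError("frame_times length does not match coords")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.sites is not None and len(self.sites) != self.n_chains:
            raise ValueError("one lattice site required per chain")

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[2]

    def chain(self, i: int) -> np.ndarray:
        """Coordinates of chain ``i``, shape (n_frames, n_atoms, 3)."""
        return self.coords[i]

    def supercell_frames(self) -> np.ndarray:
        """Frames of the whole supercell, shape (n_frames, n_chains*n_atoms, 3)."""
        return np.swapaxes(self.coords, 0, 1).reshape(
            self.n_frames, self.n_chains * self.n_atoms, 3
        )


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted center of mass along the atom (second-to-last) axis."""
    w = masses / masses.sum()
    return np.einsum("...ij,i->...j", coords, w)
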