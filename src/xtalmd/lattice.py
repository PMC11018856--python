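"""Unit-cell geometry, space-group symmetry, supercell construction, and
inverse crystallographic transforms quantifying lattice disorder.

The cell Cartesian frame follows the monoclinic standard: **a** along x,
**b** along y, **c** in the x-z plane. For a general triclinic cell the
standard PDB orthogonalization (a along x, b in the x-y plane) is used,
which reduces to the monoclinic convention when alpha = gamma = 90 deg.

Lattice disorder is measured by mapping each chain's center of mass back
into the asymmetric-unit frame with the inverse of its symmetry operator
and cell translation; in an undistorted lattice every chain maps exactly
onto the reference chain, so all displacements vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Topology, TrajectoryEnsemble, center_of_mass

__all__ = [
    "UnitCell",
    "SymmetryOperator",
    "LatticeSite",
    "unit_cell_matrix",
    "symmetry_operators",
    "build_supercell",
    "inverse_lattice_transform",
    "disorder_amplitude",
]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def cell_matrix(self) -> np.ndarray:
        return unit_cell_matrix(self)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.cell_matrix))


def unit_cell_matrix(cell: UnitCell) -> np.ndarray:
    """3x3 matrix whose columns are the cell vectors in Angstrom.

    Column 1 is (a, 0, 0); column 2 lies in the x-y plane; column 3 follows
    the standard triclinic orthogonalization. For alpha = gamma = 90 deg this
    yields b = (0, b, 0) and c = (c cos(beta), 0, c sin(beta)).
    """
    al, be, ga = np.radians([cell.alpha, cell.beta, cell.gamma])
    ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    cy = (ca - cb * cg) / sg
    czsq = 1.0 - cb**2 - cy**2
    if czsq <= 1e-12:
        raise ValueError("degenerate unit cell (near-zero volume)")
    m = np.array(
        [
            [cell.a, cell.b * cg, cell.c * cb],
            [0.0, cell.b * sg, cell.c * cy],
            [0.0, 0.0, cell.c * np.sqrt(czsq)],
        ]
    )
    # monoclinic standard frame: swap so that b is along y, c in x-z
    # (already satisfied by this construction when alpha = gamma = 90).
    if np.linalg.det(m) <= 0:
        raise ValueError("degenerate unit cell (non-positive volume)")
    return m


@dataclass(frozen=True)
class SymmetryOperator:
    """Space-group operator acting on fractional coordinates: f -> R f + t."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # fractional 3-vector

    def __post_init__(self) -> None:
        r = self.rot
        if abs(abs(np.linalg.det(r)) - 1.0) > 1e-12:
            raise ValueError("rotation part must have determinant +/-1")

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def trans(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.rot.T + self.trans

    def inverse(self) -> "SymmetryOperator":
        rinv = np.linalg.inv(self.rot)
        tinv = -rinv @ self.trans
        return SymmetryOperator(
            tuple(map(tuple, np.rint(rinv).astype(int))), tuple(tinv)
        )


# Operator registries. C121 (C2, C-centered monoclinic): identity, two-fold
# along b, and both composed with the C-centering translation (1/2, 1/2, 0).
_SPACE_GROUPS: dict[str, list[SymmetryOperator]] = {
    "P1": [SymmetryOperator(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))],
    "C121": [
        SymmetryOperator(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0)),
        SymmetryOperator(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.0, 0.0, 0.0)),
        SymmetryOperator(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.5, 0.5, 0.0)),
        SymmetryOperator(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.5, 0.5, 0.0)),
    ],
}


def symmetry_operators(space_group_label: str) -> list[SymmetryOperator]:
    """Symmetry operators of a supported space group.

    Only ``"C121"`` (4 operators) and the trivial ``"P1"`` are registered;
    the registry is a plain dict and is extensible.
    """
    key = space_group_label.replace(" ", "")
    if key not in _SPACE_GROUPS:
        raise ValueError(
            f"unknown space group {space_group_label!r}; "
            f"supported: {sorted(_SPACE_GROUPS)}"
        )
    return list(_SPACE_GROUPS[key])


@dataclass(frozen=True)
class LatticeSite:
    """One chain position in the ideal supercell lattice."""

    cell_index: tuple  # (i, j, k)
    operator_index: int
    ideal_com: tuple  # Cartesian Angstrom


def build_supercell(
    cell: UnitCell,
    asym_coords: np.ndarray,
    n_cells: tuple[int, int, int] = (3, 3, 3),
    space_group: str = "C121",
    masses: np.ndarray | None = None,
) -> tuple[np.ndarray, list[LatticeSite]]:
    """Replicate one asymmetric-unit chain into an n1 x n2 x n3 supercell.

    Chain order is deterministic: cell-major (i, then j, then k), operator-
    minor. Returns the stacked chain coordinates with shape
    (n_chains, n_atoms, 3) and the matching :class:`LatticeSite` list; for a
    3x3x3 C121 supercell there are 27 * 4 = 108 chains.
    """
    if any(n <= 0 for n in n_cells):
        raise ValueError("n_cells entries must be positive")
    asym_coords = np.asarray(asym_coords, dtype=float)
    m = cell.cell_matrix
    minv = np.linalg.inv(m)
    ops = symmetry_operators(space_group)
    frac = asym_coords @ minv.T
    if masses is None:
        masses = np.ones(len(asym_coords))
    chains = []
    sites = []
    for i in range(n_cells[0]):
        for j in range(n_cells[1]):
            for k in range(n_cells[2]):
                shift = np.array([i, j, k], dtype=float)
                for oi, op in enumerate(ops):
                    f = op.apply(frac) + shift
                    xyz = f @ m.T
                    chains.append(xyz)
                    com = center_of_mass(xyz, masses)
                    sites.append(
                        LatticeSite((i, j, k), oi, tuple(com))
                    )
    return np.array(chains), sites


def inverse_lattice_transform(
    ens: TrajectoryEnsemble,
    ref_coords: np.ndarray,
    cell: UnitCell,
    sites: list[LatticeSite] | None = None,
    space_group: str = "C121",
    selection: str = "heavy",
) -> pd.DataFrame:
    """Map each chain's center of mass back to the asymmetric-unit frame.

    Per frame, the chain COM is fractionalized (per-frame cell matrix when
    ``ens.cell_per_frame`` is set, otherwise the reference cell), the inverse
    of the chain's symmetry operator and integer cell translation is applied,
    and the result is re-orthogonalized with the reference cell matrix. The
    displacement is this mapped COM minus the reference-chain COM, so an
    undistorted lattice gives zero everywhere.

    Returns a DataFrame with columns ``chain_id, frame_ns, dx, dy, dz, d,
    ac_u, ac_v`` where (ac_u, ac_v) are the components of the displacement
    along the unit a and c cell directions (the Fig-style ac-plane
    projection).
    """
    sites = sites if sites is not None else ens.sites
    if sites is None or len(sites) != ens.n_chains:
        raise ValueError("chain/site count mismatch: one LatticeSite per chain")
    ops = symmetry_operators(space_group)
    m_ref = cell.cell_matrix
    masses = ens.topology.masses
    sel = ens.topology.selection_mask(selection)
    ref_com = center_of_mass(np.asarray(ref_coords)[sel], masses[sel])
    a_hat = m_ref[:, 0] / np.linalg.norm(m_ref[:, 0])
    c_hat = m_ref[:, 2] / np.linalg.norm(m_ref[:, 2])

    rows = []
    for ci in range(ens.n_chains):
        site = sites[ci]
        op_inv = ops[site.operator_index].inverse()
        shift = np.array(site.cell_index, dtype=float)
        coms = center_of_mass(ens.coords[ci][:, sel], masses[sel])  # (frames, 3)
        for fi in range(ens.n_frames):
            m_f = (
                ens.cell_per_frame[fi]
                if ens.cell_per_frame is not None
                else m_ref
            )
            f = np.linalg.solve(m_f, coms[fi])
            f0 = op_inv.apply(f - shift)
            mapped = m_ref @ f0
            d = mapped - ref_com
            rows.append(
                (
                    ci,
                    ens.frame_times[fi],
                    d[0],
                    d[1],
                    d[2],
                    np.linalg.norm(d),
                    d @ a_hat,
                    d @ c_hat,
                )
            )
    return pd.DataFrame(
        rows, columns=["chain_id", "frame_ns", "dx", "dy", "dz", "d", "ac_u", "ac_v"]
    )


def disorder_amplitude(
    displacements: pd.DataFrame | list[pd.DataFrame],
) -> dict:
    """Mean chain-displacement magnitude, the lattice-disorder amplitude.

    Accepts one displacement table or one per replica. Returns a dict with
    the pooled mean amplitude (Angstrom), per-replica means, and the standard
    deviation across replicas (NaN for a single replica).
    """
    if isinstance(displacements, pd.DataFrame):
        displacements = [displacements]
    if len(displacements) == 0 or any(len(df) == 0 for df in displacements):
        raise ValueError("empty displacement set")
    per_replica = np.array([df["d"].mean() for df in displacements])
    pooled = float(
        np.concatenate([df["d"].to_numpy() for df in displacements]).mean()
    )
    return {
        "amplitude": pooled,
        "per_replica": per_replica,
        "replica_std": float(np.std(per_replica, ddof=1))
        if len(per_replica) > 1
        else float("nan"),
    }
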