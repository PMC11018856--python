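"""Seeded generators of crystal-like trajectories with known ground truth.

These generators emulate the statistical structure of a crystalline MD
ensemble — a supercell of chains on ideal lattice sites, independent
per-chain rigid-body displacements, spatially correlated internal
fluctuations with an exponential distance kernel, a two-state Markovian
loop distance, and tethered ordered waters with prescribed occupancy — so
that every analysis stage has a recovery test against a known answer,
without running molecular dynamics.

All generators are bit-reproducible: the same spec and seed give identical
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, TrajectoryEnsemble
from .features import DihedralSet
from .lattice import UnitCell, build_supercell

__all__ = [
    "STUDY_CELL",
    "make_template_chain",
    "SyntheticSpec",
    "GroundTruth",
    "synth_crystal_trajectory",
    "synth_two_state_distance",
    "synth_dihedral_ensembles",
    "synth_observable_series",
]

# C121 cell of the reference PDZ-domain crystal structure.
STUDY_CELL = UnitCell(a=65.30, b=39.45, c=39.01, alpha=90.0, beta=117.54, gamma=90.0)


def make_template_chain(n_residues: int = 50) -> tuple[np.ndarray, Topology]:
    """A compact toy protein chain (N, CA, C, O, CB per residue).

    Residues are laid out on an idealized helix (1.5 Angstrom rise, 100 deg
    twist, 2.3 Angstrom radius) so the chain is compact enough to occupy an
    asymmetric unit; geometry is schematic, not stereochemically refined.
    Every third residue is labelled GLN (with CG and CD stubs so chi1/chi2
    exist), the rest ALA-like.
    """
    coords, resid, resname, atomname, element = [], [], [], [], []
    for i in range(n_residues):
        theta = np.radians(100.0 * i)
        ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        axis_out = np.array([np.cos(theta), np.sin(theta), 0.0])
        name = "GLN" if i % 3 == 0 else "ALA"
        atoms = [
            ("N", "N", ca + np.array([-0.8, -0.9, -0.6])),
            ("CA", "C", ca),
            ("C", "C", ca + np.array([0.9, 0.7, 0.7])),
            ("O", "O", ca + np.array([1.1, 1.6, 0.4])),
            ("CB", "C", ca + 1.5 * axis_out),
        ]
        if name == "GLN":
            atoms.append(("CG", "C", ca + 2.9 * axis_out + np.array([0, 0, 0.4])))
            atoms.append(("CD", "C", ca + 4.1 * axis_out + np.array([0.4, 0, 0.9])))
        for an, el, xyz in atoms:
            coords.append(xyz)
            resid.append(i + 1)
            resname.append(name)
            atomname.append(an)
            element.append(el)
    top = Topology(
        np.array(resid), np.array(resname, dtype=object),
        np.array(atomname, dtype=object), np.array(element, dtype=object),
    )
    return np.array(coords), top


@dataclass
class GroundTruth:
    """The true generator parameters a recovery analysis should return."""

    sigma_int: float = 0.0
    sigma_rb: float = 0.0
    corr_length: float = 0.0
    water_occupancies: np.ndarray | None = None
    state_populations: np.ndarray | None = None
    implied_timescale_frames: float | None = None


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic crystal trajectory.

    Defaults mirror the reference study's geometry: the C121 cell, a 3x3x3
    supercell, ~0.5 Angstrom rigid-body lattice vibrations, internal
    fluctuations correlated over 11 Angstrom, and frames every 10 ns.
    """

    cell: UnitCell = field(default_factory=lambda: STUDY_CELL)
    n_cells: tuple = (3, 3, 3)
    space_group: str = "C121"
    n_template_residues: int = 50
    sigma_int: float = 0.3  # per-axis internal noise, Angstrom
    sigma_rb: float = 0.5  # per-axis rigid-body noise, Angstrom
    corr_length: float = 11.0  # internal-noise kernel decay length, Angstrom
    n_frames: int = 100
    frame_interval_ns: float = 10.0
    n_water_sites: int = 0
    water_occupancy: float | np.ndarray = 0.8
    water_jitter: float = 0.3  # Angstrom, within the occupancy radius
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_int, self.sigma_rb) < 0 or self.corr_length < 0:
            raise ValueError("noise parameters must be non-negative")


def _correlated_noise_factor(
    coords: np.ndarray, sigma: float, ell: float
) -> np.ndarray | None:
    """Cholesky factor of the atom-distance kernel sigma^2 exp(-d/ell)."""
    if sigma == 0.0:
        return None
    if ell <= 0.0:
        return sigma * np.eye(len(coords))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    k = sigma**2 * np.exp(-d / ell)
    k[np.diag_indices_from(k)] += 1e-10
    return np.linalg.cholesky(k)


def synth_crystal_trajectory(
    spec: SyntheticSpec,
) -> tuple[TrajectoryEnsemble, GroundTruth, dict]:
    """Generate a supercell trajectory with known disorder parameters.

    Chains are placed by the C121 supercell builder; each frame adds an
    independent rigid translation ~ N(0, sigma_rb^2 I) per chain and
    internal per-atom displacements with covariance
    sigma_int^2 exp(-d_ij / ell) between atoms (independent when ell = 0).
    Optional ordered waters are tethered to three-atom anchors on randomly
    chosen chains and are present per frame with probability q.

    Returns (ensemble, ground truth, extras); ``extras`` holds the
    reference template coordinates, the ideal supercell, and — when water
    sites are requested — the per-frame water coordinates (NaN when absent)
    plus site anchor indices into the flattened supercell protein array.
    """
    template, top = make_template_chain(spec.n_template_residues)
    if len(template) < 4:
        raise ValueError("template must have at least 4 atoms")
    rng = np.random.default_rng(spec.seed)
    chains0, sites = build_supercell(
        spec.cell, template, spec.n_cells, spec.space_group, masses=top.masses
    )
    n_chains, n_atoms = chains0.shape[:2]
    chol = _correlated_noise_factor(template, spec.sigma_int, spec.corr_length)

    coords = np.empty((n_chains, spec.n_frames, n_atoms, 3))
    for ci in range(n_chains):
        base = chains0[ci]
        rigid = spec.sigma_rb * rng.standard_normal((spec.n_frames, 3))
        if chol is not None:
            # each Cartesian axis is an independent draw from the kernel
            z = rng.standard_normal((spec.n_frames, 3, n_atoms))
            internal = np.einsum("ij,fkj->fik", chol, z)  # (frames, atoms, 3)
        else:
            internal = np.zeros((spec.n_frames, n_atoms, 3))
        coords[ci] = base[None] + rigid[:, None, :] + internal

    times = spec.frame_interval_ns * np.arange(1, spec.n_frames + 1)
    ens = TrajectoryEnsemble(coords, top, times, sites=sites)

    extras: dict = {"template": template, "ideal_chains": chains0, "topology": top}
    q_arr = None
    if spec.n_water_sites > 0:
        q_arr = np.broadcast_to(
            np.asarray(spec.water_occupancy, dtype=float), (spec.n_water_sites,)
        ).copy()
        # rejection-sample tether points so sites stay well separated and
        # no site's water can satisfy a neighboring site
        site_chain = np.empty(spec.n_water_sites, dtype=int)
        site_atom = np.empty(spec.n_water_sites, dtype=int)
        positions, anchors = [], []
        for s in range(spec.n_water_sites):
            for _ in range(1000):
                c = int(rng.integers(0, n_chains))
                a = int(rng.integers(0, n_atoms - 3))
                anchor_local = np.array([a, a + 1, a + 2])
                pos = chains0[c, anchor_local].mean(axis=0) + np.array(
                    [0.0, 0.0, 2.0]
                )
                if all(np.linalg.norm(pos - p) > 4.0 for p in positions):
                    break
            else:
                raise RuntimeError("could not place well-separated water sites")
            site_chain[s], site_atom[s] = c, a
            positions.append(pos)
            anchors.append(c * n_atoms + anchor_local)
        positions = np.array(positions)
        waters = np.full((spec.n_frames, spec.n_water_sites, 3), np.nan)
        for fi in range(spec.n_frames):
            present = rng.random(spec.n_water_sites) < q_arr
            for s in np.flatnonzero(present):
                c = site_chain[s]
                # waters ride on their chain's rigid displacement
                drift = coords[c, fi, site_atom[s]] - chains0[c, site_atom[s]]
                jitter = spec.water_jitter * rng.standard_normal(3)
                waters[fi, s] = positions[s] + drift + jitter
        extras["water_traj"] = waters
        extras["water_site_positions"] = positions
        extras["water_site_anchors"] = anchors
    truth = GroundTruth(
        sigma_int=spec.sigma_int,
        sigma_rb=spec.sigma_rb,
        corr_length=spec.corr_length if spec.sigma_int > 0 else 0.0,
        water_occupancies=q_arr,
    )
    return ens, truth, extras


def synth_two_state_distance(
    p01: float,
    p10: float,
    mu0: float,
    mu1: float,
    sigma_d: float,
    n_frames: int,
    seed: int = 0,
    n_chains: int = 1,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two-state Markovian distance process (the loop coordinate stand-in).

    A hidden chain switches 0->1 with probability ``p01`` per frame and
    1->0 with ``p10``; the emitted distance is N(mu_state, sigma_d^2).
    Ground truth: stationary populations (p10, p01)/(p01+p10) and implied
    timescale -1/ln(1 - p01 - p10) frames. Requires p01 + p10 < 1 (the
    oscillatory regime is excluded).

    Returns (distances, states) with shape (n_chains, n_frames), and the
    ground truth.
    """
    if mu0 == mu1:
        raise ValueError("state means must differ")
    if not 0 <= p01 <= 1 or not 0 <= p10 <= 1 or p01 + p10 >= 1:
        raise ValueError("require 0 <= p01, p10 and p01 + p10 < 1")
    rng = np.random.default_rng(seed)
    pi = np.array([p10, p01]) / (p01 + p10)
    states = np.empty((n_chains, n_frames), dtype=np.int8)
    u = rng.random((n_chains, n_frames))
    for c in range(n_chains):
        s = 0 if u[c, 0] < pi[0] else 1
        states[c, 0] = s
        for t in range(1, n_frames):
            if s == 0:
                s = 1 if u[c, t] < p01 else 0
            else:
                s = 0 if u[c, t] < p10 else 1
            states[c, t] = s
    mu = np.where(states == 0, mu0, mu1)
    dist = mu + sigma_d * rng.standard_normal(states.shape)
    truth = GroundTruth(
        state_populations=pi,
        implied_timescale_frames=-1.0 / np.log(1.0 - p01 - p10),
    )
    return dist, states, truth


def synth_dihedral_ensembles(
    group_specs: dict,
    n_residues: int = 20,
    gln_resids: tuple = (3, 9, 15),
    n_chains: int = 4,
    n_frames: int = 250,
    seed: int = 0,
    jitter: float = 30.0,
) -> dict:
    """Dihedral ensembles with group-specific GLN rotamer populations.

    ``group_specs`` maps a group label to a 3x3 chi1 x chi2 rotamer
    population table applied at the GLN residues; backbone (phi, psi) well
    centers are shared across groups, so only the side-chain statistics
    separate them — emulating force-field-specific rotamer preferences.
    Angles are drawn in the well centers (g+ = +60, t = 180, g- = -60 deg)
    with uniform jitter of +/- ``jitter`` degrees.

    Returns {group: DihedralSet}; every group uses the same residue layout.
    """
    rng = np.random.default_rng(seed)
    resid = np.arange(1, n_residues + 1)
    resname = np.array(
        ["GLN" if r in gln_resids else "ALA" for r in resid], dtype=object
    )
    well_center = np.array([60.0, 180.0, -60.0])  # g+, t, g-
    # backbone well centers shared by every group
    phi0 = rng.uniform(-150, -50, size=n_residues)
    psi0 = rng.uniform(-60, 160, size=n_residues)
    # non-GLN chi wells shared by every group
    base_chi_states = rng.integers(0, 3, size=(n_residues, 2))

    def wrap(a):
        return ((a + 180.0) % 360.0) - 180.0

    out = {}
    for group, table in group_specs.items():
        table = np.asarray(table, dtype=float)
        if table.shape != (3, 3) or abs(table.sum() - 1.0) > 1e-9:
            raise ValueError(f"group {group!r}: need a 3x3 table summing to 1")
        shape = (n_chains, n_frames, n_residues)
        phi = wrap(phi0[None, None] + rng.uniform(-jitter, jitter, shape))
        psi = wrap(psi0[None, None] + rng.uniform(-jitter, jitter, shape))
        chi1 = np.empty(shape)
        chi2 = np.empty(shape)
        for ri in range(n_residues):
            n_draw = n_chains * n_frames
            if resname[ri] == "GLN":
                cells = rng.choice(9, size=n_draw, p=table.reshape(-1))
                s1, s2 = cells // 3, cells % 3
            else:
                s1 = np.full(n_draw, base_chi_states[ri, 0])
                s2 = np.full(n_draw, base_chi_states[ri, 1])
            chi1[:, :, ri] = wrap(
                well_center[s1] + rng.uniform(-jitter, jitter, n_draw)
            ).reshape(n_chains, n_frames)
            chi2[:, :, ri] = wrap(
                well_center[s2] + rng.uniform(-jitter, jitter, n_draw)
            ).reshape(n_chains, n_frames)
        out[group] = DihedralSet(resid, resname.copy(), phi, psi, chi1, chi2)
    return out


def synth_observable_series(
    kind: str,
    n_replicas: int = 3,
    n_points: int = 200,
    level: float = 1.0,
    noise: float = 0.05,
    drift_slope: float = 0.0,
    offsets: np.ndarray | None = None,
    ar_coeff: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Replica observable time series for equilibration-check fixtures.

    ``plateau``: AR(1) noise around a constant level (optionally with
    per-replica ``offsets``); ``drift``: the same plus a linear trend of
    ``drift_slope`` per point. The returned truth dict records which
    equilibration condition the series should fail.
    """
    if kind not in ("plateau", "drift"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    if offsets is None:
        offsets = np.zeros(n_replicas)
    series = np.empty((n_replicas, n_points))
    innov_sd = noise * np.sqrt(1 - ar_coeff**2)
    for r in range(n_replicas):
        x = np.empty(n_points)
        x[0] = noise * rng.standard_normal()
        for t in range(1, n_points):
            x[t] = ar_coeff * x[t - 1] + innov_sd * rng.standard_normal()
        series[r] = level + offsets[r] + x
        if kind == "drift":
            series[r] += drift_slope * np.arange(n_points)
    truth = {
        "plateau_should_fail": kind == "drift" and drift_slope != 0.0,
        "agreement_should_fail": bool(np.ptp(offsets) > 0),
    }
    return series, truth
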