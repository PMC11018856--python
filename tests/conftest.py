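"""Shared fixtures and geometric construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from xtalmd.core import Topology, TrajectoryEnsemble


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Internal-coordinate (NeRF) placement of atom d after a-b-c.

    |c-d| = bond, angle(b, c, d) = angle_deg, dihedral(a, b, c, d) =
    dihedral_deg with the right-handed sign convention.
    """
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omega=180.0):
    """Construct an N-CA-C backbone with prescribed phi/psi dihedrals.

    ``phis[i]`` applies to residue i (ignored for i = 0, where phi is
    undefined); ``psis[i]`` applies to residue i (ignored for the last).
    Returns (coords, Topology) with atoms N, CA, C per residue.
    """
    phis = list(phis)
    psis = list(psis)
    n_res = len(phis)
    coords = []
    # residue 1 seed geometry
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = ca0 + 1.525 * np.array([np.cos(np.radians(68.0)), np.sin(np.radians(68.0)), 0.0])
    coords += [n0, ca0, c0]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, 1.329, 117.0, psis[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, 1.458, 121.0, omega)
        c_i = place_atom(c_prev, n_i, ca_i, 1.525, 111.0, phis[i])
        coords += [n_i, ca_i, c_i]
    coords = np.array(coords)
    top = Topology(
        np.repeat(np.arange(1, n_res + 1), 3),
        np.array(["ALA"] * (3 * n_res), dtype=object),
        np.array(["N", "CA", "C"] * n_res, dtype=object),
        np.array(["N", "C", "C"] * n_res, dtype=object),
    )
    return coords, top


def single_frame_ensemble(coords, top, n_frames=1):
    """Wrap static coordinates as a (1, n_frames, n_atoms, 3) ensemble."""
    coords = np.asarray(coords, dtype=float)
    stack = np.repeat(coords[None, None], n_frames, axis=1)
    return TrajectoryEnsemble(stack, top, np.arange(1, n_frames + 1, dtype=float))


def random_rotation(rng):
    """A uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
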