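"""Local-alignment tracking of crystallographic water sites (CWS).

Each ordered water of the reference structure is anchored to its
coordinating protein heavy atoms. Per trajectory frame, the anchors are
least-squares superposed onto their reference positions, the resulting
transform is applied to the site, and the site counts as occupied when any
water oxygen lies within the occupancy radius of the transformed position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import kabsch_superpose

__all__ = [
    "WaterSiteModel",
    "SiteOccupancy",
    "anchor_cws",
    "track_cws",
    "preservation_summary",
]


@dataclass
class WaterSiteModel:
    """A crystallographic water site tied to coordinating protein atoms."""

    site_id: int
    position: np.ndarray  # crystal position, Angstrom
    anchor_idx: np.ndarray  # indices into the protein atom array
    anchor_ref: np.ndarray  # reference anchor coordinates (n_anchors, 3)
    b_exp: float = float("nan")
    valid: bool = True  # False when fewer than min_anchors coordinate it


@dataclass
class SiteOccupancy:
    """Per-frame occupation record of one water site."""

    site_id: int
    occupied: np.ndarray  # bool per frame
    occupancy: float

    def preserved(self, threshold: float = 0.5) -> bool:
        return self.occupancy >= threshold


def anchor_cws(
    protein_coords: np.ndarray,
    water_coords: np.ndarray,
    protein_heavy_mask: np.ndarray | None = None,
    anchor_cutoff: float = 4.0,
    min_anchors: int = 3,
    b_exp: np.ndarray | None = None,
) -> list[WaterSiteModel]:
    """Anchor each reference water oxygen to nearby protein heavy atoms.

    Sites with fewer than ``min_anchors`` coordinating atoms within
    ``anchor_cutoff`` Angstrom are returned with ``valid=False`` and are
    excluded from preservation statistics downstream.
    """
    water_coords = np.atleast_2d(np.asarray(water_coords, dtype=float))
    if len(water_coords) == 0:
        raise ValueError("reference contains no water sites")
    protein_coords = np.asarray(protein_coords, dtype=float)
    if protein_heavy_mask is None:
        protein_heavy_mask = np.ones(len(protein_coords), dtype=bool)
    heavy_idx = np.flatnonzero(protein_heavy_mask)
    heavy_xyz = protein_coords[heavy_idx]
    sites = []
    for k, pos in enumerate(water_coords):
        d = np.linalg.norm(heavy_xyz - pos, axis=1)
        near = np.flatnonzero(d <= anchor_cutoff)
        idx = heavy_idx[near]
        sites.append(
            WaterSiteModel(
                site_id=k,
                position=pos.copy(),
                anchor_idx=idx,
                anchor_ref=protein_coords[idx].copy(),
                b_exp=float(b_exp[k]) if b_exp is not None else float("nan"),
                valid=len(idx) >= min_anchors,
            )
        )
    return sites


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors for a (possibly triclinic) box."""
    frac = delta @ np.linalg.inv(box).T
    frac -= np.round(frac)
    return frac @ box.T


def track_cws(
    protein_traj: np.ndarray,
    sites: list[WaterSiteModel],
    water_traj: np.ndarray | list[np.ndarray],
    occupancy_radius: float = 1.4,
    box: np.ndarray | None = None,
) -> list[SiteOccupancy]:
    """Follow each water site through a trajectory and score its occupancy.

    ``protein_traj`` has shape (n_frames, n_protein_atoms, 3); ``water_traj``
    is a per-frame array/list of water oxygen coordinates (NaN rows mark
    absent waters). With ``box`` given, water distances use the minimum-image
    convention.
    """
    protein_traj = np.asarray(protein_traj, dtype=float)
    n_frames = protein_traj.shape[0]
    if len(water_traj) != n_frames:
        raise ValueError("water_traj must provide one coordinate set per frame")
    for s in sites:
        if s.valid and s.anchor_idx.max(initial=-1) >= protein_traj.shape[1]:
            raise ValueError(f"site {s.site_id}: anchors missing from topology")
    out = []
    for s in sites:
        flags = np.zeros(n_frames, dtype=bool)
        if s.valid:
            for fi in range(n_frames):
                anchors_now = protein_traj[fi, s.anchor_idx]
                # local alignment: reference anchors -> current anchors
                rot, t, _ = kabsch_superpose(s.anchor_ref, anchors_now)
                site_now = rot @ s.position + t
                waters = np.atleast_2d(np.asarray(water_traj[fi], dtype=float))
                if waters.size == 0:
                    continue
                ok = ~np.isnan(waters).any(axis=1)
                if not ok.any():
                    continue
                delta = waters[ok] - site_now
                if box is not None:
                    delta = _min_image(delta, np.asarray(box, dtype=float))
                flags[fi] = bool(
                    (np.linalg.norm(delta, axis=1) <= occupancy_radius).any()
                )
        out.append(SiteOccupancy(s.site_id, flags, float(flags.mean())))
    return out


def preservation_summary(
    occupancies: list[SiteOccupancy] | list[list[SiteOccupancy]],
    sites: list[WaterSiteModel],
    occ_threshold: float = 0.5,
    b_bin_edges: np.ndarray | None = None,
) -> dict:
    """Overall preserved fraction (with replica st.dev.) and per-B-bin table.

    Accepts one occupancy list or one per replica. Sites flagged invalid at
    anchoring are excluded. The per-bin table groups sites by experimental
    B-factor, mirroring preserved-fraction-vs-confidence plots.
    """
    if len(occupancies) == 0:
        raise ValueError("empty occupancy input")
    if isinstance(occupancies[0], SiteOccupancy):
        replicas = [occupancies]
    else:
        replicas = list(occupancies)
    valid = {s.site_id for s in sites if s.valid}
    site_by_id = {s.site_id: s for s in sites}
    fractions = []
    for rep in replicas:
        kept = [o for o in rep if o.site_id in valid]
        if not kept:
            raise ValueError("no valid sites in occupancy input")
        fractions.append(np.mean([o.preserved(occ_threshold) for o in kept]))
    fractions = np.array(fractions)

    rows = []
    if b_bin_edges is not None:
        b_bin_edges = np.asarray(b_bin_edges, dtype=float)
        for lo, hi in zip(b_bin_edges[:-1], b_bin_edges[1:]):
            per_rep = []
            for rep in replicas:
                flags = [
                    o.preserved(occ_threshold)
                    for o in rep
                    if o.site_id in valid
                    and lo <= site_by_id[o.site_id].b_exp < hi
                ]
                if flags:
                    per_rep.append(np.mean(flags))
            rows.append(
                (
                    0.5 * (lo + hi),
                    np.mean(per_rep) if per_rep else float("nan"),
                    len(per_rep),
                )
            )
    table = pd.DataFrame(rows, columns=["b_bin_center", "fraction", "n_replicas"])
    return {
        "fraction": float(fractions.mean()),
        "replica_std": float(np.std(fractions, ddof=1))
        if len(fractions) > 1
        else float("nan"),
        "per_replica": fractions,
        "per_b_bin": table,
        "n_valid_sites": len(valid),
        "n_excluded_sites": len(sites) - len(valid),
    }
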