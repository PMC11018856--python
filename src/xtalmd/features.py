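"""Dihedral/distance featurization, PCA, LDA feature importance, and
rotamer-population tables.

Backbone (phi, psi) and side-chain (chi1, chi2) dihedrals are computed per
residue with the IUPAC atom quadruples and right-handed sign convention.
The sin/cos featurization maps each angle pair to four bounded features, so
93 Ramachandran + 60 Janin residues give a (93 + 60) * 2 * 2 = 612
dimensional vector per structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import TrajectoryEnsemble

__all__ = [
    "DihedralSet",
    "compute_dihedrals",
    "FeatureMatrix",
    "featurize_sincos",
    "featurize_ca_distances",
    "ProjectionModel",
    "pca_fit",
    "lda_importance",
    "RotamerTable",
    "rotamer_populations",
    "rotamer_state",
    "table_distance",
]

ROTAMER_STATES = ("g+", "t", "g-")

# first side-chain heavy atom beyond CB (chi1) / beyond the gamma atom (chi2)
_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")
_DELTA_ATOMS = ("CD", "CD1", "SD", "OD1", "ND1")


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral in degrees, range (-180, 180], right-handed.

    Accepts arrays broadcastable to (..., 3); collinear quadruples yield NaN.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    b1n = b1 / np.maximum(np.linalg.norm(b1, axis=-1, keepdims=True), 1e-30)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    bad = (norm1 < 1e-10) | (norm2 < 1e-10)
    return np.where(bad, np.nan, ang)


@dataclass
class DihedralSet:
    """Backbone and side-chain dihedrals of an ensemble.

    Angle arrays have shape (n_chains, n_frames, n_residues) in degrees;
    undefined angles (chain termini, missing side-chain atoms, collinear
    geometry) are NaN.
    """

    resid: np.ndarray
    resname: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    chi1: np.ndarray
    chi2: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.resid)

    def angles(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _atom_index(topology, resid: int, names: tuple[str, ...] | str) -> int | None:
    if isinstance(names, str):
        names = (names,)
    mask = topology.resid == resid
    for name in names:
        hits = np.flatnonzero(mask & (topology.atomname == name))
        if len(hits):
            return int(hits[0])
    return None


def compute_dihedrals(ens: TrajectoryEnsemble) -> DihedralSet:
    """Per-chain, per-frame phi/psi/chi1/chi2 for every residue.

    phi(i) = C(i-1)-N-CA-C, psi(i) = N-CA-C-N(i+1); chi1 = N-CA-CB-G and
    chi2 = CA-CB-G-D with G/D the first gamma/delta heavy atom present.
    Terminal residues lack phi or psi; residues without the required atoms
    get NaN.
    """
    top = ens.topology
    residues = top.residues
    n_res = len(residues)
    shape = (ens.n_chains, ens.n_frames, n_res)
    out = {k: np.full(shape, np.nan) for k in ("phi", "psi", "chi1", "chi2")}
    resnames = np.empty(n_res, dtype=object)
    idx = {}
    for r in residues:
        idx[r] = {
            "N": _atom_index(top, r, "N"),
            "CA": _atom_index(top, r, "CA"),
            "C": _atom_index(top, r, "C"),
            "G": _atom_index(top, r, _GAMMA_ATOMS),
            "D": _atom_index(top, r, _DELTA_ATOMS),
        }
    for ri, r in enumerate(residues):
        resnames[ri] = top.resname[top.resid == r][0]
        a = idx[r]
        prev_c = idx[residues[ri - 1]]["C"] if ri > 0 else None
        next_n = idx[residues[ri + 1]]["N"] if ri < n_res - 1 else None
        c = ens.coords  # (chains, frames, atoms, 3)
        if None not in (prev_c, a["N"], a["CA"], a["C"]):
            out["phi"][:, :, ri] = dihedral_angle(
                c[:, :, prev_c], c[:, :, a["N"]], c[:, :, a["CA"]], c[:, :, a["C"]]
            )
        if None not in (a["N"], a["CA"], a["C"], next_n):
            out["psi"][:, :, ri] = dihedral_angle(
                c[:, :, a["N"]], c[:, :, a["CA"]], c[:, :, a["C"]], c[:, :, next_n]
            )
        cb = _atom_index(top, r, "CB")
        if None not in (a["N"], a["CA"], cb, a["G"]):
            out["chi1"][:, :, ri] = dihedral_angle(
                c[:, :, a["N"]], c[:, :, a["CA"]], c[:, :, cb], c[:, :, a["G"]]
            )
        if None not in (a["CA"], cb, a["G"], a["D"]):
            out["chi2"][:, :, ri] = dihedral_angle(
                c[:, :, a["CA"]], c[:, :, cb], c[:, :, a["G"]], c[:, :, a["D"]]
            )
    return DihedralSet(residues, resnames, **out)


@dataclass
class FeatureMatrix:
    """Samples x features with deterministic labels and per-sample metadata."""

    X: np.ndarray
    feature_labels: list[str]
    group: np.ndarray | None = None  # per-sample group label
    source: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains undefined entries")
        if self.X.shape[1] != len(self.feature_labels):
            raise ValueError("feature label count mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def featurize_sincos(
    dihedrals: DihedralSet,
    rama_resids: np.ndarray,
    janin_resids: np.ndarray,
    group: str | None = None,
) -> FeatureMatrix:
    """Sin/cos features of (phi, psi) and (chi1, chi2) angle pairs.

    Feature order is residue-major, angle order (phi, psi) then (chi1,
    chi2), sin before cos; width = (nR + nJ) * 2 * 2. A masked residue with
    an undefined angle is an error (invalid mask).
    """
    rama_resids = np.asarray(rama_resids)
    janin_resids = np.asarray(janin_resids)
    cols, labels = [], []
    for resids, pair in ((rama_resids, ("phi", "psi")), (janin_resids, ("chi1", "chi2"))):
        pos = {r: i for i, r in enumerate(dihedrals.resid)}
        for r in resids:
            if r not in pos:
                raise ValueError(f"residue {r} absent from dihedral set")
            ri = pos[r]
            for ang in pair:
                vals = dihedrals.angles(ang)[:, :, ri].reshape(-1)
                if np.isnan(vals).any():
                    raise ValueError(
                        f"residue {r}: {ang} undefined; mask is invalid"
                    )
                rad = np.radians(vals)
                cols.append(np.sin(rad))
                labels.append(f"sin({ang}[{r}])")
                cols.append(np.cos(rad))
                labels.append(f"cos({ang}[{r}])")
    X = np.column_stack(cols)
    n_chains, n_frames = dihedrals.phi.shape[:2]
    source = pd.DataFrame(
        {
            "chain": np.repeat(np.arange(n_chains), n_frames),
            "frame": np.tile(np.arange(n_frames), n_chains),
        }
    )
    grp = np.full(X.shape[0], group) if group is not None else None
    return FeatureMatrix(X, labels, grp, source)


def featurize_ca_distances(
    ens: TrajectoryEnsemble,
    exclude_resids: tuple | list = (),
    group: str | None = None,
) -> FeatureMatrix:
    """All unordered pairwise C-alpha distances among included residues."""
    ca = ens.topology.calpha
    resid = ens.topology.resid[ca]
    keep = ~np.isin(resid, np.asarray(exclude_resids))
    kept_resids = resid[keep]
    n = keep.sum()
    if n < 2:
        raise ValueError("need at least 2 included residues")
    ii, jj = np.triu_indices(n, k=1)
    labels = [f"d(CA{kept_resids[i]}-CA{kept_resids[j]})" for i, j in zip(ii, jj)]
    frames = ens.coords[:, :, ca][:, :, keep].reshape(-1, n, 3)
    X = np.array([pdist(fr) for fr in frames])
    grp = np.full(X.shape[0], group) if group is not None else None
    return FeatureMatrix(X, labels, grp)


@dataclass
class ProjectionModel:
    """A fitted linear projection (PCA or LDA) with recorded feature order."""

    kind: str
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    feature_labels: list[str]
    scale: np.ndarray | None = None  # per-feature standardization (LDA)

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scale is not None:
            X = X / self.scale
        return (X - self.mean) @ self.components.T

    def top_loadings(self, component: int = 0, n: int = 10) -> pd.DataFrame:
        load = self.components[component]
        order = np.argsort(-np.abs(load))[:n]
        return pd.DataFrame(
            {
                "feature": [self.feature_labels[i] for i in order],
                "loading": load[order],
            }
        )


def pca_fit(
    fm: FeatureMatrix, n_components: int = 2
) -> tuple[ProjectionModel, np.ndarray]:
    """Mean-centered PCA; components ordered by explained variance."""
    if np.allclose(fm.X.var(axis=0), 0.0):
        raise ValueError("zero-variance input")
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(fm.X)
    model = ProjectionModel(
        "pca",
        pca.mean_,
        pca.components_,
        pca.explained_variance_ratio_,
        list(fm.feature_labels),
    )
    return model, proj


def lda_importance(
    fm: FeatureMatrix, n_components: int | None = None
) -> tuple[ProjectionModel, np.ndarray, np.ndarray]:
    """LDA on pooled-variance-standardized features; per-feature importance.

    Features are divided by the pooled within-group standard deviation
    before fitting; features with zero pooled within-group variance fall
    back to the global standard deviation and are flagged. Importance is the
    absolute discriminant coefficient (L2 norm over discriminant axes for
    more than two groups).
    """
    if fm.group is None:
        raise ValueError("feature matrix carries no group labels")
    groups = np.unique(fm.group)
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    for g in groups:
        if (fm.group == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    n_total = fm.n_samples
    pooled_var = np.zeros(fm.n_features)
    for g in groups:
        xg = fm.X[fm.group == g]
        pooled_var += (len(xg) - 1) * xg.var(axis=0, ddof=1)
    pooled_var /= n_total - len(groups)
    flagged = pooled_var <= 1e-30
    scale = np.sqrt(np.where(flagged, fm.X.var(axis=0, ddof=1), pooled_var))
    scale = np.where(scale <= 1e-30, 1.0, scale)
    Xs = fm.X / scale
    lda = LinearDiscriminantAnalysis(n_components=n_components)
    lda.fit(Xs, fm.group)
    coef = np.atleast_2d(lda.scalings_.T)  # discriminant axes x features
    importance = np.linalg.norm(coef, axis=0)
    ev = getattr(lda, "explained_variance_ratio_", np.array([]))
    model = ProjectionModel(
        "lda",
        Xs.mean(axis=0),
        coef,
        ev,
        list(fm.feature_labels),
        scale=scale,
    )
    return model, importance, flagged


def rotamer_state(angle: float | np.ndarray) -> np.ndarray:
    """Rotamer state index from a chi angle in (-180, 180] degrees.

    0 = g+ ([0, 120)), 1 = t ([120, 180] and (-180, -120)), 2 = g-
    ([-120, 0)).
    """
    a = np.asarray(angle, dtype=float)
    state = np.full(a.shape, -1, dtype=int)
    state[(a >= 0) & (a < 120)] = 0
    state[(a >= 120) | (a < -120)] = 1
    state[(a >= -120) & (a < 0)] = 2
    return state


@dataclass
class RotamerTable:
    """3x3 chi1 x chi2 rotamer-state populations with replica SE."""

    populations: np.ndarray  # (3, 3), sums to 1
    se: np.ndarray  # (3, 3)
    n_samples: int
    label: str = ""

    def __post_init__(self) -> None:
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("rotamer populations must sum to 1")


def rotamer_populations(
    dihedrals: DihedralSet | list[DihedralSet],
    resname: str | None = None,
    resids: np.ndarray | None = None,
    label: str = "",
) -> RotamerTable:
    """chi1 x chi2 rotamer-state table over selected residues.

    Accepts one DihedralSet or one per replica; the SE is the standard error
    of the per-replica tables. Selection is by residue type (``resname``),
    explicit ``resids``, or both.
    """
    reps = dihedrals if isinstance(dihedrals, list) else [dihedrals]
    tables = []
    n_total = 0
    for ds in reps:
        sel = np.ones(ds.n_residues, dtype=bool)
        if resname is not None:
            sel &= np.asarray([rn == resname for rn in ds.resname])
        if resids is not None:
            sel &= np.isin(ds.resid, np.asarray(resids))
        chi1 = ds.chi1[:, :, sel].reshape(-1)
        chi2 = ds.chi2[:, :, sel].reshape(-1)
        ok = ~(np.isnan(chi1) | np.isnan(chi2))
        chi1, chi2 = chi1[ok], chi2[ok]
        if len(chi1) == 0:
            raise ValueError("empty rotamer selection")
        s1 = rotamer_state(chi1)
        s2 = rotamer_state(chi2)
        t = np.zeros((3, 3))
        np.add.at(t, (s1, s2), 1.0)
        tables.append(t / t.sum())
        n_total += len(chi1)
    tables = np.array(tables)
    pop = tables.mean(axis=0)
    pop = pop / pop.sum()
    se = (
        tables.std(axis=0, ddof=1) / np.sqrt(len(tables))
        if len(tables) > 1
        else np.zeros((3, 3))
    )
    return RotamerTable(pop, se, n_total, label)


def table_distance(t1: RotamerTable, t2: RotamerTable) -> float:
    """Total variation distance between two rotamer tables, in [0, 1]."""
    return float(0.5 * np.abs(t1.populations - t2.populations).sum())
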