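"""Structural accuracy and equilibration metrics.

Superposition (Kabsch), RMSD/MSD deviation metrics, iterative mean
structure, fraction of native contacts Q, lattice/chain B-factor
decomposition, scalar covariance with its distance decay, and the
two-condition equilibration check (per-replica plateau and replica
agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import TrajectoryEnsemble

__all__ = [
    "kabsch_superpose",
    "superpose_frames",
    "deviation_metrics",
    "mean_structure",
    "ContactSet",
    "build_contact_set",
    "native_contacts_q",
    "BFactorProfile",
    "bfactors",
    "CovarianceDecay",
    "covariance_analysis",
    "EquilibrationReport",
    "equilibration_check",
]

B_FROM_RMSF2 = 8.0 * np.pi**2 / 3.0  # B = (8 pi^2 / 3) RMSF^2


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation + translation of ``mobile`` onto ``target``.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` minimizes the
    (weighted) least-squares deviation from ``target``. Reflections are
    forbidden (det R = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both have shape (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("at least 3 atoms required for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mu_m = w @ mobile
    mu_t = w @ target
    x = mobile - mu_m
    y = target - mu_t
    sv = np.linalg.svd(x * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1e-30):
        raise ValueError("selection is collinear; rotation is undetermined")
    h = x.T @ (y * w[:, None])
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_t - rot @ mu_m
    aligned = x @ rot.T + mu_t
    rmsd = float(np.sqrt(np.sum(w[:, None] * (aligned - target) ** 2)))
    return rot, t, rmsd


def superpose_frames(
    frames: np.ndarray,
    target: np.ndarray,
    fit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose each frame onto ``target``, fitting on ``fit_mask`` atoms.

    ``frames`` has shape (n_frames, n_atoms, 3); the returned array has the
    same shape with the fitted transform applied to all atoms.
    """
    frames = np.asarray(frames, dtype=float)
    if fit_mask is None:
        fit_mask = np.ones(frames.shape[1], dtype=bool)
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        rot, t, _ = kabsch_superpose(fr[fit_mask], target[fit_mask])
        out[i] = fr @ rot.T + t
    return out


@dataclass
class DeviationResult:
    """Time-resolved RMSD or per-residue MSD of an ensemble vs a reference."""

    mode: str
    selection: str
    table: pd.DataFrame
    trailing_mean: float | None = None  # <RMSD> over the trailing window


def deviation_metrics(
    ens: TrajectoryEnsemble,
    ref_coords: np.ndarray,
    mode: str = "rmsd_time",
    selection: str = "heavy",
    trailing_fraction: float = 0.2,
) -> DeviationResult:
    """Per-chain RMSD time series or per-residue mean squared deviation.

    Each chain is superposed onto the reference on ``selection`` before
    measuring. ``rmsd_time`` returns mean +/- st.dev. across chains per
    frame plus the mean over the trailing ``trailing_fraction`` of frames;
    ``msd_residue`` returns one value per residue (C-alpha), averaged over
    chains and frames.
    """
    if mode not in ("rmsd_time", "msd_residue"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = ens.topology.selection_mask(selection)
    ref = np.asarray(ref_coords, dtype=float)
    if mode == "rmsd_time":
        rmsds = np.empty((ens.n_chains, ens.n_frames))
        for ci in range(ens.n_chains):
            for fi in range(ens.n_frames):
                _, _, rmsds[ci, fi] = kabsch_superpose(
                    ens.coords[ci, fi, sel], ref[sel]
                )
        table = pd.DataFrame(
            {
                "frame_ns": ens.frame_times,
                "rmsd_mean": rmsds.mean(axis=0),
                "rmsd_std": rmsds.std(axis=0),
            }
        )
        n_tail = max(1, int(round(trailing_fraction * ens.n_frames)))
        return DeviationResult(
            mode, selection, table, trailing_mean=float(rmsds[:, -n_tail:].mean())
        )
    # msd_residue: squared C-alpha deviation after superposition on `selection`
    ca = ens.topology.calpha
    ca_resids = ens.topology.resid[ca]
    sq = np.zeros(ca.sum())
    count = 0
    for ci in range(ens.n_chains):
        aligned = superpose_frames(ens.coords[ci], ref, fit_mask=sel)
        sq += ((aligned[:, ca] - ref[ca]) ** 2).sum(axis=2).mean(axis=0)
        count += 1
    table = pd.DataFrame({"resid": ca_resids, "msd": sq / count})
    return DeviationResult(mode, selection, table)


def mean_structure(
    ens: TrajectoryEnsemble,
    selection: str = "heavy",
    ref_coords: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, int, float | None]:
    """Iteratively superposed ensemble-average structure.

    All chain-frames are superposed onto the current mean (fitting on
    ``selection``), the mean is recomputed, and the loop repeats until the
    mean moves by less than ``tol`` Angstrom (RMSD between successive means).
    Returns (mean_coords, n_iterations, rmsd_to_reference_or_None).
    """
    if ens.n_chains * ens.n_frames < 2:
        raise ValueError("at least 2 structures required")
    sel = ens.topology.selection_mask(selection)
    frames = ens.coords.reshape(-1, ens.n_atoms, 3)
    mean = frames[0].copy()
    for it in range(1, max_iter + 1):
        aligned = superpose_frames(frames, mean, fit_mask=sel)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < tol:
            break
    else:
        raise RuntimeError(
            f"mean structure did not converge in {max_iter} iterations "
            f"(last shift {shift:.2e} A)"
        )
    rmsd_ref = None
    if ref_coords is not None:
        _, _, rmsd_ref = kabsch_superpose(
            mean[sel], np.asarray(ref_coords)[sel]
        )
    return mean, it, rmsd_ref


@dataclass
class ContactSet:
    """Native heavy-atom contacts of a reference structure."""

    atom_i: np.ndarray
    atom_j: np.ndarray
    ref_dist: np.ndarray

    def __len__(self) -> int:
        return len(self.atom_i)


def build_contact_set(
    ref_coords: np.ndarray,
    topology,
    cutoff: float = 4.5,
    min_seq_sep: int = 4,
) -> ContactSet:
    """Heavy-atom pairs closer than ``cutoff`` between residues separated by
    at least ``min_seq_sep`` in sequence."""
    heavy = np.flatnonzero(topology.heavy)
    xyz = np.asarray(ref_coords)[heavy]
    resid = topology.resid[heavy]
    ai, aj, dd = [], [], []
    # chunked pair scan keeps memory modest for supercell-sized inputs
    for a in range(len(heavy)):
        d = np.linalg.norm(xyz[a + 1 :] - xyz[a], axis=1)
        ok = (d < cutoff) & (np.abs(resid[a + 1 :] - resid[a]) >= min_seq_sep)
        idx = np.flatnonzero(ok) + a + 1
        ai.extend([heavy[a]] * len(idx))
        aj.extend(heavy[idx])
        dd.extend(d[idx - a - 1])
    return ContactSet(np.array(ai, int), np.array(aj, int), np.array(dd, float))


def native_contacts_q(
    frame_coords: np.ndarray,
    contacts: ContactSet,
    tolerance_factor: float = 1.2,
) -> float:
    """Fraction of native contacts preserved in one frame.

    A contact is preserved when its instantaneous distance is at most
    ``tolerance_factor`` times the reference distance.
    """
    if len(contacts) == 0:
        raise ValueError("empty contact set")
    xyz = np.asarray(frame_coords)
    d = np.linalg.norm(xyz[contacts.atom_i] - xyz[contacts.atom_j], axis=1)
    return float(np.mean(d <= tolerance_factor * contacts.ref_dist))


@dataclass
class BFactorProfile:
    """Per-C-alpha B-factors, B = (8 pi^2 / 3) RMSF^2.

    ``lattice`` mode measures fluctuations after one global superposition of
    each whole supercell frame (includes rigid-body chain motion);
    ``chain`` mode superposes each chain onto its own mean first (internal
    fluctuations only).
    """

    mode: str
    resid: np.ndarray
    b: np.ndarray  # Angstrom^2
    rmsf_sq: np.ndarray  # Angstrom^2
    pearson_r: float | None = None


def bfactors(
    ens: TrajectoryEnsemble,
    mode: str = "lattice",
    ref_coords: np.ndarray | None = None,
    experimental_b: np.ndarray | None = None,
) -> BFactorProfile:
    """Lattice or chain B-factor profile over C-alpha atoms."""
    if mode not in ("lattice", "chain"):
        raise ValueError(f"unknown mode {mode!r}")
    if ens.n_frames < 2:
        raise ValueError("B-factors require at least 2 frames")
    ca = ens.topology.calpha
    resid = ens.topology.resid[ca]
    if mode == "lattice":
        frames = ens.supercell_frames()
        fit = np.tile(ca, ens.n_chains)
        target = frames[0] if ref_coords is None else np.asarray(ref_coords)
        aligned = superpose_frames(frames, target, fit_mask=fit)
        per_chain = aligned.reshape(ens.n_frames, ens.n_chains, ens.n_atoms, 3)
        dev = per_chain - per_chain.mean(axis=0, keepdims=True)
        # (frames, chains, ca) squared displacement, averaged over time+chains
        rmsf_sq = (dev[:, :, ca] ** 2).sum(axis=3).mean(axis=(0, 1))
    else:
        acc = np.zeros(ca.sum())
        for ci in range(ens.n_chains):
            chain_ens = TrajectoryEnsemble(
                ens.coords[ci : ci + 1],
                ens.topology,
                ens.frame_times,
                replica_id=ens.replica_id,
            )
            mean, _, _ = mean_structure(chain_ens, selection="calpha")
            aligned = superpose_frames(ens.coords[ci], mean, fit_mask=ca)
            dev = aligned - aligned.mean(axis=0, keepdims=True)
            acc += (dev[:, ca] ** 2).sum(axis=2).mean(axis=0)
        rmsf_sq = acc / ens.n_chains
    b = B_FROM_RMSF2 * rmsf_sq
    r = None
    if experimental_b is not None:
        exp = np.asarray(experimental_b, dtype=float)
        r = float(np.corrcoef(b, exp)[0, 1])
    return BFactorProfile(mode, resid, b, rmsf_sq, r)


@dataclass
class CovarianceDecay:
    """Scalar C-alpha covariance vs distance with an exponential-decay fit.

    ``amplitude``/``decay_length`` come from a projection-aware fit: the
    exponential kernel A*exp(-d/ell) is pushed through the same rigid-mode
    (translation/rotation) removal the per-chain superposition applies
    before comparing with the measured bin means, so the recovered ell is
    not biased by the alignment. ``raw_amplitude``/``raw_decay_length``
    report the plain exponential fit to the bin means for reference.
    """

    covariance: np.ndarray  # (n_ca, n_ca), Angstrom^2
    bin_centers: np.ndarray  # Angstrom
    bin_means: np.ndarray  # Angstrom^2
    amplitude: float  # per-axis kernel amplitude, Angstrom^2
    decay_length: float  # ell, Angstrom
    raw_amplitude: float
    raw_decay_length: float
    residual_rms: float
    degenerate: bool = False


def _rigid_mode_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid modes of a point set, shape (3n, 6)."""
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    modes = np.zeros((3 * n, 6))
    for a in range(3):
        modes[a::3, a] = 1.0  # translations
    for a, axis in enumerate(np.eye(3)):
        modes[:, 3 + a] = np.cross(np.tile(axis, (n, 1)), centered).reshape(-1)
    q, _ = np.linalg.qr(modes)
    return q


def covariance_analysis(
    ens: TrajectoryEnsemble,
    bin_width: float = 2.0,
    min_frames: int = 100,
) -> CovarianceDecay:
    """Internal-motion covariance of C-alpha atoms and its distance decay.

    Each chain is superposed onto its own mean (removing rigid-body motion),
    then C_ij = <dr_i . dr_j> is accumulated over chains and frames. Pairs
    are binned by their mean inter-atomic distance (``bin_width`` Angstrom
    bins). The decay length is obtained by fitting A*exp(-d/ell) pushed
    through the rigid-mode projection that the superposition applies
    (see :class:`CovarianceDecay`); the uncorrected exponential fit is
    returned alongside.
    """
    if ens.n_frames < min_frames:
        raise ValueError(f"need at least {min_frames} frames")
    ca = ens.topology.calpha
    n_ca = int(ca.sum())
    cov = np.zeros((n_ca, n_ca))
    mca0 = None
    for ci in range(ens.n_chains):
        chain_ens = TrajectoryEnsemble(
            ens.coords[ci : ci + 1], ens.topology, ens.frame_times
        )
        mean, _, _ = mean_structure(chain_ens, selection="calpha")
        aligned = superpose_frames(ens.coords[ci], mean, fit_mask=ca)
        dev = aligned[:, ca] - aligned[:, ca].mean(axis=0, keepdims=True)
        cov += np.einsum("fik,fjk->ij", dev, dev) / ens.n_frames
        if mca0 is None:
            mca0 = aligned[:, ca].mean(axis=0)
    cov /= ens.n_chains
    dist = np.linalg.norm(mca0[:, None] - mca0[None, :], axis=2)

    iu_mask = np.triu(np.ones((n_ca, n_ca), dtype=bool), k=1)
    edges = np.arange(0.0, dist[iu_mask].max() + bin_width, bin_width)
    centers, means, bin_assign = [], [], []
    for b in range(len(edges) - 1):
        sel = iu_mask & (dist >= edges[b]) & (dist < edges[b + 1])
        if sel.sum() > 0:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(cov[sel].mean())
            bin_assign.append(sel)
    centers = np.array(centers)
    means = np.array(means)

    # degenerate when off-diagonal covariance is negligible against the
    # diagonal (per-atom variance) level, as for independent noise
    diag_level = float(np.mean(np.diag(cov)))
    degenerate = bool(
        np.all(means <= 0) or means.max() < max(0.1 * diag_level, 1e-12)
    )
    if degenerate:
        return CovarianceDecay(
            cov, centers, means, 0.0, float("nan"), 0.0, float("nan"),
            float("nan"), True,
        )

    rigid_q = _rigid_mode_basis(mca0)

    def model_bins(ell: float) -> np.ndarray:
        k3 = np.kron(np.exp(-dist / ell), np.eye(3))
        qtk = rigid_q.T @ k3
        kproj = (
            k3
            - rigid_q @ qtk
            - qtk.T @ rigid_q.T
            + rigid_q @ (qtk @ rigid_q) @ rigid_q.T
        )
        scalar = np.trace(
            kproj.reshape(n_ca, 3, n_ca, 3), axis1=1, axis2=3
        )
        return np.array([scalar[sel].mean() for sel in bin_assign])

    def cost(ell: float) -> tuple[float, float]:
        mb = model_bins(ell)
        denom = float(mb @ mb)
        a = float(mb @ means) / denom if denom > 0 else 0.0
        a = max(a, 0.0)
        resid = means - a * mb
        return float(resid @ resid), a

    from scipy.optimize import minimize_scalar

    d_max = float(centers.max())
    res = minimize_scalar(
        lambda e: cost(e)[0], bounds=(0.25, 2.0 * d_max), method="bounded",
        options={"xatol": 1e-3},
    )
    ell = float(res.x)
    sse, a = cost(ell)

    # reference: plain exponential fit to the bin means
    try:
        popt, _ = curve_fit(
            lambda d, a0, e0: a0 * np.exp(-d / e0),
            centers,
            means,
            p0=(max(means.max(), 1e-3), max(d_max / 4, 1.0)),
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
        raw_a, raw_ell = float(popt[0]), float(popt[1])
    except RuntimeError:
        raw_a, raw_ell = float("nan"), float("nan")

    return CovarianceDecay(
        cov, centers, means, a, ell, raw_a, raw_ell,
        float(np.sqrt(sse / len(means))),
    )


@dataclass
class EquilibrationReport:
    """Two-condition equilibration verdict for a set of replicas.

    Condition (i): every replica's observable has reached a plateau (the
    trailing-window least-squares slope is within 2 SE of zero, block-
    bootstrap SE). Condition (ii): trailing-window means of all replicas
    agree pairwise within 2x the pooled SE.
    """

    window_means: np.ndarray
    window_se: np.ndarray
    slopes: np.ndarray
    slope_se: np.ndarray
    plateau: bool
    replicas_agree: bool

    @property
    def equilibrated(self) -> bool:
        return self.plateau and self.replicas_agree


def _block_bootstrap(values: np.ndarray, stat, n_boot: int, rng) -> float:
    """Moving-block bootstrap SE of a statistic of a time series."""
    n = len(values)
    block = max(2, int(round(np.sqrt(n))))
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block
    stats = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        resampled = np.concatenate([values[s : s + block] for s in starts])[:n]
        stats[b] = stat(resampled)
    return float(np.std(stats, ddof=1))


def equilibration_check(
    series: list[np.ndarray] | np.ndarray,
    window_fraction: float = 0.5,
    n_boot: int = 200,
    seed: int = 0,
) -> EquilibrationReport:
    """Check convergence of an observable across simulation replicas."""
    series = [np.asarray(s, dtype=float) for s in series]
    if len(series) < 2:
        raise ValueError("at least 2 replicas required")
    if any(len(s) < 20 for s in series):
        raise ValueError("each replica needs at least 20 points")
    rng = np.random.default_rng(seed)
    means, mean_se, slopes, slope_se = [], [], [], []
    for s in series:
        n_w = int(round(window_fraction * len(s)))
        if n_w < 5:
            raise ValueError("trailing window shorter than 5 points")
        w = s[-n_w:]
        t = np.arange(n_w, dtype=float)
        means.append(w.mean())
        mean_se.append(_block_bootstrap(w, np.mean, n_boot, rng))
        slope = np.polyfit(t, w, 1)[0]
        slopes.append(slope)
        slope_se.append(
            _block_bootstrap(
                w, lambda v: np.polyfit(np.arange(len(v), dtype=float), v, 1)[0],
                n_boot, rng,
            )
        )
    means = np.array(means)
    mean_se = np.array(mean_se)
    slopes = np.array(slopes)
    slope_se = np.array(slope_se)
    plateau = bool(np.all(np.abs(slopes) <= 2.0 * slope_se))
    agree = True
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            pooled = np.sqrt(mean_se[i] ** 2 + mean_se[j] ** 2)
            if abs(means[i] - means[j]) > 2.0 * pooled:
                agree = False
    return EquilibrationReport(means, mean_se, slopes, slope_se, plateau, agree)
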