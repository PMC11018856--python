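"""Per-residue deviation profiles and their correlation.

The thermal-deviation profile of a simulated ensemble (mean C-alpha
deviation over randomly sampled structure pairs) is compared with the
ligand-induced deviation profile built from apo/holo crystal-structure
pairs of homologous domains; a strong correlation indicates that
equilibrium motions align with functional, ligand-induced conformational
changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .metrics import kabsch_superpose

__all__ = [
    "DeviationProfile",
    "HomologPair",
    "ensemble_deviation_profile",
    "ligand_induced_profile",
    "profile_correlation",
]


@dataclass
class DeviationProfile:
    """Mean C-alpha deviation per residue (Angstrom), reference numbering."""

    resid: np.ndarray
    deviation: np.ndarray  # NaN where coverage is 0
    coverage: np.ndarray  # pairs contributing per residue
    n_pairs: int


@dataclass
class HomologPair:
    """An apo/holo structure pair with residue mapping to the reference."""

    apo_ca: np.ndarray  # (m, 3)
    holo_ca: np.ndarray  # (m, 3)
    resid: np.ndarray  # (m,) reference numbering of the mapped residues

    def __post_init__(self) -> None:
        self.apo_ca = np.asarray(self.apo_ca, dtype=float)
        self.holo_ca = np.asarray(self.holo_ca, dtype=float)
        self.resid = np.asarray(self.resid, dtype=int)
        if not (len(self.apo_ca) == len(self.holo_ca) == len(self.resid)):
            raise ValueError("apo, holo and mapping must have equal length")


def _pair_deviation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    rot, t, _ = kabsch_superpose(b, a)
    return np.linalg.norm(b @ rot.T + t - a, axis=1)


def ensemble_deviation_profile(
    structures: np.ndarray,
    resid: np.ndarray | None = None,
    n_pairs: int | None = 2000,
    seed: int = 0,
) -> DeviationProfile:
    """Mean per-residue C-alpha deviation over sampled structure pairs.

    ``structures`` has shape (n_structures, n_residues, 3) (C-alpha only).
    Pairs are sampled uniformly with replacement (self-pairs excluded),
    each pair is superposed on all C-alpha, and per-residue deviations are
    averaged. ``n_pairs=None`` enumerates all unordered pairs exactly.
    """
    structures = np.asarray(structures, dtype=float)
    n = len(structures)
    if n < 2:
        raise ValueError("need at least 2 structures")
    n_res = structures.shape[1]
    if resid is None:
        resid = np.arange(n_res)
    if n_pairs is None:
        pairs = list(combinations(range(n), 2))
    else:
        rng = np.random.default_rng(seed)
        pairs = []
        while len(pairs) < n_pairs:
            i, j = rng.integers(0, n, size=2)
            if i != j:
                pairs.append((int(i), int(j)))
    acc = np.zeros(n_res)
    for i, j in pairs:
        acc += _pair_deviation(structures[i], structures[j])
    dev = acc / len(pairs)
    return DeviationProfile(
        np.asarray(resid), dev, np.full(n_res, len(pairs)), len(pairs)
    )


def ligand_induced_profile(
    pairs: list[HomologPair],
    ref_resids: np.ndarray | None = None,
) -> DeviationProfile:
    """Mean ligand-induced C-alpha deviation across apo/holo pairs.

    Per pair, the holo structure is superposed onto the apo structure on
    all mapped C-alpha and per-residue deviations are recorded on the
    reference numbering. Residues missing from a pair are averaged over the
    pairs that cover them; residues covered by no pair appear with
    coverage 0 and NaN deviation, never as zeros.
    """
    if not pairs:
        raise ValueError("no homolog pairs supplied")
    usable = [p for p in pairs if len(p.resid) >= 3]
    if not usable:
        raise ValueError("no pair with at least 3 mapped residues")
    if ref_resids is None:
        ref_resids = np.unique(np.concatenate([p.resid for p in usable]))
    ref_resids = np.asarray(ref_resids, dtype=int)
    acc = np.zeros(len(ref_resids))
    cov = np.zeros(len(ref_resids), dtype=int)
    pos = {r: i for i, r in enumerate(ref_resids)}
    for p in usable:
        dev = _pair_deviation(p.apo_ca, p.holo_ca)
        for r, d in zip(p.resid, dev):
            if r in pos:
                acc[pos[r]] += d
                cov[pos[r]] += 1
    with np.errstate(invalid="ignore"):
        mean_dev = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    return DeviationProfile(ref_resids, mean_dev, cov, len(usable))


def profile_correlation(
    p1: DeviationProfile, p2: DeviationProfile
) -> dict:
    """Pearson correlation of two profiles over their shared residues."""
    shared, i1, i2 = np.intersect1d(p1.resid, p2.resid, return_indices=True)
    v1 = p1.deviation[i1]
    v2 = p2.deviation[i2]
    ok = np.isfinite(v1) & np.isfinite(v2)
    v1, v2 = v1[ok], v2[ok]
    if len(v1) < 3:
        raise ValueError("fewer than 3 shared residues with finite values")
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant profile; correlation undefined")
    r, p = stats.pearsonr(v1, v2)
    return {"r": float(r), "n": int(len(v1)), "p_value": float(p)}
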