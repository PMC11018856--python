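"""Loop-coordinate thermodynamics: distance distributions, free-energy
profiles, Shannon entropy, and state populations.

The reaction coordinate is a single inter-residue distance (the
Ser14-Gly78-style loop-opening distance). Its histogram p(x) (default 50
bins on [2, 18] Angstrom, bin width 0.32) yields the free energy
G(x) = -ln p(x) in kBT units and the entropy S = -sum p_i ln p_i.
Bootstrap errors resample whole chains, since frames within a chain are
autocorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrajectoryEnsemble

__all__ = [
    "DistanceDistribution",
    "FreeEnergyProfile",
    "StateDefinition",
    "DEFAULT_STATES",
    "distance_series",
    "histogram_distribution",
    "free_energy_profile",
    "shannon_entropy",
    "state_populations",
]

KB_KCAL = 0.0019872041  # kcal / (mol K)


def distance_series(
    ens: TrajectoryEnsemble,
    resid_pair: tuple[int, int],
    atom_name: str = "CA",
) -> np.ndarray:
    """Per-chain time series of one inter-residue atom distance (Angstrom).

    An internal coordinate: no alignment is applied. Returns shape
    (n_chains, n_frames).
    """
    top = ens.topology
    idx = []
    for r in resid_pair:
        hits = np.flatnonzero((top.resid == r) & (top.atomname == atom_name))
        if len(hits) == 0:
            raise ValueError(f"residue {r} has no atom {atom_name!r}")
        idx.append(int(hits[0]))
    delta = ens.coords[:, :, idx[0]] - ens.coords[:, :, idx[1]]
    return np.linalg.norm(delta, axis=2)


@dataclass
class DistanceDistribution:
    """Binned probability masses of a distance with bootstrap errors."""

    bin_edges: np.ndarray  # (n_bins + 1,), Angstrom, uniform
    p: np.ndarray  # probability mass per bin, sums to 1
    se: np.ndarray  # bootstrap SE per bin
    n_samples: int
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probability masses must sum to 1")
        if np.any(self.p < 0):
            raise ValueError("negative probability mass")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("bin edges must be strictly increasing and uniform")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _as_chain_samples(samples) -> list[np.ndarray]:
    if isinstance(samples, np.ndarray) and samples.ndim == 2:
        return [s for s in samples]
    if isinstance(samples, (list, tuple)) and len(samples) and np.ndim(samples[0]) == 1:
        return [np.asarray(s, dtype=float) for s in samples]
    return [np.asarray(samples, dtype=float).reshape(-1)]


def histogram_distribution(
    samples,
    n_bins: int = 50,
    range_: tuple[float, float] = (2.0, 18.0),
    n_boot: int = 5,
    seed: int = 0,
) -> DistanceDistribution:
    """Histogram estimator of a distance distribution with bootstrap SE.

    ``samples`` may be a flat array, a (n_chains, n_frames) array, or a list
    of per-chain arrays. When chain structure is present the bootstrap
    resamples whole chains; otherwise it resamples frames. Out-of-range
    samples are counted and reported but excluded from the masses.
    """
    chains = _as_chain_samples(samples)
    flat = np.concatenate(chains)
    if flat.size == 0:
        raise ValueError("empty sample set")
    lo, hi = range_
    edges = np.linspace(lo, hi, n_bins + 1)
    in_range = (flat >= lo) & (flat <= hi)
    n_out = int((~in_range).sum())
    if in_range.sum() == 0:
        raise ValueError("no samples inside the histogram range")

    def masses(values: np.ndarray) -> np.ndarray:
        v = values[(values >= lo) & (values <= hi)]
        counts, _ = np.histogram(v, bins=edges)
        return counts / max(counts.sum(), 1)

    p = masses(flat)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_bins))
    resample_chains = len(chains) > 1
    for b in range(n_boot):
        if resample_chains:
            pick = rng.integers(0, len(chains), size=len(chains))
            boot[b] = masses(np.concatenate([chains[i] for i in pick]))
        else:
            pick = rng.integers(0, flat.size, size=flat.size)
            boot[b] = masses(flat[pick])
    se = boot.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(n_bins)
    return DistanceDistribution(edges, p, se, int(in_range.sum()), n_out)


@dataclass
class FreeEnergyProfile:
    """G(x) = -ln p(x), in kBT units, shifted so the minimum is 0."""

    bin_centers: np.ndarray
    g_kbt: np.ndarray  # NaN where p = 0 (undefined, not zero)
    se_kbt: np.ndarray
    temperature: float

    @property
    def g_kcal_per_mol(self) -> np.ndarray:
        return self.g_kbt * KB_KCAL * self.temperature


def free_energy_profile(
    dist: DistanceDistribution, temperature: float = 289.0
) -> FreeEnergyProfile:
    """Free-energy profile of a binned distribution.

    Empty bins are undefined (NaN). Errors propagate as dG_i = dp_i / p_i.
    """
    if np.all(dist.p == 0):
        raise ValueError("all-zero distribution")
    with np.errstate(divide="ignore"):
        g = np.where(dist.p > 0, -np.log(np.where(dist.p > 0, dist.p, 1.0)), np.nan)
    g = g - np.nanmin(g)
    se = np.where(dist.p > 0, dist.se / np.where(dist.p > 0, dist.p, 1.0), np.nan)
    return FreeEnergyProfile(dist.bin_centers, g, se, temperature)


def shannon_entropy(dist: DistanceDistribution) -> dict:
    """Shannon entropy S = -sum_{p_i > 0} p_i ln p_i of the binned masses.

    Natural-log units. The bin count is reported alongside because the
    absolute value of this estimator depends on it (max = ln n_bins).
    """
    p = dist.p[dist.p > 0]
    return {
        "entropy": float(-(p * np.log(p)).sum()),
        "n_bins": len(dist.p),
    }


@dataclass
class StateDefinition:
    """Named distance intervals partitioning the reaction coordinate.

    ``intervals`` maps state name to [lo, hi); the default three-state rule
    (closed < 6.5, intermediate [6.5, 10), open >= 10 Angstrom) is a
    transparent fallback for ensembles without external cluster labels.
    """

    intervals: dict

    def assign(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        labels = np.full(x.shape, -1, dtype=int)
        for si, (lo, hi) in enumerate(self.intervals.values()):
            labels[(x >= lo) & (x < hi)] = si
        if np.any(labels < 0):
            bad = x[labels < 0]
            raise ValueError(
                f"{bad.size} samples outside all state intervals "
                f"(e.g. {bad.flat[0]:.3g}); rules must partition the domain"
            )
        return labels

    @property
    def names(self) -> list[str]:
        return list(self.intervals)


DEFAULT_STATES = StateDefinition(
    {"closed": (0.0, 6.5), "intermediate": (6.5, 10.0), "open": (10.0, np.inf)}
)


def state_populations(
    samples,
    rule: StateDefinition = DEFAULT_STATES,
    n_boot: int = 5,
    seed: int = 0,
) -> dict:
    """State populations of a distance sample with chain-bootstrap SE."""
    chains = _as_chain_samples(samples)
    flat = np.concatenate(chains)
    if flat.size == 0:
        raise ValueError("empty sample set")
    names = rule.names
    n_states = len(names)

    def pops(values: np.ndarray) -> np.ndarray:
        lab = rule.assign(values)
        return np.bincount(lab, minlength=n_states) / len(lab)

    p = pops(flat)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_states))
    resample_chains = len(chains) > 1
    for b in range(n_boot):
        if resample_chains:
            pick = rng.integers(0, len(chains), size=len(chains))
            boot[b] = pops(np.concatenate([chains[i] for i in pick]))
        else:
            pick = rng.integers(0, flat.size, size=flat.size)
            boot[b] = pops(flat[pick])
    se = boot.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(n_states)
    return {
        "states": names,
        "populations": p,
        "se": se,
        "n_samples": int(flat.size),
    }
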