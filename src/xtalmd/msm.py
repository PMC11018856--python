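"""Markov state models of crystal relaxation.

Microstate clustering, sliding-window transition counting at a lag,
maximum-likelihood transition-matrix estimation, spectral implied
timescales and stationary populations, crisp PCCA coarse-graining, and
GMRQ-style cross-validated scoring. Implied timescales follow
t_i = -tau / ln(lambda_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import MiniBatchKMeans

__all__ = [
    "DiscreteTrajectorySet",
    "TransitionModel",
    "CoarseGraining",
    "cluster_microstates",
    "transition_counts",
    "estimate_transition_matrix",
    "implied_timescale_scan",
    "pcca_coarse_grain",
    "gmrq_cv_score",
]


@dataclass
class DiscreteTrajectorySet:
    """Integer state sequences with a common frame interval."""

    dtrajs: list[np.ndarray]
    n_states: int
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.dtrajs = [np.asarray(d, dtype=int) for d in self.dtrajs]
        if any(len(d) == 0 for d in self.dtrajs):
            raise ValueError("empty discrete trajectory")
        for d in self.dtrajs:
            if d.min() < 0 or d.max() >= self.n_states:
                raise ValueError("state index out of range")


def cluster_microstates(
    coords: np.ndarray | list[np.ndarray],
    k: int,
    seed: int = 0,
    frame_interval_ns: float = 1.0,
) -> tuple[DiscreteTrajectorySet, np.ndarray]:
    """Mini-batch k-means microstate definition on projected coordinates.

    Deterministic for a given seed; assignment is to the nearest center
    with ties broken toward the lowest center index.
    """
    trajs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in (
        coords if isinstance(coords, list) else [coords]
    )]
    stacked = np.vstack(trajs)
    if not np.isfinite(stacked).all():
        raise ValueError("coordinates must be finite")
    n_distinct = len(np.unique(stacked, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3)
    km.fit(stacked)
    centers = km.cluster_centers_
    dtrajs = []
    for t in trajs:
        d2 = ((t[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        dtrajs.append(np.argmin(d2, axis=1))  # argmin breaks ties low-index
    return DiscreteTrajectorySet(dtrajs, k, frame_interval_ns), centers


def transition_counts(
    dtrajs: DiscreteTrajectorySet | list[np.ndarray],
    lag_frames: int,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition count matrix at a lag.

    Counts (t, t+lag) pairs within each trajectory; never across trajectory
    boundaries.
    """
    if isinstance(dtrajs, DiscreteTrajectorySet):
        seqs, n = dtrajs.dtrajs, dtrajs.n_states
    else:
        seqs = [np.asarray(d, dtype=int) for d in dtrajs]
        n = n_states if n_states is not None else max(d.max() for d in seqs) + 1
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    if lag_frames >= max(len(d) for d in seqs):
        raise ValueError("lag must be shorter than the longest trajectory")
    counts = np.zeros((n, n))
    for d in seqs:
        if len(d) > lag_frames:
            np.add.at(counts, (d[:-lag_frames], d[lag_frames:]), 1.0)
    return counts


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with its spectral summary."""

    lag_frames: int
    lag_ns: float
    counts: np.ndarray
    transition_matrix: np.ndarray
    eigenvalues: np.ndarray  # sorted by modulus, lambda_1 = 1
    stationary: np.ndarray
    timescales_frames: np.ndarray  # t_i = -lag/ln(lambda_i), i >= 2
    active_states: np.ndarray  # original state labels after trimming
    reversible: bool = False

    @property
    def timescales_ns(self) -> np.ndarray:
        return self.timescales_frames * (self.lag_ns / self.lag_frames)


def estimate_transition_matrix(
    counts: np.ndarray,
    lag_frames: int = 1,
    frame_interval_ns: float = 1.0,
    reversible: bool = False,
) -> TransitionModel:
    """Maximum-likelihood transition matrix from a count matrix.

    States with no counts are trimmed (recorded in ``active_states``). The
    default estimate is the row-normalized count matrix; the reversible
    option symmetrizes counts as (C + C^T)/2 first. An error is raised when
    the count graph splits into several closed communicating sets.
    """
    counts = np.asarray(counts, dtype=float)
    active = np.flatnonzero(counts.sum(axis=0) + counts.sum(axis=1) > 0)
    if len(active) == 0:
        raise ValueError("empty count matrix")
    c = counts[np.ix_(active, active)]
    n_comp, labels = connected_components(
        csr_matrix(c > 0), directed=True, connection="strong"
    )
    if n_comp > 1:
        # closed sets: strongly connected components with no outgoing edges
        closed = []
        for comp in range(n_comp):
            members = np.flatnonzero(labels == comp)
            outside = np.setdiff1d(np.arange(len(c)), members)
            if c[np.ix_(members, outside)].sum() == 0:
                closed.append(active[members].tolist())
        if len(closed) > 1:
            raise ValueError(
                f"count graph has {len(closed)} disjoint closed sets: {closed}"
            )
    if reversible:
        c = 0.5 * (c + c.T)
    rowsum = c.sum(axis=1)
    if np.any(rowsum == 0):
        # states with incoming but no outgoing counts cannot be normalized
        raise ValueError("states with no outgoing counts remain after trimming")
    t = c / rowsum[:, None]
    evals, evecs_l = np.linalg.eig(t.T)
    order = np.argsort(-np.abs(evals))
    evals = evals[order]
    evecs_l = evecs_l[:, order]
    pi = np.real(evecs_l[:, 0])
    pi = np.abs(pi) / np.abs(pi).sum()
    lam = np.real_if_close(evals, tol=1e6)
    timescales = np.full(len(lam) - 1, np.nan)
    for i, lv in enumerate(lam[1:]):
        if np.iscomplexobj(lv) and abs(np.imag(lv)) > 1e-12:
            continue
        lv = float(np.real(lv))
        if 0.0 < lv < 1.0:
            timescales[i] = -lag_frames / np.log(lv)
        elif lv >= 1.0:
            timescales[i] = np.inf
            warnings.warn(
                "eigenvalue >= 1 beyond the stationary one; "
                "implied timescale reported as infinite"
            )
    return TransitionModel(
        lag_frames,
        lag_frames * frame_interval_ns,
        counts,
        t,
        evals,
        pi,
        timescales,
        active,
        reversible,
    )


def implied_timescale_scan(
    dtrajs: DiscreteTrajectorySet,
    lags_frames: list[int],
    n_timescales: int = 1,
    reversible: bool = False,
) -> pd.DataFrame:
    """Implied timescales vs lag, with a flatness diagnostic.

    The flatness column is the relative change of the slowest timescale
    between successive lags; small values support the Markovian lag choice.
    """
    if len(lags_frames) < 2:
        raise ValueError("need at least 2 lags")
    rows = []
    for lag in lags_frames:
        counts = transition_counts(dtrajs, lag)
        model = estimate_transition_matrix(
            counts, lag, dtrajs.frame_interval_ns, reversible
        )
        ts = model.timescales_frames[:n_timescales]
        rows.append([lag, lag * dtrajs.frame_interval_ns, *ts])
    cols = ["lag_frames", "lag_ns"] + [f"t{i+2}_frames" for i in range(n_timescales)]
    df = pd.DataFrame(rows, columns=cols)
    t2 = df["t2_frames"].to_numpy()
    flat = np.full(len(df), np.nan)
    flat[1:] = np.abs(np.diff(t2)) / np.abs(t2[:-1])
    df["flatness"] = flat
    return df


@dataclass
class CoarseGraining:
    """Crisp micro-to-macro lumping of a transition model."""

    assignment: np.ndarray  # macro index per (active) microstate
    n_macro: int
    macro_transition_matrix: np.ndarray
    macro_populations: np.ndarray
    model: TransitionModel = field(repr=False, default=None)


def _pcca_crisp_assign(evecs: np.ndarray, n_macro: int) -> np.ndarray:
    """Crisp PCCA assignment from the simplex structure of eigenvectors.

    Uses the inner-simplex vertex search (Gram-Schmidt on eigenvector rows)
    followed by argmax membership — a deterministic simplification of PCCA+.
    """
    x = np.real(evecs[:, :n_macro]).copy()
    n = x.shape[0]
    idx = np.zeros(n_macro, dtype=int)
    ortho = x.copy()
    # first vertex: farthest row from the origin
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    v = ortho[idx[0]].copy()
    ortho -= v  # shift so the first vertex is the origin
    for m in range(1, n_macro):
        norms = np.linalg.norm(ortho, axis=1)
        idx[m] = int(np.argmax(norms))
        w = ortho[idx[m]].copy()
        wn = w / max(np.linalg.norm(w), 1e-30)
        ortho -= np.outer(ortho @ wn, wn)
    a = np.linalg.pinv(x[idx])
    chi = x @ a
    return np.argmax(chi, axis=1)


def pcca_coarse_grain(
    model: TransitionModel,
    n_macro: int,
    dtrajs: DiscreteTrajectorySet | None = None,
) -> CoarseGraining:
    """Lump microstates into metastable macrostates (crisp PCCA).

    Macro populations are sums of the microstate stationary distribution.
    The macro transition matrix is re-counted on the lumped trajectories at
    the model's lag when they are supplied, otherwise aggregated from the
    microstate count matrix.
    """
    lam = np.real(model.eigenvalues)
    n_micro = model.transition_matrix.shape[0]
    if n_macro > n_micro:
        raise ValueError("n_macro exceeds number of microstates")
    if n_macro < n_micro and abs(lam[n_macro - 1] - lam[n_macro]) < 1e-10:
        raise ValueError(
            "degenerate eigenvalues at the cut; choose a different n_macro"
        )
    if n_macro == n_micro:
        assignment = np.arange(n_micro)
    else:
        _, evecs = np.linalg.eig(model.transition_matrix)
        order = np.argsort(-np.abs(np.linalg.eigvals(model.transition_matrix)))
        evecs = np.real(evecs[:, order])
        assignment = _pcca_crisp_assign(evecs, n_macro)
    macro_pi = np.array(
        [model.stationary[assignment == m].sum() for m in range(n_macro)]
    )
    if dtrajs is not None:
        full_assign = np.zeros(
            max(int(model.active_states.max()) + 1, n_micro), dtype=int
        )
        full_assign[model.active_states] = assignment
        lumped = [full_assign[d] for d in dtrajs.dtrajs]
        c_macro = transition_counts(lumped, model.lag_frames, n_states=n_macro)
    else:
        c_micro = model.counts[np.ix_(model.active_states, model.active_states)]
        c_macro = np.zeros((n_macro, n_macro))
        for a in range(n_macro):
            for b in range(n_macro):
                c_macro[a, b] = c_micro[
                    np.ix_(assignment == a, assignment == b)
                ].sum()
    rowsum = np.maximum(c_macro.sum(axis=1), 1e-30)
    t_macro = c_macro / rowsum[:, None]
    return CoarseGraining(assignment, n_macro, t_macro, macro_pi, model)


def gmrq_cv_score(
    trajs: list[np.ndarray],
    k: int,
    lag_frames: int,
    n_folds: int = 5,
    m: int = 2,
    seed: int = 0,
    frame_interval_ns: float = 1.0,
) -> dict:
    """Cross-validated generalized-matrix-Rayleigh-quotient-style score.

    Trajectories are split into folds; microstates are defined on the train
    fold (mini-batch k-means), held-out trajectories are assigned to the
    train centers, and the score is the sum of the top ``m`` eigenvalue
    magnitudes of the transition matrix estimated on the held-out data.
    Train states unvisited in the held-out data are dropped (flagged in the
    output). Deterministic for a given seed.
    """
    trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs]
    if n_folds < 2 or n_folds > len(trajs):
        raise ValueError("need 2 <= n_folds <= number of trajectories")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trajs))
    folds = np.array_split(order, n_folds)
    scores, dropped_any = [], False
    for fold in folds:
        test_idx = set(fold.tolist())
        train = [trajs[i] for i in range(len(trajs)) if i not in test_idx]
        test = [trajs[i] for i in sorted(test_idx)]
        dset, centers = cluster_microstates(
            train, k, seed=seed, frame_interval_ns=frame_interval_ns
        )
        test_dtrajs = []
        for t in test:
            d2 = ((t[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            test_dtrajs.append(np.argmin(d2, axis=1))
        counts = transition_counts(test_dtrajs, lag_frames, n_states=k)
        visited = np.flatnonzero(counts.sum(axis=0) + counts.sum(axis=1) > 0)
        if len(visited) < k:
            dropped_any = True
        model = estimate_transition_matrix(counts, lag_frames, frame_interval_ns)
        lam = np.abs(model.eigenvalues)
        scores.append(float(np.sum(lam[: min(m, len(lam))])))
    scores = np.array(scores)
    return {
        "score": float(scores.mean()),
        "se": float(scores.std(ddof=1) / np.sqrt(len(scores)))
        if len(scores) > 1
        else float("nan"),
        "per_fold": scores,
        "states_dropped": dropped_any,
    }
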