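"""Brain-state clustering and occupancy/transition metrics.

Recurring connectivity patterns ("brain states") are found by k-means with
the Manhattan (L1) distance: assignment minimises the L1 distance to
centroids and the centroid update is the coordinate-wise median, which is
the exact minimiser of the within-cluster L1 objective. Many random
restarts guard against local minima (the study setting uses 500). The
number of states k is chosen by the elbow criterion of the cluster
validity index (within-cluster over between-cluster distance), with k
scanned over 2..6.

Per subject, four metrics summarise the label sequence: (1) frequency —
fraction of windows per state; (2) mean dwell time — mean length of
maximal runs per state; (3) number of transitions; (4) mean
intertransition time — mean gap between consecutive transition positions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "StateModel",
    "StateMetrics",
    "kmeans_manhattan",
    "cluster_validity_index",
    "choose_k_elbow",
    "state_metrics",
    "cohort_state_analysis",
]


@dataclasses.dataclass
class StateModel:
    """Fitted k-means solution over pooled pattern vectors.

    ``labels`` are 1-based state indices per row of the input, with states
    ordered by descending frequency.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    objective: float
    validity_index: float | None = None


@dataclasses.dataclass
class StateMetrics:
    """The four per-subject occupancy/transition statistics.

    Dwell and intertransition times are in window (or timepoint) units;
    multiply by TR x step for seconds. ``mean_intertransition_time`` is NaN
    when fewer than two transitions occur.
    """

    frequency: np.ndarray
    mean_dwell_time: np.ndarray
    n_transitions: int
    mean_intertransition_time: float


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, float]:
    D = cdist(X, centroids, metric="cityblock")
    labels = D.argmin(axis=1)
    return labels, float(D[np.arange(len(X)), labels].sum())


def _lloyd_l1(X: np.ndarray, init: np.ndarray, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = init.copy()
    k = centroids.shape[0]
    labels, obj = _assign(X, centroids)
    for _ in range(max_iter):
        for c in range(k):
            members = labels == c
            if not np.any(members):
                # empty cluster: reseed with the point farthest from its centroid
                d = np.abs(X - centroids[labels]).sum(axis=1)
                far = int(np.argmax(d))
                centroids[c] = X[far]
            else:
                centroids[c] = np.median(X[members], axis=0)
        new_labels, new_obj = _assign(X, centroids)
        # median update cannot increase the L1 objective
        assert new_obj <= obj + 1e-9 * max(1.0, abs(obj)), "k-means objective increased"
        if np.array_equal(new_labels, labels) and new_obj >= obj - 1e-12:
            labels, obj = new_labels, new_obj
            break
        labels, obj = new_labels, new_obj
    return centroids, labels, obj


def kmeans_manhattan(
    X: np.ndarray, k: int, n_restarts: int = 500, seed: int | None = 0
) -> StateModel:
    """L1 k-means with median centroid update and multiple restarts.

    Each restart initialises centroids at k distinct data rows sampled
    uniformly; the lowest-objective solution is kept. States in the
    returned model are relabelled 1..k in descending frequency order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (patterns x features)")
    M = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if M < k:
        raise ValueError(f"cannot fit {k} clusters to {M} points")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        init = X[rng.choice(M, size=k, replace=False)]
        centroids, labels, obj = _lloyd_l1(X, init)
        if best is None or obj < best[2] - 1e-12:
            best = (centroids, labels, obj)
    centroids, labels, obj = best
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return StateModel(k, centroids[order], relabel[labels] + 1, obj)


def cluster_validity_index(X: np.ndarray, model: StateModel) -> float:
    """Within-cluster over between-cluster summed L1 distances.

    Numerator: each point's distance to its own centroid, summed.
    Denominator: each point's distances to all OTHER centroids, summed.
    Small values indicate tight, well-separated clusters.
    """
    X = np.asarray(X, dtype=float)
    D = cdist(X, model.centroids, metric="cityblock")
    own = model.labels - 1
    within = D[np.arange(len(X)), own].sum()
    between = D.sum() - D[np.arange(len(X)), own].sum()
    if between <= 0:
        raise ValueError("coincident centroids: between-cluster distance is zero")
    return float(within / between)


def choose_k_elbow(index_by_k: dict[int, float]) -> int:
    """Elbow of the validity-index curve: k of greatest discrete curvature.

    Over consecutive k values, returns the interior k maximising
    index(k-1) - 2*index(k) + index(k+1); ties break toward the smallest k.
    """
    ks = sorted(index_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive k values for the elbow criterion")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k values must be consecutive")
    best_k, best_curv = None, -np.inf
    for k in ks[1:-1]:
        curv = index_by_k[k - 1] - 2 * index_by_k[k] + index_by_k[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return best_k


def state_metrics(labels: np.ndarray, k: int, censor_boundary_runs: bool = False) -> StateMetrics:
    """Frequency, mean dwell time, transition count and intertransition time.

    Runs are maximal constant segments of the label sequence. Mean dwell
    time per state averages run lengths of that state; boundary-censored
    first/last runs are included by default (``censor_boundary_runs=True``
    excludes them where interior runs exist). A transition position is the
    1-based index of the first window of a new run; the intertransition
    time is the mean gap between consecutive transition positions, NaN if
    fewer than two transitions occur.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in [1, {k}]")
    n = labels.size
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1  # run starts (0-based)
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    run_labels = labels[starts]
    run_lengths = ends - starts
    frequency = np.bincount(labels - 1, minlength=k) / n
    dwell = np.full(k, np.nan)
    for s in range(1, k + 1):
        sel = run_labels == s
        if censor_boundary_runs and len(run_lengths) > 1:
            interior = np.ones(len(run_lengths), dtype=bool)
            interior[0] = interior[-1] = False
            sel_int = sel & interior
            sel = sel_int if np.any(sel_int) else sel
        if np.any(sel):
            dwell[s - 1] = run_lengths[sel].mean()
    n_transitions = len(run_lengths) - 1
    if n_transitions >= 2:
        positions = starts[1:] + 1  # 1-based first window of each new run
        itt = float(np.diff(positions).mean())
    else:
        itt = float("nan")
    return StateMetrics(frequency, dwell, int(n_transitions), itt)


def cohort_state_analysis(
    vectors_per_subject: list[np.ndarray],
    subject_ids: list[str],
    k_range: tuple[int, int] = (2, 6),
    k: int | None = None,
    n_restarts: int = 500,
    seed: int | None = 0,
) -> tuple[StateModel, pd.DataFrame, dict[int, float]]:
    """Pooled clustering across subjects plus per-subject state metrics.

    ``vectors_per_subject`` holds each subject's pattern rows (windowed
    upper-triangle z vectors, or LEiDA eigenvectors) in temporal order.
    All subjects are pooled for the fit; labels are split back per subject
    and the four metrics computed for each. With ``k=None`` the cluster
    count is chosen by the elbow criterion over ``k_range``.

    Returns (fitted model, long-format metrics table, validity index per k;
    empty dict when k was fixed).
    """
    if len(vectors_per_subject) < 2:
        raise ValueError("cohort analysis needs at least 2 subjects")
    widths = {v.shape[1] for v in vectors_per_subject}
    if len(widths) != 1:
        raise ValueError("subjects have differing feature dimension")
    pooled = np.vstack(vectors_per_subject)
    indices: dict[int, float] = {}
    if k is None:
        k_min, k_max = k_range
        models = {}
        for kk in range(k_min, k_max + 1):
            m = kmeans_manhattan(pooled, kk, n_restarts=n_restarts, seed=seed)
            models[kk] = m
            indices[kk] = cluster_validity_index(pooled, m)
            m.validity_index = indices[kk]
        k = choose_k_elbow(indices)
        model = models[k]
    else:
        model = kmeans_manhattan(pooled, k, n_restarts=n_restarts, seed=seed)
        model.validity_index = cluster_validity_index(pooled, model)
    rows = []
    offset = 0
    for sid, v in zip(subject_ids, vectors_per_subject):
        lab = model.labels[offset : offset + len(v)]
        offset += len(v)
        m = state_metrics(lab, model.k)
        for s in range(model.k):
            rows.append(
                {
                    "subject_id": sid,
                    "state": s + 1,
                    "frequency": m.frequency[s],
                    "mean_dwell_time": m.mean_dwell_time[s],
                    "n_transitions": m.n_transitions,
                    "mean_intertransition_time": m.mean_intertransition_time,
                }
            )
    return model, pd.DataFrame(rows), indices
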