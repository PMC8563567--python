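"""Leading Eigenvector Dynamic Analysis (LEiDA).

A window-free view of dynamic connectivity: the instantaneous phase of
each network's signal is obtained from the Hilbert transform, the
phase-coherence matrix dFC(n,p,t) = cos(theta(n,t) - theta(p,t)) is formed
at every timepoint, and its leading eigenvector V1(t) summarises the
dominant connectivity pattern. The time-by-time matrix of cosine
similarities between leading eigenvectors (the FCD matrix) describes how
patterns recur, and k-means over the pooled eigenvectors yields brain
states with the same four metrics as the sliding-window pathway.

Input signals are assumed band-pass filtered to the BOLD band of interest
(0.01-0.1 Hz) upstream.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from dynconn.prep import NetworkTimecourses
from dynconn.states import StateModel, cohort_state_analysis

__all__ = [
    "PhaseSeries",
    "EigenvectorSeries",
    "FCDMatrix",
    "hilbert_phase",
    "phase_coherence_matrix",
    "leading_eigenvector",
    "outer_pattern",
    "fcd_matrix",
    "subject_eigenvectors",
    "leida_cohort_analysis",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) per network."""

    theta: np.ndarray  # T' x N
    dropped_edges: int
    subject_id: str = ""


@dataclasses.dataclass
class EigenvectorSeries:
    """Leading eigenvectors of the phase-coherence matrix, one per timepoint.

    Rows are unit Euclidean norm with the majority-negative sign
    convention applied.
    """

    V1: np.ndarray  # T' x N
    subject_id: str = ""


@dataclasses.dataclass
class FCDMatrix:
    """Time-by-time cosine similarity between leading eigenvectors."""

    fcd: np.ndarray
    mean_similarity: float


def hilbert_phase(tc: NetworkTimecourses, drop_edges: int = 1) -> PhaseSeries:
    """Instantaneous phase of each column via the analytic signal.

    Columns are mean-centred first (the analytic phase of a non-centred
    signal is distorted); ``drop_edges`` volumes are discarded at each end
    to blunt the Hilbert transform's edge effects.
    """
    T = tc.n_volumes
    if T < 2 * drop_edges + 2:
        raise ValueError(f"T={T} too short for drop_edges={drop_edges}")
    X = tc.data - tc.data.mean(axis=0)
    if np.any(X.std(axis=0) == 0):
        bad = int(np.argmin(X.std(axis=0)))
        raise ValueError(f"column {bad + 1} is constant; phase undefined")
    theta = np.angle(hilbert(X, axis=0))
    if drop_edges > 0:
        theta = theta[drop_edges:-drop_edges]
    return PhaseSeries(theta, drop_edges, tc.subject_id)


def phase_coherence_matrix(theta_t: np.ndarray) -> np.ndarray:
    """Instantaneous phase-coherence matrix dFC(n,p) = cos(theta_n - theta_p).

    Entries are 1 for aligned phases, 0 for orthogonal phases (difference
    pi/2) and -1 in antiphase; the matrix is symmetric with unit diagonal.
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("phases must be finite")
    d = np.cos(theta_t[:, None] - theta_t[None, :])
    np.fill_diagonal(d, 1.0)
    return 0.5 * (d + d.T)


def leading_eigenvector(dfc: np.ndarray, degeneracy_tol: float = 1e-10) -> np.ndarray:
    """Unit eigenvector of the algebraically largest eigenvalue.

    Eigenvectors are sign-ambiguous; the sign is fixed so that the
    majority of components are negative, and when counts are exactly
    balanced, so that the first nonzero component is negative. A
    (near-)degenerate top eigenvalue is logged; the returned vector is
    still deterministic (LAPACK ordering plus the sign rule).
    """
    dfc = np.asarray(dfc, dtype=float)
    if not np.allclose(dfc, dfc.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(dfc)
    if dfc.shape[0] > 1 and vals[-1] - vals[-2] < degeneracy_tol * max(1.0, abs(vals[-1])):
        logger.warning("degenerate leading eigenvalue (gap %.3e); fixed tie-break used",
                       vals[-1] - vals[-2])
    v = vecs[:, -1]
    v = v / np.linalg.norm(v)
    n_neg = int(np.sum(v < 0))
    n_pos = int(np.sum(v > 0))
    if n_neg < n_pos:
        v = -v
    elif n_neg == n_pos:
        nz = v[v != 0]
        if nz.size and nz[0] > 0:
            v = -v
    return v


def outer_pattern(v: np.ndarray) -> np.ndarray:
    """Rank-one connectivity pattern V V^T of a unit vector (trace 1)."""
    v = np.asarray(v, dtype=float)
    if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
        raise ValueError("v must be unit norm")
    return np.outer(v, v)


def fcd_matrix(series: EigenvectorSeries) -> FCDMatrix:
    """Functional-connectivity-dynamics matrix: pairwise cosine similarity.

    Rows of ``series.V1`` are unit norm, so the cosine similarity is the
    plain dot product; entries lie in [-1, 1] with unit diagonal.
    ``mean_similarity`` averages the strict upper triangle.
    """
    V = np.asarray(series.V1, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    F = np.clip(V @ V.T, -1.0, 1.0)
    np.fill_diagonal(F, 1.0)
    iu = np.triu_indices(F.shape[0], k=1)
    return FCDMatrix(F, float(F[iu].mean()))


def subject_eigenvectors(tc: NetworkTimecourses, drop_edges: int = 1) -> EigenvectorSeries:
    """Per-timepoint leading eigenvectors of the phase-coherence matrices."""
    phases = hilbert_phase(tc, drop_edges=drop_edges)
    V1 = np.stack([leading_eigenvector(phase_coherence_matrix(row)) for row in phases.theta])
    return EigenvectorSeries(V1, tc.subject_id)


def leida_cohort_analysis(
    subjects: list[NetworkTimecourses],
    k_range: tuple[int, int] = (2, 6),
    k: int | None = None,
    drop_edges: int = 1,
    n_restarts: int = 500,
    seed: int | None = 0,
) -> tuple[StateModel, pd.DataFrame, pd.DataFrame]:
    """Pooled eigenvector clustering plus per-subject metrics and FCD summary.

    Clusters the pooled leading eigenvectors of all subjects with L1
    k-means (same machinery as the sliding-window states), computes the
    four occupancy/transition metrics per subject, and reports each
    subject's mean FCD similarity for the group-level Kruskal-Wallis
    comparison.
    """
    if len(subjects) < 2:
        raise ValueError("cohort analysis needs at least 2 subjects")
    ns = {tc.n_networks for tc in subjects}
    if len(ns) != 1:
        raise ValueError("subjects have differing numbers of networks")
    series = [subject_eigenvectors(tc, drop_edges=drop_edges) for tc in subjects]
    ids = [tc.subject_id for tc in subjects]
    model, metrics, _ = cohort_state_analysis(
        [s.V1 for s in series], ids, k_range=k_range, k=k, n_restarts=n_restarts, seed=seed
    )
    fcd_rows = [
        {"subject_id": sid, "mean_fcd_similarity": fcd_matrix(s).mean_similarity}
        for sid, s in zip(ids, series)
    ]
    return model, metrics, pd.DataFrame(fcd_rows)
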