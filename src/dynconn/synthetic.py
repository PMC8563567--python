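"""Synthetic multi-subject cohorts of BOLD-like network time courses.

The generator plants ground truth that the downstream pipeline should
recover: a hidden Markov state sequence per subject switching between
multivariate-Gaussian covariance regimes (for the sliding-window pathway),
or between phase-coupling regimes of a common slow oscillation (for the
LEiDA pathway), with configurable group differences in the transition
dynamics. Defaults mirror a resting-state acquisition of 290 volumes at
TR = 2.072 s over ~21 networks.

No haemodynamic-response model, head motion or image-level noise is
simulated; the output is the post-extraction network time course.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from dynconn.prep import NetworkTimecourses

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_state_sequence",
    "generate_subject_timecourses",
    "generate_phase_coupled",
    "generate_cohort",
]

_DEF_VOLUMES = 290
_DEF_TR = 2.072


def _check_transition_matrix(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0):
        raise ValueError("transition probabilities must be nonnegative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1 (within 1e-12)")
    return P


def _check_spd(C: np.ndarray, what: str = "covariance") -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{what} must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{what} must be positive-definite") from exc
    return C


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic Markov chain (left eigenvector)."""
    P = _check_transition_matrix(P)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclasses.dataclass
class SyntheticSpec:
    """Cohort-level description of the synthetic generative model.

    ``state_covariances`` defines one N x N symmetric positive-definite
    matrix per planted state; ``transition_matrix`` is the row-stochastic
    per-volume state-switch matrix. ``group_effects`` maps a group label to
    overrides (``transition_matrix`` and/or ``state_covariances``) applied
    for subjects of that group only.
    """

    n_subjects_per_group: int
    state_covariances: list[np.ndarray]
    transition_matrix: np.ndarray
    groups: tuple[str, ...] = ("HC",)
    n_volumes: int = _DEF_VOLUMES
    tr_seconds: float = _DEF_TR
    observation_noise_sd: float = 0.0
    group_effects: dict[str, dict] | None = None
    age_range: tuple[float, float] = (65.0, 85.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        if self.n_volumes < 0:
            raise ValueError("n_volumes must be nonnegative")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.observation_noise_sd < 0:
            raise ValueError("observation_noise_sd must be nonnegative")
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        self.state_covariances = [_check_spd(C) for C in self.state_covariances]
        self.transition_matrix = _check_transition_matrix(self.transition_matrix)
        K = self.transition_matrix.shape[0]
        if len(self.state_covariances) != K:
            raise ValueError("need one covariance per state")
        ns = {C.shape[0] for C in self.state_covariances}
        if len(ns) != 1:
            raise ValueError("all state covariances must share the same dimension")

    @property
    def n_networks(self) -> int:
        return self.state_covariances[0].shape[0]

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def for_group(self, group: str) -> tuple[np.ndarray, list[np.ndarray]]:
        """Effective (transition_matrix, state_covariances) for one group."""
        P = self.transition_matrix
        covs = self.state_covariances
        if self.group_effects and group in self.group_effects:
            eff = self.group_effects[group]
            if "transition_matrix" in eff:
                P = _check_transition_matrix(eff["transition_matrix"])
            if "state_covariances" in eff:
                covs = [_check_spd(C) for C in eff["state_covariances"]]
        return P, covs


@dataclasses.dataclass
class PlantedTruth:
    """Ground-truth record for one synthetic subject."""

    subject_id: str
    group_label: str
    state_sequence: np.ndarray  # 1-based state per volume

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        if np.any(self.state_sequence < 1):
            raise ValueError("state indices are 1-based")


def generate_state_sequence(
    transition_matrix: np.ndarray, n_volumes: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Realise a Markov chain of planted states (1-based), one per volume.

    The initial state is drawn from the chain's stationary distribution so
    state occupancies are unbiased from the first volume.
    """
    P = _check_transition_matrix(transition_matrix)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = P.shape[0]
    seq = np.empty(n_volumes, dtype=int)
    if n_volumes == 0:
        return seq
    pi = stationary_distribution(P)
    state = rng.choice(K, p=pi)
    seq[0] = state + 1
    for t in range(1, n_volumes):
        state = rng.choice(K, p=P[state])
        seq[t] = state + 1
    return seq


def generate_subject_timecourses(
    state_sequence: np.ndarray,
    spec: SyntheticSpec,
    seed: int | np.random.Generator,
    subject_id: str = "sub-synth",
    state_covariances: list[np.ndarray] | None = None,
) -> NetworkTimecourses:
    """Draw T x N Gaussian signals following the planted state sequence.

    At each volume the N-vector is drawn from a zero-mean multivariate
    Gaussian with the active state's covariance; i.i.d. Gaussian observation
    noise of SD ``spec.observation_noise_sd`` is added afterwards.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    covs = spec.state_covariances if state_covariances is None else state_covariances
    covs = [_check_spd(C) for C in covs]
    seq = np.asarray(state_sequence, dtype=int)
    if seq.size and (seq.min() < 1 or seq.max() > len(covs)):
        raise ValueError("state sequence indexes a state without a covariance")
    T = seq.size
    N = covs[0].shape[0]
    chol = [np.linalg.cholesky(C) for C in covs]
    z = rng.standard_normal((T, N))
    data = np.empty((T, N))
    for s in range(len(covs)):
        rows = seq == s + 1
        data[rows] = z[rows] @ chol[s].T
    if spec.observation_noise_sd > 0:
        data = data + spec.observation_noise_sd * rng.standard_normal((T, N))
    return NetworkTimecourses(subject_id, data, spec.tr_seconds)


def generate_phase_coupled(
    state_sequence: np.ndarray,
    n_networks: int,
    base_freq_hz: float,
    coupling_per_state: list[np.ndarray],
    tr_seconds: float = _DEF_TR,
    seed: int | np.random.Generator = 0,
    amplitude_noise_sd: float = 0.0,
    phase_offsets: np.ndarray | None = None,
    subject_id: str = "sub-phase",
) -> NetworkTimecourses:
    """Sinusoidal networks with state-dependent phase coupling.

    All networks oscillate at ``base_freq_hz``; network n carries a
    state-dependent phase offset that is pulled toward 0 (the common phase)
    with strength given by its mean coupling to the other networks in the
    active state's coupling matrix: offset_n = (1 - mean coupling) * u_n
    with u_n drawn uniform on (-pi, pi] per state. Coupling 1 everywhere
    gives identical phases (instantaneous coherence 1); coupling 0 leaves
    offsets uniform and independent. ``phase_offsets`` (K x N, radians)
    overrides the drawn offsets entirely, e.g. to fix a quadrature pair.
    """
    if base_freq_hz <= 0 or base_freq_hz >= 0.5 / tr_seconds:
        raise ValueError(
            f"base frequency {base_freq_hz} Hz not resolvable at TR={tr_seconds}s "
            f"(Nyquist {0.5 / tr_seconds:.4f} Hz)"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq = np.asarray(state_sequence, dtype=int)
    K = len(coupling_per_state)
    if seq.size and (seq.min() < 1 or seq.max() > K):
        raise ValueError("state sequence indexes a state without a coupling matrix")
    if phase_offsets is None:
        offsets = np.empty((K, n_networks))
        for s, C in enumerate(coupling_per_state):
            C = np.asarray(C, dtype=float)
            if C.shape != (n_networks, n_networks):
                raise ValueError("coupling matrices must be N x N")
            if np.any(C < 0) or np.any(C > 1):
                raise ValueError("coupling entries must lie in [0, 1]")
            off_diag = C[~np.eye(n_networks, dtype=bool)].reshape(n_networks, n_networks - 1)
            strength = off_diag.mean(axis=1) if n_networks > 1 else np.ones(n_networks)
            offsets[s] = (1.0 - strength) * rng.uniform(-np.pi, np.pi, size=n_networks)
    else:
        offsets = np.asarray(phase_offsets, dtype=float)
        if offsets.shape != (K, n_networks):
            raise ValueError("phase_offsets must be K x N")
    T = seq.size
    t = np.arange(T) * tr_seconds
    common = 2.0 * np.pi * base_freq_hz * t
    data = np.cos(common[:, None] + offsets[seq - 1])
    if amplitude_noise_sd > 0:
        data = data + amplitude_noise_sd * rng.standard_normal((T, n_networks))
    return NetworkTimecourses(subject_id, data, tr_seconds)


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[NetworkTimecourses], pd.DataFrame, list[PlantedTruth]]:
    """Generate a full multi-group cohort with design table and ground truth.

    Returns one time-course matrix and one :class:`PlantedTruth` per
    subject, plus a design DataFrame with columns
    ``subject_id, group, age, sex``. Ages are uniform on ``spec.age_range``
    and sexes Bernoulli(0.5). Byte-reproducible under ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects: list[NetworkTimecourses] = []
    truths: list[PlantedTruth] = []
    rows = []
    n_total = len(spec.groups) * spec.n_subjects_per_group
    child_seeds = root.spawn(n_total + 1)
    demo_rng = np.random.default_rng(child_seeds[-1])
    i = 0
    for group in spec.groups:
        P, covs = spec.for_group(group)
        for _ in range(spec.n_subjects_per_group):
            sid = f"sub-{i + 1:03d}"
            rng = np.random.default_rng(child_seeds[i])
            seq = generate_state_sequence(P, spec.n_volumes, rng)
            tc = generate_subject_timecourses(
                seq, spec, rng, subject_id=sid, state_covariances=covs
            )
            subjects.append(tc)
            truths.append(PlantedTruth(sid, group, seq))
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": float(demo_rng.uniform(*spec.age_range)),
                    "sex": "F" if demo_rng.random() < 0.5 else "M",
                }
            )
            i += 1
    design = pd.DataFrame(rows)
    return subjects, design, truths
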