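"""Nonparametric group comparisons for connectivity summary measures.

Scalar measures (per-edge variability, state frequency, dwell time,
transition counts, mean FCD similarity) are compared between diagnostic
groups with rank-based tests: Kruskal-Wallis across three groups,
Mann-Whitney U for pairwise and medication-subgroup contrasts, and a
rank-transform permutation MANOVA (Pillai trace on column ranks with a
label-permutation null) for multivariate responses.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "kruskal_wallis",
    "mann_whitney_u",
    "nonparametric_manova",
    "medication_subgroup_compare",
]


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-squared p-value.

    Degenerate input where every value is identical returns (0.0, 1.0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in names]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a (number of (a, b) pairs with a > b; ties count 1/2)."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    When n_a * n_b <= 400 the p-value is computed by full enumeration of
    all group assignments with average-rank tie handling (exact even under
    ties); otherwise the tie-corrected normal approximation is used.
    Returns (U for the first sample, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = len(a), len(b)
    u_obs = _u_statistic(a, b)
    mid = na * nb / 2
    if na * nb <= 400 and math.comb(na + nb, na) <= 500_000:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        total = 0
        hits = 0
        obs_dev = abs(u_obs - mid)
        for comb in itertools.combinations(range(na + nb), na):
            ra = ranks[list(comb)].sum()
            u = ra - na * (na + 1) / 2
            total += 1
            if abs(u - mid) >= obs_dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    n = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_u = na * nb / 12 * (n + 1 - tie_term)
    if var_u == 0:
        return u_obs, 1.0
    z = (u_obs - mid - 0.5 * np.sign(u_obs - mid)) / np.sqrt(var_u)
    return u_obs, float(2 * sps.norm.sf(abs(z)))


def _pillai_trace(Y: np.ndarray, groups: np.ndarray, names: np.ndarray) -> float:
    grand = Y.mean(axis=0)
    H = np.zeros((Y.shape[1], Y.shape[1]))
    E = np.zeros_like(H)
    for g in names:
        sub = Y[groups == g]
        d = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(d, d)
        C = sub - sub.mean(axis=0)
        E += C.T @ C
    return float(np.trace(H @ np.linalg.pinv(H + E)))


def nonparametric_manova(
    responses: np.ndarray,
    groups: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Rank-transform permutation MANOVA with a Pillai-trace statistic.

    Each response column is rank-transformed across subjects; the Pillai
    trace of the one-way between-group decomposition on the ranks is the
    test statistic and its null distribution is built by permuting group
    labels. The observed labelling is counted with the permutations, so
    p >= 1/(n_permutations + 1).
    """
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    if Y.ndim != 2:
        raise ValueError("responses must be subjects x D")
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives coarse p resolution", stacklevel=2)
    ranks = np.column_stack([sps.rankdata(Y[:, j]) for j in range(Y.shape[1])])
    stat = _pillai_trace(ranks, groups, names)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(groups))
        if _pillai_trace(ranks, groups[perm], names) >= stat - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return stat, float(p)


def medication_subgroup_compare(
    metrics: pd.DataFrame, design: pd.DataFrame, flag_column: str = "medication"
) -> pd.DataFrame:
    """Mann-Whitney U per metric between flagged and unflagged subjects.

    ``metrics`` must carry a ``subject_id`` column plus one column per
    scalar measure; ``design`` supplies the boolean ``flag_column``. A
    metric with an empty subgroup is skipped with a logged note.
    """
    import logging

    logger = logging.getLogger(__name__)
    if flag_column not in design.columns:
        raise ValueError(f"design lacks column {flag_column!r}")
    merged = metrics.merge(design[["subject_id", flag_column]], on="subject_id")
    flag = merged[flag_column].astype(bool).to_numpy()
    rows = []
    for col in metrics.columns:
        if col == "subject_id":
            continue
        vals = merged[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        a, b = vals[ok & flag], vals[ok & ~flag]
        if len(a) == 0 or len(b) == 0:
            logger.info("metric %s skipped: empty subgroup", col)
            continue
        u, p = mann_whitney_u(a, b)
        rows.append({"metric": col, "U": u, "p": p})
    return pd.DataFrame(rows)
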