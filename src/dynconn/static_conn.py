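"""Static between-network connectivity and permutation group tests.

Per subject, full (Pearson) and partial (precision-based) correlations
over the whole time series are Fisher r-to-z transformed ("netmats").
Group differences across edges are assessed with a max-statistic
permutation test on the linear model value ~ group + age + sex using the
Freedman-Lane scheme: data are residualised with respect to the nuisance
covariates, residual rows are permuted, and the family-wise error rate is
controlled by comparing each observed t against the permutation
distribution of the maximum statistic across all edges, both correlation
types, and all signed group contrasts (six for three groups).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from dynconn.prep import NetworkTimecourses

__all__ = [
    "StaticNetmat",
    "full_correlation_z",
    "partial_correlation_z",
    "subject_netmat",
    "permutation_group_test",
]


@dataclasses.dataclass
class StaticNetmat:
    """One subject's static connectivity: full and partial Fisher-z matrices."""

    full_z: np.ndarray
    partial_z: np.ndarray
    subject_id: str


def _fisher_z(r: np.ndarray) -> np.ndarray:
    off = r[~np.eye(r.shape[0], dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        i, j = np.unravel_index(
            int(np.argmax(np.abs(r - np.eye(r.shape[0])))), r.shape
        )
        raise ValueError(f"|r|=1 between columns {i + 1} and {j + 1}; Fisher z undefined")
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    return 0.5 * (z + z.T)


def full_correlation_z(tc: NetworkTimecourses) -> np.ndarray:
    """Fisher-z Pearson correlations over the full series (diagonal 0)."""
    X = tc.data
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        raise ValueError(f"zero-variance column {bad + 1} ({tc.labels[bad]})")
    if X.shape[0] <= X.shape[1]:
        import warnings

        warnings.warn(
            f"T={X.shape[0]} not greater than N={X.shape[1]}; correlations will be noisy",
            stacklevel=2,
        )
    return _fisher_z(np.corrcoef(X, rowvar=False))


def partial_correlation_z(tc: NetworkTimecourses, ridge: float | None = None) -> np.ndarray:
    """Fisher-z partial correlations from the (ridge-regularised) precision.

    partial r_ij = -P_ij / sqrt(P_ii P_jj) with P = (S + ridge*I)^-1.
    ``ridge=None`` applies 0.1 x mean(diag S) when T < 5N (short series)
    and 0 otherwise.
    """
    X = tc.data
    T, N = X.shape
    S = np.cov(X, rowvar=False)
    if ridge is None:
        ridge = 0.1 * float(np.diag(S).mean()) if T < 5 * N else 0.0
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    Sreg = S + ridge * np.eye(N)
    cond = np.linalg.cond(Sreg)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("covariance singular even after ridge regularisation")
    P = np.linalg.inv(Sreg)
    d = np.sqrt(np.diag(P))
    r = -P / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return _fisher_z(r)


def subject_netmat(tc: NetworkTimecourses, ridge: float | None = None) -> StaticNetmat:
    return StaticNetmat(full_correlation_z(tc), partial_correlation_z(tc, ridge), tc.subject_id)


def _contrast_ts(Y: np.ndarray, X: np.ndarray, pinvX: np.ndarray, XtX_inv: np.ndarray,
                 contrasts: np.ndarray) -> np.ndarray:
    """t statistics for each contrast (rows of `contrasts`) and each column of Y."""
    n, p = X.shape
    beta = pinvX @ Y
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / dof
    out = np.empty((contrasts.shape[0], Y.shape[1]))
    for i, c in enumerate(contrasts):
        se = np.sqrt(sigma2 * float(c @ XtX_inv @ c))
        out[i] = (c @ beta) / se
    return out


def permutation_group_test(
    netmats: list[StaticNetmat],
    design: pd.DataFrame,
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Max-statistic Freedman-Lane permutation test across edges and contrasts.

    For each edge, correlation type (full, partial) and signed group
    contrast (six for three groups), the statistic is the t-value of the
    contrast in a linear model with age and sex as covariates. The null is
    built by residualising the data with respect to the covariates,
    permuting the residual rows, and refitting; the family-wise-error
    corrected p-value compares each observed t against the permutation
    distribution of the maximum t over the whole family. The unpermuted
    labelling is one of the ``n_permutations`` draws, so the smallest
    attainable p is 1/n_permutations.

    Returns a long-format table with columns edge_i, edge_j (1-based),
    correlation_type, contrast, t, p_uncorrected, p_fwe.
    """
    if len(netmats) != len(design):
        raise ValueError("one design row per subject required")
    groups = design["group"].to_numpy()
    group_names = sorted(pd.unique(groups))
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 subjects")
    if design[["age", "sex"]].isna().any().any():
        raise ValueError("missing covariates")
    n = len(design)
    N = netmats[0].full_z.shape[0]
    iu = np.triu_indices(N, k=1)
    E = len(iu[0])
    Y = np.empty((n, 2 * E))
    for s, nm in enumerate(netmats):
        Y[s, :E] = nm.full_z[iu]
        Y[s, E:] = nm.partial_z[iu]

    G = np.column_stack([(groups == g).astype(float) for g in group_names])
    age = design["age"].to_numpy(dtype=float)
    sex_raw = design["sex"].to_numpy()
    sex = (
        sex_raw.astype(float)
        if np.issubdtype(np.asarray(sex_raw).dtype, np.number)
        else (sex_raw == sex_raw[0]).astype(float)
    )
    Zc = np.column_stack([age - age.mean(), sex - sex.mean()])
    X = np.column_stack([G, Zc])
    pinvX = np.linalg.pinv(X)
    XtX_inv = np.linalg.pinv(X.T @ X)

    g = len(group_names)
    pair_list = [(i, j) for i in range(g) for j in range(g) if i != j]
    contrasts = np.zeros((len(pair_list), X.shape[1]))
    contrast_names = []
    for row, (i, j) in enumerate(pair_list):
        contrasts[row, i] = 1.0
        contrasts[row, j] = -1.0
        contrast_names.append(f"{group_names[i]}>{group_names[j]}")

    # Freedman-Lane: permute residuals from the nuisance-only model
    Znuis = np.column_stack([np.ones(n), Zc])
    Hz = Znuis @ np.linalg.pinv(Znuis)
    fitted = Hz @ Y
    R = Y - fitted

    t_obs = _contrast_ts(Y, X, pinvX, XtX_inv, contrasts)  # C x 2E

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_permutations)
    exceed = np.zeros_like(t_obs)
    for p in range(n_permutations):
        perm = np.arange(n) if p == 0 else rng.permutation(n)
        Ystar = fitted + R[perm]
        t_perm = _contrast_ts(Ystar, X, pinvX, XtX_inv, contrasts)
        max_null[p] = t_perm.max()
        exceed += t_perm >= t_obs - 1e-12
    p_unc = exceed / n_permutations
    p_fwe = (max_null[:, None, None] >= t_obs[None] - 1e-12).mean(axis=0)

    rows = []
    for c, cname in enumerate(contrast_names):
        for kind, off in (("full", 0), ("partial", E)):
            for e in range(E):
                rows.append(
                    {
                        "edge_i": int(iu[0][e]) + 1,
                        "edge_j": int(iu[1][e]) + 1,
                        "correlation_type": kind,
                        "contrast": cname,
                        "t": t_obs[c, off + e],
                        "p_uncorrected": p_unc[c, off + e],
                        "p_fwe": p_fwe[c, off + e],
                    }
                )
    return pd.DataFrame(rows)
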