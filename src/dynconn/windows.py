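"""Tapered sliding-window connectivity with graphical-LASSO regularisation.

A rectangular window of L TRs convolved with a Gaussian (sigma in TRs)
yields the taper; within each window a taper-weighted covariance is
computed, the precision matrix is estimated by graphical LASSO (L1 penalty
on off-diagonal entries, lambda selected per subject by cross-validation
over windows), and the implied correlations are Fisher r-to-z transformed.
Variability of connectivity over time is summarised by the per-edge
standard deviation of z across windows.

Defaults follow a 22-TR (~44 s at TR = 2.072 s) window with sigma = 3 TR
moved in steps of 1 TR, which gives 269 windows for 290 volumes;
alternative lengths (18, 20, 24, 26 TR) support sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.covariance import graphical_lasso

from dynconn.prep import NetworkTimecourses

__all__ = [
    "TaperSpec",
    "PrecisionEstimate",
    "WindowedConnectivityStack",
    "VariabilityMetrics",
    "build_taper",
    "enumerate_windows",
    "windowed_covariance",
    "glasso_precision",
    "select_lambda_cv",
    "precision_to_z",
    "residualize_edges",
    "connectivity_variability",
    "subject_connectivity_stack",
    "default_lambda_grid",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class TaperSpec:
    """Tapered sliding-window geometry (all quantities in TR units)."""

    window_length_tr: int = 22
    gaussian_sigma_tr: float = 3.0
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.window_length_tr < 2:
            raise ValueError("window length must be at least 2 TR")
        if self.gaussian_sigma_tr <= 0:
            raise ValueError("gaussian sigma must be positive")
        if self.step_tr < 1:
            raise ValueError("step must be at least 1 TR")


@dataclasses.dataclass
class PrecisionEstimate:
    """Graphical-LASSO precision estimate for one window."""

    sample_covariance: np.ndarray
    precision: np.ndarray
    lam: float


@dataclasses.dataclass
class WindowedConnectivityStack:
    """W x N x N stack of Fisher-z connectivity matrices over windows.

    Diagonal entries are stored as 0 by convention (self-connections are
    undefined on the z scale); ``window_centers`` holds 0-based central
    volume indices.
    """

    z: np.ndarray
    window_centers: np.ndarray
    subject_id: str
    lam: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 3 or self.z.shape[1] != self.z.shape[2]:
            raise ValueError("z must be W x N x N")

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_networks(self) -> int:
        return self.z.shape[1]

    def upper_triangle_vectors(self) -> np.ndarray:
        """W x E matrix of strict-upper-triangle edges in row-major order."""
        iu = np.triu_indices(self.n_networks, k=1)
        return self.z[:, iu[0], iu[1]]


@dataclasses.dataclass
class VariabilityMetrics:
    """Standard deviation of Fisher-z connectivity across windows."""

    per_edge_sd: np.ndarray
    per_network_mean_sd: np.ndarray
    global_mean_sd: float


def build_taper(spec: TaperSpec) -> np.ndarray:
    """Taper weights: rectangle (length L) convolved with a Gaussian.

    The full discrete convolution of a length-L rectangular window of ones
    with a discretised Gaussian kernel (sigma in TRs, support +-4 sigma) is
    cropped symmetrically about the convolution peak to length L and
    normalised to sum 1. The result is symmetric and unimodal.
    """
    L = spec.window_length_tr
    sigma = spec.gaussian_sigma_tr
    radius = max(1, int(np.ceil(4 * sigma)))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(L), kernel, mode="full")  # length L + 2*radius
    w = full[radius : radius + L]
    return w / w.sum()


def enumerate_windows(T: int, spec: TaperSpec) -> list[tuple[int, int]]:
    """Ordered (start, end) half-open 0-based window index pairs.

    The count is floor((T - L)/step) + 1; for 290 volumes with L=22 and
    step=1 this yields 269 overlapping windows.
    """
    L, step = spec.window_length_tr, spec.step_tr
    if T < L:
        raise ValueError(f"series of {T} volumes shorter than window length {L}")
    starts = range(0, T - L + 1, step)
    return [(s, s + L) for s in starts]


def windowed_covariance(
    data: np.ndarray, window: tuple[int, int], taper: np.ndarray
) -> np.ndarray:
    """Taper-weighted sample covariance of one window.

    Columns are centred by their taper-weighted mean and cross-products are
    taper-weighted (observation weighting), normalised by the sum of
    weights. A uniform taper reduces to the ordinary biased sample
    covariance.
    """
    start, end = window
    T = data.shape[0]
    if start < 0 or end > T or end - start != len(taper):
        raise ValueError("window out of range or taper length mismatch")
    X = data[start:end]
    w = np.asarray(taper, dtype=float)
    w = w / w.sum()
    mu = w @ X
    Xc = X - mu
    S = (Xc * w[:, None]).T @ Xc
    var = np.diag(S)
    if np.any(var <= 1e-12 * max(float(var.max()), np.finfo(float).tiny)):
        bad = int(np.argmin(var))
        raise ValueError(f"zero-variance column {bad + 1} in window [{start + 1}, {end}]")
    return 0.5 * (S + S.T)


def _prox_grad_glasso(
    S: np.ndarray, lam: float, tol: float = 1e-6, max_iter: int = 20000
) -> np.ndarray | None:
    """Proximal-gradient fallback solver for the graphical LASSO.

    Minimises -logdet(T) + tr(S T) + lam*||T_offdiag||_1 by ISTA with
    backtracking (step halved until the iterate stays positive-definite and
    the smooth part satisfies the descent condition). Stops when the
    successive-iterate max-change falls below ``tol``. Slower than
    coordinate descent but does not share its failure modes on
    near-singular inputs.
    """
    n = S.shape[0]
    off = ~np.eye(n, dtype=bool)

    def objective(T: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return np.inf
        return float(-logdet + np.trace(S @ T) + lam * np.abs(T[off]).sum())

    T = np.linalg.inv(S + max(lam, 1e-3) * np.eye(n))
    obj = objective(T)
    step = 1.0
    for _ in range(max_iter):
        G = S - np.linalg.inv(T)
        while True:
            cand = T - step * G
            cand[off] = np.sign(cand[off]) * np.maximum(np.abs(cand[off]) - step * lam, 0.0)
            cand = 0.5 * (cand + cand.T)
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj <= obj + 1e-10 * max(1.0, abs(obj)):
                break
            step *= 0.5
            if step < 1e-12:
                return None
        delta = float(np.max(np.abs(cand - T)))
        T, obj = cand, cand_obj
        step = min(step * 1.1, 1.0)
        if delta < tol:
            return T
    return None


def glasso_precision(
    S: np.ndarray, lam: float, tol: float = 1e-4, max_iter: int = 500
) -> PrecisionEstimate:
    """Graphical-LASSO precision matrix for a sample covariance.

    Maximises log det(Theta) - tr(S Theta) - lam * sum |Theta_ij| over the
    off-diagonal entries (diagonal unpenalised). At lam=0 this is the
    unpenalised maximum-likelihood estimate S^-1 (S must be invertible).
    Coordinate descent can stall on the near-singular covariances that
    short tapered windows produce, so a LARS-based solve is attempted
    before reporting non-convergence.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "sample covariance is singular at lambda=0; use lambda > 0"
            )
        precision = np.linalg.inv(S)
        return PrecisionEstimate(S, 0.5 * (precision + precision.T), 0.0)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    def _solve(S_in: np.ndarray, mode: str, iters: int) -> np.ndarray | None:
        # only the outer glasso loop's own warning counts as failure; the
        # inner coordinate-descent solver warns on single lasso passes
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                _, prec = graphical_lasso(
                    S_in, alpha=lam, tol=tol, max_iter=iters, mode=mode
                )
            except FloatingPointError:
                return None
        if any("graphical_lasso" in str(w.message) for w in caught):
            return None
        return prec

    precision = _solve(S, "cd", max_iter)
    if precision is None:
        precision = _solve(S, "lars", 2 * max_iter)
    if precision is None:
        # coordinate descent can enter a limit cycle on some matrices; a
        # relative 1e-8 diagonal jitter breaks it without moving the optimum
        jitter = 1e-8 * float(np.mean(np.diag(S))) * np.eye(S.shape[0])
        precision = _solve(S + jitter, "cd", 2 * max_iter)
    if precision is None:
        precision = _prox_grad_glasso(S, lam)
    if precision is None:
        raise RuntimeError(
            f"graphical lasso did not converge at lambda={lam} "
            f"within {2 * max_iter} iterations"
        )
    return PrecisionEstimate(S, 0.5 * (precision + precision.T), float(lam))


def default_lambda_grid(n_values: int = 20) -> np.ndarray:
    """Log-spaced lambda grid on [1e-3, 1]."""
    return np.logspace(-3, 0, n_values)


def _loglik(precision: np.ndarray, S: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S @ precision))


def select_lambda_cv(
    window_covariances: list[np.ndarray] | np.ndarray,
    grid: np.ndarray | None = None,
    n_folds: int = 20,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """Choose lambda by cross-validated held-out window log-likelihood.

    Windows are partitioned into ``n_folds`` contiguous-in-time folds
    (overlapping windows are strongly dependent, so random folds would leak
    information; ``seed`` is accepted for alternative schemes but unused
    here). For each lambda and fold, the precision is fitted on the mean
    covariance of the training windows and scored by the mean Gaussian
    log-likelihood log det(Theta) - tr(S_test Theta) over held-out windows.
    Returns the lambda maximising the mean held-out score; ties break toward
    larger lambda. A lambda that fails to converge on a fold scores -inf.
    The fit tolerance is looser than the final fit's (model selection does
    not need fully converged solutions).
    """
    covs = np.asarray(window_covariances, dtype=float)
    W = covs.shape[0]
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if W < n_folds:
        raise ValueError(f"need at least {n_folds} windows for {n_folds}-fold CV, got {W}")
    bounds = np.linspace(0, W, n_folds + 1).astype(int)
    scores = np.zeros(grid.size)
    for f in range(n_folds):
        test = np.zeros(W, dtype=bool)
        test[bounds[f] : bounds[f + 1]] = True
        S_train = covs[~test].mean(axis=0)
        S_tests = covs[test]
        for i, lam in enumerate(grid):
            try:
                est = glasso_precision(S_train, lam, tol=tol, max_iter=max_iter)
            except (np.linalg.LinAlgError, RuntimeError):
                scores[i] += -np.inf
                continue
            scores[i] += np.mean([_loglik(est.precision, St) for St in S_tests])
    # ties toward larger lambda: scan from the largest value down
    order = np.argsort(grid)[::-1]
    best = order[0]
    for i in order:
        if scores[i] > scores[best] + 1e-12:
            best = i
    return float(grid[best])


def precision_to_z(est: PrecisionEstimate) -> np.ndarray:
    """Fisher-z correlation matrix implied by a precision estimate.

    The covariance C = Theta^-1 is converted to correlations
    r_ij = C_ij / sqrt(C_ii C_jj) and z = atanh(r); the diagonal is 0 by
    convention.
    """
    C = np.linalg.inv(est.precision)
    d = np.sqrt(np.diag(C))
    r = C / np.outer(d, d)
    off = r[~np.eye(r.shape[0], dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("off-diagonal correlation of magnitude 1; Fisher z undefined")
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    return 0.5 * (z + z.T)


def subject_connectivity_stack(
    tc: NetworkTimecourses,
    spec: TaperSpec = TaperSpec(),
    lam: float | str = "cv",
    grid: np.ndarray | None = None,
    n_folds: int = 20,
) -> WindowedConnectivityStack:
    """Full per-subject sliding-window pipeline: taper -> covariance ->
    graphical LASSO -> Fisher z.

    ``lam='cv'`` selects the L1 weight by per-subject cross-validation over
    windows; a float fixes it (0 means plain inverse-covariance
    correlations).
    """
    taper = build_taper(spec)
    wins = enumerate_windows(tc.n_volumes, spec)
    covs = [windowed_covariance(tc.data, w, taper) for w in wins]
    if lam == "cv":
        lam_val = select_lambda_cv(covs, grid=grid, n_folds=n_folds)
    else:
        lam_val = float(lam)
    z = np.stack([precision_to_z(glasso_precision(S, lam_val)) for S in covs])
    centers = np.array([(s + e - 1) // 2 for s, e in wins])
    return WindowedConnectivityStack(z, centers, tc.subject_id, lam=lam_val)


def residualize_edges(
    values: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Residualise per-subject edge values with respect to age and sex.

    Per edge (column), ordinary least squares of the value on
    [intercept, centred age, centred sex] across subjects; the returned
    values are residuals plus the fitted intercept, so they stay on the
    original (z) scale. Group structure is deliberately NOT in the model.
    A constant covariate column is dropped with a warning.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    if n < 2:
        raise ValueError("residualisation needs at least 2 subjects")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    cols = [np.ones(n)]
    for name, c in (("age", age), ("sex", sex)):
        if c.shape != (n,):
            raise ValueError(f"{name} must have one entry per subject")
        if np.ptp(c) == 0:
            logger.warning("covariate %s is constant; dropped from residualisation", name)
            continue
        cols.append(c - c.mean())
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return resid + beta[0]


def connectivity_variability(stack: WindowedConnectivityStack) -> VariabilityMetrics:
    """Per-edge, per-network and global SD of z across windows.

    Per-edge sample SD uses denominator W-1; the per-network value is the
    mean of that network's row excluding the diagonal; the global value is
    the mean over the strict upper triangle.
    """
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows to compute variability")
    sd = stack.z.std(axis=0, ddof=1)
    sd = 0.5 * (sd + sd.T)
    np.fill_diagonal(sd, 0.0)
    N = sd.shape[0]
    off = ~np.eye(N, dtype=bool)
    per_network = np.array([sd[i, off[i]].mean() for i in range(N)])
    iu = np.triu_indices(N, k=1)
    return VariabilityMetrics(sd, per_network, float(sd[iu].mean()))
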