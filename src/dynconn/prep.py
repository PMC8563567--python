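"""Time-course post-processing: detrending and despiking.

Network time courses extracted from resting-state fMRI retain slow scanner
drifts and occasional isolated spikes even after image-level preprocessing.
This module removes polynomial trends up to cubic order and replaces
spike outliers by a cubic-spline interpolation through the clean samples.
Band-pass filtering (0.01-0.1 Hz) is assumed to have been applied upstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

__all__ = ["NetworkTimecourses", "detrend_polynomial", "despike"]


@dataclasses.dataclass
class NetworkTimecourses:
    """One subject's T x N matrix of network signals.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (T, N)
        Signal matrix, one column per network/region; arbitrary units.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    labels : list of str, optional
        Network names; defaults to ``net01 .. netNN``.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (T x N) array")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time courses of {self.subject_id}")
        if self.labels is None:
            self.labels = [f"net{j + 1:02d}" for j in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("labels length must equal number of columns")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_networks(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "NetworkTimecourses":
        return NetworkTimecourses(self.subject_id, data, self.tr_seconds, list(self.labels))


def _poly_basis(n: int, max_order: int) -> np.ndarray:
    # Legendre basis on [-1, 1] for conditioning; spans the same space as
    # {1, t, t^2, ..., t^max_order}.
    t = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(t, max_order)


def detrend_polynomial(tc: NetworkTimecourses, max_order: int = 3) -> NetworkTimecourses:
    """Remove a least-squares polynomial trend (including intercept) per column.

    The default ``max_order=3`` removes linear, quadratic and cubic trends
    together with the mean. Residual columns have zero mean and zero
    projection onto the polynomial basis.
    """
    T = tc.n_volumes
    if T <= max_order + 1:
        raise ValueError(
            f"need more than {max_order + 1} timepoints to remove an order-{max_order} "
            f"trend, got T={T}"
        )
    basis = _poly_basis(T, max_order)
    coef, *_ = np.linalg.lstsq(basis, tc.data, rcond=None)
    return tc.with_data(tc.data - basis @ coef)


def despike(
    tc: NetworkTimecourses,
    spike_threshold_mad: float = 5.0,
    window: int = 11,
) -> tuple[NetworkTimecourses, np.ndarray]:
    """Flag spike outliers and replace them by cubic-spline interpolation.

    Per column, a running median (window of ``window`` samples) serves as a
    smooth reference; samples whose deviation from it exceeds
    ``spike_threshold_mad`` robust standard deviations are flagged. The
    robust SD is estimated from the first differences of the signal
    (1.4826 x MAD(diff) / sqrt(2)), which is insensitive both to smooth
    deterministic structure (trends, oscillations) and to the isolated
    spikes being detected. Flagged samples are replaced by evaluating a
    cubic spline fitted to the unflagged samples; unflagged samples are
    returned unchanged.

    Returns
    -------
    (NetworkTimecourses, ndarray of bool shape (T, N))
        The despiked signals and the outlier mask.
    """
    T, N = tc.data.shape
    if T < 8:
        raise ValueError(f"need at least 8 timepoints for spline-based despiking, got T={T}")
    out = tc.data.copy()
    mask = np.zeros((T, N), dtype=bool)
    idx = np.arange(T, dtype=float)
    for j in range(N):
        x = tc.data[:, j]
        ref = median_filter(x, size=window, mode="nearest")
        resid = x - ref
        dx = np.diff(x)
        robust_sd = 1.4826 * np.median(np.abs(dx - np.median(dx))) / np.sqrt(2.0)
        flagged = np.abs(resid) > spike_threshold_mad * robust_sd
        if not np.any(flagged):
            continue
        if flagged.sum() > 0.5 * T:
            raise ValueError(
                f"more than half of column {j + 1} flagged as outliers; signal unusable"
            )
        clean = ~flagged
        spline = CubicSpline(idx[clean], x[clean])
        out[flagged, j] = spline(idx[flagged])
        mask[:, j] = flagged
    return tc.with_data(out), mask
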