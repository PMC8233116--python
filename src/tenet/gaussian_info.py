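"""Closed-form Gaussian estimators for MI, conditional MI and transfer
entropy on lagged variables, with chi-square and surrogate-based
significance tests.

For jointly Gaussian variables the mutual information is a function of
the correlation structure alone: I(X;Y) = -1/2 ln(1 - rho^2) nats for
1-d variables, and in general

    I(X;Y|Z) = 1/2 ln( |S_XZ| |S_YZ| / (|S_Z| |S_XYZ|) )

with covariance determinants (|S_empty| = 1). Transfer entropy is the
conditional MI between the source's past and the target's present given
the target's own past; for Gaussian variables it is equivalent to
Granger causality. Analytic significance uses the likelihood-ratio
result that 2 n I_hat is asymptotically chi-square under independence;
family-wise error control over a candidate set uses the null
distribution of the *maximum* statistic over circularly time-shifted
surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import TimeSeriesSet

__all__ = [
    "LagVariable",
    "TestResult",
    "lagged_design",
    "gaussian_mi",
    "gaussian_cmi",
    "gaussian_te",
    "chi_square_test",
    "max_statistic_test",
]

RIDGE = 1e-10
MIN_SHIFT = 20


@dataclass(frozen=True, order=True)
class LagVariable:
    """One lagged scalar variable: ``node`` at ``lag`` steps in the past
    (lag 0 = contemporaneous)."""

    node: int
    lag: int

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be nonnegative")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alpha: float
    null_kind: str
    n_surrogates: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def lagged_design(
    ts: TimeSeriesSet,
    variables: list[LagVariable],
    align_lag: int | None = None,
) -> np.ndarray:
    """Time-aligned design matrix for a list of lagged variables.

    Rows are joint realizations; row count is ``T - align_lag`` where
    ``align_lag`` defaults to the maximum lag among ``variables``. Passing
    an explicit ``align_lag`` lets several designs for the same target
    share rows (all statistics for one target use rows valid for the
    maximal lag among variables under test).
    """
    T = ts.n_samples
    max_lag = max((v.lag for v in variables), default=0)
    if align_lag is None:
        align_lag = max_lag
    if align_lag >= T:
        raise ValueError(f"lag {align_lag} exceeds series length {T} - 1")
    if max_lag > align_lag:
        raise ValueError("a variable's lag exceeds the alignment lag")
    cols = [
        ts.samples[align_lag - v.lag : T - v.lag, v.node] for v in variables
    ]
    if not cols:
        return np.empty((T - align_lag, 0))
    return np.column_stack(cols)


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian MI between two scalar samples: -1/2 ln(1 - r^2) nats."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    r = min(abs(r), 1.0 - 1e-15)
    return -0.5 * np.log1p(-(r**2))


def _logdet_cov(data: np.ndarray) -> float:
    """Log-determinant of the ML (1/n) covariance, with a small diagonal
    ridge on near-singular matrices. Empty variable sets contribute 0."""
    if data.shape[1] == 0:
        return 0.0
    c = np.cov(data, rowvar=False, bias=True)
    c = np.atleast_2d(c)
    sign, logdet = np.linalg.slogdet(c)
    if sign <= 0 or logdet < np.log(RIDGE):
        c = c + RIDGE * np.eye(c.shape[0])
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular covariance after ridge")
    return logdet


def gaussian_cmi(X: np.ndarray, Y: np.ndarray, Z: np.ndarray | None = None) -> float:
    """Gaussian conditional MI I(X;Y|Z) in nats (Z may be empty/None)."""
    X, Y = _as_2d(X), _as_2d(Y)
    Z = np.empty((X.shape[0], 0)) if Z is None else _as_2d(Z)
    if not (X.shape[0] == Y.shape[0] == Z.shape[0]):
        raise ValueError("row-count mismatch between X, Y, Z")
    if Z.shape[1] == 0 and X.shape[1] == 1 and Y.shape[1] == 1:
        return gaussian_mi(X[:, 0], Y[:, 0])
    ld_xz = _logdet_cov(np.hstack([X, Z]))
    ld_yz = _logdet_cov(np.hstack([Y, Z]))
    ld_z = _logdet_cov(Z)
    ld_xyz = _logdet_cov(np.hstack([X, Y, Z]))
    return 0.5 * (ld_xz + ld_yz - ld_z - ld_xyz)


def gaussian_te(
    ts: TimeSeriesSet,
    source_vars: list[LagVariable],
    target: int,
    target_past: list[LagVariable],
    align_lag: int | None = None,
) -> float:
    """Transfer entropy from a set of lagged source variables to a target.

    Equals the single-link TE when ``source_vars`` is one lag-1 variable
    and the collective TE for larger source sets. Source and target-past
    lags must be >= 1 (the target's own past is conditioning, never a
    source).
    """
    if not source_vars:
        raise ValueError("source_vars must be nonempty")
    if any(v.lag < 1 for v in source_vars):
        raise ValueError("source lags must be >= 1")
    if any(v.node == target for v in source_vars):
        raise ValueError("the target's own past cannot be a source")
    if any(v.lag < 1 or v.node != target for v in target_past):
        raise ValueError("target_past must hold the target at lags >= 1")
    all_vars = source_vars + [LagVariable(target, 0)] + target_past
    if align_lag is None:
        align_lag = max(v.lag for v in all_vars)
    design = lagged_design(ts, all_vars, align_lag=align_lag)
    k = len(source_vars)
    return gaussian_cmi(
        design[:, :k], design[:, k : k + 1], design[:, k + 1 :]
    )


def chi_square_test(
    statistic: float, n_rows: int, dof: int, alpha: float
) -> TestResult:
    """Analytic likelihood-ratio test: 2 n I_hat ~ chi-square(dof) under
    the null of (conditional) independence."""
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if statistic < 0:
        statistic = 0.0
    p = float(stats.chi2.sf(2.0 * n_rows * statistic, dof))
    return TestResult(statistic, p, alpha, null_kind="chi_square")


# ---------------------------------------------------------------------------
# fast partial-correlation statistics used by the surrogate machinery


def _orthonormal_basis(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis of [1, Z]'s column space (the intercept makes
    residualization equivalent to centering)."""
    n = Z.shape[0]
    M = np.hstack([np.ones((n, 1)), Z])
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r[0, 0]))
    return q[:, keep]


def partial_corr_stat(x: np.ndarray, y_resid: np.ndarray, Q: np.ndarray) -> float:
    """CMI(x; y | Z) from precomputed pieces: ``Q`` an orthonormal basis
    of [1, Z], ``y_resid`` = y residualized against Q."""
    xq = Q.T @ x
    rx_norm2 = np.dot(x, x) - np.dot(xq, xq)
    ry_norm2 = np.dot(y_resid, y_resid)
    if rx_norm2 <= 0 or ry_norm2 <= 0:
        return 0.0
    r = np.dot(x, y_resid) / np.sqrt(rx_norm2 * ry_norm2)
    r = min(abs(r), 1.0 - 1e-15)
    return -0.5 * np.log1p(-(r**2))


def _shifted_stats(
    x: np.ndarray, y_resid: np.ndarray, Q: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """CMI statistics of circular shifts of ``x`` (one per offset) with a
    fixed residualized target and conditioning basis.

    Inner products of every circular shift of ``x`` with a fixed vector
    form a circular cross-correlation, computed for all offsets at once
    via FFT; shift-invariance of the norm gives the residual norms from
    the projections onto the conditioning basis.
    """
    n = x.size
    fx = np.fft.rfft(x)

    def circ_corr(v: np.ndarray) -> np.ndarray:
        # out[k] = sum_t v[t] * x[(t + k) mod n]
        return np.fft.irfft(np.conj(np.fft.rfft(v)) * fx, n)

    xy = circ_corr(y_resid)[offsets]
    xq2 = np.zeros(n)
    for k in range(Q.shape[1]):
        xq2 += circ_corr(Q[:, k]) ** 2
    rx2 = np.dot(x, x) - xq2[offsets]
    ry2 = np.dot(y_resid, y_resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(xy) / np.sqrt(rx2 * ry2)
    r = np.nan_to_num(r, nan=0.0)
    r = np.minimum(r, 1.0 - 1e-15)
    return -0.5 * np.log1p(-(r**2))


def max_statistic_test(
    ts: TimeSeriesSet,
    candidates: list[LagVariable],
    winner: LagVariable,
    conditioning: list[LagVariable],
    target: int,
    n_surrogates: int = 500,
    alpha: float = 0.01,
    rng_seed: int = 0,
    align_lag: int | None = None,
    min_shift: int = MIN_SHIFT,
) -> TestResult:
    """Family-wise surrogate test of the greedy winner against the null of
    the *maximum* statistic over all candidates.

    For each surrogate, every candidate's aligned sample column is
    independently circularly shifted in time (offset uniform in
    [min_shift, n - min_shift], destroying its temporal relation to the
    target while preserving its autocorrelation), its CMI with the target
    given the conditioning set is computed, and the maximum over
    candidates recorded. p = (1 + #{surrogate maxima >= observed}) /
    (1 + n_surrogates).
    """
    if winner not in candidates:
        raise ValueError("winner must be one of the candidates")
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    if align_lag is None:
        align_lag = max(v.lag for v in candidates + conditioning + [winner])
    y = lagged_design(ts, [LagVariable(target, 0)], align_lag=align_lag)[:, 0]
    Z = lagged_design(ts, conditioning, align_lag=align_lag)
    n = y.size
    if n <= 2 * min_shift:
        raise ValueError("series too short for the minimum circular shift")
    Q = _orthonormal_basis(Z)
    y_resid = y - Q @ (Q.T @ y)
    x_win = lagged_design(ts, [winner], align_lag=align_lag)[:, 0]
    observed = partial_corr_stat(x_win, y_resid, Q)

    rng = np.random.default_rng(rng_seed)
    surrogate_max = np.zeros(n_surrogates)
    for cand in candidates:
        x = lagged_design(ts, [cand], align_lag=align_lag)[:, 0]
        offsets = rng.integers(min_shift, n - min_shift + 1, size=n_surrogates)
        np.maximum(
            surrogate_max,
            _shifted_stats(x, y_resid, Q, offsets),
            out=surrogate_max,
        )
    p = (1.0 + np.count_nonzero(surrogate_max >= observed)) / (1.0 + n_surrogates)
    return TestResult(
        observed, float(p), alpha, null_kind="surrogate_max",
        n_surrogates=n_surrogates,
    )
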