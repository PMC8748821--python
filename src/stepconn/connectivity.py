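"""Per-subject functional connectivity: ridge partial correlation and degree.

The connectivity estimate is the L2-regularised (ridge) partial correlation.
Columns are z-scored, so the regularisation strength ``rho`` is scale-free:
with standardized sample covariance S, the precision is P = (S + rho I)^-1 and

    r_ij = -P_ij / sqrt(P_ii P_jj),   i != j,

with the diagonal defined as 0. ``rho = 0.5`` is the pipeline default.
Degree centrality is the total connection strength of a region, by default the
sum of absolute edge weights (negative partial correlations count by
magnitude; a positive-only variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DesignMatrixError, EstimationError, InputError


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric region-by-region partial-correlation matrix for one subject."""

    values: np.ndarray
    subject_id: str = ""
    regularization: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError("connectivity values must be a square matrix")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DegreeVector:
    values: np.ndarray
    subject_id: str = ""


def _standardize_columns(timeseries: np.ndarray) -> np.ndarray:
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2:
        raise InputError("timeseries must be a T x R matrix")
    if not np.all(np.isfinite(x)):
        raise InputError("timeseries contains non-finite values")
    if x.shape[0] < 3:
        raise InputError(f"need at least 3 timepoints, got {x.shape[0]}")
    sd = x.std(axis=0)
    # exact repeats give sd ~ 1e-16 * |mean| through cancellation, not 0
    dead = np.flatnonzero((np.ptp(x, axis=0) == 0) | (sd < 1e-12 * (np.abs(x).max() + 1)))
    if dead.size:
        raise EstimationError(
            f"constant time series in region column(s) {dead.tolist()}: variance is zero"
        )
    return (x - x.mean(axis=0)) / sd


def partial_correlation(
    timeseries: np.ndarray,
    rho: float = 0.5,
    subject_id: str = "",
    ridge_dialect: str = "identity",
) -> ConnectivityMatrix:
    """Ridge-regularised partial correlation of a T x R time-series matrix.

    ``ridge_dialect`` selects how the ridge is added to the standardized
    covariance S: ``"identity"`` uses S + rho*I (default), ``"scaled"`` uses
    S + rho*mean(diag(S))*I. With z-scored columns diag(S) is all ones, so the
    two coincide up to the covariance normalisation; both are kept because
    published descriptions of the estimator differ.
    """
    if rho < 0:
        raise InputError(f"rho must be >= 0, got {rho}")
    if ridge_dialect not in ("identity", "scaled"):
        raise InputError(f"unknown ridge dialect {ridge_dialect!r}")
    z = _standardize_columns(timeseries)
    t = z.shape[0]
    s = z.T @ z / t
    scale = rho * (np.trace(s) / s.shape[0] if ridge_dialect == "scaled" else 1.0)
    p = np.linalg.inv(s + scale * np.eye(s.shape[0]))
    d = np.sqrt(np.diag(p))
    r = -p / np.outer(d, d)
    r = (r + r.T) / 2.0  # enforce exact symmetry against round-off
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, subject_id=subject_id, regularization=rho)


def degree_centrality(fc: ConnectivityMatrix | np.ndarray, mode: str = "absolute") -> DegreeVector:
    """Total connection strength per region.

    ``mode="absolute"`` (default) sums |w_ij| over j != i; ``"positive_only"``
    sums max(w_ij, 0), discarding negative edges.
    """
    if isinstance(fc, ConnectivityMatrix):
        w, sid = fc.values, fc.subject_id
    else:
        w, sid = np.asarray(fc, dtype=float), ""
    if mode == "absolute":
        deg = np.abs(w).sum(axis=1)
    elif mode == "positive_only":
        deg = np.clip(w, 0.0, None).sum(axis=1)
    else:
        raise InputError(f"unknown degree mode {mode!r}")
    return DegreeVector(values=deg, subject_id=sid)


def regress_out(
    values: np.ndarray,
    covariates: np.ndarray,
    keep_mean: bool = True,
) -> np.ndarray:
    """Residualise each column of ``values`` on covariates by OLS.

    An intercept is always included. With ``keep_mean`` (default) the original
    column means are added back to the residuals so that downstream thresholds
    remain comparable. Residuals are orthogonal to every covariate.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    if y.shape[0] == 1 and np.asarray(values).ndim == 1:
        y = y.T
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] == 1 and np.asarray(covariates).ndim == 1:
        c = c.T
    n = y.shape[0]
    if c.shape[0] != n:
        raise DesignMatrixError(f"{n} observations but {c.shape[0]} covariate rows")
    x = np.column_stack([np.ones(n), c])
    if n <= x.shape[1]:
        raise DesignMatrixError(f"need more than {x.shape[1]} observations, got {n}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignMatrixError("covariate design is rank deficient after adding an intercept")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    if keep_mean:
        resid = resid + y.mean(axis=0, keepdims=True)
    out = resid if np.asarray(values).ndim == 2 else resid.ravel()
    return out
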