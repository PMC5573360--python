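"""Geographically weighted regression with an adaptive Gaussian kernel.

GWR fits a separate weighted least-squares regression at every observation
location, with observation weights decaying with geographic distance from
the focal point:

    beta_hat(i) = (X' W_i X)^-1 X' W_i y,   W_i = diag(w_i1 ... w_in)

* kernel: Gaussian, ``w = exp(-0.5 (d/b)^2)`` — weights are never exactly
  zero, so every local system uses all observations;
* adaptive bandwidth: at point *i*, ``b_i`` is the distance to its k-th
  nearest other point with ``k = max(2, round(q*(n-1)))``, so each local
  fit effectively uses a fixed fraction ``q`` of the data;
* bandwidth fraction ``q`` chosen by leave-one-out cross-validation
  (golden-section search; AICc minimisation available as an alternative
  selector);
* diagnostics: RSS, global R² = 1 - RSS/TSS, the effective-parameter trace
  tr(S) of the exact hat matrix, the GWR-style corrected AIC

      AICc = n ln(sigma_hat^2) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S)

  with ``sigma_hat^2 = RSS/n``, and per-point local R² computed with the
  same kernel weights as estimation.

Distances are Euclidean on planar km coordinates, or great-circle
(haversine, Earth radius 6371 km) for longitude/latitude input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .exceptions import DegenerateStatisticError, DomainError, SingularFitError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------- distances
def distance_matrix(coords: np.ndarray, mode: str = "euclidean") -> np.ndarray:
    """Pairwise distances in km between points.

    ``coords`` is (n, 2): planar (x_km, y_km) for ``mode="euclidean"`` or
    (longitude, latitude) degrees for ``mode="haversine"``.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DomainError("need >= 2 points with 2 coordinates each")
    if not np.isfinite(pts).all():
        raise DomainError("coordinates must be finite")
    if mode == "euclidean":
        diff = pts[:, None, :] - pts[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if mode == "haversine":
        lon = np.radians(pts[:, 0])
        lat = np.radians(pts[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise DomainError(f"unknown distance mode {mode!r}")


def adaptive_bandwidths(distances: np.ndarray, q: float) -> np.ndarray:
    """Per-point bandwidth: distance to the k-th nearest *other* point,
    k = max(2, round(q*(n-1)))."""
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise DomainError("adaptive bandwidths need >= 3 points")
    if not (0 < q <= 1):
        raise DomainError(f"adaptive fraction q must be in (0, 1], got {q}")
    k = min(max(2, int(round(q * (n - 1)))), n - 1)
    ordered = np.sort(D, axis=1)[:, 1:]  # drop self-distance 0
    bw = ordered[:, k - 1]
    if np.any(bw <= 0):
        raise DegenerateStatisticError(
            "zero adaptive bandwidth: duplicate coordinates among nearest neighbours"
        )
    return bw


def gaussian_weights(d, b):
    """Gaussian kernel weight exp(-0.5 (d/b)^2); b > 0."""
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise DomainError("bandwidth must be positive")
    return np.exp(-0.5 * (np.asarray(d, dtype=float) / b) ** 2)


def _weight_matrix(D: np.ndarray, bw: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * (D / bw[:, None]) ** 2)


# ------------------------------------------------------------- local fits
def _design(x) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_local(y, X, weights):
    """Weighted least squares at one focal point.

    ``X`` is the full design (including intercept column).  Returns
    ``(beta, hat_row)`` where ``hat_row`` maps y to the focal fitted value.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    try:
        beta = np.linalg.solve(A, b)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError(f"singular local system: {exc}") from exc
    return beta, Ainv @ (X.T * w)


def _fit_all(y: np.ndarray, X: np.ndarray, W: np.ndarray, need_hat: bool):
    """Vectorised local WLS at every focal point.

    Returns (beta (n,p), S hat matrix (n,n) or None)."""
    A = np.einsum("ij,jk,jl->ikl", W, X, X)  # (n, p, p)
    b = (W * y[None, :]) @ X  # (n, p)
    try:
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        bad = [i for i in range(len(A)) if abs(np.linalg.det(A[i])) < 1e-300]
        raise SingularFitError(
            f"singular local system at point index {bad[:5]}"
        ) from exc
    S = None
    if need_hat:
        Ainv = np.linalg.inv(A)
        # S_ij = x_i' A_i^-1 x_j w_ij
        S = np.einsum("ik,ikl,jl,ij->ij", X, Ainv, X, W, optimize=True)
    return beta, S


def cv_score(y, x, distances, q: float) -> float:
    """Leave-one-out CV score sum_i (y_i - yhat_(not i))^2 at fraction q.

    Each local fit drops the focal observation's own weight."""
    y = np.asarray(y, dtype=float)
    X = _design(x)
    D = np.asarray(distances, dtype=float)
    bw = adaptive_bandwidths(D, q)
    W = _weight_matrix(D, bw)
    np.fill_diagonal(W, 0.0)
    beta, _ = _fit_all(y, X, W, need_hat=False)
    yhat = np.einsum("ij,ij->i", X, beta)
    return float(np.sum((y - yhat) ** 2))


def select_bandwidth(
    y,
    x,
    coords,
    *,
    mode: str = "euclidean",
    q_bounds: tuple[float, float] = (0.02, 1.0),
    tol: float = 1e-3,
    criterion: str = "cv",
):
    """Choose the adaptive fraction q* by golden-section search.

    ``criterion="cv"`` (default) minimises the leave-one-out CV score;
    ``criterion="aicc"`` minimises the GWR AICc instead.  Returns
    ``(q_star, trace)`` where ``trace`` is the list of (q, score)
    evaluations.  A flat score curve returns the upper bound with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise DomainError("bandwidth selection needs n >= 10")
    D = distance_matrix(np.asarray(coords, dtype=float), mode)
    trace: list[tuple[float, float]] = []

    def score(q: float) -> float:
        try:
            if criterion == "cv":
                s = cv_score(y, x, D, q)
            elif criterion == "aicc":
                s = fit_gwr(y, x, coords, q, mode=mode).aicc
            else:
                raise DomainError(f"unknown selection criterion {criterion!r}")
        except (SingularFitError, DegenerateStatisticError):
            s = float("inf")
        trace.append((q, s))
        return s

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = q_bounds
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = score(c), score(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = score(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = score(d)
    finite = [s for _, s in trace if np.isfinite(s)]
    if finite and (max(finite) - min(finite)) <= 1e-12 * max(abs(max(finite)), 1.0):
        warnings.warn("flat CV curve: returning upper bandwidth bound", stacklevel=2)
        return q_bounds[1], trace
    return float((a + b) / 2.0), trace


# --------------------------------------------------------------- full fit
@dataclass
class GWRFit:
    """Local coefficients and diagnostics of one fitted GWR model."""

    params: np.ndarray  # (n, p) local coefficients, intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    local_r2: np.ndarray
    bandwidths: np.ndarray  # km
    hat_diag: np.ndarray
    trace_s: float
    rss: float
    tss: float
    r2: float
    aicc: float
    q: float
    mode: str = "euclidean"

    @property
    def slopes(self) -> np.ndarray:
        """Local slope of the (single) predictor at each observation."""
        return self.params[:, 1]


def fit_gwr(
    y,
    x,
    coords,
    q: float,
    *,
    mode: str = "euclidean",
    bandwidth_override: float | None = None,
) -> GWRFit:
    """Fit GWR of ``y`` on predictor(s) ``x`` at locations ``coords``.

    ``x`` is (n,) or (n, k) without intercept; one is added.  ``q`` is the
    adaptive-kernel fraction; ``bandwidth_override`` forces a single fixed
    bandwidth (km) at every point (used e.g. to verify the OLS limit).
    """
    y = np.asarray(y, dtype=float)
    X = _design(x)
    n, p = X.shape
    if len(y) != n:
        raise DomainError("y and x lengths differ")
    D = distance_matrix(np.asarray(coords, dtype=float), mode)
    if bandwidth_override is not None:
        if bandwidth_override <= 0:
            raise DomainError("bandwidth override must be positive")
        bw = np.full(n, float(bandwidth_override))
    else:
        bw = adaptive_bandwidths(D, q)
    W = _weight_matrix(D, bw)
    beta, S = _fit_all(y, X, W, need_hat=True)
    fitted = np.einsum("ij,ij->i", X, beta)
    resid = y - fitted
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-12 * n:
        raise DegenerateStatisticError("response has (near-)zero variance")
    r2 = 1.0 - rss / tss
    tr_s = float(np.trace(S))
    if n - 2.0 - tr_s <= 0:
        raise DegenerateStatisticError(
            f"AICc undefined: n - 2 - tr(S) = {n - 2 - tr_s:.3g} <= 0"
        )
    sigma2 = rss / n
    aicc = n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + tr_s) / (n - 2.0 - tr_s)
    # local goodness of fit with the estimation weights
    wsum = W.sum(axis=1)
    ybar_w = (W @ y) / wsum
    num = W @ (resid**2)
    den = np.einsum("ij,ij->i", W, (y[None, :] - ybar_w[:, None]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_r2 = 1.0 - num / den
    if np.any(local_r2 < 0):
        warnings.warn("negative local R² clipped to 0", stacklevel=2)
        local_r2 = np.clip(local_r2, 0.0, None)
    return GWRFit(
        params=beta,
        fitted=fitted,
        residuals=resid,
        local_r2=local_r2,
        bandwidths=bw,
        hat_diag=np.diag(S).copy(),
        trace_s=tr_s,
        rss=rss,
        tss=tss,
        r2=r2,
        aicc=float(aicc),
        q=float(q),
        mode=mode,
    )


@dataclass
class OLSFit:
    """Global OLS fit with the same diagnostic definitions (tr S = p)."""

    params: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    tss: float
    r2: float
    aicc: float
    rank: int = field(default=0)


def fit_ols(y, x) -> OLSFit:
    """Ordinary least squares of y on x (intercept added), with RSS, R² and
    the GWR-style AICc evaluated at tr(S) = p."""
    y = np.asarray(y, dtype=float)
    X = _design(x)
    n, p = X.shape
    model = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError("design matrix is rank deficient")
    resid = y - model.fittedvalues
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if rss <= np.finfo(float).tiny * n:
        aicc = float("-inf")
    elif n - 2.0 - p <= 0:
        aicc = float("nan")
    else:
        aicc = float(n * np.log(rss / n) + n * np.log(2 * np.pi) + n * (n + p) / (n - 2.0 - p))
    return OLSFit(
        params=np.asarray(model.params),
        fitted=np.asarray(model.fittedvalues),
        residuals=resid,
        rss=rss,
        tss=tss,
        r2=r2,
        aicc=aicc,
        rank=p,
    )
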