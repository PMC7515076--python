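"""Delay-embedding reconstruction and recurrence-based dynamical measures.

The analysis chain mirrors standard nonlinear time-series practice: choose the
embedding delay at the first local minimum of the lagged auto mutual
information (falling back to the first zero crossing of the autocorrelation),
choose the embedding dimension with the false-nearest-neighbour criterion,
then quantify the reconstructed dynamics with

* recurrence quantification (recurrence rate, determinism, Shannon entropy of
  the diagonal-line length distribution in bits, longest diagonal line and the
  inverse-maxline divergence proxy),
* a Rosenstein-style maximal Lyapunov exponent (mean log divergence rate of
  initially close trajectory pairs), and
* the Grassberger-Procaccia correlation dimension with Theiler correction and
  an automatically selected scaling region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "EmbeddingSpec",
    "RQAResult",
    "embed",
    "select_delay",
    "false_nearest_neighbors",
    "recurrence_matrix",
    "radius_for_rate",
    "rqa_measures",
    "max_lyapunov",
    "max_lyapunov_jacobian",
    "correlation_dimension",
    "series_entropy",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters (in samples)."""

    delay: int
    dimension: int
    theiler_window: int | None = None

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise ValueError("delay and dimension must be >= 1")

    @property
    def theiler(self) -> int:
        if self.theiler_window is not None:
            return self.theiler_window
        return self.delay * self.dimension


@dataclass
class RQAResult:
    recurrence_rate: float
    determinism: float
    entropy_bits: float
    l_max: int
    lyapunov_estimate: float
    correlation_dimension: float = math.nan
    flags: list[str] = field(default_factory=list)


def embed(series: np.ndarray, delay: int, dimension: int) -> np.ndarray:
    """Time-delay embedding; rows are reconstructed state vectors."""
    x = np.asarray(series, dtype=float).ravel()
    n = x.size - (dimension - 1) * delay
    if n < 1:
        raise ValueError(
            f"series of length {x.size} too short for dimension {dimension}, "
            f"delay {delay}"
        )
    return np.stack([x[i * delay : i * delay + n] for i in range(dimension)], axis=1)


def _auto_mutual_information(x: np.ndarray, lag: int, bins: int = 16) -> float:
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def select_delay(series: np.ndarray, max_lag: int | None = None, bins: int = 16) -> int:
    """First local minimum of the lagged auto-MI; autocorrelation fallback.

    Raises on a structureless (constant) series.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 samples to select a delay")
    if np.ptp(x) == 0:
        raise ValueError("flat series: no temporal structure to embed")
    max_lag = max_lag or max(2, min(100, x.size // 5))
    mi = np.array([_auto_mutual_information(x, k, bins) for k in range(1, max_lag + 1)])
    for k in range(1, len(mi) - 1):
        if mi[k] < mi[k - 1] and mi[k] <= mi[k + 1]:
            return k + 1
    if mi[0] <= mi[1] if len(mi) > 1 else False:
        return 1
    # fallback: first zero crossing of the autocorrelation
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    for k in range(1, max_lag + 1):
        if np.dot(xc[:-k], xc[k:]) / denom <= 0:
            return k
    return max_lag


def _nearest_nontrivial(points: np.ndarray, theiler: int) -> tuple[np.ndarray, np.ndarray]:
    """Index and distance of each point's nearest neighbour outside the
    Theiler window (Chebyshev norm)."""
    n = len(points)
    tree = cKDTree(points)
    idx = np.full(n, -1)
    dist = np.full(n, np.inf)
    pending = np.arange(n)
    k = min(n, 2 * theiler + 2)
    while pending.size:
        d, j = tree.query(points[pending], k=k, p=np.inf)
        if d.ndim == 1:
            d, j = d[:, None], j[:, None]
        ok = np.abs(j - pending[:, None]) > theiler
        has = ok.any(axis=1)
        first = ok.argmax(axis=1)
        rows = np.nonzero(has)[0]
        idx[pending[rows]] = j[rows, first[rows]]
        dist[pending[rows]] = d[rows, first[rows]]
        pending = pending[~has]
        if k >= n:
            break
        k = min(n, k * 2)
    return idx, dist


def false_nearest_neighbors(
    series: np.ndarray,
    delay: int,
    max_dim: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    theiler: int | None = None,
) -> tuple[int, bool]:
    """Smallest embedding dimension with an FNN fraction below ``threshold``.

    Returns ``(dimension, saturated)`` where ``saturated`` flags that no
    dimension below ``max_dim`` passed (noise-like series).
    """
    x = np.asarray(series, dtype=float).ravel()
    sigma = x.std()
    if sigma == 0:
        raise ValueError("flat series")
    th = theiler if theiler is not None else delay
    for m in range(1, max_dim):
        pts = embed(x, delay, m)
        # neighbour in dimension m, checked against coordinate m+1
        horizon = m * delay
        pts_valid = pts[: len(pts) - horizon] if horizon < len(pts) else pts[:0]
        if len(pts_valid) < 10:
            break
        idx, dist = _nearest_nontrivial(pts_valid, th)
        ok = idx >= 0
        i = np.nonzero(ok)[0]
        if i.size == 0:
            break
        j = idx[i]
        extra = np.abs(x[i + horizon] - x[j + horizon])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist[i] > 0, extra / np.maximum(dist[i], 1e-300),
                             np.where(extra > 0, np.inf, 0.0))
        false = (ratio > rtol) | (np.sqrt(dist[i] ** 2 + extra**2) / sigma > atol)
        if false.mean() < threshold:
            return m, False
    return max_dim, True


def recurrence_matrix(
    series: np.ndarray, spec: EmbeddingSpec, radius: float
) -> np.ndarray:
    """Binary recurrence matrix under the Chebyshev norm.

    Entries with ``|i - j| <= theiler_window`` are zeroed (for
    ``theiler_window = 0`` the main diagonal survives, as distance zero is
    always within any radius).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pts = embed(series, spec.delay, spec.dimension)
    d = cdist(pts, pts, metric="chebyshev")
    rec = (d <= radius).astype(np.uint8)
    w = spec.theiler_window if spec.theiler_window is not None else 0
    if w > 0:
        n = len(rec)
        ii, jj = np.indices((n, n), sparse=True)
        rec[np.abs(ii - jj) <= w] = 0
    return rec


def radius_for_rate(
    series: np.ndarray, spec: EmbeddingSpec, target_rate: float = 0.02
) -> float:
    """Radius giving approximately the target recurrence rate (off-band)."""
    pts = embed(series, spec.delay, spec.dimension)
    d = cdist(pts, pts, metric="chebyshev")
    w = spec.theiler
    n = len(d)
    ii, jj = np.indices((n, n), sparse=True)
    vals = d[np.abs(ii - jj) > w]
    if vals.size == 0:
        raise ValueError("Theiler window excludes every pair")
    return float(np.quantile(vals, target_rate))


def _diagonal_lengths(rec: np.ndarray, exclude_band: int) -> list[int]:
    """Lengths of all maximal diagonal 1-runs with offset > exclude_band."""
    n = len(rec)
    lengths: list[int] = []
    for off in range(exclude_band + 1, n):
        diag = np.diagonal(rec, offset=off)
        if diag.size == 0:
            continue
        padded = np.concatenate([[0], diag, [0]])
        change = np.diff(padded.astype(int))
        starts = np.nonzero(change == 1)[0]
        ends = np.nonzero(change == -1)[0]
        lengths.extend((ends - starts).tolist())
    return lengths


def rqa_measures(
    matrix: np.ndarray,
    min_line: int = 2,
    theiler: int = 0,
    dt: float = 1.0,
) -> RQAResult:
    """Recurrence quantification of a binary recurrence matrix.

    Diagonal-line statistics are computed off the ``theiler`` band (and the
    line of identity); the Shannon entropy of the line-length distribution is
    in bits; the divergence proxy for the Lyapunov exponent is
    ``1 / (l_max * dt)``.
    """
    rec = np.asarray(matrix)
    n = len(rec)
    band = max(theiler, 0)
    ii, jj = np.indices((n, n), sparse=True)
    off_band = np.abs(ii - jj) > band
    denom = int(off_band.sum())
    n_rec = int(rec[off_band].sum())
    if n_rec == 0:
        return RQAResult(0.0, math.nan, math.nan, 0, math.nan,
                         flags=["no-recurrences"])
    rate = n_rec / denom
    lengths = np.asarray(_diagonal_lengths(rec, band))
    long_lines = lengths[lengths >= min_line]
    flags: list[str] = []
    if long_lines.size == 0:
        return RQAResult(rate, 0.0, 0.0, 0, math.nan, flags=["no-lines"])
    determinism = float(2 * long_lines.sum() / n_rec)  # matrix is symmetric
    l_max = int(long_lines.max())
    counts = np.bincount(long_lines)[min_line:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    lyap_proxy = 1.0 / (l_max * dt)
    return RQAResult(rate, min(determinism, 1.0), entropy, l_max, lyap_proxy,
                     flags=flags)


def max_lyapunov(
    series: np.ndarray,
    spec: EmbeddingSpec,
    k_max: int | None = None,
    fit_range: tuple[int, int] | None = None,
    dt: float = 1.0,
    min_pairs: int = 10,
) -> float:
    """Rosenstein estimate of the maximal Lyapunov exponent, per time unit.

    For every embedded point the nearest neighbour outside the Theiler window
    seeds a trajectory pair; the slope of the mean log separation over the
    first ``fit_range`` steps (default ``(1, 8)``) is the exponent.  The sign
    is the headline output: positive means exponential divergence (chaos).
    """
    pts = embed(series, spec.delay, spec.dimension)
    n = len(pts)
    if n < 50:
        raise ValueError("embedded series too short for divergence tracking")
    k_max = k_max or min(50, n // 5)
    fit_lo, fit_hi = fit_range or (1, 8)
    if not 0 <= fit_lo < fit_hi <= k_max:
        raise ValueError("invalid fit range")
    idx, dist = _nearest_nontrivial(pts, spec.theiler)
    valid = idx >= 0
    if valid.sum() < min_pairs:
        return math.nan
    i0 = np.nonzero(valid)[0]
    j0 = idx[i0]
    curve = np.full(k_max + 1, np.nan)
    for k in range(k_max + 1):
        keep = (i0 + k < n) & (j0 + k < n)
        if keep.sum() < min_pairs:
            break
        d = np.abs(pts[i0[keep] + k] - pts[j0[keep] + k]).max(axis=1)
        d = d[d > 0]
        if d.size < min_pairs:
            break
        curve[k] = np.log(d).mean()
    ks = np.arange(fit_lo, fit_hi + 1)
    ys = curve[fit_lo : fit_hi + 1]
    ok = np.isfinite(ys)
    if ok.sum() < 2:
        return math.nan
    slope = np.polyfit(ks[ok], ys[ok], 1)[0]
    return float(slope / dt)


def max_lyapunov_jacobian(
    series: np.ndarray,
    spec: EmbeddingSpec,
    evolve: int = 1,
    n_neighbors: int | None = None,
    dt: float = 1.0,
    ridge: float = 1e-6,
) -> float:
    """Largest Lyapunov exponent from local Jacobians (Eckmann et al. style).

    At every embedded point a local linear map is fitted by least squares
    from the displacements of its nearest neighbours to their images
    ``evolve`` steps ahead; the maps are accumulated with QR
    re-orthonormalisation and the mean log of the leading diagonal entry of
    R gives the exponent per time unit.  Unlike divergence tracking this can
    resolve negative exponents, so it is the estimator of choice for
    noise-driven, phase-locked network activity.
    """
    pts = embed(series, spec.delay, spec.dimension)
    n, m = pts.shape
    if n < 100:
        raise ValueError("embedded series too short for Jacobian estimation")
    k = n_neighbors or max(2 * m, 8)
    tree = cKDTree(pts[: n - evolve])
    _, all_j = tree.query(pts[: n - evolve], k=k + spec.theiler + 2, p=2)
    q_mat = np.eye(m)
    log_sum = 0.0
    count = 0
    for i in range(0, n - evolve):
        j = all_j[i]
        j = j[(np.abs(j - i) > spec.theiler) & (j < n - evolve)][:k]
        if len(j) < m + 1:
            continue
        u = pts[j] - pts[i]
        v = pts[j + evolve] - pts[i + evolve]
        # ridge-regularised least squares for the local map A: v ~ u A^T
        g = u.T @ u + ridge * np.eye(m)
        a_t = np.linalg.solve(g, u.T @ v)
        q_mat, r = np.linalg.qr(a_t.T @ q_mat)
        diag = np.abs(np.diag(r))
        # guard against singular local fits
        if diag[0] <= 0:
            continue
        log_sum += np.log(diag[0])
        count += 1
    if count < 10:
        return math.nan
    return float(log_sum / (count * evolve * dt))


def correlation_dimension(
    series: np.ndarray,
    spec: EmbeddingSpec,
    n_radii: int = 24,
    max_points: int = 1500,
    min_window: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Grassberger-Procaccia correlation dimension D2.

    The correlation sum is evaluated on log-spaced radii with Theiler
    correction; D2 is the slope over the flattest ``min_window``-point window
    of the local log-log slopes (the automatically selected scaling region).
    Returns 0 for a constant series and NaN when no scaling region exists.
    """
    x = np.asarray(series, dtype=float).ravel()
    if np.ptp(x) == 0:
        return 0.0
    pts = embed(x, spec.delay, spec.dimension)
    n = len(pts)
    if n > max_points:
        stride = int(np.ceil(n / max_points))
        pts_idx = np.arange(0, n, stride)
        pts_used = pts[pts_idx]
    else:
        pts_idx = np.arange(n)
        pts_used = pts
    d = cdist(pts_used, pts_used, metric="chebyshev")
    sep = np.abs(pts_idx[:, None] - pts_idx[None, :])
    vals = d[np.triu(sep > spec.theiler)]
    vals = vals[vals > 0]
    if vals.size < 100:
        return math.nan
    r_lo = np.quantile(vals, 0.002)
    r_hi = np.quantile(vals, 0.5)
    if r_lo <= 0 or r_hi <= r_lo:
        return math.nan
    radii = np.geomspace(r_lo, r_hi, n_radii)
    c = np.searchsorted(np.sort(vals), radii, side="right") / vals.size
    ok = c > 0
    logr, logc = np.log(radii[ok]), np.log(c[ok])
    if logr.size < min_window + 1:
        return math.nan
    local = np.diff(logc) / np.diff(logr)
    # a scaling region must actually scale: among windows with clearly
    # positive mean slope pick the flattest (lowest slope variance)
    best, best_var = None, np.inf
    fallback, fallback_var = None, np.inf
    for lo in range(0, len(local) - min_window + 1):
        seg = local[lo : lo + min_window]
        v = seg.var()
        if seg.mean() >= 0.05 and v < best_var:
            best_var, best = v, seg.mean()
        if v < fallback_var:
            fallback_var, fallback = v, seg.mean()
    if best is not None:
        return float(best)
    return float(fallback) if fallback is not None else math.nan


def series_entropy(series: np.ndarray, bins: int = 32) -> float:
    """Distributional Shannon entropy of the series values, in bits."""
    x = np.asarray(series, dtype=float).ravel()
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())
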