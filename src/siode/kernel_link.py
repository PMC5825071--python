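"""Local-linear kernel estimation of the single-index link function.

The single-index ODE model writes the derivative of module k as
Y = eta_k(X^T beta) + eps with unknown smooth link eta_k and unit-norm
index vector beta.  For a candidate beta the link is profiled out by
local-linear kernel regression of Y on the scalar index L_i = X_i^T beta:
at each evaluation point u a kernel-weighted straight line is fitted, and
its intercept is the link estimate.  The profile loss Q(beta) is the sum
of squared residuals of that fit at the observations' own index values.

Everything here is vectorized over evaluation points; the pairwise
index-distance matrix makes a full profile-loss evaluation O(N^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IndexVector",
    "LinkEstimate",
    "normalize_index",
    "kernel_moments",
    "local_linear_link",
    "link_on_grid",
    "profile_loss",
    "profile_residuals",
    "select_bandwidth",
    "bandwidth_from_multiplier",
]

logger = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: default GCV candidate multipliers for h = c * sd(index) * N^(-1/5)
DEFAULT_BANDWIDTH_MULTIPLIERS = (0.5, 0.75, 1.0, 1.5, 2.0, 3.0)

# relative threshold below which the local-linear denominator is treated
# as degenerate and the local-constant fallback is used
_DEGENERACY_REL = 1e-12


def _kernel(z: np.ndarray, name: str) -> np.ndarray:
    if name == "gaussian":
        return np.exp(-0.5 * z * z) / _SQRT2PI
    if name == "epanechnikov":
        return 0.75 * np.maximum(0.0, 1.0 - z * z)
    raise ValueError(f"unknown kernel {name!r}; choose 'gaussian' or 'epanechnikov'")


@dataclass
class IndexVector:
    """Unit-norm index vector with the first-nonzero-positive sign fix."""

    beta: np.ndarray
    module_index: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)


def normalize_index(raw: np.ndarray, module_index: int = 0) -> IndexVector:
    """Scale to unit Euclidean norm and make the first nonzero entry
    positive (the identifiability convention; eta absorbs sign and scale)."""
    raw = np.asarray(raw, dtype=float)
    nrm = np.linalg.norm(raw)
    if nrm == 0.0 or not np.isfinite(nrm):
        raise ValueError("cannot normalize an all-zero (or non-finite) index vector")
    beta = raw / nrm
    nz = np.flatnonzero(beta)
    if beta[nz[0]] < 0:
        beta = -beta
    return IndexVector(beta=beta, module_index=module_index)


@dataclass
class LinkEstimate:
    """Estimated link eta(u) on a grid of index values."""

    eval_points: np.ndarray
    values: np.ndarray
    slope: np.ndarray
    bandwidth: float
    kernel_name: str = "gaussian"


def kernel_moments(u, index_values, y, h, kernel="gaussian"):
    """The six kernel moments K_jl(u) = sum_i K_h(L_i - u) (L_i - u)^j Y_i^l
    for j in {0,1,2}, l in {0,1}, with K_h(.) = K(./h)/h.

    Returns a dict keyed ``(j, l)``.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    index_values = np.asarray(index_values, dtype=float)
    y = np.asarray(y, dtype=float)
    d = index_values - u
    w = _kernel(d / h, kernel) / h
    out = {}
    for j in (0, 1, 2):
        dj = d**j
        out[(j, 0)] = float(np.sum(w * dj))
        out[(j, 1)] = float(np.sum(w * dj * y))
    return out


def local_linear_link(u, index_values, y, h, kernel="gaussian"):
    """Local-linear link estimate at a single point u: the intercept of
    the kernel-weighted least-squares line,
    (K20*K01 - K10*K11) / (K00*K20 - K10^2).

    Falls back to the local-constant (Nadaraya-Watson) estimate K01/K00
    when the local design is degenerate.
    """
    mom = kernel_moments(u, index_values, y, h, kernel)
    den = mom[(0, 0)] * mom[(2, 0)] - mom[(1, 0)] ** 2
    scale = abs(mom[(0, 0)] * mom[(2, 0)]) + 1e-300
    if den <= _DEGENERACY_REL * scale:
        logger.warning("degenerate local design at u=%g; local-constant fallback", u)
        return mom[(0, 1)] / mom[(0, 0)]
    return (mom[(2, 0)] * mom[(0, 1)] - mom[(1, 0)] * mom[(1, 1)]) / den


def _moment_arrays(eval_points, index_values, y, h, kernel):
    """Vectorized moments for many evaluation points.

    Returns (K00, K10, K20, K01, K11) arrays over eval points, plus the
    self-weight diagonal info needed for the smoother trace when
    eval_points is index_values itself.
    """
    d = index_values[None, :] - eval_points[:, None]
    w = _kernel(d / h, kernel) / h
    wd = w * d
    wdd = wd * d
    k00 = w.sum(axis=1)
    k10 = wd.sum(axis=1)
    k20 = wdd.sum(axis=1)
    k01 = w @ y
    k11 = wd @ y
    return w, d, k00, k10, k20, k01, k11


def _link_values(eval_points, index_values, y, h, kernel):
    w, d, k00, k10, k20, k01, k11 = _moment_arrays(eval_points, index_values, y, h, kernel)
    den = k00 * k20 - k10**2
    scale = np.abs(k00 * k20) + 1e-300
    bad = den <= _DEGENERACY_REL * scale
    eta = np.empty_like(k00)
    slope = np.zeros_like(k00)
    ok = ~bad
    eta[ok] = (k20[ok] * k01[ok] - k10[ok] * k11[ok]) / den[ok]
    slope[ok] = (k00[ok] * k11[ok] - k10[ok] * k01[ok]) / den[ok]
    if bad.any():
        logger.debug("local-constant fallback at %d evaluation points", int(bad.sum()))
        eta[bad] = k01[bad] / np.maximum(k00[bad], 1e-300)
    return eta, slope, w, k10, k20, den, bad


def link_on_grid(beta, X, y, h, kernel="gaussian", n_grid=200) -> LinkEstimate:
    """Evaluate the fitted link on an equally spaced index grid (for
    diagnostics and fit reports)."""
    beta = np.asarray(beta, dtype=float)
    lam = X @ beta
    grid = np.linspace(lam.min(), lam.max(), n_grid)
    eta, slope, *_ = _link_values(grid, lam, y, h, kernel)
    return LinkEstimate(
        eval_points=grid, values=eta, slope=slope, bandwidth=h, kernel_name=kernel
    )


def bandwidth_from_multiplier(c: float, index_values: np.ndarray) -> float:
    """Rate-optimal bandwidth h = c * sd(index) * N^(-1/5)."""
    n = index_values.shape[0]
    s = float(np.std(index_values))
    if s == 0.0:
        s = 1e-8
    return c * s * n ** (-0.2)


def profile_residuals(beta, X, y, bandwidth_multiplier=1.0, kernel="gaussian"):
    """Residuals Y_i - eta_hat(X_i^T beta) of the local-linear fit
    evaluated at each observation's own index value.

    The bandwidth is tied to the current index spread via
    :func:`bandwidth_from_multiplier`, which makes the profile loss
    invariant to rescaling beta (the link absorbs scale).
    """
    beta = np.asarray(beta, dtype=float)
    lam = X @ beta
    h = bandwidth_from_multiplier(bandwidth_multiplier, lam)
    eta, *_ = _link_values(lam, lam, y, h, kernel)
    return y - eta


def profile_loss(beta, X, y, bandwidth_multiplier=1.0, kernel="gaussian") -> float:
    """Profile least-squares objective Q(beta) = sum_i {Y_i - eta_hat(L_i)}^2."""
    r = profile_residuals(beta, X, y, bandwidth_multiplier, kernel)
    return float(r @ r)


def select_bandwidth(
    beta,
    X,
    y,
    candidates=DEFAULT_BANDWIDTH_MULTIPLIERS,
    kernel="gaussian",
):
    """Choose the bandwidth multiplier minimizing the generalized
    cross-validation score GCV(h) = N * RSS(h) / (N - tr(S_h))^2 of the
    local-linear smoother at the current index.

    Returns ``(c, h, scores)`` with ``scores`` the GCV value per candidate
    (NaN where the candidate was degenerate).
    """
    beta = np.asarray(beta, dtype=float)
    lam = X @ beta
    n = lam.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations for GCV bandwidth selection")
    scores = np.full(len(candidates), np.nan)
    for i, c in enumerate(candidates):
        h = bandwidth_from_multiplier(c, lam)
        eta, slope, w, k10, k20, den, bad = _link_values(lam, lam, y, h, kernel)
        # smoother diagonal: weight of Y_i in eta_hat(L_i); d_ii = 0
        diag_w = np.diag(w)
        s_ii = np.where(
            bad,
            diag_w / np.maximum(w.sum(axis=1), 1e-300),
            diag_w * k20 / np.where(den == 0, 1.0, den),
        )
        tr = float(np.sum(s_ii))
        if tr >= n:
            continue
        rss = float(np.sum((y - eta) ** 2))
        scores[i] = n * rss / (n - tr) ** 2
    if np.all(np.isnan(scores)):
        raise ValueError(f"all bandwidth candidates degenerate: {list(candidates)}")
    best = int(np.nanargmin(scores))
    c = candidates[best]
    return c, bandwidth_from_multiplier(c, lam), scores
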