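"""Module state-curve estimation and derivative computation.

Each functional module's population expression curve X(t) is estimated
from its member genes by a penalized-spline nonparametric mixed-effects
(NPME) model: a truncated-power spline for the population curve (knot
coefficients shrunk as a random effect, the classical penalized-spline /
mixed-model equivalence) plus per-gene spline random effects for
individual departures, with iid measurement noise.  Variance components
are estimated by REML; fixed effects and BLUPs come from Henderson's
mixed-model equations.

First derivatives are taken by a second pass: a cubic interpolating
spline through the fitted population curve on an augmented equally
spaced grid, differentiated analytically.  Natural boundary conditions
are used, so derivative values at the grid ends are flagged as
lower-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline

from .datatypes import ExpressionMatrix, StateSet, TrajectorySet

__all__ = [
    "SplineBasisSpec",
    "PopulationCurveFit",
    "truncated_power_design",
    "default_basis",
    "fit_npme",
    "estimate_derivative",
    "augment_grid",
    "states_from_modules",
    "states_from_trajectory",
]


@dataclass
class SplineBasisSpec:
    """Truncated power basis {1, t, ..., t^l, (t - z_r)_+^l}."""

    degree: int = 2
    knots: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.size and np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def dim(self) -> int:
        return self.degree + 1 + self.n_knots


def default_basis(times: np.ndarray, degree: int = 2, max_knots: int = 10) -> SplineBasisSpec:
    """Knots at interior sample quantiles: R = min(floor(n_times/4), max_knots)."""
    times = np.unique(np.asarray(times, dtype=float))
    r = min(times.size // 4, max_knots)
    if r < 1:
        return SplineBasisSpec(degree=degree)
    q = np.linspace(0, 1, r + 2)[1:-1]
    knots = np.quantile(times, q)
    knots = np.unique(knots)
    return SplineBasisSpec(degree=degree, knots=knots)


def truncated_power_design(times: np.ndarray, spec: SplineBasisSpec):
    """Design matrices (S, Z): S columns 1, t, ..., t^l; Z columns (t - z_r)_+^l."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    l = spec.degree
    S = np.vander(times, l + 1, increasing=True)
    if spec.n_knots:
        Z = np.maximum(0.0, times[:, None] - spec.knots[None, :]) ** l
    else:
        Z = np.empty((times.size, 0))
    return S, Z


@dataclass
class PopulationCurveFit:
    """Fitted NPME model for one module.

    ``alpha`` and ``u`` give the population curve via the truncated
    power basis; ``per_gene_b`` / ``per_gene_w`` are the per-gene
    random-effect coefficient matrices; ``variance_components`` maps
    {'residual', 'knots', 'gene_poly', 'gene_knots'} to variances.
    """

    alpha: np.ndarray
    u: np.ndarray
    per_gene_b: np.ndarray
    per_gene_w: np.ndarray
    variance_components: dict
    basis: SplineBasisSpec
    converged: bool = True
    reml: float | None = None

    def population_curve(self, times: np.ndarray) -> np.ndarray:
        S, Z = truncated_power_design(times, self.basis)
        out = S @ self.alpha
        if self.u.size:
            out = out + Z @ self.u
        return out

    def gene_curve(self, i: int, times: np.ndarray) -> np.ndarray:
        S, Z = truncated_power_design(times, self.basis)
        out = self.population_curve(times) + S @ self.per_gene_b[i]
        if self.per_gene_w.size:
            out = out + Z @ self.per_gene_w[i]
        return out


def _henderson_solve(y, S, Z, m, ratios):
    """Mixed-model-equations solve at fixed variance ratios.

    Random effects: global knot coefficients u (ratio[0] = s2_u/s2_e),
    per-gene polynomial b_i (ratio[1]), per-gene knot w_i (ratio[2]).
    Returns (alpha, u, b, w) where b is (m, l+1) and w is (m, R).
    """
    n, p = S.shape
    R = Z.shape[1]
    per = n // m  # observations per gene (shared grid)
    blocks = [S, Z] if R else [S]
    # per-gene block-diagonal designs
    cols_b = []
    cols_w = []
    for i in range(m):
        sel = np.zeros((n, 1))
        sel[i * per:(i + 1) * per] = 1.0
        cols_b.append(S * sel)
        if R:
            cols_w.append(Z * sel)
    Xr = np.hstack([Z] if R else [np.empty((n, 0))] + [])
    B = np.hstack(cols_b)
    W = np.hstack(cols_w) if R else np.empty((n, 0))
    Zr = np.hstack([Xr, B, W])
    q = Zr.shape[1]
    d = np.concatenate(
        [
            np.full(R, 1.0 / max(ratios[0], 1e-10)),
            np.full(m * p, 1.0 / max(ratios[1], 1e-10)),
            np.full(m * R, 1.0 / max(ratios[2], 1e-10)),
        ]
    )
    C = np.block(
        [
            [S.T @ S, S.T @ Zr],
            [Zr.T @ S, Zr.T @ Zr + np.diag(d)],
        ]
    )
    rhs = np.concatenate([S.T @ y, Zr.T @ y])
    C[np.diag_indices_from(C)] += 1e-10
    sol = np.linalg.solve(C, rhs)
    alpha = sol[:p]
    v = sol[p:]
    u = v[:R]
    b = v[R:R + m * p].reshape(m, p)
    w = v[R + m * p:].reshape(m, R) if R else np.empty((m, 0))
    return alpha, u, b, w, Zr, d


def _reml_neg_loglik(log_theta, y, S, Z, m):
    """-2 x REML log-likelihood at log variance ratios + log residual var."""
    ratios = np.exp(log_theta[:3])
    s2e = np.exp(log_theta[3])
    n, p = S.shape
    alpha, u, b, w, Zr, d = _henderson_solve(y, S, Z, m, ratios)
    # V = s2e * (I + Zr D^{-1} Zr^T); Woodbury: (V/s2e)^{-1} = I - Zr (D + Zr^T Zr)^{-1} Zr^T
    K = np.diag(d) + Zr.T @ Zr
    sign_k, logdet_K = np.linalg.slogdet(K)
    if sign_k <= 0:
        return 1e10
    Kinv_ZrT = np.linalg.solve(K, Zr.T)

    def vinv(x):
        return (x - Zr @ (Kinv_ZrT @ x)) / s2e

    ViS = vinv(S)
    Viy = vinv(y)
    F = S.T @ ViS
    sign_f, logdet_F = np.linalg.slogdet(F)
    if sign_f <= 0:
        return 1e10
    beta = np.linalg.solve(F, S.T @ Viy)
    resid_quad = y @ Viy - (S.T @ Viy) @ beta
    # log|V| = n log s2e + log|I + Zr D^{-1} Zr^T| = n log s2e + log|K| - log|D|
    logdet_V = n * np.log(s2e) + logdet_K - np.sum(np.log(d))
    return logdet_V + logdet_F + resid_quad


def fit_npme(
    module_data: ExpressionMatrix,
    spec: SplineBasisSpec | None = None,
    fallback_ratio: float = 1.0,
) -> PopulationCurveFit:
    """Fit the NPME model to one module's genes by REML.

    Falls back to a fixed knot-shrinkage ratio of ``fallback_ratio``
    (variance ratio 1.0 on all random effects) if the REML optimizer
    does not converge, with a warning.
    """
    times = module_data.times
    m = module_data.n_genes
    if spec is None:
        spec = default_basis(times)
    if np.unique(times).size < spec.degree + 2:
        raise ValueError("need at least degree + 2 distinct timepoints")
    S1, Z1 = truncated_power_design(times, spec)
    # stack genes; shared grid means simple tiling
    S = np.tile(S1, (m, 1))
    Z = np.tile(Z1, (m, 1))
    y = module_data.values.reshape(-1)
    if np.linalg.matrix_rank(S1) < S1.shape[1]:
        raise np.linalg.LinAlgError("singular polynomial design: too few distinct timepoints")

    x0 = np.array([0.0, 0.0, 0.0, np.log(max(np.var(y), 1e-8))])
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _reml_neg_loglik,
                x0,
                args=(y, S, Z, m),
                method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-5, "fatol": 1e-7},
            )
        theta = res.x
        converged = bool(res.success)
    except (np.linalg.LinAlgError, ValueError):
        converged = False
        theta = x0
    if not converged:
        warnings.warn(
            "REML did not converge; falling back to fixed variance ratio "
            f"{fallback_ratio}",
            RuntimeWarning,
        )
        theta = np.array([np.log(fallback_ratio)] * 3 + [np.log(max(np.var(y), 1e-8))])

    ratios = np.exp(theta[:3])
    s2e = float(np.exp(theta[3]))
    alpha, u, b, w, _, _ = _henderson_solve(y, S, Z, m, ratios)
    return PopulationCurveFit(
        alpha=alpha,
        u=u,
        per_gene_b=b,
        per_gene_w=w,
        variance_components={
            "residual": s2e,
            "knots": s2e * ratios[0],
            "gene_poly": s2e * ratios[1],
            "gene_knots": s2e * ratios[2],
        },
        basis=spec,
        converged=converged,
        reml=None if not converged else -0.5 * float(_reml_neg_loglik(theta, y, S, Z, m)),
    )


def estimate_derivative(grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """First derivative by analytic differentiation of a cubic
    interpolating spline through (grid, values).

    Not-a-knot boundary conditions are used: natural boundaries (zero
    second derivative at the ends) distort the derivative near the grid
    ends by orders of magnitude whenever the underlying curve has
    nonzero curvature there, and those boundary artifacts propagate into
    the downstream variable selection.  Endpoint values remain the
    least-accurate part of the estimate and are flagged downstream.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be strictly increasing and unique")
    cs = CubicSpline(grid, values, bc_type="not-a-knot")
    return cs(grid, 1)


def augment_grid(t_min: float, t_max: float, n: int) -> np.ndarray:
    """n equally spaced points on [t_min, t_max] including both endpoints."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not t_min < t_max:
        raise ValueError("t_min must be < t_max")
    return np.linspace(t_min, t_max, n)


def states_from_modules(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    n_grid: int = 300,
    spec: SplineBasisSpec | None = None,
) -> StateSet:
    """Run the smoothing step for every module: NPME population curves
    evaluated on an augmented grid, derivatives by spline differentiation."""
    labels = np.asarray(labels)
    modules = np.unique(labels)
    grid = augment_grid(expr.times.min(), expr.times.max(), n_grid)
    states = np.empty((n_grid, modules.size))
    derivs = np.empty_like(states)
    for j, mod in enumerate(modules):
        sub = ExpressionMatrix(
            gene_ids=[g for g, l in zip(expr.gene_ids, labels) if l == mod],
            times=expr.times,
            values=expr.values[labels == mod],
        )
        fit = fit_npme(sub, spec=spec)
        states[:, j] = fit.population_curve(grid)
        derivs[:, j] = estimate_derivative(grid, states[:, j])
    flags = np.zeros(n_grid, dtype=bool)
    flags[0] = flags[-1] = True  # natural-spline boundary: lower confidence
    return StateSet(
        grid=grid,
        states=states,
        derivatives=derivs,
        module_names=[str(mod) for mod in modules],
        boundary_flags=flags,
    )


def states_from_trajectory(traj: TrajectorySet) -> StateSet:
    """StateSet for simulated data: states are the integrated trajectories
    themselves; only the derivative pass is applied."""
    derivs = np.column_stack(
        [estimate_derivative(traj.grid, traj.states[:, p]) for p in range(traj.states.shape[1])]
    )
    return StateSet(grid=traj.grid, states=traj.states, derivatives=derivs)
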