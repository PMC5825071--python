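"""SCAD-penalized profile least-squares models for ODE gradient matching.

Two model families regress a module's estimated derivative Y_i on the
module state vector X_i:

* :class:`SingleIndexODE` — Y = eta(X^T beta) + eps with unknown smooth
  link eta (profiled out by local-linear kernel regression) and
  unit-norm beta.  Fitted by penalized profile least squares: the
  objective is 0.5*Q(beta) + N * sum_j p_lam(|beta_j|) with Q the
  profile loss and p_lam the SCAD penalty, minimized by local quadratic
  approximation (LQA) of the penalty with a quasi-Newton inner solve and
  renormalization after every outer step.

* :class:`LinearODE` — Y = X^T beta + eps, the linear-ODE baseline, with
  the same SCAD/LQA machinery but closed-form ridge inner solves and no
  norm constraint.

Both expose ``fit(lam)`` for a single penalty level and ``fit_path()``
for a warm-started path with BIC tuning:
BIC(lam) = log(MSE) + (log N / N) * DF, DF = number of nonzeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import kernel_link as kl

__all__ = [
    "PenaltySpec",
    "scad_penalty",
    "scad_derivative",
    "mse_bic",
    "SingleIndexODE",
    "SingleIndexODEResults",
    "LinearODE",
    "LinearODEResults",
    "classify_fit",
    "replication_metrics",
]


@dataclass
class PenaltySpec:
    """SCAD penalty configuration: level ``lam``, shape ``a`` (> 2) and
    the magnitude ``zero_threshold`` below which coefficients are set to
    exactly zero during the LQA iterations."""

    lam: float = 0.0
    a: float = 3.7
    zero_threshold: float = 1e-4

    def __post_init__(self):
        if self.a <= 2:
            raise ValueError("SCAD shape parameter a must be > 2")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.zero_threshold <= 0:
            raise ValueError("zero_threshold must be > 0")


def scad_penalty(theta, lam, a=3.7):
    """SCAD penalty p_lam(theta) for theta >= 0.

    lam*theta on [0, lam]; (2*a*lam*theta - theta^2 - lam^2)/(2*(a-1))
    on (lam, a*lam]; lam^2*(a+1)/2 beyond.  Continuous with continuous
    derivative on (0, inf).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0 (pass |beta_j|)")
    out = np.where(
        theta <= lam,
        lam * theta,
        np.where(
            theta <= a * lam,
            (2 * a * lam * theta - theta**2 - lam**2) / (2 * (a - 1)),
            lam**2 * (a + 1) / 2,
        ),
    )
    return out if out.ndim else float(out)


def scad_derivative(theta, lam, a=3.7):
    """d/dtheta of the SCAD penalty: lam on [0, lam]; (a*lam - theta)/(a-1)
    on (lam, a*lam]; 0 beyond."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0 (pass |beta_j|)")
    out = np.where(
        theta <= lam,
        lam,
        np.maximum(a * lam - theta, 0.0) / (a - 1),
    )
    return out if out.ndim else float(out)


def mse_bic(mse: float, df: int, n_obs: int) -> float:
    """BIC(lam) = log(MSE) + (log N / N) * DF."""
    return math.log(mse) + math.log(n_obs) / n_obs * df


def _lqa_weights(beta, spec: PenaltySpec):
    """Penalty curvature weights p'(|b_j|)/|b_j| of the local quadratic
    approximation around the current iterate."""
    ab = np.abs(beta)
    return scad_derivative(ab, spec.lam, spec.a) / np.maximum(ab, 1e-8)


class _PathMixin:
    """Warm-started ascending lambda path with BIC selection (shared by
    both families)."""

    def fit_path(
        self,
        lambda_grid=None,
        n_lambdas: int = 30,
        lambda_min_ratio: float = 1e-3,
        init=None,
        **fit_kwargs,
    ):
        if lambda_grid is None:
            lam_max = self._lambda_max()
            lambda_grid = np.geomspace(lam_max * lambda_min_ratio, lam_max, n_lambdas)
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
        if lambda_grid.size == 0 or np.any(lambda_grid < 0):
            raise ValueError("lambda_grid must be non-empty and nonnegative")

        results = []
        warm = init
        for lam in lambda_grid:
            try:
                res = self.fit(lam=lam, init=warm, **fit_kwargs)
            except (ValueError, np.linalg.LinAlgError):  # pragma: no cover - rare
                import logging

                logging.getLogger(__name__).warning("lambda=%g fit failed; dropped", lam)
                continue
            results.append(res)
            warm = res.params
        if not results:
            raise RuntimeError("no lambda on the path produced a successful fit")

        path = pd.DataFrame(
            {
                "lam": [r.lam for r in results],
                "bic": [r.bic for r in results],
                "mse": [r.mse for r in results],
                "df": [r.df for r in results],
                "beta": [r.params.copy() for r in results],
            }
        )
        bics = path["bic"].to_numpy()
        # ties resolved toward larger lambda (the sparser model)
        best = len(bics) - 1 - int(np.argmin(bics[::-1]))
        selected = results[best]
        selected.lambda_path = path
        selected.selected_lambda = float(path["lam"].iloc[best])
        return selected


@dataclass
class SingleIndexODEResults:
    """Fit results of the single-index family.

    ``params`` is the unit-norm index vector with the first-nonzero-
    positive sign convention; ``active_set`` its nonzero support
    (0-based); ``rss`` equals the profile loss Q at ``params``.
    """

    model: "SingleIndexODE"
    params: np.ndarray
    lam: float
    rss: float
    converged: bool
    bandwidth_multiplier: float
    bandwidth: float
    n_outer_iterations: int

    lambda_path: pd.DataFrame | None = None
    selected_lambda: float | None = None
    model_family: str = "single-index"

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    @property
    def active_set(self):
        return tuple(int(j) for j in np.flatnonzero(self.params))

    @property
    def df(self) -> int:
        return len(self.active_set)

    @property
    def mse(self) -> float:
        return self.rss / self.nobs

    @property
    def bic(self) -> float:
        return mse_bic(self.mse, self.df, self.nobs)

    @property
    def link(self) -> kl.LinkEstimate:
        """Fitted link on a 200-point index grid (diagnostic)."""
        m = self.model
        return kl.link_on_grid(
            self.params, m.exog, m.endog, self.bandwidth, kernel=m.kernel
        )

    def fittedvalues(self) -> np.ndarray:
        m = self.model
        return m.endog - kl.profile_residuals(
            self.params, m.exog, m.endog, self.bandwidth_multiplier, m.kernel
        )

    def plot_link(self, ax=None):
        """Plot the estimated link over the observed index values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        le = self.link
        lam_idx = self.model.exog @ self.params
        ax.scatter(lam_idx, self.model.endog, s=8, alpha=0.4, label="observations")
        ax.plot(le.eval_points, le.values, color="C1", label="estimated link")
        ax.set_xlabel("index  $X^T\\hat\\beta$")
        ax.set_ylabel("derivative")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Single-index ODE (SCAD-penalized profile least squares)",
            "=" * 56,
            f"module index:      {self.model.module_index + 1}",
            f"n observations:    {self.nobs}",
            f"lambda:            {self.lam:.6g}"
            + (
                f"  (BIC-selected from a {len(self.lambda_path)}-point path)"
                if self.lambda_path is not None
                else ""
            ),
            f"kernel / h:        {self.model.kernel} / {self.bandwidth:.6g}",
            f"RSS (profile):     {self.rss:.6g}",
            f"BIC:               {self.bic:.6g}",
            f"converged:         {self.converged}",
            "",
            "coef        estimate   active",
        ]
        for j, b in enumerate(self.params):
            lines.append(f"beta_{j + 1:<6} {b: .6f}   {'*' if b != 0 else ''}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        le = self.link
        rep = {
            "family": self.model_family,
            "module": self.model.module_index + 1,
            "beta_hat": self.params.tolist(),
            "active_set": [j + 1 for j in self.active_set],
            "lambda": self.lam,
            "rss": self.rss,
            "mse": self.mse,
            "bic": self.bic,
            "converged": self.converged,
            "kernel": self.model.kernel,
            "bandwidth": self.bandwidth,
            "link": {
                "u": le.eval_points.tolist(),
                "eta": le.values.tolist(),
            },
        }
        if self.lambda_path is not None:
            rep["lambda_path"] = {
                "lam": self.lambda_path["lam"].tolist(),
                "bic": self.lambda_path["bic"].tolist(),
                "mse": self.lambda_path["mse"].tolist(),
                "df": [int(d) for d in self.lambda_path["df"]],
            }
            rep["selected_lambda"] = self.selected_lambda
        return rep


class SingleIndexODE(_PathMixin):
    """Single-index ODE model for one module's derivative.

    Parameters
    ----------
    endog : ndarray, shape (N,)
        Estimated derivative of the target module (the response Y).
    exog : ndarray, shape (N, p)
        Module state curves evaluated on the same grid.
    module_index : int
        0-based index k of the target module (metadata only).
    kernel : {'gaussian', 'epanechnikov'}
    bandwidth_candidates : sequence of float
        GCV candidate multipliers for h = c * sd(index) * N^(-1/5).
    """

    def __init__(
        self,
        endog,
        exog,
        module_index: int = 0,
        kernel: str = "gaussian",
        bandwidth_candidates=kl.DEFAULT_BANDWIDTH_MULTIPLIERS,
        penalty_a: float = 3.7,
        zero_threshold: float = 1e-4,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (N, p) matching endog length N")
        if self.exog.shape[0] <= self.exog.shape[1]:
            import warnings

            warnings.warn("N <= p: profile fits may be unstable", RuntimeWarning)
        self.module_index = module_index
        self.kernel = kernel
        self.bandwidth_candidates = tuple(bandwidth_candidates)
        self.penalty_a = penalty_a
        self.zero_threshold = zero_threshold

    @classmethod
    def from_states(cls, states, k: int, **kwargs) -> "SingleIndexODE":
        """Build the model for module k (0-based) from a StateSet."""
        return cls(states.derivatives[:, k], states.states, module_index=k, **kwargs)

    @property
    def n_params(self) -> int:
        return self.exog.shape[1]

    def _default_init(self) -> np.ndarray:
        """OLS direction, normalized — the standard single-index start."""
        coef, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        if np.linalg.norm(coef) == 0:
            coef = np.ones(self.n_params)
        return kl.normalize_index(coef, self.module_index).beta

    def _lambda_max(self) -> float:
        # unit norm caps every |beta_j| at 1, so lam = 1 places all
        # coefficients in SCAD's maximal-shrinkage segment and forces the
        # sparsest feasible (single-coefficient) model
        return 1.0

    def _objective_pieces(self, beta, spec, c_mult):
        q = kl.profile_loss(beta, self.exog, self.endog, c_mult, self.kernel)
        pen = float(np.sum(scad_penalty(np.abs(beta), spec.lam, spec.a)))
        return q, 0.5 * q + self.endog.shape[0] * pen

    def fit(
        self,
        lam: float = 0.0,
        init=None,
        bandwidth_multiplier: float | None = None,
        maxiter_outer: int = 50,
        maxiter_inner: int = 60,
        tol: float = 1e-6,
    ) -> SingleIndexODEResults:
        """Fit at a single penalty level by LQA + bounded quasi-Newton.

        Coefficients falling below ``zero_threshold`` in magnitude are
        frozen at exactly zero for the remaining iterations (exact zeros
        in ``init`` start frozen, which is what warm-started ascending
        paths rely on).  The penalized objective is non-increasing over
        accepted outer iterations; a non-improving step terminates the
        loop with the previous iterate.
        """
        spec = PenaltySpec(lam=lam, a=self.penalty_a, zero_threshold=self.zero_threshold)
        n = self.endog.shape[0]
        if init is None:
            beta = self._default_init()
        else:
            beta = kl.normalize_index(np.asarray(init, dtype=float), self.module_index).beta
        # coordinates that start at exact zero stay frozen: penalized
        # fits cannot revive a zero under LQA, and unpenalized candidate
        # fits are refined within their own support, so sparse starting
        # directions compete as genuinely sparse index models
        free = beta != 0.0
        if not free.any():
            raise ValueError("init has no nonzero coefficients")

        if bandwidth_multiplier is None:
            c_mult, _, _ = kl.select_bandwidth(
                beta, self.exog, self.endog, self.bandwidth_candidates, self.kernel
            )
        else:
            c_mult = bandwidth_multiplier

        _, lp_cur = self._objective_pieces(beta, spec, c_mult)
        converged = False
        n_outer = 0
        for n_outer in range(1, maxiter_outer + 1):
            w = np.zeros(self.n_params)
            if lam > 0:
                w[free] = _lqa_weights(beta[free], spec)
            idx = np.flatnonzero(free)

            def obj(bf):
                full = np.zeros(self.n_params)
                full[idx] = bf
                q = kl.profile_loss(full, self.exog, self.endog, c_mult, self.kernel)
                return 0.5 * q + 0.5 * n * float(np.sum(w[idx] * bf**2))

            res = optimize.minimize(
                obj,
                beta[idx],
                method="L-BFGS-B",
                jac=None,
                options={"maxiter": maxiter_inner, "ftol": 1e-12, "gtol": 1e-8},
            )
            cand = np.zeros(self.n_params)
            cand[idx] = res.x
            if lam > 0:
                small = np.abs(cand) < spec.zero_threshold
                if small.all() and np.any(cand):
                    # unit norm forbids the all-zero solution: keep the
                    # single best coefficient (sparsest feasible model)
                    small[int(np.argmax(np.abs(cand)))] = False
                cand[small] = 0.0
            if not np.any(cand):
                raise ValueError(
                    "all coefficients thresholded to zero: cannot normalize the index"
                )
            cand = kl.normalize_index(cand, self.module_index).beta
            _, lp_new = self._objective_pieces(cand, spec, c_mult)
            if lp_new > lp_cur + 1e-10:
                break  # non-improving LQA step: keep the previous iterate
            move = float(np.linalg.norm(cand - beta))
            beta = cand
            free = beta != 0.0
            lp_cur = lp_new
            if move < tol:
                converged = True
                break
            if lam == 0 and n_outer >= 2:
                converged = True
                break

        rss = kl.profile_loss(beta, self.exog, self.endog, c_mult, self.kernel)
        lam_idx = self.exog @ beta
        return SingleIndexODEResults(
            model=self,
            params=beta,
            lam=lam,
            rss=rss,
            converged=converged,
            bandwidth_multiplier=c_mult,
            bandwidth=kl.bandwidth_from_multiplier(c_mult, lam_idx),
            n_outer_iterations=n_outer,
        )

    def _candidate_directions(self, n_random: int, seed: int, n_angles: int = 12) -> list:
        """Starting directions for the multimodal profile surface.

        Regulatory indices are sparse, so two-coordinate directions are
        the natural candidates: for every coordinate pair (j, k) the
        index cos(t)*e_j + sin(t)*e_k is profiled over an angle grid and
        the best angle kept.  The OLS direction and seeded random unit
        vectors complete the set.  A raw profile-loss screen over
        un-refined directions is a poor basin predictor; the per-pair
        angle refinement makes the screen informative.
        """
        p = self.n_params
        cands = [self._default_init()]
        angles = np.linspace(-np.pi / 2, np.pi / 2, n_angles, endpoint=False)
        eye = np.eye(p)
        for j in range(p):
            for k in range(j + 1, p):
                best, best_q = None, np.inf
                for th in angles:
                    v = np.cos(th) * eye[j] + np.sin(th) * eye[k]
                    q = kl.profile_loss(v, self.exog, self.endog, 1.0, self.kernel)
                    if q < best_q:
                        best, best_q = v, q
                cands.append(best)
        rng = np.random.default_rng(seed)
        for _ in range(n_random):
            cands.append(kl.normalize_index(rng.standard_normal(p)).beta)
        return cands

    def fit_unpenalized_multistart(
        self, n_starts: int = 3, n_random: int = 20, seed: int = 0, **kwargs
    ):
        """Unpenalized profile LS robust to the multimodal profile surface
        of nonlinear links.

        A structured candidate set (:meth:`_candidate_directions`) is
        screened by a single profile-loss evaluation each; the best
        ``n_starts`` candidates are optimized fully and the lowest-Q fit
        returned.  The GCV bandwidth multiplier is selected once at the
        best screening candidate and shared by all starts so their
        profile losses are comparable.
        """
        cands = self._candidate_directions(n_random, seed)
        qs = np.array(
            [kl.profile_loss(v, self.exog, self.endog, 1.0, self.kernel) for v in cands]
        )
        order = np.argsort(qs)
        c_mult, _, _ = kl.select_bandwidth(
            cands[order[0]], self.exog, self.endog, self.bandwidth_candidates, self.kernel
        )
        kwargs.setdefault("bandwidth_multiplier", c_mult)
        best = None
        for i in order[:n_starts]:
            res = self.fit(lam=0.0, init=cands[i], **kwargs)
            if best is None or res.rss < best.rss:
                best = res
        return best

    def fit_path(self, lambda_grid=None, n_starts: int = 4, seed: int = 0, **kwargs):
        """BIC-tuned warm-started path; the smallest-lambda fit is
        initialized by multistart unpenalized profile LS.

        The GCV bandwidth multiplier selected at the multistart base fit
        is shared by every fit on the path, so the MSEs entering the BIC
        comparison are computed at a common smoothing level (per-lambda
        reselection would let undersmoothed fits win on MSE alone).
        """
        base = self.fit_unpenalized_multistart(n_starts=n_starts, seed=seed)
        kwargs.setdefault("bandwidth_multiplier", base.bandwidth_multiplier)
        return _PathMixin.fit_path(self, lambda_grid=lambda_grid, init=base.params, **kwargs)


@dataclass
class LinearODEResults:
    """Fit results of the linear-ODE baseline (no norm constraint)."""

    model: "LinearODE"
    params: np.ndarray
    lam: float
    rss: float
    converged: bool
    n_outer_iterations: int

    lambda_path: pd.DataFrame | None = None
    selected_lambda: float | None = None
    model_family: str = "linear"

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    @property
    def active_set(self):
        return tuple(int(j) for j in np.flatnonzero(self.params))

    @property
    def df(self) -> int:
        return len(self.active_set)

    @property
    def mse(self) -> float:
        return self.rss / self.nobs

    @property
    def bic(self) -> float:
        return mse_bic(self.mse, self.df, self.nobs)

    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params

    def summary(self) -> str:
        lines = [
            "Linear ODE (SCAD-penalized least squares)",
            "=" * 42,
            f"module index:      {self.model.module_index + 1}",
            f"n observations:    {self.nobs}",
            f"lambda:            {self.lam:.6g}",
            f"RSS:               {self.rss:.6g}",
            f"BIC:               {self.bic:.6g}",
            "",
            "coef        estimate   active",
        ]
        for j, b in enumerate(self.params):
            lines.append(f"beta_{j + 1:<6} {b: .6f}   {'*' if b != 0 else ''}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        rep = {
            "family": self.model_family,
            "module": self.model.module_index + 1,
            "beta_hat": self.params.tolist(),
            "active_set": [j + 1 for j in self.active_set],
            "lambda": self.lam,
            "rss": self.rss,
            "mse": self.mse,
            "bic": self.bic,
            "converged": self.converged,
        }
        if self.lambda_path is not None:
            rep["lambda_path"] = {
                "lam": self.lambda_path["lam"].tolist(),
                "bic": self.lambda_path["bic"].tolist(),
                "mse": self.lambda_path["mse"].tolist(),
                "df": [int(d) for d in self.lambda_path["df"]],
            }
            rep["selected_lambda"] = self.selected_lambda
        return rep


class LinearODE(_PathMixin):
    """Linear-ODE baseline Y = X^T beta + eps with SCAD selection."""

    def __init__(self, endog, exog, module_index: int = 0, penalty_a: float = 3.7,
                 zero_threshold: float = 1e-4):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (N, p) matching endog length N")
        self.module_index = module_index
        self.penalty_a = penalty_a
        self.zero_threshold = zero_threshold

    @classmethod
    def from_states(cls, states, k: int, **kwargs) -> "LinearODE":
        return cls(states.derivatives[:, k], states.states, module_index=k, **kwargs)

    @property
    def n_params(self) -> int:
        return self.exog.shape[1]

    def _lambda_max(self) -> float:
        n = self.endog.shape[0]
        return float(np.max(np.abs(self.exog.T @ self.endog)) / n)

    def fit(self, lam: float = 0.0, init=None, maxiter_outer: int = 50,
            tol: float = 1e-8) -> LinearODEResults:
        """LQA iterations with closed-form ridge inner solves; lam = 0 is
        ordinary least squares (pseudo-inverse, ridge-stabilized if the
        design is singular)."""
        spec = PenaltySpec(lam=lam, a=self.penalty_a, zero_threshold=self.zero_threshold)
        X, y = self.exog, self.endog
        n, p = X.shape
        xtx = X.T @ X
        xty = X.T @ y
        if lam == 0.0:
            if np.linalg.matrix_rank(xtx) < p:
                import warnings

                warnings.warn("singular design at lam=0: ridge-stabilized solve",
                              RuntimeWarning)
                beta = np.linalg.solve(xtx + 1e-8 * np.eye(p), xty)
            else:
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            return LinearODEResults(model=self, params=beta, lam=0.0, rss=rss,
                                    converged=True, n_outer_iterations=1)

        if init is None:
            beta = self.fit(lam=0.0).params
        else:
            beta = np.asarray(init, dtype=float).copy()
        free = beta != 0.0
        if not free.any():
            # an all-zero warm start is a valid (fully sparse) linear fit
            rss = float(np.sum(y**2))
            return LinearODEResults(model=self, params=beta, lam=lam, rss=rss,
                                    converged=True, n_outer_iterations=0)
        converged = False
        n_outer = 0
        for n_outer in range(1, maxiter_outer + 1):
            idx = np.flatnonzero(free)
            w = _lqa_weights(beta[idx], spec)
            A = xtx[np.ix_(idx, idx)] + n * np.diag(w)
            try:
                sol = np.linalg.solve(A, xty[idx])
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(A, xty[idx], rcond=None)[0]
            cand = np.zeros(p)
            cand[idx] = sol
            cand[np.abs(cand) < spec.zero_threshold] = 0.0
            move = float(np.linalg.norm(cand - beta))
            beta = cand
            free = beta != 0.0
            if not free.any():
                break
            if move < tol:
                converged = True
                break
        rss = float(np.sum((y - X @ beta) ** 2))
        return LinearODEResults(model=self, params=beta, lam=lam, rss=rss,
                                converged=converged, n_outer_iterations=n_outer)


def classify_fit(support_est, support_true) -> str:
    """Classify one replication's selected support against the truth.

    'C' — exact recovery; 'O' — all true variables plus extras;
    'U' — a strict subset of the truth (misses >= 1, no extras);
    'other' — both misses a true variable and includes a spurious one.
    The classes are exclusive and deliberately non-exhaustive.
    """
    est = frozenset(support_est)
    true = frozenset(support_true)
    if est == true:
        return "C"
    if est > true:
        return "O"
    if est < true:
        return "U"
    return "other"


def replication_metrics(estimates, truth, trim_fraction: float = 0.05) -> pd.DataFrame:
    """Replication summary per coefficient.

    MSE_q = mean_j (beta_hat_qj - beta_0q)^2; ARE_q = mean_j
    |beta_hat_qj - beta_0q| / |beta_0q| in percent (NaN where the true
    coefficient is zero).  Trimmed variants drop ceil(trim_fraction * n)
    of the lowest and highest per-replication values from each tail
    before averaging.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n_reps, p = estimates.shape
    if n_reps < 3:
        raise ValueError("need >= 3 replications for trimming")
    k = math.ceil(trim_fraction * n_reps)

    def trimmed_mean(v):
        v = np.sort(v)
        return float(np.mean(v[k:n_reps - k]))

    rows = []
    for q in range(p):
        sq = (estimates[:, q] - truth[q]) ** 2
        row = {
            "coefficient": q + 1,
            "mse": float(np.mean(sq)),
            "mse_trim": trimmed_mean(sq),
        }
        if truth[q] != 0:
            rel = np.abs(estimates[:, q] - truth[q]) / abs(truth[q]) * 100.0
            row["are_pct"] = float(np.mean(rel))
            row["are_trim_pct"] = trimmed_mean(rel)
        else:
            row["are_pct"] = np.nan
            row["are_trim_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
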