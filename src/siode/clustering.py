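"""Grouping genes into functional modules.

Time-course expression profiles are modelled as a finite mixture: gene
curve g_i ~ sum_k pi_k N(mu_k, sigma_k^2 I) over the shared time grid,
where each cluster mean mu_k is constrained to be a smooth curve (a
penalized-spline smooth in the truncated power basis).  The mixture is
fitted by EM with k-means initialization and multiple seeded restarts;
the number of modules is selected by BIC over a candidate range.

The smoothing enters the M-step: each cluster mean is the penalized
smooth of the responsibility-weighted average profile, so EM ascends the
penalized log-likelihood (log-likelihood minus the spline roughness
penalty of the means) rather than the raw likelihood.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, ModuleAssignment
from .smoothing import SplineBasisSpec, default_basis, truncated_power_design

__all__ = ["cluster_expression_curves", "mixture_bic"]


def mixture_bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Standard Bayesian information criterion -2*loglik + n_params*log(n_obs)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_obs)


def _smoother_matrix(times: np.ndarray, spec: SplineBasisSpec, penalty: float) -> np.ndarray:
    """Hat matrix of the penalized truncated-power smooth: ridge on the
    knot coefficients only."""
    S, Z = truncated_power_design(times, spec)
    B = np.hstack([S, Z])
    pen = np.zeros(B.shape[1])
    pen[S.shape[1]:] = penalty
    A = B.T @ B + np.diag(pen)
    A[np.diag_indices_from(A)] += 1e-10
    return B @ np.linalg.solve(A, B.T)


def _penalized_loglik(values, means, variances, props, H_pen_quad):
    """Log-likelihood of the mixture minus the roughness penalty of the
    cluster means (the objective EM ascends)."""
    n, T = values.shape
    K = means.shape[0]
    ll = np.empty((n, K))
    for k in range(K):
        r2 = np.sum((values - means[k]) ** 2, axis=1)
        ll[:, k] = (
            np.log(props[k] + 1e-300)
            - 0.5 * T * np.log(2 * np.pi * variances[k])
            - 0.5 * r2 / variances[k]
        )
    m = ll.max(axis=1)
    loglik = float(np.sum(m + np.log(np.sum(np.exp(ll - m[:, None]), axis=1))))
    return loglik - H_pen_quad(means), ll


def _em_once(values, times, K, spec, penalty, seed, max_iter=200, tol=1e-8):
    n, T = values.shape
    H = _smoother_matrix(times, spec, penalty)
    # roughness penalty implied by the ridge smooth, expressed through the
    # basis-coefficient fit of each mean; evaluated via the residual of the
    # smooth (quadratic form equivalent up to the basis projection)
    S, Z = truncated_power_design(times, spec)
    B = np.hstack([S, Z])
    pen_vec = np.zeros(B.shape[1])
    pen_vec[S.shape[1]:] = penalty
    A = B.T @ B + np.diag(pen_vec)
    A[np.diag_indices_from(A)] += 1e-10
    Ainv_Bt = np.linalg.solve(A, B.T)

    def roughness(means):
        tot = 0.0
        for mu in means:
            coef = Ainv_Bt @ mu
            tot += 0.5 * float(np.sum(pen_vec * coef**2))
        return tot

    km = KMeans(n_clusters=K, n_init=3, random_state=seed)
    labels0 = km.fit_predict(values)
    resp = np.full((n, K), 1e-3)
    resp[np.arange(n), labels0] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)

    means = np.zeros((K, T))
    variances = np.full(K, np.var(values))
    props = np.full(K, 1.0 / K)
    prev = -np.inf
    history = []
    for _ in range(max_iter):
        # M-step: smoothed weighted means, then variances and proportions
        wsum = resp.sum(axis=0)
        if np.any(wsum < 1e-8):
            raise _EmptyCluster()
        for k in range(K):
            wavg = resp[:, k] @ values / wsum[k]
            means[k] = H @ wavg
            variances[k] = max(
                float(resp[:, k] @ np.sum((values - means[k]) ** 2, axis=1) / (wsum[k] * T)),
                1e-10,
            )
        props = wsum / n
        # E-step
        pen_ll, ll = _penalized_loglik(values, means, variances, props, roughness)
        m = ll.max(axis=1)
        post = np.exp(ll - m[:, None])
        post /= post.sum(axis=1, keepdims=True)
        resp = post
        history.append(pen_ll)
        if pen_ll - prev < tol and np.isfinite(prev):
            break
        prev = pen_ll
    loglik_raw, _ = _penalized_loglik(values, means, variances, props, lambda mm: 0.0)
    return resp, means, variances, props, loglik_raw, history


class _EmptyCluster(Exception):
    pass


def cluster_expression_curves(
    expr: ExpressionMatrix,
    k_range=range(1, 6),
    spec: SplineBasisSpec | None = None,
    seed: int = 0,
    n_starts: int = 10,
    penalty: float = 1.0,
) -> ModuleAssignment:
    """Cluster genes into modules and select K by BIC.

    For each K in ``k_range`` the EM mixture is run from ``n_starts``
    seeded k-means initializations and the best (highest penalized
    log-likelihood) kept; the returned assignment minimizes BIC with
    n_params = K * basis_dim + K + (K - 1) (means, variances,
    proportions) and the genes as the independent observations.  Module
    labels are relabelled canonically by first gene occurrence.
    """
    values = expr.values
    n = values.shape[0]
    if spec is None:
        spec = default_basis(expr.times)
    k_range = [int(k) for k in k_range]
    if any(k < 1 or k > n for k in k_range):
        raise ValueError("k_range must lie within [1, n_genes]")

    bic_by_k = {}
    best_overall = None
    for K in k_range:
        best = None
        for s in range(n_starts):
            try:
                out = _em_once(values, expr.times, K, spec, penalty, seed + 1000 * s)
            except _EmptyCluster:
                continue
            if best is None or out[4] > best[4]:
                best = out
        if best is None:
            raise RuntimeError(f"all {n_starts} EM starts collapsed for K={K}")
        resp, means, variances, props, loglik, _ = best
        n_params = K * (spec.dim) + K + (K - 1)
        bic = mixture_bic(loglik, n_params, n)
        bic_by_k[K] = float(bic)
        if best_overall is None or bic < best_overall[0]:
            best_overall = (bic, K, resp, means, variances)

    _, k_sel, resp, means, variances = best_overall
    labels = resp.argmax(axis=1)
    # canonical relabelling: clusters ordered by their first member gene
    order = []
    for lab in labels:
        if lab not in order:
            order.append(int(lab))
    for k in range(k_sel):
        if k not in order:
            order.append(k)
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    resp = resp[:, order]
    means = means[order]
    variances = variances[np.asarray(order)]
    return ModuleAssignment(
        labels=labels,
        responsibilities=resp,
        mean_curves=means,
        noise_variances=variances,
        k_selected=k_sel,
        bic_by_k=bic_by_k,
        gene_ids=list(expr.gene_ids),
    )
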