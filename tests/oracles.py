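"""Independent oracle implementations used to cross-check the package.

These deliberately avoid the code paths of the package: the maximized score
statistic is recomputed by direct numerical optimization over the weight
vector, by the nonsymmetric K-by-K eigenvalue form, and (with covariates)
from the explicit projection matrix of the covariate design.
"""

import numpy as np
import scipy.linalg
import scipy.optimize


def score_ratio_max(Xc, Yc, n_starts=8, seed=0):
    """Numerically maximize w'X'Y(Y'Y)^{-1}Y'Xw / (w'Aw) over w.

    Multistart L-BFGS with the analytic gradient of the generalized Rayleigh
    quotient. Xc, Yc must be column-centered.
    """
    n = Xc.shape[0]
    A = np.diag((Xc * Xc).sum(axis=0) / n)
    N = Xc.T @ Yc @ np.linalg.solve(Yc.T @ Yc, Yc.T @ Xc)

    def neg_ratio_and_grad(w):
        Aw = A @ w
        Nw = N @ w
        denom = w @ Aw
        ratio = (w @ Nw) / denom
        grad = 2.0 * (Nw - ratio * Aw) / denom
        return -ratio, -grad

    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_starts):
        w0 = rng.standard_normal(Xc.shape[1])
        res = scipy.optimize.minimize(
            neg_ratio_and_grad,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"gtol": 1e-14, "ftol": 1e-16, "maxiter": 5000},
        )
        best = max(best, -res.fun)
    return best


def nonsymmetric_eigen_stat(Xc, Yc):
    """Largest eigenvalue of (Y'Y)^{-1} Y' C Y with C = X A^{-1} X'."""
    n = Xc.shape[0]
    A = (Xc * Xc).sum(axis=0) / n
    C = Xc @ np.diag(1.0 / A) @ Xc.T
    M = np.linalg.solve(Yc.T @ Yc, Yc.T @ C @ Yc)
    return float(np.max(np.real(np.linalg.eigvals(M))))


def projection_residuals(M, Z):
    """Residual maker from the textbook projector P = D (D'D)^{-1} D'."""
    n = M.shape[0]
    D = np.column_stack([np.ones(n), Z]) if Z is not None else np.ones((n, 1))
    P = D @ np.linalg.solve(D.T @ D, D.T)
    return (np.eye(n) - P) @ M


def covariate_score_stat(X, Y, Z):
    """Maximized covariate-adjusted score statistic from projection matrices.

    Builds U = Y'(I-P)Xw, V = Y'(I-P)Y and sigma^2 = w'X'(I-P)Xw/n with the
    explicit projector (diagonal-A simplification applied), and maximizes
    U'V^{-1}U / sigma^2 over w via the generalized eigenvalue problem.
    """
    n = X.shape[0]
    D = np.column_stack([np.ones(n), Z]) if Z is not None else np.ones((n, 1))
    P = D @ np.linalg.solve(D.T @ D, D.T)
    Q = np.eye(n) - P
    Xt = Q @ X
    Yt = Q @ Y
    A = np.diag((Xt * Xt).sum(axis=0) / n)
    N = Xt.T @ Yt @ np.linalg.solve(Yt.T @ Yt, Yt.T @ Xt)
    vals = scipy.linalg.eigvalsh(N, A)
    return float(vals[-1])
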