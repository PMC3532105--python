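"""Source-based morphometry: MDL order selection, infomax ICA of
subject x voxel GMC matrices, and loading-level group tests.

The decomposition follows ``X = A S``: ``S`` holds spatially
independent maps (components x voxels, z-scored) and ``A`` the subject
loadings, defined by pseudo-inverse back-projection so that ``A S``
equals the rank-k PCA approximation of the (row-centered) data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .linmod import build_design, ols

__all__ = [
    "Decomposition",
    "estimate_order_mdl",
    "fix_signs",
    "infomax_ica",
    "loading_covariate_regression",
    "network_group_test",
]


@dataclass
class Decomposition:
    S: np.ndarray  # k x voxels, z-scored rows
    A: np.ndarray  # subjects x k
    k: int
    variance_explained: float
    row_means: np.ndarray  # per-subject offsets removed before whitening
    n_iter: int = 0
    converged: bool = True
    final_delta: float = 0.0
    seed: int | None = None

    def reconstruct(self) -> np.ndarray:
        return self.A @ self.S + self.row_means


def estimate_order_mdl(
    X: np.ndarray,
    voxel_stride: int = 5,
    seed: int = 0,
    max_k: int | None = None,
    random_subsample: bool = False,
) -> int:
    """MDL estimate of the number of components.

    Voxels are subsampled (strided by default, random with
    ``random_subsample``) to break spatial autocorrelation; the
    criterion combines the log of the arithmetic/geometric mean ratio
    of trailing subject-covariance eigenvalues with the usual
    parameter-count penalty, minimized over candidate orders.
    """
    X = np.asarray(X, dtype=float)
    n, V = X.shape
    if n < 10:
        raise ValueError("MDL order estimation needs at least 10 subjects")
    if random_subsample:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(V, size=max(V // voxel_stride, n + 1), replace=False))
    else:
        idx = np.arange(0, V, voxel_stride)
    Y = X[:, idx]
    N = Y.shape[1]
    if N <= n:
        raise ValueError("fewer voxels than subjects after subsampling")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    C = (Yc @ Yc.T) / N
    lam = np.linalg.eigvalsh(C)[::-1]
    lam = np.clip(lam, 1e-12, None)

    K = max_k if max_k is not None else n - 1
    K = min(K, n - 1)
    best_k, best_val = 0, np.inf
    for k in range(K + 1):
        tail = lam[k:]
        m = len(tail)
        log_g = float(np.mean(np.log(tail)))
        log_a = float(np.log(np.mean(tail)))
        ll = -N * m * (log_g - log_a)
        pen = 0.5 * k * (2 * n - k) * np.log(N)
        val = ll + pen
        if val < best_val:
            best_val, best_k = val, k
    return best_k


def _whiten(Xc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten row-centered data to k dims: Z = K @ Xc with cov(Z)=I."""
    n, V = Xc.shape
    C = (Xc @ Xc.T) / V
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 1e-12, None)
    E = evecs[:, order]
    Kw = (E / np.sqrt(lam)).T  # k x n
    Kinv = E * np.sqrt(lam)  # n x k (pseudo-inverse of Kw)
    return Kw @ Xc, Kw, Kinv


def infomax_ica(
    X: np.ndarray,
    k: int,
    learning_rate: float = 0.1,
    max_iter: int = 1024,
    tol: float = 1e-6,
    seed: int = 0,
) -> Decomposition:
    """Natural-gradient infomax ICA with a logistic nonlinearity.

    Rows of ``X`` (subjects) are centered over voxels, PCA-whitened to
    ``k`` dimensions and unmixed by full-batch natural-gradient ascent
    with learning-rate annealing on oscillation. Non-convergence sets
    ``converged=False`` rather than raising. Components are ordered by
    explained variance, spatial maps are z-scored and loadings are the
    pseudo-inverse back-projection (``A S`` = rank-k approximation).
    """
    X = np.asarray(X, dtype=float)
    n, V = X.shape
    if not (0 < k <= min(n, V)):
        raise ValueError("k must satisfy 0 < k <= min(n_subjects, n_voxels)")
    row_means = X.mean(axis=1, keepdims=True)
    Xc = X - row_means
    Z, Kw, Kinv = _whiten(Xc, k)

    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.normal(size=(k, k)))[0]
    I = np.eye(k)
    lr = learning_rate
    prev_grad = None
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        U = W @ Z
        Y = special.expit(U)
        grad = (I + (1.0 - 2.0 * Y) @ U.T / V) @ W
        if prev_grad is not None and float((grad * prev_grad).sum()) < 0:
            lr *= 0.9  # oscillation: anneal
        prev_grad = grad
        step = lr * grad
        W = W + step
        delta = float(np.linalg.norm(step) / max(np.linalg.norm(W), 1e-12))
        if delta < tol:
            break
    converged = delta < tol

    M = W @ Kw  # k x n total unmixing
    S = M @ Xc  # k x V
    A = Kinv @ np.linalg.inv(W)  # n x k back-projection, A @ S = rank-k approx

    recon = A @ S
    total = float((Xc**2).sum())
    ve = 1.0 - float(((Xc - recon) ** 2).sum()) / total if total > 0 else 0.0

    # order by per-component energy, then z-score maps
    energy = (A**2).sum(axis=0) * (S**2).sum(axis=1)
    order = np.argsort(energy)[::-1]
    A, S = A[:, order], S[order]
    sd = S.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    A = A * sd[None, :]
    S = (S - S.mean(axis=1, keepdims=True)) / sd[:, None]

    return Decomposition(
        S=S,
        A=A,
        k=k,
        variance_explained=ve,
        row_means=row_means,
        n_iter=it,
        converged=converged,
        final_delta=delta,
        seed=seed,
    )


def fix_signs(dec: Decomposition) -> Decomposition:
    """Flip components so each spatial map has positive skewness.

    Idempotent; ``A @ S`` is unchanged."""
    flips = np.where(stats.skew(dec.S, axis=1) < 0, -1.0, 1.0)
    dec.S = dec.S * flips[:, None]
    dec.A = dec.A * flips[None, :]
    return dec


def _per_component_regression(
    A: np.ndarray,
    regressor: np.ndarray,
    regressor_name: str,
    age: np.ndarray,
    gender: np.ndarray,
    site: np.ndarray,
) -> pd.DataFrame:
    k = A.shape[1]
    D, names = build_design(age=age, gender=gender, site=site, extra={regressor_name: regressor})
    rows = []
    for i in range(k):
        fit = ols(A[:, i], D, names)
        beta, t, p = fit.coef(regressor_name)
        rows.append({"component": i, "beta": beta, "t": t, "p": p})
    out = pd.DataFrame(rows).set_index("component")
    out["bonferroni_threshold"] = 0.05 / k
    out["significant"] = out["p"] < 0.05 / k
    return out


def network_group_test(
    A: np.ndarray,
    diagnosis: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    site: np.ndarray,
) -> pd.DataFrame:
    """Per-component loading ~ diagnosis + age + gender + site dummies.

    Reports the diagnosis coefficient's p per component and flags
    passes at the Bonferroni threshold 0.05/k."""
    diag_arr = np.asarray(diagnosis)
    if diag_arr.dtype.kind in "OUS":
        diag = (diag_arr == "case").astype(float)
    else:
        diag = diag_arr.astype(float)
    if np.all(diag == diag[0]):
        raise ValueError("diagnosis has a single level")
    return _per_component_regression(np.asarray(A, dtype=float), diag, "diagnosis", age, gender, site)


def loading_covariate_regression(
    A: np.ndarray,
    dose: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    site: np.ndarray,
) -> pd.DataFrame:
    """Same machinery as :func:`network_group_test` with a continuous
    regressor (e.g. medication dose)."""
    dose = np.asarray(dose, dtype=float)
    if np.allclose(dose, dose[0]):
        raise ValueError("degenerate regressor: dose is constant")
    return _per_component_regression(np.asarray(A, dtype=float), dose, "dose", age, gender, site)
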