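"""Reference-guided multi-set CCA with joint ICA refinement.

The engine fuses K subjects x features matrices (one per imaging
modality) under the guidance of a per-subject scalar reference (here, a
DNA-methylation beta-value).  Each modality is PCA-whitened to M
dimensions, then per-modality weight matrices ``W_k`` are found that
maximize

    J = sum_{i<j} sum_c corr(D_i[:,c], D_j[:,c])^2
        + lambda * sum_k sum_c corr(D_k[:,c], ref)^2,

where ``D_k = Y_k W_k`` are canonical variates.  Squared correlations
make the objective smooth and sign-free; ``lambda`` trades inter-set
covariation against reference alignment (0 recovers plain multi-set
CCA).  Optimization is deflationary: each component's weight vectors are
updated by closed-form top-eigenvector steps, constrained to the
covariance-orthogonal complement of earlier components, so the objective
trace is non-decreasing and for K=2, lambda=0 the solution coincides
with classical CCA.

The canonical maps of all modalities are then concatenated and rotated
toward independence by ICA (natural-gradient infomax by default); final
subject loadings are least-squares projections of the data on the final
maps.  Gaussian sources make the ICA rotation unidentifiable (any
rotation of Gaussian factors is equally independent): the run still
converges numerically but the recovered maps are arbitrary within the
Gaussian subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg, stats
from scipy.special import expit

from .features import ModalityFeatures

__all__ = [
    "FusionConfig",
    "Whitener",
    "JointDecomposition",
    "LambdaSelection",
    "whiten",
    "fit_mcca_with_reference",
    "joint_ica",
    "compute_subject_loadings",
    "select_lambda_cv",
]


@dataclass
class FusionConfig:
    """Settings for the fusion engine.

    ``n_components=None`` means estimate per modality by MDL;
    ``lam=None`` means select by subject-wise cross-validation over
    ``lambda_grid``.
    """

    n_components: int | None = 20
    lam: float | None = 0.5
    max_iter: int = 1000
    tol: float = 1e-6
    ica_algorithm: str = "infomax"
    seed: int = 0
    cv_folds: int = 5
    lambda_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)

    def __post_init__(self) -> None:
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ica_algorithm not in ("infomax", "fastica-logcosh"):
            raise ValueError(f"unknown ica_algorithm {self.ica_algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lam is None and not self.lambda_grid:
            raise ValueError("lambda_grid must be non-empty when lam is None")


@dataclass
class Whitener:
    """Rank-M PCA whitening operator for one modality."""

    mean_: np.ndarray  # (p,)
    forward_: np.ndarray  # (p, M): (X - mean) @ forward_ = whitened
    dewhiten_: np.ndarray  # (M, p): whitened @ dewhiten_ + mean ~ X (rank-M)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) @ self.forward_

    def inverse_transform(self, Y: np.ndarray) -> np.ndarray:
        return np.asarray(Y, float) @ self.dewhiten_ + self.mean_


@dataclass
class JointDecomposition:
    """Canonical + ICA stages of one fusion run."""

    weights: list  # W_k (d_k x M), C_kk-orthonormal columns
    variates: list  # D_k (n x M) canonical variates
    objective_trace: np.ndarray
    converged: bool
    contributions: np.ndarray  # (M,) per-component objective contribution
    ref_correlations: np.ndarray  # (K, M) corr(D_k[:,c], reference)
    whiteners: list | None = None
    canonical_maps: list | None = None  # M x p_k per modality
    maps: list | None = None  # final joint maps (post-ICA), M x p_k
    loadings: list | None = None  # subjects x M per modality
    unmixing: np.ndarray | None = None  # M x M ICA rotation
    ica_converged: bool | None = None

    @property
    def n_components(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_modalities(self) -> int:
        return len(self.weights)


@dataclass
class LambdaSelection:
    lam: float
    grid: np.ndarray
    criterion: np.ndarray  # mean held-out |corr(D[:,0], ref)| per grid value


def whiten(features: "ModalityFeatures | np.ndarray", n_components: int) -> tuple[np.ndarray, Whitener]:
    """PCA-whiten a subjects x features matrix to M dimensions.

    The output has zero column means and identity sample covariance
    (ddof=1); the returned operator's ``inverse_transform`` reproduces
    the best rank-M approximation of the input.
    """
    X = features.data if isinstance(features, ModalityFeatures) else np.asarray(features, float)
    n, p = X.shape
    M = int(n_components)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if M > rank:
        raise ValueError(f"n_components={M} exceeds data rank {rank}")
    # deterministic sign convention
    signs = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    Y = U[:, :M] * np.sqrt(n - 1)
    forward = (Vt[:M].T / s[:M]) * np.sqrt(n - 1)
    dewhiten = (s[:M, None] * Vt[:M]) / np.sqrt(n - 1)
    return Y, Whitener(mean_=mean, forward_=forward, dewhiten_=dewhiten)


def _standardize(v: np.ndarray, what: str = "reference") -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{what} contains non-finite values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{what} is constant")
    return (v - v.mean()) / sd


def fit_mcca_with_reference(
    whitened: Sequence[np.ndarray],
    reference: np.ndarray,
    config: FusionConfig,
) -> JointDecomposition:
    """Canonical stage: maximize inter-set + reference-correlation objective.

    ``whitened`` holds K subjects x d_k matrices sharing subject order
    (d_k >= M; exactly whitened input gives square orthonormal weights).
    The reference is standardized internally.  Components are sorted by
    their contribution to the objective, descending.  Non-convergence is
    reported through ``converged=False`` with a warning, never silently.
    """
    Ys = [np.asarray(Y, dtype=float) for Y in whitened]
    K = len(Ys)
    if K < 2:
        raise ValueError("need at least 2 modalities")
    n = Ys[0].shape[0]
    if any(Y.shape[0] != n for Y in Ys):
        raise ValueError("all modalities must share subject order (row count)")
    M = config.n_components
    if M is None:
        raise ValueError("config.n_components must be set before fitting")
    if any(Y.shape[1] < M for Y in Ys):
        raise ValueError("whitened dimension smaller than n_components")
    lam = config.lam
    if lam is None:
        raise ValueError("config.lam must be set before fitting (use select_lambda_cv)")

    ref = _standardize(reference)
    Yc = [Y - Y.mean(axis=0) for Y in Ys]

    # covariance blocks and Cholesky factors; work in the transformed
    # space where within-modality covariance is the identity, so unit
    # vectors correspond to unit-variance variates and orthogonality
    # to uncorrelatedness.
    C = [[Yc[i].T @ Yc[j] / (n - 1) for j in range(K)] for i in range(K)]
    Ls = []
    for k in range(K):
        Ckk = C[k][k]
        jitter = 1e-12 * np.trace(Ckk) / Ckk.shape[0]
        Ls.append(linalg.cholesky(Ckk + jitter * np.eye(Ckk.shape[0]), lower=True))
    T = [[None] * K for _ in range(K)]
    for i in range(K):
        for j in range(K):
            if i != j:
                tmp = linalg.solve_triangular(Ls[i], C[i][j], lower=True)
                T[i][j] = linalg.solve_triangular(Ls[j], tmp.T, lower=True).T
    t_ref = [
        linalg.solve_triangular(Ls[k], Yc[k].T @ ref / (n - 1), lower=True) for k in range(K)
    ]

    # init from the lambda=0 multi-set solution (MAXVAR-style: common
    # subspace of the per-modality sphered data)
    Zs = [linalg.solve_triangular(Ls[k], Yc[k].T, lower=True).T for k in range(K)]
    G = np.linalg.svd(np.hstack(Zs), full_matrices=False)[0][:, :M]
    V_init = []
    for k in range(K):
        B = Zs[k].T @ G  # d_k x M
        Ub, _, Vb = np.linalg.svd(B, full_matrices=False)
        V_init.append(Ub @ Vb)

    dks = [Y.shape[1] for Y in Ys]
    V = [np.zeros((dks[k], M)) for k in range(K)]
    trace: list[float] = []
    converged = True
    J_locked = 0.0

    def _component_objective(vs: list[np.ndarray]) -> float:
        J = 0.0
        for i in range(K):
            for j in range(i + 1, K):
                J += float(vs[i] @ T[i][j] @ vs[j]) ** 2
            J += lam * float(t_ref[i] @ vs[i]) ** 2
        return J

    for c in range(M):
        vs = []
        for k in range(K):
            v0 = V_init[k][:, c].copy()
            if c > 0:
                Vf = V[k][:, :c]
                v0 -= Vf @ (Vf.T @ v0)
            nrm = np.linalg.norm(v0)
            if nrm < 1e-10:
                # degenerate init: any unit vector in the complement
                Vf = V[k][:, :c]
                Q = np.eye(dks[k]) - Vf @ Vf.T
                idx = int(np.argmax(np.diag(Q)))
                v0 = Q[:, idx]
                nrm = np.linalg.norm(v0)
            vs.append(v0 / nrm)

        J_prev = -np.inf
        comp_converged = False
        for _ in range(config.max_iter):
            for k in range(K):
                A = lam * np.outer(t_ref[k], t_ref[k])
                for j in range(K):
                    if j != k:
                        b = T[k][j] @ vs[j]
                        A += np.outer(b, b)
                if c > 0:
                    Vf = V[k][:, :c]
                    P = np.eye(dks[k]) - Vf @ Vf.T
                    A = P @ A @ P
                A = 0.5 * (A + A.T)
                evals, evecs = np.linalg.eigh(A)
                if evals[-1] <= 1e-14:
                    continue  # no signal direction for this modality
                w = evecs[:, -1]
                if c > 0:
                    Vf = V[k][:, :c]
                    w = w - Vf @ (Vf.T @ w)
                    w /= np.linalg.norm(w)
                if w @ vs[k] < 0:
                    w = -w
                vs[k] = w
            J_c = _component_objective(vs)
            trace.append(J_locked + J_c)
            if J_c - J_prev < config.tol:
                comp_converged = True
                break
            J_prev = J_c
        if not comp_converged:
            converged = False
        for k in range(K):
            V[k][:, c] = vs[k]
        J_locked += _component_objective(vs)

    if not converged:
        import warnings

        warnings.warn(
            "MCCA-with-reference did not converge within max_iter; "
            "results returned with converged=False",
            RuntimeWarning,
            stacklevel=2,
        )

    # per-component contributions, then sort descending (stable)
    contrib = np.empty(M)
    for c in range(M):
        contrib[c] = _component_objective([V[k][:, c] for k in range(K)])
    order = np.argsort(-contrib, kind="stable")
    V = [Vk[:, order] for Vk in V]
    contrib = contrib[order]

    W = [linalg.solve_triangular(Ls[k].T, V[k], lower=False) for k in range(K)]
    D = [Yc[k] @ W[k] for k in range(K)]
    ref_corr = np.vstack([t_ref[k] @ V[k] for k in range(K)])

    return JointDecomposition(
        weights=W,
        variates=D,
        objective_trace=np.asarray(trace),
        converged=converged,
        contributions=contrib,
        ref_correlations=ref_corr,
    )


def _infomax(Z: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float) -> tuple[np.ndarray, bool]:
    """Natural-gradient infomax ICA with logistic nonlinearity.

    ``Z`` is M x S, row-whitened.  Returns the M x M rotation and a
    convergence flag.  The learning rate follows a fixed decay schedule
    and halves on numerical blow-up.
    """
    M, S = Z.shape
    Q, _ = np.linalg.qr(rng.standard_normal((M, M)))
    W = Q
    lrate0 = 0.05
    eye = np.eye(M)
    converged = False
    it = 0
    while it < max_iter:
        lrate = lrate0 / (1.0 + it / 500.0)
        U = W @ Z
        Y = expit(U)
        dW = (eye + (1.0 - 2.0 * Y) @ U.T / S) @ W
        W_new = W + lrate * dW
        if not np.all(np.isfinite(W_new)) or np.abs(W_new).max() > 1e8:
            lrate0 *= 0.5
            Q, _ = np.linalg.qr(rng.standard_normal((M, M)))
            W = Q
            it += 1
            continue
        change = np.linalg.norm(W_new - W) / max(np.linalg.norm(W), 1e-12)
        W = W_new
        it += 1
        if change < tol:
            converged = True
            break
    return W, converged


def joint_ica(
    maps: np.ndarray,
    config: FusionConfig,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rotate concatenated canonical maps toward independence.

    ``maps`` is M x (sum of features); rows are the canonical maps of all
    modalities concatenated feature-wise.  Returns ``(unmixing, joint_maps,
    converged)`` with ``joint_maps = unmixing @ (maps - row means)``, rows
    scaled to unit SD and signed so the largest-magnitude entry is
    positive.
    """
    X = np.asarray(maps, dtype=float)
    M, S = X.shape
    if M < 2:
        raise ValueError("joint ICA needs at least 2 components")
    Xc = X - X.mean(axis=1, keepdims=True)
    rng = np.random.default_rng(config.seed)

    if config.ica_algorithm == "fastica-logcosh":
        from sklearn.decomposition import FastICA

        ica = FastICA(
            n_components=M,
            fun="logcosh",
            whiten="unit-variance",
            random_state=int(rng.integers(2**31 - 1)),
            max_iter=1000,
            tol=1e-8,
        )
        with np.errstate(all="ignore"):
            ica.fit(Xc.T)
        A = ica.components_
        converged = ica.n_iter_ < 1000
    else:
        # row whitening, then infomax rotation
        Cm = Xc @ Xc.T / S
        d, E = np.linalg.eigh(Cm)
        d = np.maximum(d, np.finfo(float).tiny)
        Wh = E @ np.diag(d**-0.5) @ E.T
        Z = Wh @ Xc
        Wrot, converged = _infomax(Z, rng, max_iter=5000, tol=1e-6)
        A = Wrot @ Wh

    sources = A @ Xc
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    A = A / sd[:, None]
    sources = sources / sd[:, None]
    signs = np.sign(sources[np.arange(M), np.argmax(np.abs(sources), axis=1)])
    signs[signs == 0] = 1.0
    A = A * signs[:, None]
    sources = sources * signs[:, None]
    return A, sources, converged


def compute_subject_loadings(data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Least-squares subject loadings: ``data @ maps.T @ (maps maps.T)^-1``."""
    X = np.asarray(data, dtype=float)
    Cmat = np.asarray(maps, dtype=float)
    if X.shape[1] != Cmat.shape[1]:
        raise ValueError("data and maps disagree on feature count")
    G = Cmat @ Cmat.T
    if np.linalg.cond(G) > 1e12:
        raise ValueError("maps are rank-deficient (duplicated or collinear rows)")
    return linalg.solve(G, Cmat @ X.T, assume_a="pos").T


def select_lambda_cv(
    whitened: Sequence[np.ndarray],
    reference: np.ndarray,
    config: FusionConfig,
) -> LambdaSelection:
    """Choose lambda by subject-wise k-fold cross-validation.

    For each grid value the weights are fit on the training folds and the
    criterion is the mean over folds and modalities of |corr| between the
    held-out top canonical variate and the held-out reference.  Ties (and
    flat criteria) resolve toward the smallest lambda.
    """
    grid = np.asarray(sorted(config.lambda_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda_grid is empty")
    Ys = [np.asarray(Y, dtype=float) for Y in whitened]
    ref = np.asarray(reference, dtype=float).ravel()
    n = Ys[0].shape[0]
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.cv_folds)

    crit = np.empty(grid.size)
    for gi, lam in enumerate(grid):
        vals = []
        for test_idx in folds:
            train_idx = np.setdiff1d(perm, test_idx)
            if ref[test_idx].std() == 0:
                raise ValueError("degenerate reference variance in a CV fold")
            sub_cfg = replace(config, lam=float(lam))
            fit = fit_mcca_with_reference([Y[train_idx] for Y in Ys], ref[train_idx], sub_cfg)
            for k, Y in enumerate(Ys):
                d_test = (Y[test_idx] - Y[train_idx].mean(axis=0)) @ fit.weights[k][:, 0]
                if d_test.std() == 0:
                    raise ValueError("degenerate variate variance in a CV fold")
                vals.append(abs(stats.pearsonr(d_test, ref[test_idx])[0]))
        crit[gi] = float(np.mean(vals))

    best = 0
    for gi in range(1, grid.size):
        if crit[gi] > crit[best]:
            best = gi
    return LambdaSelection(lam=float(grid[best]), grid=grid, criterion=crit)
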