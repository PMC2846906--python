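"""Kernel partial least squares classification in dual (Gram-matrix) form.

Classical PLS extracts latent components maximising covariance between
projections of the predictors and the response.  The kernel variant
replaces the predictor cross-product X^T X (samples-by-samples) with a
kernel Gram matrix K, so all computation happens among samples and the
feature map stays implicit.  Here the kernel is polynomial,

    kappa(x, z) = (<x, z> + r)^p        (defaults p = 3, r = 1),

the Gram matrix is mean-centred in feature space by the double-sided
projection (I - 11^T/n) K (I - 11^T/n), and latent scores are extracted
by the kernel-NIPALS recursion with deflation.  For a single +/-1
response the inner NIPALS loop closes in one step per component.

Prediction uses the standard dual regression solution: with T the score
matrix, U the (deflated) response loadings, Kc the centred *undeflated*
training kernel and y0 the centred response,

    alpha = U (T^T Kc U)^{-1} T^T y0,
    score(test) = Kt_c alpha + y_mean,

and the class label is the sign of the score (ties at exactly 0 go to +1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import UsageError

__all__ = [
    "KernelParams",
    "KPLSModel",
    "polynomial_kernel",
    "center_train_kernel",
    "center_test_kernel",
    "fit",
    "predict",
    "select_components",
]


@dataclass(frozen=True)
class KernelParams:
    """Polynomial kernel parameters: degree ``p`` and offset ``r``."""

    degree: int = 3
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise UsageError(f"kernel degree must be >= 1, got {self.degree}")
        if self.offset < 0:
            raise UsageError(f"kernel offset must be >= 0, got {self.offset}")


def polynomial_kernel(X: np.ndarray, Z: np.ndarray, params: KernelParams) -> np.ndarray:
    """Gram block between columns of X [d x n1] and Z [d x n2].

    Entry (i, j) = (<x_i, z_j> + r)^p.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim != 2 or Z.ndim != 2 or X.shape[0] != Z.shape[0]:
        raise UsageError(
            f"feature dimension mismatch: X has shape {X.shape}, Z {Z.shape}"
        )
    return (X.T @ Z + params.offset) ** params.degree


def center_train_kernel(K: np.ndarray) -> np.ndarray:
    """Double-sided centring of a symmetric training Gram matrix.

    Equivalent to mean-centring the implicit feature images; every row and
    column of the result sums to zero.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise UsageError(f"training kernel must be square, got {K.shape}")
    scale = max(1.0, np.abs(K).max())
    if not np.allclose(K, K.T, atol=1e-8 * scale):
        raise UsageError("training kernel must be symmetric")
    n = K.shape[0]
    row_mean = K.mean(axis=0, keepdims=True)
    total_mean = K.mean()
    return K - row_mean - row_mean.T + total_mean


def center_test_kernel(Kt: np.ndarray, K_train: np.ndarray) -> np.ndarray:
    """Centre a test-vs-train Gram block consistently with the training centring.

    ``Kt`` is (nt x n) with Kt[i, j] = kappa(test_i, train_j) and
    ``K_train`` the *uncentred* (n x n) training Gram matrix:

        Kt_c = (Kt - 1_nt 1_n^T K / n)(I - 1_n 1_n^T / n).

    Every row of the result sums to zero.
    """
    Kt = np.asarray(Kt, dtype=float)
    K_train = np.asarray(K_train, dtype=float)
    n = K_train.shape[0]
    if Kt.ndim != 2 or Kt.shape[1] != n:
        raise UsageError(
            f"test kernel has {Kt.shape} but training kernel is {K_train.shape}"
        )
    train_col_mean = K_train.mean(axis=0, keepdims=True)  # (1, n)
    shifted = Kt - train_col_mean
    return shifted - shifted.mean(axis=1, keepdims=True)


@dataclass
class KPLSModel:
    """Fitted kernel-PLS state needed for prediction."""

    training_features: np.ndarray  # (d, n)
    kernel_params: KernelParams
    n_components: int
    scores: np.ndarray             # T, (n, C), orthonormal columns
    dual_coef: np.ndarray          # alpha, (n,)
    y_mean: float
    K_train: np.ndarray            # uncentred training Gram matrix, (n, n)
    training_scores: np.ndarray = field(default=None)  # fitted responses, (n,)


def fit(
    features: np.ndarray,
    y: np.ndarray,
    params: KernelParams = KernelParams(),
    n_components: int = 2,
) -> KPLSModel:
    """Fit kernel PLS on features [d x n] and a +/-1 response vector.

    Extracts ``n_components`` latent score vectors by kernel NIPALS with
    deflation of both K and y; if the kernel's rank is exhausted earlier,
    the component count is reduced with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise UsageError("features must be a 2-D (d x n) matrix")
    n = X.shape[1]
    if y.size != n:
        raise UsageError(f"{n} samples but {y.size} responses")
    if np.unique(np.sign(y)).size < 2:
        raise UsageError("both classes must be present in y")
    if not 1 <= n_components <= n - 1:
        raise UsageError(
            f"n_components must be in [1, n-1] = [1, {n - 1}], got {n_components}"
        )

    K_raw = polynomial_kernel(X, X, params)
    Kc = center_train_kernel(K_raw)
    y_mean = y.mean()
    y0 = y - y_mean

    Kd = Kc.copy()
    yd = y0.copy()
    T = np.empty((n, n_components))
    U = np.empty((n, n_components))
    C = n_components
    for c in range(n_components):
        u = yd  # single response: inner loop converges in one step
        t = Kd @ u
        norm = np.linalg.norm(t)
        if norm <= 1e-12 * max(1.0, np.abs(Kd).max()) or norm == 0.0:
            C = c
            warnings.warn(
                f"kernel rank exhausted after {C} components "
                f"(requested {n_components})",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        t = t / norm
        T[:, c] = t
        U[:, c] = u
        # deflate K and y by the extracted score direction
        proj = np.eye(n) - np.outer(t, t)
        Kd = proj @ Kd @ proj
        yd = yd - t * (t @ yd)
    if C == 0:
        raise UsageError("no latent component could be extracted (zero kernel)")
    T, U = T[:, :C], U[:, :C]

    # dual regression coefficients from the undeflated centred kernel
    M = T.T @ Kc @ U  # (C, C)
    alpha = U @ np.linalg.solve(M, T.T @ y0)

    model = KPLSModel(
        training_features=X,
        kernel_params=params,
        n_components=C,
        scores=T,
        dual_coef=alpha,
        y_mean=float(y_mean),
        K_train=K_raw,
    )
    model.training_scores = Kc @ alpha + y_mean
    return model


def predict(model: KPLSModel, test_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regression scores and +/-1 labels for test columns [d x nt]."""
    Xt = np.asarray(test_features, dtype=float)
    if Xt.ndim != 2 or Xt.shape[0] != model.training_features.shape[0]:
        raise UsageError(
            f"test features have shape {Xt.shape}; training dimension is "
            f"{model.training_features.shape[0]}"
        )
    Kt = polynomial_kernel(Xt, model.training_features, model.kernel_params)
    Kt_c = center_test_kernel(Kt, model.K_train)
    scores = Kt_c @ model.dual_coef + model.y_mean
    labels = np.where(scores >= 0, 1, -1)
    return scores, labels


def select_components(
    features: np.ndarray,
    y: np.ndarray,
    candidates,
    seed: int,
    params: KernelParams = KernelParams(),
    n_folds: int = 5,
) -> int:
    """Choose the component count by inner stratified k-fold accuracy.

    Ties break toward the smaller candidate; deterministic given ``seed``.
    Candidates infeasible for a fold's training size are skipped; if all
    are degenerate a ``UsageError`` is raised.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise UsageError("select_components needs at least one candidate")
    if len(candidates) == 1:
        return candidates[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X.T, y))
    best_c, best_acc = None, -np.inf
    for c in candidates:
        accs = []
        for train_idx, test_idx in folds:
            if c > len(train_idx) - 1:
                continue
            try:
                with warnings.catch_warnings():
                    # oversized candidates routinely exhaust the rank here
                    warnings.simplefilter("ignore", RuntimeWarning)
                    m = fit(X[:, train_idx], y[train_idx], params, c)
                _, pred = predict(m, X[:, test_idx])
            except UsageError:
                continue
            accs.append(float(np.mean(pred == y[test_idx])))
        if not accs:
            continue
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: smallest candidate wins ties
            best_c, best_acc = c, acc
    if best_c is None:
        raise UsageError("all component candidates were degenerate")
    return best_c
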