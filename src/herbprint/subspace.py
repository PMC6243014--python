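"""Per-class sparse non-negative Tucker / NMF subspace models.

Each class (species) gets its own low-rank non-negative model of the
(sample x m/z x polarity) subtensor of its training samples:

* SNTD: ``T ~ [[G; I, B, C]]`` with the sample-mode factor fixed to the
  identity, an m/z factor B (N_mz x r2), a polarity factor C
  (N_polarity x r3) and a non-negative core G, fitted by minimizing the
  squared Frobenius residual plus l1 penalties on G, B and C under
  non-negativity constraints.
* SNMF: ``X ~ S M^T`` on the unfolded (sample x N_mz*N_polarity) matrix,
  with the same constraints; SNTD is the special case ``M = C kron B``.

A query fingerprint is classified by distance between its column space and
each class's m/z factor column space — principal angles or distance
correlation — after removing the polarity mixing by multiplying with the
inverse of the class's polarity factor.  Class models are independent:
adding a new class never re-estimates existing factors.

Optimization is exact block-coordinate descent: each factor column update
solves its non-negative l1-penalized least-squares subproblem in closed
form (HALS-style), so the objective is monotonically non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orth
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class SNTDConfig:
    """Hyperparameters of the per-class sparse non-negative Tucker fit.

    ``r2`` is the m/z-mode rank (default 25), ``r3`` the polarity-mode rank
    (2: one component per ionization mode).  ``lambda_g/b/c`` are the l1
    sparsity penalties; ``None`` resolves to 0.1 x mean data magnitude at
    fit time.
    """

    r2: int = 25
    r3: int = 2
    lambda_g: float | None = None
    lambda_b: float | None = None
    lambda_c: float | None = None
    n_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r2 < 1 or self.r3 < 1:
            raise ValueError("ranks must be >= 1")
        for lam in (self.lambda_g, self.lambda_b, self.lambda_c):
            if lam is not None and lam < 0:
                raise ValueError("penalties must be non-negative")


@dataclass
class ClassSubspaceModel:
    """Fitted SNTD factors of one class: core G (n_c x r2 x r3), m/z factor
    B (N_mz x r2), polarity factor C (N_pol x r3)."""

    class_id: object
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    objective_history: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ibg,jb,kg->ijk", self.G, self.B, self.C)


@dataclass
class SNMFModel:
    """Fitted SNMF factors of one class: basis M (n_features x rank) and
    coefficients S (n_c x rank)."""

    class_id: object
    M: np.ndarray
    S: np.ndarray
    objective_history: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.S @ self.M.T


def _hals_update(A: np.ndarray, B: np.ndarray, X: np.ndarray, lam: float) -> None:
    """In-place exact column updates of ``min_{A>=0} |X - A B^T|_F^2 + lam*sum(A)``.

    Each column of A is the closed-form minimizer given all others fixed,
    so every update weakly decreases the objective.
    """
    BtB = B.T @ B
    XB = X @ B
    r = A.shape[1]
    for j in range(r):
        denom = BtB[j, j]
        if denom <= 0:
            A[:, j] = 0.0
            continue
        num = XB[:, j] - A @ BtB[:, j] + A[:, j] * denom
        A[:, j] = np.maximum(0.0, (num - 0.5 * lam) / denom)


def _resolve_penalty(lam: float | None, data: np.ndarray) -> float:
    return 0.1 * float(np.mean(np.abs(data))) if lam is None else float(lam)


def sntd_objective(T: np.ndarray, m: ClassSubspaceModel,
                   lg: float, lb: float, lc: float) -> float:
    R = m.reconstruct()
    return float(
        np.sum((T - R) ** 2)
        + lg * np.sum(m.G) + lb * np.sum(m.B) + lc * np.sum(m.C)
    )


def fit_sntd_class_model(T_class: np.ndarray, cfg: SNTDConfig | None = None,
                         class_id: object = None) -> ClassSubspaceModel:
    """Block-coordinate descent on the penalized Tucker objective.

    ``T_class`` is the (n_c x N_mz x N_pol) non-negative subtensor of one
    class.  Stops after ``cfg.n_iter`` sweeps or when the relative
    objective change drops below ``cfg.tol``.  Deterministic given
    ``cfg.seed``.  All-zero columns of B (and C) are pruned with a warning
    after convergence.
    """
    cfg = cfg or SNTDConfig()
    T = np.asarray(T_class, dtype=float)
    if T.ndim != 3:
        raise ValueError("T_class must be a 3-way array (samples x m/z x polarity)")
    n, J, K = T.shape
    if np.any(T < 0):
        raise ValueError("input tensor must be non-negative")
    if not np.any(T > 0):
        raise ValueError("all-zero class subtensor: nothing to model")
    if cfg.r2 > J:
        raise ValueError(f"m/z rank {cfg.r2} exceeds m/z dimension {J}")
    if cfg.r3 > K:
        raise ValueError(f"polarity rank {cfg.r3} exceeds polarity dimension {K}")
    lg = _resolve_penalty(cfg.lambda_g, T)
    lb = _resolve_penalty(cfg.lambda_b, T)
    lc = _resolve_penalty(cfg.lambda_c, T)

    rng = np.random.default_rng(cfg.seed)
    scale = float(np.mean(T[T > 0])) if np.any(T > 0) else 1.0
    B = rng.uniform(0, 1, size=(J, cfg.r2))
    C = rng.uniform(0, 1, size=(K, cfg.r3))
    G = rng.uniform(0, scale, size=(n, cfg.r2, cfg.r3))
    model = ClassSubspaceModel(class_id, B, C, G)

    X1 = np.ascontiguousarray(T.transpose(0, 2, 1).reshape(n, K * J))  # sample-mode
    X2 = np.ascontiguousarray(T.transpose(1, 0, 2).reshape(J, n * K))  # m/z-mode
    X3 = np.ascontiguousarray(T.transpose(2, 0, 1).reshape(K, n * J))  # polarity-mode

    prev = sntd_objective(T, model, lg, lb, lc)
    model.objective_history.append(prev)
    for _ in range(cfg.n_iter):
        # core update: vec over (polarity, m/z), basis C kron B
        M = np.kron(C, B)                                   # (K*J) x (r3*r2)
        Gmat = np.ascontiguousarray(G.transpose(0, 2, 1).reshape(n, cfg.r3 * cfg.r2))
        _hals_update(Gmat, M, X1, lg)
        G[:] = Gmat.reshape(n, cfg.r3, cfg.r2).transpose(0, 2, 1)
        # m/z factor update against H2[b, (i,k)] = sum_g G[i,b,g] C[k,g]
        H2 = np.einsum("ibg,kg->bik", G, C).reshape(cfg.r2, n * K)
        _hals_update(B, H2.T, X2, lb)
        # polarity factor update against H3[g, (i,j)] = sum_b G[i,b,g] B[j,b]
        H3 = np.einsum("ibg,jb->gij", G, B).reshape(cfg.r3, n * J)
        _hals_update(C, H3.T, X3, lc)

        obj = sntd_objective(T, model, lg, lb, lc)
        model.objective_history.append(obj)
        if obj > prev + 1e-9:
            raise AssertionError(
                f"objective increased by {obj - prev:.3e}; update rule is broken"
            )
        if prev > 0 and (prev - obj) / prev < cfg.tol:
            break
        prev = obj

    dead_b = np.flatnonzero(~np.any(model.B > 0, axis=0))
    if dead_b.size:
        warnings.warn(f"pruning {dead_b.size} all-zero m/z factor column(s)")
        keep = np.setdiff1d(np.arange(model.B.shape[1]), dead_b)
        if keep.size == 0:
            keep = dead_b[:1]  # keep one column so downstream shapes survive
        model.B = model.B[:, keep]
        model.G = model.G[:, keep, :]
    return model


def snmf_objective(X: np.ndarray, m: SNMFModel, ls: float, lm: float) -> float:
    return float(
        np.sum((X - m.reconstruct()) ** 2) + ls * np.sum(m.S) + lm * np.sum(m.M)
    )


def fit_snmf_class_model(
    X_class: np.ndarray,
    rank: int = 25,
    penalty: float | None = None,
    n_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    class_id: object = None,
) -> SNMFModel:
    """Sparse non-negative matrix factorization of one class's unfolded data,
    by the same exact block-coordinate scheme as the Tucker fit (two blocks:
    coefficients S and basis M, one shared l1 penalty)."""
    X = np.asarray(X_class, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_class must be 2-d (samples x features)")
    if np.any(X < 0):
        raise ValueError("input must be non-negative")
    if not np.any(X > 0):
        raise ValueError("all-zero class matrix: nothing to model")
    n, d = X.shape
    if rank > d:
        raise ValueError(f"rank {rank} exceeds feature dimension {d}")
    lam = _resolve_penalty(penalty, X)
    rng = np.random.default_rng(seed)
    scale = float(np.mean(X[X > 0]))
    S = rng.uniform(0, scale, size=(n, rank))
    M = rng.uniform(0, 1, size=(d, rank))
    model = SNMFModel(class_id, M, S)
    Xt = np.ascontiguousarray(X.T)

    prev = snmf_objective(X, model, lam, lam)
    model.objective_history.append(prev)
    for _ in range(n_iter):
        _hals_update(S, M, X, lam)
        _hals_update(M, S, Xt, lam)
        obj = snmf_objective(X, model, lam, lam)
        model.objective_history.append(obj)
        if obj > prev + 1e-9:
            raise AssertionError("objective increased; update rule is broken")
        if prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj

    dead = np.flatnonzero(~np.any(model.M > 0, axis=0))
    if dead.size and dead.size < rank:
        warnings.warn(f"pruning {dead.size} all-zero basis column(s)")
        keep = np.setdiff1d(np.arange(rank), dead)
        model.M = model.M[:, keep]
        model.S = model.S[:, keep]
    return model


def polarity_whiten(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Remove the polarity mixing of a query: returns ``X (C^T)^-1``.

    For data generated by the class model (columns of X in the image of
    B G C^T), the result's columns lie in the column space of B.  A nearly
    singular C (condition number > 1e8) falls back to the pseudoinverse
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("polarity factor must be square for whitening")
    if X.shape[1] != C.shape[0]:
        raise ValueError("query column count must match polarity factor size")
    if np.linalg.cond(C) > 1e8:
        warnings.warn("polarity factor nearly singular; using pseudoinverse")
        return X @ np.linalg.pinv(C.T)
    return X @ np.linalg.inv(C.T)


def principal_angle_distance(Y: np.ndarray, B: np.ndarray) -> float:
    """Chordal principal-angle distance between column spaces.

    Orthonormal bases Q_Y, Q_B are computed (rank-deficient inputs reduce
    to their column-space bases); the cosines of the principal angles are
    the singular values of ``Q_Y^T Q_B`` and the distance aggregates all
    min(rank Y, rank B) angles as ``sqrt(sum_i sin^2 theta_i)``.  Zero
    exactly when the smaller subspace is contained in the larger.

    The sines are evaluated through the projection residual of the
    smaller-rank basis onto the other subspace
    (``sum sin^2 = |(I - P) Q|_F^2``), which is numerically exact near
    containment where ``sqrt(1 - cos^2)`` would lose half the digits.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if Y.ndim != 2 or B.ndim != 2 or Y.shape[0] != B.shape[0]:
        raise ValueError("Y and B must be 2-d with equal row counts")
    Qy = orth(Y)
    Qb = orth(B)
    if Qy.shape[1] == 0:
        raise ValueError("query spans no subspace (all-zero input)")
    if Qb.shape[1] == 0:
        raise ValueError("reference spans no subspace (all-zero factor)")
    Qs, Ql = (Qy, Qb) if Qy.shape[1] <= Qb.shape[1] else (Qb, Qy)
    resid = Qs - Ql @ (Ql.T @ Qs)
    return float(np.linalg.norm(resid))


def _dcenter(D: np.ndarray) -> np.ndarray:
    return D - D.mean(axis=0) - D.mean(axis=1, keepdims=True) + D.mean()


def dcor_distance(Y: np.ndarray, B: np.ndarray) -> float:
    """``1 - dCor(Y, B)`` with rows as paired observations (one per m/z bin).

    dCor is the sample distance correlation: the normalized mean product of
    the double-centered pairwise Euclidean distance matrices of the two row
    samples.  If either argument has zero distance variance (constant
    rows), the distance is defined as 1 with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if B.ndim == 2 and B.shape[0] == 1:
        B = B.T
    if Y.shape[0] != B.shape[0] or Y.shape[0] < 2:
        raise ValueError("Y and B need >= 2 paired rows")
    from scipy.spatial.distance import pdist, squareform

    Ay = _dcenter(squareform(pdist(Y)))
    Ab = _dcenter(squareform(pdist(B)))
    dvar_y = float(np.mean(Ay * Ay))
    dvar_b = float(np.mean(Ab * Ab))
    if dvar_y <= 0 or dvar_b <= 0:
        warnings.warn("zero distance variance; dcor distance defined as 1")
        return 1.0
    dcov2 = float(np.mean(Ay * Ab))
    dcor = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_y * dvar_b))
    return float(1.0 - dcor)


def classify_subspace(
    models: list[ClassSubspaceModel | SNMFModel],
    x: np.ndarray,
    metric: str = "principal_angle",
) -> list[tuple[object, float]]:
    """Rank all class models by ascending subspace distance to the query.

    SNTD queries are reshaped to (N_mz x N_pol), polarity-whitened with
    each class's C, and compared against that class's B; SNMF queries are
    the flat vector (a one-column subspace) compared against span(M).
    Ties are broken by class id.
    """
    if len(models) < 2:
        raise ValueError("need models for at least 2 classes")
    if metric not in ("principal_angle", "dcor"):
        raise ValueError(f"unknown metric {metric!r}")
    x = np.asarray(x, dtype=float).ravel()
    if not np.any(x != 0):
        raise ValueError("zero query vector cannot be classified")
    dist_fn = principal_angle_distance if metric == "principal_angle" else dcor_distance

    out = []
    for m in models:
        if isinstance(m, ClassSubspaceModel):
            K = m.C.shape[0]
            J = x.size // K
            Xq = x.reshape(K, J).T  # polarity-major flat layout -> (J, K)
            if m.C.shape[0] == m.C.shape[1]:
                Xq = polarity_whiten(Xq, m.C)
            out.append((m.class_id, dist_fn(Xq, m.B)))
        else:
            out.append((m.class_id, dist_fn(x[:, None], m.M)))
    out.sort(key=lambda t: (t[1], str(t[0])))
    return out


class SubspaceClassifier(ClassifierMixin, BaseEstimator):
    """Classifier backed by one sparse non-negative factor model per class.

    Parameters
    ----------
    model:
        ``"sntd"`` (3-way Tucker with identity sample factor) or ``"snmf"``
        (matrix factorization on the unfolded features).
    metric:
        ``"principal_angle"`` (chordal) or ``"dcor"`` (1 - distance
        correlation) between query and class subspaces.
    r2, r3:
        Tucker ranks of the m/z and polarity modes (SNTD).
    rank:
        Basis rank of the SNMF variant.
    lambda_g, lambda_b, lambda_c, penalty:
        l1 sparsity penalties; ``None`` resolves to 0.1 x mean magnitude of
        each class's data.
    n_pol:
        Number of polarity channels the flat feature vector interleaves
        (polarity-major blocks).
    """

    def __init__(
        self,
        model: str = "sntd",
        metric: str = "principal_angle",
        r2: int = 25,
        r3: int = 2,
        rank: int = 25,
        lambda_g: float | None = None,
        lambda_b: float | None = None,
        lambda_c: float | None = None,
        penalty: float | None = None,
        n_iter: int = 200,
        tol: float = 1e-6,
        seed: int = 0,
        n_pol: int = 2,
    ):
        self.model = model
        self.metric = metric
        self.r2 = r2
        self.r3 = r3
        self.rank = rank
        self.lambda_g = lambda_g
        self.lambda_b = lambda_b
        self.lambda_c = lambda_c
        self.penalty = penalty
        self.n_iter = n_iter
        self.tol = tol
        self.seed = seed
        self.n_pol = n_pol

    def _fit_one(self, Xc: np.ndarray, label: object):
        if self.model == "sntd":
            J = Xc.shape[1] // self.n_pol
            Tc = Xc.reshape(-1, self.n_pol, J).transpose(0, 2, 1)
            cfg = SNTDConfig(
                r2=min(self.r2, J, Xc.shape[0] * self.r3),
                r3=self.r3,
                lambda_g=self.lambda_g,
                lambda_b=self.lambda_b,
                lambda_c=self.lambda_c,
                n_iter=self.n_iter,
                tol=self.tol,
                seed=self.seed,
            )
            return fit_sntd_class_model(Tc, cfg, class_id=label)
        if self.model == "snmf":
            return fit_snmf_class_model(
                Xc, rank=min(self.rank, Xc.shape[1]), penalty=self.penalty,
                n_iter=self.n_iter, tol=self.tol, seed=self.seed, class_id=label,
            )
        raise ValueError(f"unknown model {self.model!r}")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SubspaceClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self.models_ = {}
        for label in self.classes_:
            self.models_[label] = self._fit_one(X[y == label], label)
        self.n_features_in_ = X.shape[1]
        return self

    def add_class(self, X_new: np.ndarray, label: object) -> "SubspaceClassifier":
        """Fit one additional class model; existing factors are untouched."""
        check_is_fitted(self, "models_")
        self.models_[label] = self._fit_one(np.asarray(X_new, dtype=float), label)
        self.classes_ = np.asarray(sorted(self.models_, key=str))
        return self

    def decision_distances(self, X: np.ndarray) -> np.ndarray:
        """Matrix of subspace distances, one row per query, columns in
        ``classes_`` order."""
        check_is_fitted(self, "models_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        models = [self.models_[c] for c in self.classes_]
        out = np.empty((X.shape[0], len(models)))
        for i, x in enumerate(X):
            ranked = dict(classify_subspace(models, x, metric=self.metric))
            out[i] = [ranked[c] for c in self.classes_]
        return out

    def predict_ranked(self, X: np.ndarray) -> np.ndarray:
        D = self.decision_distances(X)
        order = np.argsort(D, axis=1, kind="stable")
        return self.classes_[order]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_ranked(X)[:, 0]
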