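"""Orthogonal preparatory/movement subspace identification.

Given covariance matrices of delay-epoch and movement-epoch population
activity, find two mutually orthogonal orthonormal bases W_prep, W_move that
jointly maximize the normalized captured variance

    1/2 * [ Tr(W_prep' C_prep W_prep) / sum_i^d_prep s_prep(i)
          + Tr(W_move' C_move W_move) / sum_i^d_move s_move(i) ]

subject to W_prep' W_move = 0 and orthonormal blocks, where s(i) are the
covariance singular values.  The normalizers bound each term by 1 and make
the objective insensitive to the relative strength and dimensionality of the
two epochs.  The problem is solved by Riemannian gradient ascent on the
Stiefel manifold of the joined n x (d_prep + d_move) orthonormal matrix (the
cross-orthogonality constraint is then automatic), with a PCA-based feasible
initialization and seeded random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import linalg


@dataclass
class CovarianceMatrix:
    """Symmetric PSD covariance of an epoch data matrix, with its spectrum."""

    values: np.ndarray
    epoch: str = ""
    singular_values: np.ndarray = field(default=None)  # descending

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("covariance must be square")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        scale = max(np.abs(v).max(), 1.0)
        if asym > 1e-10 * scale:
            raise ValueError("covariance must be symmetric")
        self.values = 0.5 * (v + v.T)
        if self.singular_values is None:
            self.singular_values = np.linalg.svd(self.values, compute_uv=False)
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("covariance must be positive semi-definite")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def epoch_covariance(P: np.ndarray, epoch: str = "") -> CovarianceMatrix:
    """Covariance across columns (samples = condition-time points).

    Row means are removed; the unbiased (n-1) denominator is used.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 sample columns")
    return CovarianceMatrix(np.cov(P), epoch=epoch)


@dataclass
class SubspacePair:
    """The two orthonormal bases with captured-variance diagnostics."""

    W_prep: np.ndarray
    W_move: np.ndarray
    objective_value: float
    captured: dict  # {"prep"/"move" subspace -> {"prep"/"move" epoch -> fraction}}
    optimizer_report: dict

    def check(self, atol: float = 1e-8) -> None:
        """Raise if the feasibility invariants are violated."""
        for name, W in [("W_prep", self.W_prep), ("W_move", self.W_move)]:
            err = np.abs(W.T @ W - np.eye(W.shape[1])).max()
            if err > atol:
                raise AssertionError(f"{name} not orthonormal (residual {err:.2e})")
        cross = np.abs(self.W_prep.T @ self.W_move).max()
        if cross > atol:
            raise AssertionError(f"cross-orthogonality violated ({cross:.2e})")
        if not (-atol <= self.objective_value <= 1.0 + atol):
            raise AssertionError(f"objective {self.objective_value} outside [0, 1]")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("W_prep", data=self.W_prep)
            f.create_dataset("W_move", data=self.W_move)
            f.create_dataset("objective", data=self.objective_value)
            for k, sub in self.captured.items():
                for e, v in sub.items():
                    f.attrs[f"captured_{k}_{e}"] = v


def _qf(A: np.ndarray) -> np.ndarray:
    """QR-based retraction onto the Stiefel manifold (positive diag R)."""
    Q, R = np.linalg.qr(A)
    sgn = np.sign(np.diag(R))
    sgn[sgn == 0] = 1.0
    return Q * sgn


def _objective_and_grad(W, C1, C2, d1, inv_s1, inv_s2):
    W1, W2 = W[:, :d1], W[:, d1:]
    A1, A2 = C1 @ W1, C2 @ W2
    f = 0.5 * (inv_s1 * np.sum(W1 * A1) + inv_s2 * np.sum(W2 * A2))
    G = np.hstack([inv_s1 * A1, inv_s2 * A2])  # euclidean gradient of f (x2/2)
    return f, G


def _riemannian_grad(W, G):
    WtG = W.T @ G
    return G - W @ (0.5 * (WtG + WtG.T))


def optimize_subspaces(
    C_prep: CovarianceMatrix,
    C_move: CovarianceMatrix,
    d_prep: int = 12,
    d_move: int = 12,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-10,
    order: bool = True,
) -> SubspacePair:
    """Maximize the normalized-trace objective over feasible basis pairs.

    Deterministic given ``seed``.  The first start is the per-epoch PCA
    initialization made jointly feasible by orthogonalization; the final
    objective never falls below its value there.  Non-convergence of every
    restart is flagged in ``optimizer_report["converged"]``, not silent.
    """
    n = C_prep.n
    if C_move.n != n:
        raise ValueError("covariances must have matching size")
    if d_prep + d_move > n:
        raise ValueError(f"d_prep + d_move = {d_prep + d_move} exceeds n = {n}")
    if d_prep < 1 or d_move < 1:
        raise ValueError("subspace dimensions must be positive")

    s1 = float(np.sum(C_prep.singular_values[:d_prep]))
    s2 = float(np.sum(C_move.singular_values[:d_move]))
    inv_s1 = 1.0 / s1 if s1 > 0 else 0.0
    inv_s2 = 1.0 / s2 if s2 > 0 else 0.0

    # PCA initialization: top eigenvectors of each epoch covariance, joined
    # and orthogonalized (QR preserves the preparatory block exactly)
    w1 = np.linalg.eigh(C_prep.values)[1][:, ::-1][:, :d_prep]
    w2 = np.linalg.eigh(C_move.values)[1][:, ::-1][:, :d_move]
    W_pca = _qf(np.hstack([w1, w2]))
    f_pca, _ = _objective_and_grad(W_pca, C_prep.values, C_move.values,
                                   d_prep, inv_s1, inv_s2)

    rng = np.random.default_rng(seed)
    best = None
    report = {"restarts": [], "pca_init_objective": f_pca}
    for r in range(max(n_restarts, 1)):
        if r == 0:
            W = W_pca.copy()
        else:
            W = _qf(rng.standard_normal((n, d_prep + d_move)))
        f, G = _objective_and_grad(W, C_prep.values, C_move.values,
                                   d_prep, inv_s1, inv_s2)
        alpha = 1.0
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            R = _riemannian_grad(W, G)
            gnorm2 = float(np.sum(R * R))
            if gnorm2 < 1e-30:
                converged = True
                break
            accepted = False
            for _ in range(40):
                W_new = _qf(W + alpha * R)
                f_new, G_new = _objective_and_grad(
                    W_new, C_prep.values, C_move.values, d_prep, inv_s1, inv_s2
                )
                if f_new > f:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                converged = True  # no ascent direction at line-search floor
                break
            if f_new - f < tol * max(1.0, abs(f)):
                W, f, G = W_new, f_new, G_new
                converged = True
                break
            W, f, G = W_new, f_new, G_new
            alpha *= 1.3
        report["restarts"].append({"iterations": it, "converged": converged,
                                   "objective": f})
        if best is None or f > best[0]:
            best = (f, W, r)

    f_best, W_best, r_best = best
    report["best_restart"] = r_best
    report["converged"] = any(rs["converged"] for rs in report["restarts"])
    W1, W2 = W_best[:, :d_prep], W_best[:, d_prep:]
    if order:
        W1 = order_basis(W1, C_prep)
        W2 = order_basis(W2, C_move)

    def frac(W, C):
        tot = np.trace(C.values)
        return float(np.trace(W.T @ C.values @ W) / tot) if tot > 0 else 0.0

    captured = {
        "prep": {"prep": frac(W1, C_prep), "move": frac(W1, C_move)},
        "move": {"prep": frac(W2, C_prep), "move": frac(W2, C_move)},
    }
    return SubspacePair(
        W_prep=W1, W_move=W2, objective_value=float(f_best),
        captured=captured, optimizer_report=report,
    )


def brute_force_oracle_2d(
    C_prep: CovarianceMatrix, C_move: CovarianceMatrix, resolution: float = 0.001
) -> tuple[float, float]:
    """Exhaustive grid-search oracle for the n=2, d=1+1 problem.

    All feasible pairs form the one-parameter family
    W_prep = (cos t, sin t), W_move = (-sin t, cos t), t in [0, pi).
    Returns (best objective, best angle).
    """
    if C_prep.n != 2 or C_move.n != 2:
        raise ValueError("oracle requires 2x2 covariances")
    s1 = float(C_prep.singular_values[0])
    s2 = float(C_move.singular_values[0])
    inv1 = 1.0 / s1 if s1 > 0 else 0.0
    inv2 = 1.0 / s2 if s2 > 0 else 0.0
    theta = np.arange(0.0, np.pi, resolution)
    c, s = np.cos(theta), np.sin(theta)
    w1 = np.stack([c, s])  # (2, n_theta)
    w2 = np.stack([-s, c])
    t1 = np.einsum("it,ij,jt->t", w1, C_prep.values, w1)
    t2 = np.einsum("it,ij,jt->t", w2, C_move.values, w2)
    obj = 0.5 * (inv1 * t1 + inv2 * t2)
    i = int(np.argmax(obj))
    return float(obj[i]), float(theta[i])


def order_basis(W: np.ndarray, C: CovarianceMatrix) -> np.ndarray:
    """Rotate within span(W) so projected variance is diagonal and descending.

    The span is unchanged (a pure within-subspace rotation).  Sign
    convention: the largest-magnitude element of each column is made
    positive, so output is deterministic across platforms.
    """
    W = np.asarray(W, dtype=float)
    if np.abs(W.T @ W - np.eye(W.shape[1])).max() > 1e-8:
        raise ValueError("W must be orthonormal")
    S = W.T @ C.values @ W
    evals, evecs = np.linalg.eigh(0.5 * (S + S.T))
    order = np.argsort(evals)[::-1]
    out = W @ evecs[:, order]
    idx = np.argmax(np.abs(out), axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs


def variance_captured(W: np.ndarray, X: np.ndarray) -> float:
    """Fraction of data variance captured by the subspace: in [0, 1].

    ``Tr(W' cov(X) W) / Tr(cov(X))`` with the same column-sample convention
    as :func:`epoch_covariance`.
    """
    C = np.cov(np.asarray(X, dtype=float))
    tot = float(np.trace(C))
    if tot <= 0:
        raise ValueError("data has zero total variance")
    return float(np.trace(W.T @ C @ W) / tot)


@dataclass
class RotationalPlaneFit:
    """Least-squares skew-symmetric dynamics fit within a subspace."""

    plane: np.ndarray  # (d, 2) orthonormal
    M_skew: np.ndarray  # (d, d), M = -M'
    frequency_hz: float
    no_rotation: bool


def fit_rotational_plane(
    latents: np.ndarray, dt_ms: float = 1.0
) -> RotationalPlaneFit:
    """Fit dX/dt = M X with skew-symmetric M; return the fastest plane.

    ``latents`` is (d, n_conditions, n_times).  The fit pools all conditions
    and times; the returned plane spans the real/imaginary parts of the
    eigenvector of the largest-|frequency| conjugate eigenvalue pair,
    orthonormalized.  Time-constant data yields a zero dynamics matrix,
    flagged ``no_rotation``.  This is a deliberately simplified plane fit
    for visualizing rotational structure, not a full oscillation-discovery
    method.
    """
    Z = np.asarray(latents, dtype=float)
    if Z.ndim != 3 or Z.shape[0] < 2 or Z.shape[1] < 2 or Z.shape[2] < 3:
        raise ValueError("need (d>=2, n_conditions>=2, n_times>=3) latents")
    d = Z.shape[0]
    Zdot = np.gradient(Z, dt_ms, axis=2)
    X = Z.reshape(d, -1)
    Xdot = Zdot.reshape(d, -1)
    # work inside the data's row space: rotations confined to a plane
    # embedded in higher dimension are still fittable
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(sv > 1e-10 * sv[0])) if sv.size else 0
    if r < 2:
        raise ValueError("rank-deficient projections; cannot fit dynamics")
    Ur = U[:, :r]
    Xr = Ur.T @ X
    Xdr = Ur.T @ Xdot
    S = Xr @ Xr.T
    B = Xdr @ Xr.T - Xr @ Xdr.T
    Mr = linalg.solve_sylvester(S, S, B)
    Mr = 0.5 * (Mr - Mr.T)  # exact skew symmetry
    M = Ur @ Mr @ Ur.T
    scale = max(np.abs(Xdot).max(), 1e-300)
    if np.abs(Mr).max() * np.abs(Xr).max() < 1e-12 * scale or np.abs(Mr).max() < 1e-14:
        return RotationalPlaneFit(
            plane=np.eye(d)[:, :2], M_skew=M, frequency_hz=0.0, no_rotation=True
        )
    evals, evecs = np.linalg.eig(Mr)
    i = int(np.argmax(np.abs(evals.imag)))
    v = Ur @ evecs[:, i]
    plane = _qf(np.stack([v.real, v.imag], axis=1))
    freq = float(np.abs(evals.imag[i]) * 1000.0 / (2.0 * np.pi))
    return RotationalPlaneFit(plane=plane, M_skew=M, frequency_hz=freq,
                              no_rotation=False)
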