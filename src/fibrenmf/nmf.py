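"""Pathway-constrained nonnegative matrix factorization.

The count matrix X (samples x AFTs) is decomposed as X ~ W H with W >= 0
(per-sample profile weights) and H >= 0 (profiles over AFTs), subject to the
pathway-completeness constraints F H^T <= 0, by minimizing

    || (X - W H) D^-1 ||_F^2  +  alpha ( ||W||_F^2 + ||H D^-1||_{1,2}^2 )

where D is the diagonal matrix of column l2 norms of X (so every AFT enters
the fit on a comparable scale) and ||A||_{1,2}^2 sums, over feature columns,
the squared l1 norm across profiles -- on nonnegative H a quadratic penalty
that pushes each AFT to load on few profiles.  The ridge ||W||_F^2 evens out
profile weights within a sample.

Optimization is block coordinate descent: with H fixed, each sample row of W
is an independent nonnegative ridge regression; with W fixed, H solves a
convex QP (the F rows couple the feature columns of H within each profile,
so the H update is one QP over all k*p entries, solved exactly through its
dual).  Both half-steps reach the global optimum of their convex subproblem,
which makes the objective trace monotone.

Internally everything runs in the column-scaled space Y = X D^-1, G = H D^-1;
the constraint becomes (F D) G^T <= 0 and results are mapped back to H = G D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _solvers
from .containers import CountMatrix
from .network import ConstraintMatrix, check_feasibility

#: tolerance used when deciding whether an unconstrained H update already
#: satisfies the pathway constraints (then it is the constrained optimum)
_FEAS_EPS = 1e-9


class FitError(ValueError):
    pass


@dataclass
class ScalingVector:
    """Per-feature l2 column norms of the training matrix (diagonal of D)."""

    d: np.ndarray  # positive, one entry per retained feature
    retained: np.ndarray  # indices into the full feature axis
    n_features: int  # full feature count

    @property
    def dropped(self) -> np.ndarray:
        mask = np.ones(self.n_features, dtype=bool)
        mask[self.retained] = False
        return np.flatnonzero(mask)


@dataclass
class Hyperparams:
    k: int
    alpha: float
    max_iter: int = 500
    rel_tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class Decomposition:
    W: np.ndarray
    H: np.ndarray
    D: ScalingVector
    alpha: float
    k: int
    objective_trace: list[float]
    converged: bool
    seed: int
    restart: int = 0
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def _as_values(X) -> np.ndarray:
    if isinstance(X, CountMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def compute_scaling(X) -> ScalingVector:
    """Column l2 norms; zero-norm features are dropped (D^-1 undefined)."""
    V = _as_values(X)
    if np.any(V < 0):
        raise FitError("count matrix must be nonnegative")
    norms = np.sqrt((V**2).sum(axis=0))
    retained = np.flatnonzero(norms > 0)
    if retained.size == 0:
        raise FitError("all feature columns have zero norm")
    if retained.size < norms.size:
        warnings.warn(
            f"dropping {norms.size - retained.size} zero-norm feature columns", stacklevel=2
        )
    return ScalingVector(d=norms[retained], retained=retained, n_features=norms.size)


def _scaled(X, D: ScalingVector) -> np.ndarray:
    V = _as_values(X)
    return V[:, D.retained] / D.d[None, :]


def _restrict_F(F: ConstraintMatrix | None, D: ScalingVector) -> np.ndarray | None:
    """Constraint rows on the retained, column-scaled variables: (F D) G^T <= 0."""
    if F is None or F.n_constraints == 0:
        return None
    sub = F.values[:, D.retained] * D.d[None, :]
    keep = [i for i, r in enumerate(sub) if np.any(r > 0) and np.any(r < 0)]
    if not keep:
        return None
    return sub[keep]


def objective(X, W, H, alpha, D: ScalingVector, F: ConstraintMatrix | None = None) -> float:
    """Evaluate the penalized, column-scaled factorization objective."""
    Y = _scaled(X, D)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    G = H[:, D.retained] / D.d[None, :]
    if W.shape[0] != Y.shape[0] or W.shape[1] != H.shape[0] or H.shape[1] != D.n_features:
        raise FitError(
            f"shape mismatch: X {Y.shape}, W {W.shape}, H {H.shape} (p={D.n_features})"
        )
    fit = float(((Y - W @ G) ** 2).sum())
    pen_w = float((W**2).sum())
    pen_h = float((np.abs(G).sum(axis=0) ** 2).sum())
    if F is not None:
        rep = check_feasibility(H, F, tol=1e-6)
        if not rep.all_feasible:
            warnings.warn(
                f"H violates constraints (max violation {rep.max_violation.max():.3g})",
                stacklevel=2,
            )
    return fit + alpha * (pen_w + pen_h)


def update_W(X, H, alpha, D: ScalingVector) -> np.ndarray:
    """Exact nonnegative ridge solve for every sample row, H fixed."""
    Y = _scaled(X, D)
    H = np.asarray(H, dtype=float)
    if not np.any(H):
        raise FitError("H is all zero; W update undefined")
    G = H[:, D.retained] / D.d[None, :]
    k = G.shape[0]
    AtA = G @ G.T + alpha * np.eye(k)
    AtB = G @ Y.T  # k x n
    return _solvers.nnls_gram_multi(AtA, AtB).T


def _update_G(
    Y: np.ndarray,
    W: np.ndarray,
    alpha: float,
    A: np.ndarray | None,
    warm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """H update in scaled coordinates; returns (G, dual warm-start mask)."""
    n, k = W.shape
    p = Y.shape[1]
    AtA = W.T @ W + alpha * np.ones((k, k))
    AtB = W.T @ Y  # k x p
    G = _solvers.nnls_gram_multi(AtA, AtB)
    if A is None:
        return G, None
    viol = (A @ G.T).max(initial=0.0)
    if viol <= _FEAS_EPS * max(1.0, np.abs(G).max(initial=0.0)):
        return G, None  # unconstrained optimum is feasible, hence optimal
    # coupled QP over all k*p entries: P block-diagonal (identical k x k blocks),
    # constraints = nonnegativity + per-profile pathway rows
    P0 = 2.0 * AtA
    jitter = 1e-12 * (np.trace(P0) / k + 1.0)
    L0 = _solvers._gram_chol(P0 + jitter * np.eye(k))
    L0inv = np.linalg.inv(L0)
    Q = -2.0 * AtB  # k x p, q_j = Q[:, j]
    # dual design matrix, variable order x = [G[:,0]; G[:,1]; ...]
    M = np.hstack([-np.kron(np.eye(p), L0inv), np.kron(A.T, L0inv)])
    v = (L0inv @ Q).T.reshape(-1)  # stacked L0^-1 q_j
    lam, passive = _solvers.nnls_active_set(M, -v, warm=warm)
    c = A.shape[0]
    lam_n = lam[: k * p].reshape(p, k).T  # nonnegativity multipliers as k x p
    lam_f = lam[k * p :].reshape(c, k)
    Ct_lam = -lam_n + lam_f.T @ A  # k x p
    rhs = Q + Ct_lam
    G = -np.linalg.solve(P0 + jitter * np.eye(k), rhs)
    return np.clip(G, 0.0, None), passive


def update_H(
    X,
    W,
    alpha,
    D: ScalingVector,
    F: ConstraintMatrix | None = None,
    warm: np.ndarray | None = None,
    return_warm: bool = False,
):
    """Exact constrained H update, W fixed.

    Solves one convex QP over all k*p entries of H (feature columns are
    coupled by the pathway rows of F within each profile).  Returns H on the
    full feature axis (dropped features reinserted as zero columns).
    """
    Y = _scaled(X, D)
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        raise FitError("W is all zero; H update undefined")
    A = _restrict_F(F, D)
    G, passive = _update_G(Y, W, alpha, A, warm=warm)
    H = np.zeros((W.shape[1], D.n_features))
    H[:, D.retained] = G * D.d[None, :]
    if return_warm:
        return H, passive
    return H


def _objective_scaled(Y, W, G, alpha) -> float:
    fit = float(((Y - W @ G) ** 2).sum())
    return fit + alpha * (float((W**2).sum()) + float((np.abs(G).sum(axis=0) ** 2).sum()))


def fit(X, hp: Hyperparams, F: ConstraintMatrix | None = None) -> Decomposition:
    """Block coordinate descent with seeded random restarts.

    Runs ``hp.n_restarts`` starts from seeded Uniform(0,1) factors (drawn in
    the column-scaled space and matched to the data scale), alternating exact
    W and H updates until the relative objective change drops below
    ``hp.rel_tol`` or ``hp.max_iter`` iterations; the lowest-objective restart
    wins, ties broken toward the lowest restart seed.  A final W half-step
    makes the returned W the exact regression of X on the returned H, so
    projecting the training data reproduces it.
    """
    V = _as_values(X)
    n = V.shape[0]
    D = compute_scaling(V)
    Y = _scaled(V, D)
    p_r = Y.shape[1]
    if n < hp.k or p_r < hp.k:
        raise FitError(f"need at least k={hp.k} samples and features, got {Y.shape}")
    A = _restrict_F(F, D)
    best: Decomposition | None = None
    for r in range(hp.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((hp.seed, r)))
        W = rng.uniform(size=(n, hp.k))
        G = rng.uniform(size=(hp.k, p_r))
        scale = np.sqrt(Y.mean() / max((W @ G).mean(), 1e-300))
        W *= scale
        G *= scale
        if A is not None:
            # start from a feasible H so every later half-step is a descent step
            C = np.vstack([-np.eye(p_r), A])
            for i in range(hp.k):
                G[i] = np.clip(_solvers.project_to_polyhedron(G[i], C), 0.0, None)
        trace: list[float] = []
        warm: np.ndarray | None = None
        converged = False
        prev = np.inf
        for _ in range(hp.max_iter):
            W = _ridge_W(Y, G, hp.alpha)
            trace.append(_objective_scaled(Y, W, G, hp.alpha))
            G, warm = _update_G(Y, W, hp.alpha, A, warm=warm)
            obj = _objective_scaled(Y, W, G, hp.alpha)
            trace.append(obj)
            if np.isfinite(prev) and prev - obj <= hp.rel_tol * max(abs(prev), 1e-300):
                converged = True
                break
            prev = obj
        W = _ridge_W(Y, G, hp.alpha)
        trace.append(_objective_scaled(Y, W, G, hp.alpha))
        if not converged:
            warnings.warn(f"restart {r}: not converged in {hp.max_iter} iterations", stacklevel=2)
        H = np.zeros((hp.k, D.n_features))
        H[:, D.retained] = G * D.d[None, :]
        # canonical profile order: decreasing average contribution to the
        # reconstruction (profile 1 = dominant), invariant to the W/H scale split
        contrib = W.mean(axis=0) * H.sum(axis=1)
        order = np.argsort(-contrib, kind="stable")
        W, H = W[:, order], H[order]
        dec = Decomposition(
            W=W, H=H, D=D, alpha=hp.alpha, k=hp.k,
            objective_trace=trace, converged=converged, seed=hp.seed, restart=r,
            sample_ids=list(X.sample_ids) if isinstance(X, CountMatrix) else [],
            feature_ids=list(X.feature_ids) if isinstance(X, CountMatrix) else [],
        )
        if best is None or dec.objective < best.objective:
            best = dec
    assert best is not None
    return best


def _identity_scaling(p: int) -> ScalingVector:
    return ScalingVector(d=np.ones(p), retained=np.arange(p), n_features=p)


def _ridge_W(Y: np.ndarray, G: np.ndarray, alpha: float) -> np.ndarray:
    k = G.shape[0]
    AtA = G @ G.T + alpha * np.eye(k)
    AtB = G @ Y.T
    return _solvers.nnls_gram_multi(AtA, AtB).T


def project(X_new, H, alpha, D_train: ScalingVector) -> np.ndarray:
    """Fixed-H nonnegative ridge projection of new samples onto the profiles.

    Reuses the TRAINING scaling D (the profiles' column scale is defined
    relative to it), so external cohorts are mapped into the same weight
    space as the training samples.
    """
    V = _as_values(X_new)
    if V.shape[1] != D_train.n_features:
        raise FitError(
            f"feature mismatch: X has {V.shape[1]} features, scaling has {D_train.n_features}"
        )
    return update_W(V, H, alpha, D_train)


def affect_features(X_other, W_fixed, alpha, F: ConstraintMatrix | None = None) -> np.ndarray:
    """Affect a feature space (genomes, genera, transcripts) to the profiles.

    One fixed-W H update on the target matrix: features that co-vary with a
    profile's weights across samples are attributed to it.  D is recomputed
    from the target matrix's own columns; F is supplied for transcript
    targets (the pathway semantics applies) and omitted for taxonomic ones.
    """
    V = _as_values(X_other)
    W_fixed = np.asarray(W_fixed, dtype=float)
    if V.shape[0] != W_fixed.shape[0]:
        raise FitError(
            f"sample mismatch: X has {V.shape[0]} rows, W has {W_fixed.shape[0]}"
        )
    if not np.any(V):
        return np.zeros((W_fixed.shape[1], V.shape[1]))
    D = compute_scaling(V)
    return update_H(V, W_fixed, alpha, D, F=F)


def normalize_profile_scale(W, H) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each profile so its H row sums to one (frequency convention).

    The factorization W H is invariant under per-profile diagonal rescaling;
    profiles are reported as frequency vectors (rows summing to 1) with the
    compensating scale moved into W.  Weight-balance statistics such as
    W* = W2/(W1+W2) are only comparable under a fixed convention, so apply
    this before computing them.  Zero profiles are left untouched.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    s = H.sum(axis=1)
    s_safe = np.where(s > 0, s, 1.0)
    return W * s_safe[None, :], H / s_safe[:, None]


def relative_error(X, W, H) -> np.ndarray:
    """Per-sample relative reconstruction error ||x_i - (WH)_i|| / ||x_i||.

    Unscaled (no D), per the validation definition.  Zero-norm samples get
    NaN with a warning.
    """
    V = _as_values(X)
    R = V - np.asarray(W) @ np.asarray(H)
    num = np.sqrt((R**2).sum(axis=1))
    den = np.sqrt((V**2).sum(axis=1))
    out = np.full(V.shape[0], np.nan)
    ok = den > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-norm samples: relative error undefined", stacklevel=2)
    out[ok] = num[ok] / den[ok]
    return out
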