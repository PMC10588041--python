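"""Exact solvers for the small convex programs inside the factorization.

Three primitives cover every subproblem of the block-coordinate descent:

* :func:`nnls_gram_multi` -- many nonnegative least-squares problems sharing
  one Gram matrix (the W update and the unconstrained H update).  The number
  of variables equals the number of profiles k, which is small, so the exact
  solution is found by enumerating active sets and checking the KKT
  conditions, vectorized over right-hand sides.
* :func:`nnls_active_set` -- a single nonnegative least-squares problem of
  moderate size, solved by a warm-startable block-pivoting active-set
  iteration (Portugal-Judice-Vicente with Murty's finite-termination
  safeguard), falling back on :func:`scipy.optimize.nnls`.
* :func:`qp_ineq_dual` -- a strictly convex quadratic program with linear
  inequality constraints, solved exactly through its Lagrangian dual, which
  for constraints C x <= 0 is itself a nonnegative least-squares problem.

All three are deterministic and solve their problem to active-set (machine)
precision, which is what makes the objective trace of the factorization
monotone.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.optimize

#: default KKT tolerance of the quadratic subproblem solvers
QP_TOL = 1e-9


def _solve_psd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric positive semi-definite A, tolerating
    rank deficiency."""
    try:
        c = scipy.linalg.cho_factor(A, check_finite=False)
        return scipy.linalg.cho_solve(c, B, check_finite=False)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, B, rcond=None)[0]


def nnls_gram_multi(AtA: np.ndarray, AtB: np.ndarray, tol: float = QP_TOL) -> np.ndarray:
    """Solve ``min_{x>=0} x'AtA x/2 - AtB_r' x`` for every column r of AtB.

    Equivalent to nonnegative least squares ``min ||A x - b_r||`` expressed
    through the Gram matrix ``AtA = A'A`` and cross products ``AtB = A'B``.
    Exact for small k (<= ~12) by KKT enumeration over the 2^k active sets;
    vectorized over right-hand sides.

    Returns an array of shape ``(k, R)``.
    """
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.atleast_2d(np.asarray(AtB, dtype=float))
    k, R = AtB.shape
    if AtA.shape != (k, k):
        raise ValueError(f"Gram matrix shape {AtA.shape} does not match rhs {AtB.shape}")
    if k > 14:  # enumeration would explode; fall back to per-column active set
        out = np.empty((k, R))
        L = _gram_chol(AtA)
        for r in range(R):
            b = scipy.linalg.solve_triangular(L, AtB[:, r], lower=True)
            out[:, r] = scipy.optimize.nnls(L.T, b)[0]
        return out

    scale = max(np.abs(AtB).max(), np.abs(AtA).max(), 1.0)
    X = np.zeros((k, R))
    unsolved = np.ones(R, dtype=bool)
    for eff_tol in (tol * scale, tol * scale * 1e3):
        # x = 0 candidate: optimal iff gradient -AtB >= 0
        zero_ok = unsolved & np.all(AtB <= eff_tol, axis=0)
        X[:, zero_ok] = 0.0
        unsolved &= ~zero_ok
        if not unsolved.any():
            return X
        for mask in range(1, 2**k):
            if not unsolved.any():
                break
            S = np.array([i for i in range(k) if mask >> i & 1])
            idx = np.flatnonzero(unsolved)
            Z = _solve_psd(AtA[np.ix_(S, S)], AtB[np.ix_(S, idx)])
            primal_ok = np.all(Z >= -eff_tol, axis=0)
            grad = AtA[:, S] @ Z - AtB[:, idx]  # gradient at candidate
            comp = np.setdiff1d(np.arange(k), S)
            dual_ok = (
                np.all(grad[comp] >= -eff_tol, axis=0) if comp.size else np.ones(idx.size, bool)
            )
            ok = primal_ok & dual_ok
            if ok.any():
                cols = idx[ok]
                X[:, cols] = 0.0
                X[np.ix_(S, cols)] = np.clip(Z[:, ok], 0.0, None)
                unsolved[cols] = False
        if not unsolved.any():
            return X
    # numerical stragglers: solve via Cholesky factor + reference NNLS
    L = _gram_chol(AtA)
    for r in np.flatnonzero(unsolved):
        b = scipy.linalg.solve_triangular(L, AtB[:, r], lower=True)
        X[:, r] = scipy.optimize.nnls(L.T, b)[0]
    return X


def _gram_chol(AtA: np.ndarray) -> np.ndarray:
    """Cholesky factor of a Gram matrix, with a tiny jitter if singular."""
    k = AtA.shape[0]
    jitter = 0.0
    base = np.trace(AtA) / max(k, 1) + 1.0
    for _ in range(12):
        try:
            return np.linalg.cholesky(AtA + jitter * np.eye(k))
        except np.linalg.LinAlgError:
            jitter = base * 1e-14 if jitter == 0.0 else jitter * 100.0
    raise np.linalg.LinAlgError("Gram matrix could not be factorized")


def nnls_active_set(
    M: np.ndarray,
    b: np.ndarray,
    warm: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact NNLS ``min_{lam>=0} ||M lam - b||^2`` by block pivoting.

    ``warm`` is an optional boolean passive-set guess (e.g. from the previous
    outer iteration); a good guess typically converges in one or two least
    squares solves.  Returns ``(lam, passive_mask)``.
    """
    m, n = M.shape
    passive = np.zeros(n, dtype=bool) if warm is None else warm.copy()
    max_iter = max_iter if max_iter is not None else 3 * n + 30
    scale = max(np.abs(b).max(initial=0.0), 1.0)
    eff = tol * scale
    best_inf = np.inf
    backup = 3
    lam = np.zeros(n)
    for _ in range(max_iter):
        lam = np.zeros(n)
        if passive.any():
            sol = scipy.linalg.lstsq(M[:, passive], b, lapack_driver="gelsy",
                                     check_finite=False)[0]
            lam[passive] = sol
        grad = M.T @ (M @ lam - b)
        viol_p = passive & (lam < -eff)
        viol_a = ~passive & (grad < -eff)
        ninf = int(viol_p.sum() + viol_a.sum())
        if ninf == 0:
            return np.clip(lam, 0.0, None), passive
        if ninf < best_inf:
            best_inf = ninf
            backup = 3
            passive[viol_p] = False
            passive[viol_a] = True
        elif backup > 0:
            backup -= 1
            passive[viol_p] = False
            passive[viol_a] = True
        else:  # Murty's rule: flip only the highest-index violator
            i = int(np.max(np.flatnonzero(viol_p | viol_a)))
            passive[i] = not passive[i]
    # reference fallback (Lawson-Hanson)
    lam, _ = scipy.optimize.nnls(M, b)
    return lam, lam > 0


def qp_ineq_dual(
    P: np.ndarray,
    q: np.ndarray,
    C: np.ndarray,
    warm: np.ndarray | None = None,
    tol: float = QP_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``min 0.5 x'Px + q'x  s.t.  C x <= 0`` for positive definite P.

    Strong duality holds (polyhedral constraints, x = 0 feasible); the dual in
    the multipliers lam >= 0 is the NNLS problem ``min ||L^-1 C' lam + L^-1 q||``
    with ``P = L L'``.  Returns ``(x, passive_mask)`` where the mask can warm
    start the next call.
    """
    L = _gram_chol(P)
    v = scipy.linalg.solve_triangular(L, q, lower=True, check_finite=False)
    B = scipy.linalg.solve_triangular(L, C.T, lower=True, check_finite=False)
    lam, passive = nnls_active_set(B, -v, warm=warm, tol=tol)
    rhs = q + C.T @ lam
    y = scipy.linalg.solve_triangular(L, rhs, lower=True, check_finite=False)
    x = -scipy.linalg.solve_triangular(L.T, y, lower=False, check_finite=False)
    return x, passive


def project_to_polyhedron(
    h0: np.ndarray, C: np.ndarray, tol: float = QP_TOL
) -> np.ndarray:
    """Euclidean projection of h0 onto ``{h : C h <= 0}``.

    Used with C stacking ``-I`` and a pathway constraint matrix to draw
    feasible synthetic profiles:  min ||h - h0||^2  s.t.  C h <= 0.
    """
    h0 = np.asarray(h0, dtype=float)
    P = np.eye(h0.size)
    x, _ = qp_ineq_dual(P, -h0, C, tol=tol)
    return x
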