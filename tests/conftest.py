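"""Shared fixtures: a small toy network, the packaged reference network, and
independent convex-optimization oracles (scipy.optimize based, never the
package's own solver path)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from fibrenmf.network import (
    AftEntry,
    ConstraintMatrix,
    MetabolicNetwork,
    build_chain_constraints,
    reference_constraints,
    reference_network,
)


def _aft(aft_id, kind, members, sub, prod, module="m"):
    return AftEntry(aft_id, kind, members, sub, prod, module)


@pytest.fixture(scope="session")
def toy_network() -> MetabolicNetwork:
    """Six-AFT chain: fibre -(gh1)-> A -(aft1)-> m1 -(aft2)-> m2 -(aft3)-> B,
    with a second producer of m1 (aft4 from C) and an uptake-only edge."""
    metabolites = {
        "fibre": "extracellular",
        "A": "extracellular",
        "B": "extracellular",
        "C": "extracellular",
        "m1": "intracellular",
        "m2": "intracellular",
    }
    afts = [
        _aft("GH_toy", "GH", ["GH_toy"], "fibre", "A", "cleavage"),
        _aft("AFT_a", "KO-pathway", ["K00001"], "A", "m1", "entry"),
        _aft("AFT_b", "KO-pathway", ["K00002"], "C", "m1", "entry"),
        _aft("AFT_c", "KO-pathway", ["K00003"], "m1", "m2", "core"),
        _aft("AFT_d", "KO-pathway", ["K00004"], "m2", "B", "exit"),
        _aft("AFT_e", "KO-pathway", ["K00005"], "A", "B", "bypass"),
    ]
    return MetabolicNetwork(metabolites=metabolites, afts=afts)


@pytest.fixture(scope="session")
def toy_F(toy_network) -> ConstraintMatrix:
    return build_chain_constraints(toy_network)


@pytest.fixture(scope="session")
def ref_network():
    return reference_network()


@pytest.fixture(scope="session")
def ref_F(ref_network):
    return reference_constraints(ref_network)


# ---------------------------------------------------------------------------
# oracles


def qp_oracle(P, q, C=None, x0=None):
    """Generic QP oracle: min 0.5 x'Px + q'x s.t. C x <= 0, via SLSQP."""
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float)
    n = q.size
    cons = []
    if C is not None and len(C):
        cons.append(LinearConstraint(np.asarray(C, dtype=float), -np.inf, 0.0))
    res = minimize(
        lambda x: 0.5 * x @ P @ x + q @ x,
        x0 if x0 is not None else np.zeros(n),
        jac=lambda x: P @ x + q,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 800, "ftol": 1e-14},
    )
    return res.x


def nnls_ridge_oracle(M, y, alpha):
    """Oracle for min_{x>=0} ||y - M x||^2 + alpha ||x||^2."""
    M = np.asarray(M, dtype=float)
    P = 2.0 * (M.T @ M + alpha * np.eye(M.shape[1]))
    q = -2.0 * M.T @ y
    return qp_oracle(P, q, C=-np.eye(M.shape[1]))


def h_update_oracle(Y, W, alpha, A=None):
    """Oracle for the coupled H update in scaled coordinates.

    min_G>=0, A G^T <= 0 of ||Y - W G||_F^2 + alpha * sum_j (1'g_j)^2,
    solved as one QP over all k*p entries (variable order: columns of G).
    """
    n, k = W.shape
    p = Y.shape[1]
    P0 = 2.0 * (W.T @ W + alpha * np.ones((k, k)))
    P = np.kron(np.eye(p), P0)
    q = (-2.0 * (W.T @ Y)).T.reshape(-1)
    rows = [-np.eye(k * p)]
    if A is not None and len(A):
        c = A.shape[0]
        Cf = np.zeros((c * k, k * p))
        for ci in range(c):
            for i in range(k):
                for j in range(p):
                    Cf[ci * k + i, j * k + i] = A[ci, j]
        rows.append(Cf)
    x = qp_oracle(P, q, C=np.vstack(rows))
    return x.reshape(p, k).T


def scaled_objective(Y, W, G, alpha):
    """Scripted evaluation of the scaled objective (independent of nmf.py)."""
    fit = np.sum((Y - W @ G) ** 2)
    return fit + alpha * (np.sum(W**2) + np.sum(np.abs(G).sum(axis=0) ** 2))
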