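"""Hyperparameter selection: internal error, bi-cross-validation, stability.

The number of profiles k and the penalty alpha are chosen by a triple
criterion: (1) internal reconstruction error on the full training matrix;
(2) a Gabriel-style bi-cross-validation error, holding out a samples x
features block and predicting it through factors fitted on the complementary
blocks; (3) stability of the profiles under row subsampling, measured as the
permutation-matched mean cosine similarity between independently refitted
profile matrices.  The decision rule keeps the grid points whose stability
clears a threshold and among them picks the lowest bi-CV error, breaking ties
toward fewer profiles and stronger regularization.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import nmf
from .containers import CountMatrix
from .network import ConstraintMatrix


@dataclass
class SelectionGrid:
    k_values: list[int] = field(default_factory=lambda: list(range(2, 9)))
    alpha_values: list[float] = field(
        default_factory=lambda: list(np.logspace(-3, 0, 7))
    )
    n_cv_folds: int = 3  # row folds x column folds
    n_subsamples: int = 10
    subsample_fraction: float = 0.8
    seed: int = 0
    stability_threshold: float = 0.9
    # one-standard-error-style parsimony: bi-CV errors within this relative
    # margin of the minimum count as tied, and ties resolve to the smallest k
    bicv_tie_tol: float = 0.005
    # budget of the many fits run during selection (full-convergence runs are
    # only needed for the final refit at the chosen point)
    fit_restarts: int = 2
    fit_max_iter: int = 120
    fit_rel_tol: float = 1e-5

    def __post_init__(self) -> None:
        if not self.k_values or not self.alpha_values:
            raise ValueError("empty selection grid")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")


@dataclass
class SelectionReport:
    table: pd.DataFrame  # columns k, alpha, internal_error, bicv_error, stability
    chosen_k: int
    chosen_alpha: float
    rule_trace: list[str]


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)


def _restrict_cols(F: ConstraintMatrix | None, cols: np.ndarray) -> ConstraintMatrix | None:
    """Constraint rows fully supported on a column subset (by position)."""
    if F is None:
        return None
    ids = [F.aft_order[c] for c in cols]
    return F.restrict(ids)


def _hp(k, alpha, grid: SelectionGrid, seed: int) -> nmf.Hyperparams:
    return nmf.Hyperparams(
        k=k, alpha=alpha, max_iter=grid.fit_max_iter, rel_tol=grid.fit_rel_tol,
        n_restarts=grid.fit_restarts, seed=seed,
    )


def internal_error(X, k, alpha, F=None, grid: SelectionGrid | None = None, seed: int = 0) -> float:
    """Mean per-sample relative reconstruction error of a full fit."""
    grid = grid or SelectionGrid()
    V = _values(X)
    dec = nmf.fit(V, _hp(k, alpha, grid, seed), F)
    return float(np.nanmean(nmf.relative_error(V, dec.W, dec.H)))


def bicross_validate(X, k, alpha, F=None, folds: int = 3, seed: int = 0,
                     grid: SelectionGrid | None = None) -> float:
    """Gabriel bi-cross-validation error.

    Rows and columns are split into ``folds`` groups each.  For every held-out
    block X22 the factors (W1, H1) are fitted on the complementary block X11,
    the held-out columns' profiles H12 are inferred from X12 with W1 fixed,
    the held-out rows' weights W21 are projected from X21 with H1 fixed, and
    X22 is predicted as W21 H12 through the shared k-space.  Returns the mean
    per-sample relative error over all fold pairs.
    """
    grid = grid or SelectionGrid()
    V = _values(X)
    n, p = V.shape
    rng = np.random.default_rng(seed)
    row_folds = np.array_split(rng.permutation(n), folds)
    col_folds = np.array_split(rng.permutation(p), folds)
    for rf in row_folds:
        if n - rf.size < k:
            raise ValueError("row fold too small for the requested k")
    for cf in col_folds:
        if p - cf.size < k:
            raise ValueError("column fold too small for the requested k")
    errs: list[float] = []
    for rf, cf in itertools.product(row_folds, col_folds):
        tr = np.setdiff1d(np.arange(n), rf)
        tc = np.setdiff1d(np.arange(p), cf)
        F11 = _restrict_cols(F, tc)
        dec = nmf.fit(V[np.ix_(tr, tc)], _hp(k, alpha, grid, seed), F11)
        H12 = nmf.affect_features(V[np.ix_(tr, cf)], dec.W, alpha, F=_restrict_cols(F, cf))
        W21 = nmf.project(V[np.ix_(rf, tc)], dec.H, alpha, dec.D)
        X22 = V[np.ix_(rf, cf)]
        pred = W21 @ H12
        den = np.sqrt((X22**2).sum(axis=1))
        num = np.sqrt(((X22 - pred) ** 2).sum(axis=1))
        ok = den > 0
        errs.extend((num[ok] / den[ok]).tolist())
    return float(np.mean(errs))


def matched_cosine(H1: np.ndarray, H2: np.ndarray) -> float:
    """Mean cosine similarity between profile rows under the best matching."""
    def norm_rows(H):
        nrm = np.linalg.norm(H, axis=1, keepdims=True)
        zero = nrm[:, 0] == 0
        if zero.any():
            warnings.warn(f"{zero.sum()} all-zero profiles excluded from matching", stacklevel=2)
        nrm[nrm == 0] = 1.0
        return H / nrm, ~zero

    A, ka = norm_rows(np.asarray(H1, dtype=float))
    B, kb = norm_rows(np.asarray(H2, dtype=float))
    S = A @ B.T
    S = S[np.ix_(np.flatnonzero(ka), np.flatnonzero(kb))]
    if S.size == 0:
        return 0.0
    r, c = linear_sum_assignment(-S)
    return float(S[r, c].mean())


def stability(X, k, alpha, F=None, n_subsamples: int = 10, fraction: float = 0.8,
              seed: int = 0, grid: SelectionGrid | None = None) -> float:
    """Profile stability under row subsampling, in [0, 1].

    Fits the factorization on ``n_subsamples`` random row subsets and returns
    the mean permutation-matched cosine similarity over all pairs of runs.
    """
    grid = grid or SelectionGrid()
    V = _values(X)
    n = V.shape[0]
    m = int(round(fraction * n))
    if m < k:
        raise ValueError("subsample smaller than k")
    if n_subsamples == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    Hs = []
    for s in range(n_subsamples):
        rows = rng.choice(n, size=m, replace=False)
        dec = nmf.fit(V[rows], _hp(k, alpha, grid, seed + 1 + s), F)
        Hs.append(dec.H)
    scores = [matched_cosine(Hs[i], Hs[j]) for i, j in itertools.combinations(range(len(Hs)), 2)]
    return float(np.mean(scores))


def select_hyperparameters(X, grid: SelectionGrid, F=None) -> SelectionReport:
    """Triple-criterion grid search over (k, alpha).

    Among grid points with stability >= ``grid.stability_threshold`` the one
    with the lowest bi-CV error wins; points within ``grid.bicv_tie_tol``
    (relative) of the minimum count as tied, and ties break toward smaller k,
    then larger alpha (a one-standard-error-style parsimony rule).  If no
    point clears the stability threshold, the maximum-stability point is
    returned with a warning.
    """
    rows = []
    trace: list[str] = []
    for k, alpha in itertools.product(grid.k_values, grid.alpha_values):
        ie = internal_error(X, k, alpha, F, grid=grid, seed=grid.seed)
        bc = bicross_validate(X, k, alpha, F, folds=grid.n_cv_folds, seed=grid.seed, grid=grid)
        st = stability(
            X, k, alpha, F, n_subsamples=grid.n_subsamples,
            fraction=grid.subsample_fraction, seed=grid.seed, grid=grid,
        )
        rows.append(dict(k=k, alpha=alpha, internal_error=ie, bicv_error=bc, stability=st))
        trace.append(f"(k={k}, alpha={alpha:g}): internal={ie:.4f} bicv={bc:.4f} stab={st:.4f}")
    table = pd.DataFrame(rows)
    ok = table[table.stability >= grid.stability_threshold]
    if ok.empty:
        warnings.warn("no grid point reaches the stability threshold; using max stability",
                      stacklevel=2)
        ok = table.loc[[table.stability.idxmax()]]
        trace.append("fallback: max-stability point")
    # min bicv with a parsimony margin: errors within bicv_tie_tol of the
    # minimum are tied; ties -> smaller k, then larger alpha
    best = ok.bicv_error.min()
    tied = ok[ok.bicv_error <= best * (1 + grid.bicv_tie_tol)]
    tied = tied.sort_values(["k", "alpha"], ascending=[True, False])
    chosen = tied.iloc[0]
    trace.append(
        f"bicv min {best:.4f}; {len(tied)} candidates within {grid.bicv_tie_tol:.1%}"
    )
    trace.append(f"chosen: k={int(chosen.k)}, alpha={chosen.alpha:g}")
    return SelectionReport(
        table=table, chosen_k=int(chosen.k), chosen_alpha=float(chosen.alpha), rule_trace=trace
    )
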