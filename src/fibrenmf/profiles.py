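"""Downstream profile statistics.

Average weights and counts, per-AFT profile contributions
(Wbar_i H_ij / Xbar_j) with their residual, the profile-1/2 balance
W* = W2/(W1+W2) (~0.2, i.e. a 4:1 mix, in non-dysbiotic samples), ternary
coordinates over a profile triple, and the differential contribution-shift
ranking between two sample groups (per-feature Welch t-test, BH FDR filter,
then ranking by the l2 difference of per-profile contribution vectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, SchemaError


@dataclass
class ContributionReport:
    mean_weights: np.ndarray  # per profile
    mean_counts: np.ndarray  # per feature
    contribution: np.ndarray  # profiles x features, NaN columns where excluded
    residual: np.ndarray  # per feature
    feature_ids: list[str]
    excluded: list[str]  # zero-mean features

    def to_frame(self) -> pd.DataFrame:
        k = self.contribution.shape[0]
        df = pd.DataFrame(
            self.contribution.T,
            index=self.feature_ids,
            columns=[f"profile_{i+1}" for i in range(k)],
        )
        df["residual"] = self.residual
        return df


def average_weights(W) -> np.ndarray:
    """Mean profile weight over samples."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.size == 0:
        raise SchemaError("empty weight matrix")
    return W.mean(axis=0)


def average_counts(X) -> np.ndarray:
    """Mean feature count over samples."""
    V = X.values if isinstance(X, CountMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if V.size == 0:
        raise SchemaError("empty count matrix")
    return V.mean(axis=0)


def contribution(mean_w, H, mean_x, feature_ids=None) -> ContributionReport:
    """Average profile contribution per feature: Wbar_i H_ij / Xbar_j.

    The residual 1 - sum_i contribution(i, j) is the fraction of the average
    count of feature j not explained by the profile mixture.  Features with
    zero average count are excluded (flagged NaN) with a warning.
    """
    mean_w = np.asarray(mean_w, dtype=float)
    H = np.asarray(H, dtype=float)
    mean_x = np.asarray(mean_x, dtype=float)
    k, p = H.shape
    if mean_w.shape != (k,) or mean_x.shape != (p,):
        raise SchemaError(f"shape mismatch: Wbar {mean_w.shape}, H {H.shape}, Xbar {mean_x.shape}")
    feature_ids = list(feature_ids) if feature_ids is not None else [f"f{j}" for j in range(p)]
    contrib = np.full((k, p), np.nan)
    residual = np.full(p, np.nan)
    ok = mean_x > 0
    contrib[:, ok] = mean_w[:, None] * H[:, ok] / mean_x[None, ok]
    residual[ok] = 1.0 - contrib[:, ok].sum(axis=0)
    excluded = [feature_ids[j] for j in np.flatnonzero(~ok)]
    if excluded:
        warnings.warn(f"{len(excluded)} zero-mean features excluded from contributions",
                      stacklevel=2)
    return ContributionReport(mean_w, mean_x, contrib, residual, feature_ids, excluded)


def barycentric_w12(W) -> np.ndarray:
    """Profile balance W* = W2 / (W1 + W2) per sample; NaN where W1+W2 = 0."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[1] < 2:
        raise SchemaError("W* needs at least two profiles")
    tot = W[:, 0] + W[:, 1]
    out = np.full(W.shape[0], np.nan)
    ok = tot > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} samples have W1 + W2 = 0; W* undefined", stacklevel=2)
    out[ok] = W[ok, 1] / tot[ok]
    return out


def ternary_coords(W, profile_triple=(0, 1, 2)) -> np.ndarray:
    """Normalized (W_a, W_b, W_c) triples summing to 1; NaN rows where the sum is 0."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    idx = list(profile_triple)
    T = W[:, idx]
    tot = T.sum(axis=1)
    out = np.full_like(T, np.nan)
    ok = tot > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} samples have zero weight on the triple", stacklevel=2)
    out[ok] = T[ok] / tot[ok, None]
    return out


def first_timepoint_mask(metadata: pd.DataFrame) -> np.ndarray:
    """Keep only each individual's first timepoint (avoids individual effects)."""
    md = metadata.copy()
    if "Patient_ID" not in md.columns:
        raise SchemaError("metadata must provide Patient_ID")
    tp = pd.to_numeric(md.get("Timepoint", pd.Series(0, index=md.index)), errors="coerce")
    md["_tp"] = tp.fillna(np.inf)
    first = md.groupby("Patient_ID")["_tp"].transform("min")
    mask = (md["_tp"] == first).to_numpy()
    # several samples can share the minimal timepoint; keep the first occurrence
    seen: set[str] = set()
    out = np.zeros(len(md), dtype=bool)
    for i, (pid, keep) in enumerate(zip(md["Patient_ID"].astype(str), mask)):
        if keep and pid not in seen:
            seen.add(pid)
            out[i] = True
    return out


def group_contribution_shift(
    X,
    W,
    H,
    groups,
    metadata: pd.DataFrame | None = None,
    n_top: int = 20,
    fdr: float = 0.05,
    normalize_l1: bool = False,
    test_on_relative: bool = False,
    feature_ids=None,
) -> pd.DataFrame:
    """Rank features by the contribution shift between two sample groups.

    Procedure: (1) deduplicate to each individual's first timepoint when
    ``metadata`` is given; (2) per-feature Welch t-test between the two groups
    on the counts (optionally per-sample l1-normalized first), BH-adjusted,
    keeping FDR < ``fdr``; (3) per-group contribution reports from the group
    means of W and X (optionally l1-normalized per sample first, the
    module-level convention); (4) rank the kept features by the l2 norm of the
    difference of their per-profile contribution vectors; (5) keep the top
    ``n_top``.

    Returns a table with feature_id, p, q, l2_shift and per-group per-profile
    contributions; empty if nothing is significant.
    """
    V = X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = X.feature_ids if isinstance(X, CountMatrix) else [
            f"f{j}" for j in range(V.shape[1])
        ]
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if metadata is not None:
        keep = first_timepoint_mask(metadata)
        V, W, groups = V[keep], W[keep], groups[keep]
    names = pd.unique(groups)
    if len(names) != 2:
        raise SchemaError(f"exactly two groups required, got {list(names)}")
    g1, g2 = (groups == names[0]), (groups == names[1])
    if g1.sum() < 3 or g2.sum() < 3:
        raise SchemaError("each group needs at least 3 samples after deduplication")
    T = V / V.sum(axis=1, keepdims=True) if test_on_relative else V
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(T[g1], T[g2], equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    reject, qvals, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    if not reject.any():
        return pd.DataFrame(
            columns=["feature_id", "p", "q", "l2_shift"]
        )
    Vn = V / V.sum(axis=1, keepdims=True) if normalize_l1 else V
    Wn = W / W.sum(axis=1, keepdims=True) if normalize_l1 else W
    k = H.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep1 = contribution(Wn[g1].mean(axis=0), H, Vn[g1].mean(axis=0), feature_ids)
        rep2 = contribution(Wn[g2].mean(axis=0), H, Vn[g2].mean(axis=0), feature_ids)
    diff = rep1.contribution - rep2.contribution
    l2 = np.sqrt(np.nansum(diff**2, axis=0))
    l2 = np.where(np.all(np.isnan(diff), axis=0), np.nan, l2)
    rows = []
    for j in np.flatnonzero(reject):
        if np.isnan(l2[j]):
            continue
        row = {
            "feature_id": feature_ids[j], "p": pvals[j], "q": qvals[j], "l2_shift": l2[j],
        }
        for i in range(k):
            row[f"{names[0]}_profile_{i+1}"] = rep1.contribution[i, j]
            row[f"{names[1]}_profile_{i+1}"] = rep2.contribution[i, j]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("l2_shift", ascending=False, kind="mergesort")
    return out.head(n_top).reset_index(drop=True)


def two_group_tests(x1, x2) -> dict:
    """Convenience wrapper: Mann-Whitney U and Levene tests for two samples."""
    mw = stats.mannwhitneyu(x1, x2, alternative="two-sided")
    lev = stats.levene(x1, x2)
    return {"mannwhitney_p": float(mw.pvalue), "levene_p": float(lev.pvalue)}
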