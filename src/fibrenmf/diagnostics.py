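"""Ecological dissimilarity and dysbiosis statistics.

Pairwise Bray-Curtis dissimilarity (pBCd) between sample count vectors, the
dysbiosis index (DI: median pBCd of a sample to a healthy reference set,
excluding samples from the same individual), the dysbiotic threshold (0.9
quantile of DI in healthy samples) and intra/inter-cohort distance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .containers import CountMatrix, SchemaError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, hollow, in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise SchemaError("distance matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise SchemaError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise SchemaError("distance matrix diagonal is not zero")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise SchemaError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class DysbiosisReport:
    sample_ids: list[str]
    di: np.ndarray  # NaN where undefined
    threshold: float
    is_dysbiotic: np.ndarray  # boolean (False where DI undefined)
    reference_sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Dysbiosis_index": self.di, "Is_dysbiotic": self.is_dysbiotic},
            index=self.sample_ids,
        )


def bray_curtis(X: CountMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis: BC(u, v) = sum|u-v| / sum(u+v)."""
    V = X.values
    zero = np.flatnonzero(V.sum(axis=1) == 0)
    if zero.size:
        raise SchemaError(
            f"all-zero samples have no Bray-Curtis distance: {[X.sample_ids[i] for i in zero[:5]]}"
        )
    D = squareform(pdist(V, metric="braycurtis"))
    return DistanceMatrix(list(X.sample_ids), D)


def hmp2_reference_rule(metadata: pd.DataFrame) -> np.ndarray:
    """The published reference rule: non-IBD diagnosis, timepoint > 20 weeks."""
    diag = metadata["Diagnosis"].astype(str)
    non_ibd = ~diag.isin(["CD", "UC", "IBD"])
    tp = pd.to_numeric(metadata.get("Timepoint"), errors="coerce")
    return (non_ibd & (tp > 20)).to_numpy()


def healthy_group_rule(metadata: pd.DataFrame) -> np.ndarray:
    """Reference rule for synthetic runs: the generator's healthy group."""
    return (metadata["Diagnosis"].astype(str) == "healthy").to_numpy()


def dysbiosis_index(
    X: CountMatrix,
    metadata: pd.DataFrame,
    reference_rule: Callable[[pd.DataFrame], np.ndarray] = healthy_group_rule,
    healthy_rule: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> DysbiosisReport:
    """DI per sample plus the dysbiotic threshold and flags.

    ``metadata`` is indexed by sample id and provides at least Patient_ID,
    Diagnosis and (for the published rule) Timepoint.  For each sample, DI is
    the median Bray-Curtis distance to the reference samples excluding those
    sharing the sample's individual; samples whose exclusions empty the
    reference get NaN with a warning.  The threshold is the 0.9 quantile of
    DI over healthy samples (``healthy_rule``, defaulting to the reference
    rule) and flags samples strictly above it.
    """
    md = metadata.loc[X.sample_ids]
    if "Patient_ID" not in md.columns:
        raise SchemaError("metadata must provide Patient_ID")
    ref_mask = np.asarray(reference_rule(md), dtype=bool)
    if not ref_mask.any():
        raise SchemaError("reference rule selects no samples")
    D = bray_curtis(X).values
    individuals = md["Patient_ID"].astype(str).to_numpy()
    ref_idx = np.flatnonzero(ref_mask)
    di = np.full(X.n_samples, np.nan)
    for i in range(X.n_samples):
        usable = ref_idx[(individuals[ref_idx] != individuals[i]) & (ref_idx != i)]
        if usable.size == 0:
            warnings.warn(
                f"sample {X.sample_ids[i]!r}: reference empty after exclusions, DI undefined",
                stacklevel=2,
            )
            continue
        di[i] = np.median(D[i, usable])
    healthy_mask = np.asarray((healthy_rule or reference_rule)(md), dtype=bool)
    healthy_di = di[healthy_mask & ~np.isnan(di)]
    if healthy_di.size == 0:
        warnings.warn("no defined healthy DI values; threshold undefined", stacklevel=2)
        threshold = float("nan")
    else:
        threshold = dysbiosis_threshold(healthy_di)
    flags = np.where(np.isnan(di) | np.isnan(threshold), False, di > threshold)
    return DysbiosisReport(
        sample_ids=list(X.sample_ids),
        di=di,
        threshold=threshold,
        is_dysbiotic=flags.astype(bool),
        reference_sample_ids=[X.sample_ids[i] for i in ref_idx],
    )


def dysbiosis_threshold(di_healthy) -> float:
    """0.9 empirical quantile of healthy DI (linear interpolation)."""
    v = np.asarray(di_healthy, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise SchemaError("no healthy DI values to derive a threshold from")
    return float(np.quantile(v, 0.9, method="linear"))


def cohort_distance_summary(D: DistanceMatrix, cohort_labels) -> pd.DataFrame:
    """Split pair distances into intra- and inter-cohort distributions.

    Returns a long table with columns cohort, kind ('intra'|'inter'),
    distance; inter-cohort pairs are attributed to both cohorts involved.
    """
    labels = np.asarray([str(c) for c in cohort_labels])
    if labels.size != len(D.sample_ids):
        raise SchemaError("one cohort label per sample required")
    iu, ju = np.triu_indices(labels.size, k=1)
    same = labels[iu] == labels[ju]
    rows = []
    for cohort in pd.unique(labels):
        in_c = (labels[iu] == cohort) | (labels[ju] == cohort)
        intra = D.values[iu[in_c & same], ju[in_c & same]]
        inter = D.values[iu[in_c & ~same], ju[in_c & ~same]]
        if intra.size == 0:
            warnings.warn(f"cohort {cohort!r} has no intra-cohort pairs", stacklevel=2)
        rows.extend({"cohort": cohort, "kind": "intra", "distance": d} for d in intra)
        rows.extend({"cohort": cohort, "kind": "inter", "distance": d} for d in inter)
    return pd.DataFrame(rows, columns=["cohort", "kind", "distance"])
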