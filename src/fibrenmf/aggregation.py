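"""Gene-level abundances to feature frequency matrices.

Raw gene counts are normalized per sample by gene length and sequencing depth
(FPKM) and closed to relative frequencies; gene frequencies are then pooled
into aggregated functional traits (AFTs) by summing over each trait's
annotated genes, splitting multi-annotated genes equally across their
annotations.  Taxonomic marker counts are pooled into genomes/genera by plain
summation over a feature-to-group mapping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAbundanceTable, SchemaError
from .network import MetabolicNetwork


def fpkm_normalize(table: GeneAbundanceTable) -> CountMatrix:
    """Per-sample FPKM followed by closure to relative frequencies.

    fpkm_g = count_g / ((length_g/1e3) * (total_g/1e6)); each sample's FPKM
    vector is then rescaled to sum to one, so the output rows are relative
    gene frequencies.
    """
    totals = table.raw_counts.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise SchemaError(f"samples with zero total counts: {names[:5]}")
    fpkm = table.raw_counts / (table.lengths_bp[None, :] / 1e3) / (totals[:, None] / 1e6)
    freqs = fpkm / fpkm.sum(axis=1, keepdims=True)
    return CountMatrix(table.sample_ids, list(table.gene_ids), freqs, namespace="gene")


def aggregate_genes_to_aft(
    freqs: CountMatrix, table: GeneAbundanceTable, network: MetabolicNetwork
) -> CountMatrix:
    """Pool gene frequencies into AFT frequencies.

    Each gene contributes its frequency split equally across its m annotations
    (the equal-split rule conserves total annotated mass); unannotated genes
    are excluded.  Output columns follow the network feature order.
    """
    if freqs.feature_ids != list(table.gene_ids):
        raise SchemaError("gene frequency columns do not match the gene table")
    idx = network.feature_index
    p = network.n_features
    # sparse assignment matrix genes x AFTs with entries 1/m
    A = np.zeros((table.n_genes, p))
    any_annotated = False
    for g, annots in enumerate(table.annotations):
        if not annots:
            continue
        unknown = [a for a in annots if a not in idx]
        if unknown:
            raise SchemaError(f"gene {table.gene_ids[g]!r}: unknown aft annotation {unknown}")
        any_annotated = True
        w = 1.0 / len(annots)
        for a in annots:
            A[g, idx[a]] += w
    if not any_annotated:
        warnings.warn("no annotated genes; AFT matrix is all zero", stacklevel=2)
    values = freqs.values @ A
    return CountMatrix(freqs.sample_ids, list(network.aft_ids), values, namespace="AFT")


def pool_features(
    counts: CountMatrix, mapping: pd.Series | dict, namespace: str, drop_unmapped: bool = False
) -> CountMatrix:
    """Pool feature columns into groups by summation.

    ``mapping`` sends feature_id -> group_id (e.g. marker genes -> genome, or
    MGS -> genus).  Unmapped features raise unless ``drop_unmapped``, in which
    case they are dropped with a warning.  Group order is first appearance.
    """
    if isinstance(mapping, pd.Series):
        mapping = mapping.to_dict()
    if not mapping:
        raise SchemaError("empty feature mapping")
    unmapped = [f for f in counts.feature_ids if f not in mapping]
    if unmapped and not drop_unmapped:
        raise SchemaError(f"features missing from mapping: {unmapped[:5]}")
    if unmapped:
        warnings.warn(f"dropping {len(unmapped)} unmapped features", stacklevel=2)
    groups: list[str] = []
    gpos: dict[str, int] = {}
    cols: list[tuple[int, int]] = []
    for j, f in enumerate(counts.feature_ids):
        if f not in mapping:
            continue
        g = str(mapping[f])
        if g not in gpos:
            gpos[g] = len(groups)
            groups.append(g)
        cols.append((j, gpos[g]))
    values = np.zeros((counts.n_samples, len(groups)))
    for j, gj in cols:
        values[:, gj] += counts.values[:, j]
    return CountMatrix(counts.sample_ids, groups, values, namespace=namespace)
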