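"""Shared in-memory containers for count data and gene tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognized feature namespaces
NAMESPACES = ("AFT", "PG", "genus", "AFT-transcript", "gene")


class SchemaError(ValueError):
    """A file or table violates the expected layout or an invariant."""


@dataclass
class CountMatrix:
    """A samples x features matrix of nonnegative frequencies.

    ``namespace`` records which feature space the columns live in (aggregated
    functional traits, prevalent genomes, genera, AFT transcripts or raw
    genes); operations downstream are namespace-agnostic but propagate the tag.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    namespace: str = "AFT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != n:
            raise SchemaError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise SchemaError("duplicate feature ids")
        if np.any(self.values < 0):
            raise SchemaError("negative values in count matrix")
        if self.namespace not in NAMESPACES:
            raise SchemaError(f"unknown namespace {self.namespace!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, namespace: str = "AFT") -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), namespace)

    def reindex_features(self, feature_ids: list[str]) -> "CountMatrix":
        """Return a copy with columns in the requested order (all must exist)."""
        missing = [f for f in feature_ids if f not in set(self.feature_ids)]
        if missing:
            raise SchemaError(f"features not present: {missing[:5]}")
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        order = [pos[f] for f in feature_ids]
        return CountMatrix(self.sample_ids, list(feature_ids), self.values[:, order], self.namespace)


@dataclass
class GeneAbundanceTable:
    """Raw gene-level counts with lengths and AFT annotations.

    ``annotations[g]`` may be empty (unannotated gene) or hold several AFT ids
    (multi-annotated gene); ``raw_counts`` is samples x genes.
    """

    gene_ids: list[str]
    lengths_bp: np.ndarray
    annotations: list[list[str]]
    sample_ids: list[str]
    raw_counts: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths_bp = np.asarray(self.lengths_bp, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        g = len(self.gene_ids)
        if len(set(self.gene_ids)) != g:
            raise SchemaError("duplicate gene ids")
        if self.lengths_bp.shape != (g,) or np.any(self.lengths_bp <= 0):
            raise SchemaError("gene lengths must be positive, one per gene")
        if len(self.annotations) != g:
            raise SchemaError("one annotation list per gene required")
        if self.raw_counts.shape != (len(self.sample_ids), g):
            raise SchemaError(
                f"raw_counts shape {self.raw_counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {g} genes"
            )
        if np.any(self.raw_counts < 0):
            raise SchemaError("negative gene counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)
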