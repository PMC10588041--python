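"""Readers/writers for the TSV/JSON artifacts and run provenance.

TSV is the native dialect (bit-exact diffs in tests); layouts mirror the
supplementary spreadsheet sheets: count matrices have a header row of feature
ids and a first column of sample ids; decompositions are three TSVs (W, H, D)
plus a JSON sidecar with alpha, k, seed, trace and the convergence flag.
Numeric output uses 10 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAbundanceTable, SchemaError
from .nmf import Decomposition, ScalingVector

FLOAT_FMT = "%.10g"


def read_matrix(path, namespace: str = "AFT") -> CountMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise SchemaError(f"{path}: duplicate sample ids")
    if df.columns.has_duplicates:
        raise SchemaError(f"{path}: duplicate feature ids")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise SchemaError(f"{path}: non-numeric cell ({e})") from e
    if np.isnan(values).any():
        raise SchemaError(f"{path}: missing values")
    if (values < 0).any():
        raise SchemaError(f"{path}: negative values")
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       values, namespace)


def write_matrix(m: CountMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    """Metadata table keyed by Sample_ID; unknown columns preserved verbatim."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "Sample_ID" not in df.columns:
        raise SchemaError(f"{path}: missing Sample_ID column")
    if df["Sample_ID"].duplicated().any():
        raise SchemaError(f"{path}: duplicate Sample_ID values")
    df = df.set_index("Sample_ID")
    for col in ("Timepoint", "Dysbiosis_index", "age", "BMI"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_metadata(md: pd.DataFrame, path) -> None:
    out = md.copy()
    out.index.name = "Sample_ID"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_gene_table(path) -> GeneAbundanceTable:
    """Gene table TSV: gene_id, length_bp, annotations (';'-separated), then
    one raw-count column per sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "length_bp", "annotations"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length_bp", "annotations")]
    annots = [
        [a for a in str(s).split(";") if a and a != "nan"] for s in df["annotations"].fillna("")
    ]
    return GeneAbundanceTable(
        gene_ids=list(df["gene_id"]),
        lengths_bp=df["length_bp"].to_numpy(dtype=float),
        annotations=annots,
        sample_ids=sample_cols,
        raw_counts=df[sample_cols].to_numpy(dtype=float).T,
    )


def write_gene_table(t: GeneAbundanceTable, path) -> None:
    head = pd.DataFrame(
        {
            "gene_id": t.gene_ids,
            "length_bp": t.lengths_bp,
            "annotations": [";".join(a) for a in t.annotations],
        }
    )
    counts = pd.DataFrame(t.raw_counts.T, columns=t.sample_ids)
    pd.concat([head, counts], axis=1).to_csv(path, sep="\t", index=False,
                                             float_format=FLOAT_FMT)


def write_decomposition(dec: Decomposition, prefix) -> None:
    """Write W/H/D TSVs plus a JSON sidecar under ``prefix`` (a path stem)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    k = dec.k
    samples = dec.sample_ids or [f"S{i:04d}" for i in range(dec.W.shape[0])]
    features = dec.feature_ids or [f"f{j}" for j in range(dec.H.shape[1])]
    profs = [f"profile_{i+1}" for i in range(k)]
    pd.DataFrame(dec.W, index=samples, columns=profs).rename_axis("sample_id").to_csv(
        f"{prefix}_W.tsv", sep="\t", float_format=FLOAT_FMT
    )
    pd.DataFrame(dec.H, index=profs, columns=features).rename_axis("profile").to_csv(
        f"{prefix}_H.tsv", sep="\t", float_format=FLOAT_FMT
    )
    d_full = np.zeros(dec.D.n_features)
    d_full[dec.D.retained] = dec.D.d
    pd.DataFrame({"d": d_full}, index=features).rename_axis("feature_id").to_csv(
        f"{prefix}_D.tsv", sep="\t", float_format=FLOAT_FMT
    )
    sidecar = {
        "alpha": dec.alpha, "k": dec.k, "seed": dec.seed, "restart": dec.restart,
        "converged": bool(dec.converged),
        "objective_trace": [float(x) for x in dec.objective_trace],
        "retained_features": [int(i) for i in dec.D.retained],
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))


def read_decomposition(prefix) -> Decomposition:
    prefix = Path(prefix)
    W = pd.read_csv(f"{prefix}_W.tsv", sep="\t", index_col=0)
    H = pd.read_csv(f"{prefix}_H.tsv", sep="\t", index_col=0)
    Dd = pd.read_csv(f"{prefix}_D.tsv", sep="\t", index_col=0)["d"].to_numpy()
    meta = json.loads(Path(f"{prefix}.json").read_text())
    retained = np.array(meta["retained_features"], dtype=int)
    D = ScalingVector(d=Dd[retained], retained=retained, n_features=len(Dd))
    return Decomposition(
        W=W.to_numpy(), H=H.to_numpy(), D=D, alpha=meta["alpha"], k=meta["k"],
        objective_trace=meta["objective_trace"], converged=meta["converged"],
        seed=meta["seed"], restart=meta.get("restart", 0),
        sample_ids=list(W.index.astype(str)), feature_ids=list(H.columns.astype(str)),
    )


def write_provenance(path, **fields) -> None:
    """Run provenance JSON: package version, seed echo and resolved parameters."""
    from . import __version__

    payload = {"package": "fibrenmf", "version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
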