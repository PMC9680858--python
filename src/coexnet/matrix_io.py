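"""Expression/count matrix I/O, log transformation and exploratory analysis.

The central containers are thin dataclass wrappers around pandas objects:

* :class:`ExpressionMatrix` — gene × sample abundances (TPM or log2 scale),
* :class:`CountMatrix` — gene × sample non-negative integer raw counts,
* sample metadata and long-format annotation tables as plain DataFrames
  validated by the readers.

Orientation is fixed: genes in rows, samples in columns. Readers never
transpose or guess — the file layout (first column gene IDs, header row
sample IDs) is the contract.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "ANNOTATION_NAMESPACES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_annotation_table",
    "write_annotation_table",
    "log_transform",
    "inverse_log_transform",
    "filter_samples",
    "aggregate_by_group",
    "sample_clustering",
    "sample_pca",
]

#: Closed set of annotation namespaces. ``NAME`` carries curated gene names.
ANNOTATION_NAMESPACES = frozenset({"GO", "KEGG", "KOG", "Pfam", "NAME"})

SAMPLE_TABLE_COLUMNS = ["sample_id", "group", "study", "qc_value"]
ANNOTATION_COLUMNS = ["gene_id", "namespace", "term_id", "description"]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups[:5]}")


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame with gene IDs as index and sample IDs as columns.
    scale
        ``"tpm"`` for raw TPM (all values ≥ 0) or ``"log2"`` for
        log2-transformed values.
    """

    values: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2"):
            raise ValueError(f"scale must be 'tpm' or 'log2', got {self.scale!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "tpm" and (arr < 0).any():
            raise ValueError("TPM-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer raw counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            asfloat = arr.astype(float)
            if not np.isfinite(asfloat).all() or (asfloat != np.round(asfloat)).any():
                raise ValueError("count matrix must be integer-valued")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def _delimiter_for(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).removesuffix(".gz").endswith(".csv") else "\t"


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    sep = _delimiter_for(path, delimiter)
    # pandas mangles duplicate header fields; check the raw header first
    raw_header = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str).iloc[0]
    _check_unique(raw_header[1:], "sample")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        for col in bad:
            nonnum = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if nonnum.any():
                row = df.index[nonnum.to_numpy().nonzero()[0][0]]
                raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r}")
        df = df.apply(pd.to_numeric)
    if df.isna().to_numpy().any():
        raise ValueError("matrix contains missing values (ragged or empty cells)")
    return df


def read_expression_matrix(path, delimiter: str | None = None, scale: str = "tpm") -> ExpressionMatrix:
    """Read a gene × sample matrix from TSV/CSV (gzip-transparent).

    First column holds gene IDs, header row holds sample IDs. The caller
    declares the scale; nothing is auto-detected.
    """
    return ExpressionMatrix(_read_table(path, delimiter), scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    m.values.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="gene_id")


def read_count_matrix(path, delimiter: str | None = None) -> CountMatrix:
    """Read a raw count matrix; values must be non-negative integers."""
    return CountMatrix(_read_table(path, delimiter))


def write_count_matrix(c: CountMatrix, path, delimiter: str | None = None) -> None:
    c.counts.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="gene_id")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (sample_id, group, study, qc_value)."""
    missing = [c for c in ("sample_id", "group") if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    samples = samples.copy()
    if "study" not in samples.columns:
        samples["study"] = ""
    if "qc_value" not in samples.columns:
        samples["qc_value"] = np.nan
    _check_unique(samples["sample_id"], "sample")
    qc = samples["qc_value"].astype(float)
    ok = qc.isna() | ((qc >= 0) & (qc <= 1))
    if not ok.all():
        raise ValueError("qc_value must be within [0, 1] when present")
    samples["qc_value"] = qc
    return samples[SAMPLE_TABLE_COLUMNS + [c for c in samples.columns if c not in SAMPLE_TABLE_COLUMNS]]


def read_sample_table(path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str}))


def write_sample_table(samples: pd.DataFrame, path) -> None:
    validate_sample_table(samples).to_csv(path, sep="\t", index=False)


def validate_annotation_table(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad = set(ann["namespace"]) - ANNOTATION_NAMESPACES
    if bad:
        raise ValueError(f"unknown annotation namespaces: {sorted(bad)}")
    if ann.duplicated(["gene_id", "namespace", "term_id"]).any():
        raise ValueError("duplicate (gene_id, namespace, term_id) records")
    return ann[ANNOTATION_COLUMNS].copy()


def read_annotation_table(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna({"description": ""})
    return validate_annotation_table(ann)


def write_annotation_table(ann: pd.DataFrame, path) -> None:
    validate_annotation_table(ann).to_csv(path, sep="\t", index=False)


def log_transform(m: ExpressionMatrix, pseudo: float = 0.25) -> ExpressionMatrix:
    """Return log2(TPM + pseudo) on a TPM-scale matrix.

    The pseudo-count of 0.25 maps zero TPM to −2 and keeps the transform
    invertible; re-transforming an already-log matrix is refused.
    """
    if m.scale != "tpm":
        raise ValueError("log_transform requires a TPM-scale matrix (already log2?)")
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    return ExpressionMatrix(np.log2(m.values + pseudo), scale="log2")


def inverse_log_transform(m: ExpressionMatrix, pseudo: float = 0.25) -> ExpressionMatrix:
    """Invert :func:`log_transform`: TPM = 2**value − pseudo (clipped at 0)."""
    if m.scale != "log2":
        raise ValueError("inverse_log_transform requires a log2-scale matrix")
    tpm = np.power(2.0, m.values) - pseudo
    return ExpressionMatrix(tpm.clip(lower=0.0), scale="tpm")


def filter_samples(m: ExpressionMatrix, samples: pd.DataFrame, qc_threshold: float = 0.5) -> ExpressionMatrix:
    """Drop samples whose qc_value (e.g. mapping rate) falls below a threshold.

    Samples without a qc_value are retained — missing QC is not evidence of
    failure. Raises if the filter would remove every sample.
    """
    if not 0 <= qc_threshold <= 1:
        raise ValueError("qc_threshold must be in [0, 1]")
    samples = validate_sample_table(samples)
    table = samples.set_index("sample_id")
    unknown = [s for s in m.sample_ids if s not in table.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown[:5]}")
    qc = table.loc[m.sample_ids, "qc_value"]
    keep = [s for s, v in qc.items() if pd.isna(v) or v >= qc_threshold]
    if not keep:
        raise ValueError("QC filter removed all samples")
    return ExpressionMatrix(m.values[keep], scale=m.scale)


def aggregate_by_group(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    group_key: str = "group",
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-(gene, group) mean/SD/n summary backing bar, line and clustergram views.

    SD uses the population convention (``ddof=0``) by default so that a
    single-sample group reports SD 0 rather than NaN; pass ``ddof=1`` for the
    sample convention.
    """
    samples = validate_sample_table(samples) if group_key == "group" else samples.copy()
    if group_key not in samples.columns:
        raise ValueError(f"sample table has no column {group_key!r}")
    table = samples.set_index("sample_id")
    unknown = [s for s in table.index if s not in m.values.columns]
    if unknown:
        raise ValueError(f"metadata names samples absent from the matrix: {unknown[:5]}")
    missing = [s for s in m.sample_ids if s not in table.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing[:5]}")
    groups = table.loc[m.sample_ids, group_key]
    rows = []
    for group, cols in groups.groupby(groups).groups.items():
        block = m.values[list(cols)]
        n = block.shape[1]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=ddof) if n > ddof else pd.Series(0.0, index=block.index)
        rows.append(pd.DataFrame({
            "gene_id": block.index,
            "group": group,
            "mean": mean.to_numpy(),
            "sd": sd.fillna(0.0).to_numpy(),
            "n": n,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["gene_id", "group"], kind="stable").reset_index(drop=True)


def sample_clustering(m: ExpressionMatrix) -> np.ndarray:
    """Ward/Euclidean hierarchical clustering of samples on log2 expression.

    Returns the SciPy linkage matrix; leaves are samples in column order.
    """
    if m.scale != "log2":
        raise ValueError("sample_clustering expects log2-scale expression")
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    data = m.values.to_numpy(dtype=float).T  # samples × genes
    return scipy.cluster.hierarchy.linkage(data, method="ward", metric="euclidean")


def sample_pca(m: ExpressionMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on per-gene mean-centered log2 expression.

    Returns (coordinates sample × k, explained-variance fractions). No
    unit-variance scaling. The sign of each component is fixed by making its
    largest-magnitude gene loading positive, so results are deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n_genes, n_samples = m.shape
    if k > min(n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(n_genes, n_samples)}")
    if m.scale != "log2":
        raise ValueError("sample_pca expects log2-scale expression")
    X = m.values.to_numpy(dtype=float).T  # samples × genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    coords = U[:, :k] * s[:k]
    total_var = (Xc**2).sum()
    frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=m.sample_ids, columns=cols), frac
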