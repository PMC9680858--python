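"""Pairwise co-expression scoring: PCC, p-values, ranks, HRR and MR.

Given a log2-scale expression matrix, every ordered gene pair (A, B) gets a
rank: the position of B in A's partner list sorted by descending Pearson
correlation, with rank(A, A) = 0. The two symmetric pair scores are

* HRR (Highest Reciprocal Rank) = max(rank(A,B), rank(B,A)),
* MR  (Mutual Rank)             = sqrt(rank(A,B) × rank(B,A)),

so MR ≤ HRR always, and low values mean strong mutual co-expression. Ties in
PCC receive fractional (average) ranks, which keeps the scores deterministic
and stable under gene relabeling; MR/HRR may then be non-integer.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .matrix_io import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "CoexpressionScores",
    "correlation_matrix",
    "coexpression_scores",
    "rank_table",
    "pair_profile",
]


@dataclasses.dataclass
class CorrelationResult:
    """All-pairs Pearson correlation with two-sided p-values.

    ``pcc`` and ``pvalue`` are gene × gene arrays aligned to ``gene_ids``.
    Genes with zero variance over the selected samples yield NaN correlations
    (flagged missing); the diagonal is 1 with p = 0 by convention.
    """

    gene_ids: list[str]
    pcc: np.ndarray
    pvalue: np.ndarray
    n_samples: int

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            near = [g for g in self.gene_ids if gene.lower() in g.lower()][:5]
            raise KeyError(f"unknown gene {gene!r}; near matches: {near}") from None


@dataclasses.dataclass
class CoexpressionScores:
    """Rank / HRR / MR matrices derived from a :class:`CorrelationResult`."""

    gene_ids: list[str]
    rank: np.ndarray  # rank[i, j] = rank of j among i's partners; rank[i, i] = 0
    hrr: np.ndarray
    mr: np.ndarray

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            near = [g for g in self.gene_ids if gene.lower() in g.lower()][:5]
            raise KeyError(f"unknown gene {gene!r}; near matches: {near}") from None


def _pcc_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-transform t = r·sqrt((n−2)/(1−r²)), df = n−2.

    Equivalent to the incomplete-beta form used by scipy.stats.pearsonr.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = 0.5 * (n - 2)
        p = 2.0 * scipy.special.betainc(ab, ab, 0.5 * (1.0 - np.abs(r)))
    return np.clip(p, 0.0, 1.0)


def correlation_matrix(m: ExpressionMatrix, sample_subset: list[str] | None = None) -> CorrelationResult:
    """All-pairs PCC and p-values over all samples or a condition subset.

    Requires log2-scale input and ≥ 3 samples in the subset. Zero-variance
    genes get NaN correlations off-diagonal.
    """
    if m.scale != "log2":
        raise ValueError("correlation_matrix expects log2-scale expression")
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in m.values.columns]
        if unknown:
            raise KeyError(f"unknown sample IDs: {unknown[:5]}")
        values = m.values[list(sample_subset)]
    else:
        values = m.values
    n = values.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples to correlate, got {n}")
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.sqrt((Xc**2).sum(axis=1))
    zero_var = ss == 0
    ss_safe = np.where(zero_var, 1.0, ss)
    R = (Xc @ Xc.T) / np.outer(ss_safe, ss_safe)
    np.clip(R, -1.0, 1.0, out=R)
    R[zero_var, :] = np.nan
    R[:, zero_var] = np.nan
    np.fill_diagonal(R, 1.0)
    P = _pcc_pvalues(R, n)
    P[np.isnan(R)] = np.nan
    np.fill_diagonal(P, 0.0)
    return CorrelationResult(list(values.index), R, P, n)


def coexpression_scores(c: CorrelationResult) -> CoexpressionScores:
    """Row-wise co-expression ranks and the symmetric HRR/MR matrices.

    Per row, partners are ranked by descending PCC excluding self (self gets
    rank 0); ties get fractional ranks; missing (NaN) PCCs rank below every
    finite value. A row whose off-diagonal PCCs are all missing is an error.
    """
    n = len(c.gene_ids)
    if n < 3:
        raise ValueError("need at least 3 genes to rank")
    rank = np.zeros((n, n))
    for i in range(n):
        row = c.pcc[i].copy()
        row[i] = np.nan
        finite = np.isfinite(row)
        if not finite.any():
            raise ValueError(f"gene {c.gene_ids[i]!r} has no finite correlations")
        # descending PCC → ascending rank; NaNs pushed below all finite values
        idx = np.delete(np.arange(n), i)
        keyed = np.where(finite, -row, np.inf)[idx]
        rank[i, idx] = scipy.stats.rankdata(keyed, method="average")
        rank[i, i] = 0.0
    hrr = np.maximum(rank, rank.T)
    mr = np.sqrt(rank * rank.T)
    return CoexpressionScores(list(c.gene_ids), rank, hrr, mr)


def rank_table(
    scores: CoexpressionScores,
    c: CorrelationResult,
    query_gene: str,
    mr_cutoff: float = 1000.0,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genes co-expressed with a query below an MR cutoff, as a table.

    Rows are sorted by ascending MR (ties by gene ID) and joined to curated
    names and KOG/KEGG/Pfam descriptions when an annotation table is given —
    the columns of the downloadable rank-table view.
    """
    if mr_cutoff <= 0:
        raise ValueError("mr_cutoff must be positive")
    qi = scores.index_of(query_gene)
    mr_row = scores.mr[qi]
    keep = [
        j for j in range(len(scores.gene_ids))
        if j != qi and np.isfinite(mr_row[j]) and mr_row[j] < mr_cutoff
    ]
    df = pd.DataFrame({
        "gene_id": [scores.gene_ids[j] for j in keep],
        "hrr": scores.hrr[qi, keep],
        "mr": mr_row[keep],
        "pcc": c.pcc[qi, keep],
    })
    df = df.sort_values(["mr", "gene_id"], kind="stable").reset_index(drop=True)
    df.insert(1, "name", "")
    for ns in ("KOG", "KEGG", "Pfam"):
        df[ns.lower() + "_description"] = ""
    if annotations is not None and len(df):
        for ns, col in (("NAME", "name"), ("KOG", "kog_description"),
                        ("KEGG", "kegg_description"), ("Pfam", "pfam_description")):
            sub = annotations[annotations["namespace"] == ns]
            joined = sub.groupby("gene_id")["description"].apply("; ".join)
            df[col] = df["gene_id"].map(joined).fillna("")
    return df


def pair_profile(
    m: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    samples: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Paired per-sample expression of two genes plus their PCC.

    Backs the two-gene scatter view: one row per sample with both values and
    the sample's group label when metadata is supplied. The PCC is NaN when
    either gene has zero variance.
    """
    if gene_a == gene_b:
        raise ValueError("pair_profile requires two distinct genes")
    for g in (gene_a, gene_b):
        if g not in m.values.index:
            raise KeyError(f"unknown gene {g!r}")
    a = m.values.loc[gene_a]
    b = m.values.loc[gene_b]
    df = pd.DataFrame({"sample_id": m.sample_ids, gene_a: a.to_numpy(), gene_b: b.to_numpy()})
    if samples is not None:
        table = samples.set_index("sample_id")
        df["group"] = [table["group"].get(s, "") for s in df["sample_id"]]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        return df, float("nan")
    pcc = float(np.corrcoef(a.to_numpy(dtype=float), b.to_numpy(dtype=float))[0, 1])
    return df, pcc
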