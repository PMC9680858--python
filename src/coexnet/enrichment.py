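"""Functional term enrichment: Fisher's exact test with BH FDR over GO,
KEGG, KOG and Pfam annotations, with GO DAG propagation.

For a study set of n genes drawn from a background of N genes, each term
annotated to K background genes and k study genes is scored with the
two-sided Fisher's exact test on the 2×2 table

    [[k, n − k], [K − k, N − K − (n − k)]]

labelled "over" when k/n > K/N and "under" when k/n < K/N (equality counts
as "over" by convention). p-values are Benjamini–Hochberg adjusted across
all terms tested within one namespace. GO annotations are propagated to all
ancestors through is_a/part_of edges before counting, matching standard GO
enrichment semantics; KEGG/KOG/Pfam are flat namespaces with no hierarchy.
"""

from __future__ import annotations

import dataclasses
import re
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GODag",
    "parse_obo",
    "write_obo",
    "propagate_annotations",
    "enrich",
    "bh_adjust",
    "term_word_frequencies",
    "STOP_WORDS",
]

#: Fixed stop-word list for word-frequency summaries (versioned with the
#: package so counts are reproducible).
STOP_WORDS = frozenset("""
a an and are as at be by for from in into is it its of on or that the to via
with process activity regulation positive negative involved other unknown
""".split())


@dataclasses.dataclass
class GODag:
    """A Gene Ontology-style DAG: term → (name, namespace, direct parents).

    Parents follow is_a and part_of relations; the graph is validated
    acyclic and closed (every referenced parent is a defined term).
    """

    name: dict[str, str]
    namespace: dict[str, str]
    parents: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` through parent links (excl. self)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents[p])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


def parse_obo(path) -> GODag:
    """Parse an OBO 1.2 file into a :class:`GODag`.

    Keeps is_a and part_of edges of non-obsolete terms; a cycle or a parent
    reference to an undefined term is a hard error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    dangling = [n for n, d in graph.nodes(data=True) if "name" not in d]
    if dangling:
        raise ValueError(f"parent terms referenced but not defined: {sorted(dangling)[:5]}")
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology contains a cycle")
    parents: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        names[term] = data.get("name", "")
        namespaces[term] = data.get("namespace", "")
        ps = {v for _, v, rel in graph.out_edges(term, keys=True) if rel in ("is_a", "part_of")}
        parents[term] = frozenset(ps)
    return GODag(names, namespaces, parents)


def write_obo(dag: GODag, path) -> None:
    """Serialize a :class:`GODag` back to OBO 1.2 (is_a edges only for
    synthetic DAGs, which carry no part_of relations)."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(dag.parents):
        lines += ["[Term]", f"id: {term}", f"name: {dag.name.get(term, term)}"]
        ns = dag.namespace.get(term)
        if ns:
            lines.append(f"namespace: {ns}")
        for p in sorted(dag.parents[term]):
            lines.append(f"is_a: {p} ! {dag.name.get(p, p)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def propagate_annotations(annotations: pd.DataFrame, dag: GODag) -> pd.DataFrame:
    """Extend GO records to all ancestor terms (idempotent).

    Genes annotated to a term become annotated to every ancestor of that
    term too; non-GO namespaces pass through untouched. GO records whose
    term is absent from the DAG are dropped with a warning record count.
    """
    go = annotations[annotations["namespace"] == "GO"]
    rest = annotations[annotations["namespace"] != "GO"]
    known = go[go["term_id"].isin(dag.parents.keys())]
    records: set[tuple[str, str]] = set(zip(known["gene_id"], known["term_id"]))
    for gene, term in list(records):
        for anc in dag.ancestors(term):
            records.add((gene, anc))
    out = pd.DataFrame(sorted(records), columns=["gene_id", "term_id"])
    out["namespace"] = "GO"
    out["description"] = out["term_id"].map(dag.name).fillna("")
    out = out[["gene_id", "namespace", "term_id", "description"]]
    return pd.concat([rest, out], ignore_index=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study_genes,
    annotations: pd.DataFrame,
    namespace: str,
    background=None,
    dag: GODag | None = None,
    propagate: bool = True,
) -> pd.DataFrame:
    """Over/under-representation of terms in a study set via Fisher's exact test.

    Parameters
    ----------
    study_genes
        Genes of interest (e.g. DEGs or a co-expression neighborhood).
    annotations
        Long-format annotation table.
    namespace
        One of GO / KEGG / KOG / Pfam.
    background
        Population gene universe. Defaults to all genes carrying ≥ 1
        annotation in the tested namespace — a choice that changes N and K,
        so callers comparing against a fixed universe should pass it.
    dag, propagate
        For GO, annotations are propagated up the DAG before counting
        unless ``propagate=False``.

    Returns a DataFrame sorted by (fdr, p, term_id) with one row per term
    with K ≥ 1 in the background.
    """
    study = list(dict.fromkeys(study_genes))
    if not study:
        raise ValueError("study set is empty")
    ann = annotations[annotations["namespace"] == namespace]
    if namespace == "GO" and dag is not None and propagate:
        ann = propagate_annotations(annotations, dag)
        ann = ann[ann["namespace"] == "GO"]
    if background is None:
        bg = set(ann["gene_id"])
    else:
        bg = set(background)
    missing = [g for g in study if g not in bg]
    if missing:
        raise ValueError(f"study genes absent from background: {missing[:5]}")
    ann = ann[ann["gene_id"].isin(bg)]
    study_set = set(study)
    N, n = len(bg), len(study_set)
    rows = []
    for term, sub in ann.groupby("term_id"):
        genes = set(sub["gene_id"])
        K = len(genes)
        k = len(genes & study_set)
        _, p = scipy.stats.fisher_exact([[k, n - k], [K - k, N - K - (n - k)]], alternative="two-sided")
        direction = "over" if k * N >= K * n else "under"
        rows.append({
            "term_id": term,
            "namespace": namespace,
            "name": sub["description"].iloc[0],
            "study_count": k,
            "study_size": n,
            "pop_count": K,
            "pop_size": N,
            "direction": direction,
            "p": float(p),
        })
    if not rows:
        return pd.DataFrame(columns=["term_id", "namespace", "name", "study_count", "study_size",
                                     "pop_count", "pop_size", "direction", "p", "fdr"])
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["fdr", "p", "term_id"], kind="stable").reset_index(drop=True)


def term_word_frequencies(results: pd.DataFrame, fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Word-frequency table over the names of significantly enriched terms.

    Term names with fdr < cutoff are tokenized on non-alphanumeric
    boundaries, lowercased, and stripped of stop-words; this is the table
    behind word-cloud style summaries.
    """
    counts: dict[str, int] = {}
    if len(results):
        for name in results.loc[results["fdr"] < fdr_cutoff, "name"]:
            for token in re.split(r"[^0-9A-Za-z]+", str(name).lower()):
                if token and token not in STOP_WORDS:
                    counts[token] = counts.get(token, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["word", "count"])
    return df.sort_values(["count", "word"], ascending=[False, True], kind="stable").reset_index(drop=True)
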