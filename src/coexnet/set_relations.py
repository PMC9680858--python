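"""Exclusive-intersection (UpSet-style) analysis of named gene sets.

Given k named sets, every gene in their union belongs to exactly one
*region*: the non-empty subset of set names it is a member of. Regions
therefore partition the union — the quantity an UpSet plot draws — unlike
plain pairwise intersections which overlap.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = ["SetRelation", "exclusive_intersections", "upset_table", "read_gene_list"]


@dataclasses.dataclass
class SetRelation:
    """Partition of a union of named gene sets into exclusive regions.

    ``regions`` maps a region label (member set names joined with ``&`` in
    input order) to the sorted genes belonging to exactly those sets;
    ``membership`` is the gene × set boolean table.
    """

    set_names: list[str]
    regions: dict[str, list[str]]
    membership: pd.DataFrame

    def region_genes(self, *names: str) -> list[str]:
        return self.regions.get("&".join(names), [])


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene ID list (one per line), deduplicated in order."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return list(dict.fromkeys(ln for ln in lines if ln))


def exclusive_intersections(named_sets: dict[str, list] | list[tuple[str, list]]) -> SetRelation:
    """Partition the union of ≥ 2 named sets into exclusive regions.

    IDs are deduplicated within each set. Region labels follow the input
    set order; region ordering in downstream tables is by size descending,
    ties by label.
    """
    items = list(named_sets.items()) if isinstance(named_sets, dict) else list(named_sets)
    if len(items) < 2:
        raise ValueError("set relation requires at least 2 sets")
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    sets = {n: set(v) for n, v in items}
    union = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {n: [g in sets[n] for g in union] for n in names},
        index=pd.Index(union, name="gene_id"),
    )
    regions: dict[str, list[str]] = {}
    for gene in union:
        label = "&".join(n for n in names if gene in sets[n])
        regions.setdefault(label, []).append(gene)
    return SetRelation(names, regions, membership)


def upset_table(sr: SetRelation) -> tuple[pd.DataFrame, pd.Series]:
    """(region, size) rows ordered by size desc (ties by label) + set totals.

    Per-set totals are the plain set cardinalities, i.e. the sum of every
    region containing that set.
    """
    rows = sorted(sr.regions.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    table = pd.DataFrame(
        [{"region": label, "size": len(genes), "genes": ";".join(genes)} for label, genes in rows]
    )
    totals = pd.Series(
        {n: int(sr.membership[n].sum()) for n in sr.set_names}, name="total"
    )
    return table, totals
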