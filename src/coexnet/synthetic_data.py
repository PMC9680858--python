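"""Seeded generators for synthetic expression atlases, counts and ontologies.

These generators produce inputs with the statistical structure the rest of
the toolkit assumes, so every stage can be exercised end to end without any
external download:

* :func:`simulate_expression` — a log2-scale expression matrix containing
  planted co-expression modules on a latent-factor model: every member of a
  module follows the module's smooth latent profile plus independent noise,
  which guarantees high within-module correlation regardless of sample
  count; background genes are independent noise around gene-specific
  baselines.
* :func:`simulate_counts` — raw NB counts with planted log2 fold changes
  between two groups and known per-sample depth multipliers.
* :func:`simulate_annotations` — a random GO-style DAG plus a long-format
  annotation table with optional planted enriched terms.
* :func:`oil_body_demo` — a bundled scenario shaped like a marker-gene case
  study: four bait genes inside a co-expression module of terpenoid-pathway
  enzymes, a knockout-vs-wild-type count experiment in which the module is
  downregulated, and annotations whose planted GO term ties it together.

All functions are deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .enrichment import GODag
from .matrix_io import CountMatrix, ExpressionMatrix

__all__ = [
    "CoexpressionTruth",
    "DEGTruth",
    "simulate_expression",
    "simulate_counts",
    "simulate_annotations",
    "oil_body_demo",
    "OilBodyDemo",
]


@dataclasses.dataclass
class CoexpressionTruth:
    """Planted module structure of a simulated expression matrix."""

    modules: dict[str, list[str]]
    latent: dict[str, np.ndarray]
    noise_sd: float
    seed: int

    def module_of(self, gene: str) -> str | None:
        for mod, members in self.modules.items():
            if gene in members:
                return mod
        return None


@dataclasses.dataclass
class DEGTruth:
    """Planted differential-expression ground truth for simulated counts."""

    base_mean: pd.Series
    dispersion: pd.Series
    log2fc: pd.Series  # 0 for null genes
    n_per_group: tuple[int, int]
    seed: int

    @property
    def de_genes(self) -> list[str]:
        return list(self.log2fc.index[self.log2fc != 0])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression(
    n_genes: int = 500,
    n_samples: int = 24,
    module_sizes: dict[str, int] | list[int] | None = None,
    noise_sd: float = 0.5,
    background_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CoexpressionTruth]:
    """Log2-scale expression with planted co-expression modules.

    Each module has a latent profile built as a smooth random walk across
    samples; member genes equal the latent profile plus N(0, noise_sd)
    noise. Background genes are N(baseline, background_sd) independently
    per sample. Samples are labelled S000…; genes G00000….
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    if module_sizes is None:
        module_sizes = {"M1": 20}
    if not isinstance(module_sizes, dict):
        module_sizes = {f"M{i + 1}": s for i, s in enumerate(module_sizes)}
    total = sum(module_sizes.values())
    if total > n_genes:
        raise ValueError(f"module sizes sum to {total} > n_genes={n_genes}")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    samples = [f"S{j:03d}" for j in range(n_samples)]
    baselines = rng.normal(4.0, 1.5, size=n_genes)
    values = baselines[:, None] + rng.normal(0.0, background_sd, size=(n_genes, n_samples))
    modules: dict[str, list[str]] = {}
    latents: dict[str, np.ndarray] = {}
    start = 0
    for mod, size in module_sizes.items():
        latent = 4.0 + np.cumsum(rng.normal(0.0, 1.0, size=n_samples))
        members = genes[start:start + size]
        idx = np.arange(start, start + size)
        values[idx] = latent[None, :] + rng.normal(0.0, noise_sd, size=(size, n_samples))
        modules[mod] = members
        latents[mod] = latent
        start += size
    m = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale="log2")
    return m, CoexpressionTruth(modules, latents, noise_sd, seed)


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: tuple[int, int] = (3, 3),
    de_spec: dict[float, int] | None = None,
    dispersion: float = 0.1,
    base_mean: float = 100.0,
    depth_multipliers: list[float] | None = None,
    seed: int = 0,
    poisson: bool = False,
) -> tuple[CountMatrix, DEGTruth, pd.DataFrame]:
    """Raw NB counts for a two-group design with planted fold changes.

    Counts follow NB(mean = baseline × 2^(lfc·group) × depth, dispersion α)
    with variance μ + αμ². ``de_spec`` maps a log2 fold change to a number
    of genes carrying it, e.g. ``{2: 100, -2: 100}``; remaining genes are
    null. Per-gene baselines are drawn log-normal around ``base_mean``.
    ``poisson=True`` takes the α → 0 limit. Returns the count matrix, the
    ground truth, and a ready sample table (groups ``g1``/``g2``).
    """
    if not poisson and dispersion <= 0:
        raise ValueError("dispersion must be positive (or pass poisson=True)")
    n1, n2 = n_per_group
    if min(n1, n2) < 3:
        raise ValueError("each group needs ≥ 3 replicates")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    de_spec = de_spec or {}
    lfc = np.zeros(n_genes)
    pos = 0
    for value, count in de_spec.items():
        if pos + count > n_genes:
            raise ValueError("de_spec assigns more genes than n_genes")
        lfc[pos:pos + count] = value
        pos += count
    baselines = base_mean * np.exp(rng.normal(0.0, 0.5, size=n_genes))
    n_samples = n1 + n2
    depth = np.asarray(depth_multipliers if depth_multipliers is not None else np.ones(n_samples), dtype=float)
    if depth.shape != (n_samples,):
        raise ValueError(f"depth_multipliers must have length {n_samples}")
    group = np.array([0] * n1 + [1] * n2)
    mu = baselines[:, None] * np.power(2.0, lfc[:, None] * group[None, :]) * depth[None, :]
    if poisson:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion  # NB size so that var = mu + dispersion*mu^2
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    sample_ids = [f"A{j}" for j in range(n1)] + [f"B{j}" for j in range(n2)]
    c = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    truth = DEGTruth(
        base_mean=pd.Series(baselines, index=genes),
        dispersion=pd.Series(0.0 if poisson else dispersion, index=genes),
        log2fc=pd.Series(lfc, index=genes),
        n_per_group=(n1, n2),
        seed=seed,
    )
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": ["g1"] * n1 + ["g2"] * n2,
        "study": "simulated",
        "qc_value": 1.0,
    })
    return c, truth, samples


_NAME_VOCAB = [
    "oxidoreductase", "kinase", "transport", "membrane", "signal", "binding",
    "metabolic", "biosynthesis", "response", "stress", "transferase",
    "photosynthesis", "cell", "wall", "division", "rna", "dna", "repair",
    "transcription", "translation", "lipid", "protein", "folding",
]


def simulate_annotations(
    genes: list[str],
    n_terms: int = 50,
    dag_depth: int = 3,
    enriched_term_spec: dict[str, tuple[list[str], float]] | None = None,
    background_p: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, GODag]:
    """Random GO-style DAG plus gene annotations with planted enrichment.

    The DAG has ``dag_depth`` levels under a single root; each non-root term
    draws 1–2 parents from the level above. Every gene receives each leaf
    term independently with probability ``background_p``. Planted terms
    (``{term_id: (gene_subset, probability)}``) additionally annotate their
    subset with the given probability — terms not already in the DAG are
    appended under the root.
    """
    if dag_depth < 1:
        raise ValueError("dag_depth must be ≥ 1")
    rng = np.random.default_rng(seed)
    root = "GO:0000000"
    names = {root: "biological process"}
    namespaces = {root: "biological_process"}
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    levels: list[list[str]] = [[root]]
    tid = 1
    per_level = max(1, n_terms // dag_depth)
    for depth in range(1, dag_depth + 1):
        level = []
        n_here = per_level if depth < dag_depth else max(1, n_terms - per_level * (dag_depth - 1))
        for _ in range(n_here):
            term = f"GO:{tid:07d}"
            tid += 1
            words = rng.choice(_NAME_VOCAB, size=2, replace=False)
            names[term] = " ".join(words)
            namespaces[term] = "biological_process"
            k = int(rng.integers(1, min(2, len(levels[depth - 1])) + 1))
            ps = rng.choice(levels[depth - 1], size=k, replace=False)
            parents[term] = frozenset(str(p) for p in ps)
            level.append(term)
        levels.append(level)
    records: set[tuple[str, str]] = set()
    leaf_terms = levels[-1]
    for g in genes:
        mask = rng.random(len(leaf_terms)) < background_p
        for t in np.array(leaf_terms)[mask]:
            records.add((g, str(t)))
    for term, (subset, prob) in (enriched_term_spec or {}).items():
        if term not in parents:
            parents[term] = frozenset({root})
            names.setdefault(term, term)
            namespaces[term] = "biological_process"
        for g in subset:
            if rng.random() < prob:
                records.add((g, term))
    dag = GODag(names, namespaces, parents)
    ann = pd.DataFrame(sorted(records), columns=["gene_id", "term_id"])
    ann["namespace"] = "GO"
    ann["description"] = ann["term_id"].map(names)
    return ann[["gene_id", "namespace", "term_id", "description"]], dag


@dataclasses.dataclass
class OilBodyDemo:
    """Bundled synthetic case study around four bait genes.

    An expression atlas with a 29-gene module (4 baits + 25 pathway enzyme
    genes annotated with "terpenoid"), a wild-type vs knockout count
    experiment downregulating the module, annotations and a GO DAG with a
    planted "terpenoid biosynthetic process" term over the module genes.
    """

    expression: ExpressionMatrix
    expression_truth: CoexpressionTruth
    counts: CountMatrix
    count_samples: pd.DataFrame
    count_truth: DEGTruth
    annotations: pd.DataFrame
    dag: GODag
    bait_genes: list[str]
    module_genes: list[str]  # the 25 non-bait planted genes
    planted_term: str


def oil_body_demo(seed: int = 0) -> OilBodyDemo:
    """Build the demo scenario (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    n_genes = 400
    expr, truth = simulate_expression(
        n_genes=n_genes, n_samples=24, module_sizes={"oil_body": 29},
        noise_sd=0.5, seed=int(rng.integers(2**31)),
    )
    module = truth.modules["oil_body"]
    baits, planted = module[:4], module[4:]
    genes = expr.gene_ids

    # counts: module genes downregulated (lfc −2) in the knockout
    n_mod = len(module)
    c_seed = int(rng.integers(2**31))
    counts, ctruth, samples = simulate_counts(
        n_genes=n_genes, n_per_group=(4, 4), de_spec={-2.0: n_mod},
        dispersion=0.1, base_mean=100.0, seed=c_seed,
    )
    # align gene IDs so the planted-DE block IS the module
    order = module + [g for g in genes if g not in module]
    counts = CountMatrix(counts.counts.set_axis(order, axis=0).loc[genes])
    ctruth = DEGTruth(
        base_mean=ctruth.base_mean.set_axis(order).loc[genes],
        dispersion=ctruth.dispersion.set_axis(order).loc[genes],
        log2fc=ctruth.log2fc.set_axis(order).loc[genes],
        n_per_group=ctruth.n_per_group,
        seed=c_seed,
    )
    samples["group"] = samples["group"].map({"g1": "WT", "g2": "knockout"})

    planted_term = "GO:7777777"
    go_ann, dag = simulate_annotations(
        genes, n_terms=40, dag_depth=3,
        enriched_term_spec={planted_term: (module, 1.0)},
        background_p=0.05, seed=int(rng.integers(2**31)),
    )
    dag.name[planted_term] = "terpenoid biosynthetic process"
    go_ann.loc[go_ann["term_id"] == planted_term, "description"] = dag.name[planted_term]

    extra = []
    bait_names = ["MpERF13", "MpC1HDZ", "MpABCG1", "MpSYP12B"]
    for g, nm in zip(baits, bait_names):
        extra.append((g, "NAME", nm, nm))
        extra.append((g, "KOG", "KOG-K", "transcription factor / transporter marker"))
    pathway_words = ["terpenoid biosynthesis enzyme", "terpenoid backbone biosynthesis",
                     "terpenoid synthase"]
    for i, g in enumerate(planted):
        extra.append((g, "Pfam", f"PF{i:05d}", pathway_words[i % len(pathway_words)]))
        extra.append((g, "KOG", "KOG-Q", "secondary metabolite biosynthesis"))
    decoys = ["protein kinase domain", "wd40 repeat", "cytochrome b561",
              "ribosomal protein", "zinc finger"]
    background = [g for g in genes if g not in module]
    for i, g in enumerate(background[:100]):
        extra.append((g, "Pfam", f"PFB{i:04d}", decoys[i % len(decoys)]))
    ann = pd.concat(
        [go_ann, pd.DataFrame(extra, columns=["gene_id", "namespace", "term_id", "description"])],
        ignore_index=True,
    ).drop_duplicates(["gene_id", "namespace", "term_id"]).reset_index(drop=True)

    return OilBodyDemo(
        expression=expr, expression_truth=truth,
        counts=counts, count_samples=samples, count_truth=ctruth,
        annotations=ann, dag=dag,
        bait_genes=baits, module_genes=planted, planted_term=planted_term,
    )
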