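import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import coexnet as cx
from coexnet import enrichment as en


def fisher_oracle(k, n, K, N):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact integer arithmetic: p = Σ pmf(x) over the support where
    pmf(x) ≤ pmf(k)·(1 + 1e-7) — the standard two-sided convention.
    """
    denom = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    pmf = {x: math.comb(K, x) * math.comb(N - K, n - x) / denom for x in range(lo, hi + 1)}
    cutoff = pmf[k] * (1 + 1e-7)
    return sum(v for v in pmf.values() if v <= cutoff)


def bh_oracle(p):
    """Direct step-up formula: p_(i)·m/i, cumulative min from the largest."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def chain_dag():
    """c is_a b is_a a."""
    return cx.GODag(
        name={"a": "root term", "b": "mid term", "c": "leaf term"},
        namespace={t: "biological_process" for t in "abc"},
        parents={"a": frozenset(), "b": frozenset({"a"}), "c": frozenset({"b"})},
    )


class TestParseObo:
    def test_chain_parents_and_ancestors(self, tmp_path):
        dag = chain_dag()
        p = tmp_path / "chain.obo"
        en.write_obo(dag, p)
        back = cx.parse_obo(p)
        assert back.parents["c"] == frozenset({"b"})
        assert back.ancestors("c") == frozenset({"a", "b"})

    def test_obsolete_excluded(self, tmp_path):
        p = tmp_path / "obs.obo"
        p.write_text(
            "format-version: 1.2\nontology: synthetic\n\n"
            "[Term]\nid: GO:1\nname: alive\n\n"
            "[Term]\nid: GO:2\nname: dead\nis_obsolete: true\n"
        )
        dag = cx.parse_obo(p)
        assert "GO:1" in dag and "GO:2" not in dag

    def test_dangling_parent_errors(self, tmp_path):
        p = tmp_path / "dangle.obo"
        p.write_text(
            "format-version: 1.2\nontology: synthetic\n\n"
            "[Term]\nid: GO:1\nname: child\nis_a: GO:9 ! missing\n"
        )
        with pytest.raises(ValueError, match="GO:9"):
            cx.parse_obo(p)

    def test_cycle_errors(self, tmp_path):
        p = tmp_path / "cycle.obo"
        p.write_text(
            "format-version: 1.2\nontology: synthetic\n\n"
            "[Term]\nid: GO:1\nname: one\nis_a: GO:2 ! two\n\n"
            "[Term]\nid: GO:2\nname: two\nis_a: GO:1 ! one\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            cx.parse_obo(p)

    def test_part_of_kept(self, tmp_path):
        p = tmp_path / "po.obo"
        p.write_text(
            "format-version: 1.2\nontology: synthetic\n\n"
            "[Term]\nid: GO:1\nname: whole\n\n"
            "[Term]\nid: GO:2\nname: part\nrelationship: part_of GO:1 ! whole\n"
        )
        dag = cx.parse_obo(p)
        assert dag.parents["GO:2"] == frozenset({"GO:1"})

    def test_synthetic_dag_ancestors_match_closure_oracle(self, tmp_path):
        genes = [f"G{i:05d}" for i in range(30)]
        _, dag = cx.simulate_annotations(genes, n_terms=50, dag_depth=4, seed=2)
        p = tmp_path / "dag.obo"
        en.write_obo(dag, p)
        back = cx.parse_obo(p)
        assert back.parents == dag.parents
        for term in dag.parents:
            # transitive-closure oracle by repeated parent expansion
            closure, frontier = set(), set(dag.parents[term])
            while frontier:
                closure |= frontier
                frontier = {p2 for t in frontier for p2 in dag.parents[t]} - closure
            assert back.ancestors(term) == closure


class TestPropagation:
    def ann(self, pairs):
        return pd.DataFrame([
            {"gene_id": g, "namespace": "GO", "term_id": t, "description": ""}
            for g, t in pairs
        ])

    def test_chain_propagation(self):
        out = cx.propagate_annotations(self.ann([("g1", "c")]), chain_dag())
        assert set(out[out["gene_id"] == "g1"]["term_id"]) == {"a", "b", "c"}

    def test_idempotent(self):
        dag = chain_dag()
        once = cx.propagate_annotations(self.ann([("g1", "c"), ("g2", "b")]), dag)
        twice = cx.propagate_annotations(once, dag)
        pd.testing.assert_frame_equal(
            once.sort_values(["gene_id", "term_id"]).reset_index(drop=True),
            twice.sort_values(["gene_id", "term_id"]).reset_index(drop=True),
        )

    def test_never_removes_and_counts_monotone(self):
        genes = [f"G{i:05d}" for i in range(50)]
        ann, dag = cx.simulate_annotations(genes, n_terms=30, dag_depth=3,
                                           background_p=0.2, seed=5)
        out = cx.propagate_annotations(ann, dag)
        before = set(zip(ann["gene_id"], ann["term_id"]))
        after = set(zip(out["gene_id"], out["term_id"]))
        assert before <= after
        K_before = ann.groupby("term_id")["gene_id"].nunique()
        K_after = out.groupby("term_id")["gene_id"].nunique()
        assert (K_after.loc[K_before.index] >= K_before).all()

    def test_matches_per_gene_closure_oracle(self):
        genes = [f"G{i:05d}" for i in range(20)]
        ann, dag = cx.simulate_annotations(genes, n_terms=25, dag_depth=3,
                                           background_p=0.3, seed=9)
        out = cx.propagate_annotations(ann, dag)
        for g in genes:
            direct = set(ann[ann["gene_id"] == g]["term_id"])
            expected = set(direct)
            for t in direct:
                expected |= dag.ancestors(t)
            assert set(out[out["gene_id"] == g]["term_id"]) == expected


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(cx.bh_adjust([0.03]), [0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(cx.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_worked_example_step_up(self):
        np.testing.assert_allclose(cx.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cx.bh_adjust([0.5, 1.2])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(cx.bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_properties(self, p):
        adj = cx.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()  # never decreases
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in sorted order

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(cx.bh_adjust(p)[perm], cx.bh_adjust(p[perm]))


class TestEnrich:
    def flat_ann(self, assignment):
        return pd.DataFrame([
            {"gene_id": g, "namespace": "Pfam", "term_id": t, "description": t}
            for g, terms in assignment.items() for t in terms
        ])

    def test_fisher_matches_enumeration_oracle(self):
        # study of 10 with k = 5; N = 100, K = 10
        genes = [f"g{i}" for i in range(100)]
        assignment = {g: ["PF_other"] for g in genes}
        for g in genes[:5] + genes[50:55]:
            assignment[g] = assignment[g] + ["PF_target"]
        ann = self.flat_ann(assignment)
        study = genes[:10]  # contains 5 of the 10 PF_target genes
        res = cx.enrich(study, ann, "Pfam").set_index("term_id")
        row = res.loc["PF_target"]
        assert (row["study_count"], row["pop_count"]) == (5, 10)
        assert row["p"] == pytest.approx(fisher_oracle(5, 10, 10, 100), abs=1e-10)
        assert row["direction"] == "over"

    def test_term_covering_everything_p_one_over(self):
        genes = [f"g{i}" for i in range(20)]
        ann = self.flat_ann({g: ["PF_all"] for g in genes})
        res = cx.enrich(genes[:6], ann, "Pfam")
        row = res.iloc[0]
        assert row["p"] == pytest.approx(1.0)
        assert row["direction"] == "over"  # equality labeled over by convention

    def test_full_background_study_all_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(1)
        assignment = {g: [f"PF{rng.integers(3)}"] for g in genes}
        ann = self.flat_ann(assignment)
        res = cx.enrich(sorted(set(ann["gene_id"])), ann, "Pfam")
        np.testing.assert_allclose(res["p"], 1.0)

    def test_under_representation_detected(self):
        genes = [f"g{i}" for i in range(60)]
        assignment = {g: ["PF_common"] for g in genes}
        for g in genes[30:]:
            assignment[g].append("PF_rare")
        ann = self.flat_ann(assignment)
        res = cx.enrich(genes[:20], ann, "Pfam").set_index("term_id")
        assert res.loc["PF_rare", "direction"] == "under"
        assert res.loc["PF_rare", "study_count"] == 0

    def test_empty_study_and_missing_gene_errors(self):
        ann = self.flat_ann({"g1": ["PF1"]})
        with pytest.raises(ValueError, match="empty"):
            cx.enrich([], ann, "Pfam")
        with pytest.raises(ValueError, match="absent"):
            cx.enrich(["ghost"], ann, "Pfam")

    def test_go_propagation_changes_counts(self):
        dag = chain_dag()
        ann = pd.DataFrame([
            {"gene_id": f"g{i}", "namespace": "GO", "term_id": "c", "description": "leaf term"}
            for i in range(5)
        ] + [
            {"gene_id": f"g{i}", "namespace": "GO", "term_id": "b", "description": "mid term"}
            for i in range(5, 10)
        ])
        study = [f"g{i}" for i in range(5)]
        with_prop = cx.enrich(study, ann, "GO", dag=dag).set_index("term_id")
        no_prop = cx.enrich(study, ann, "GO", dag=dag, propagate=False).set_index("term_id")
        assert with_prop.loc["b", "pop_count"] == 10  # c genes propagate to b
        assert no_prop.loc["b", "pop_count"] == 5

    def test_custom_background_changes_N(self):
        genes = [f"g{i}" for i in range(10)]
        ann = self.flat_ann({g: ["PF1"] for g in genes[:4]})
        res = cx.enrich(genes[:2], ann, "Pfam", background=genes)
        assert res.iloc[0]["pop_size"] == 10

    def test_planted_term_ranks_first(self):
        genes = [f"G{i:05d}" for i in range(300)]
        ann, dag = cx.simulate_annotations(
            genes, enriched_term_spec={"GO:9999999": (genes[:25], 1.0)}, seed=8)
        res = cx.enrich(genes[:25], ann, "GO", dag=dag)
        assert res.iloc[0]["term_id"] == "GO:9999999"


class TestWordFrequencies:
    def result(self, names, fdrs):
        return pd.DataFrame({
            "term_id": [f"T{i}" for i in range(len(names))],
            "name": names, "fdr": fdrs,
        })

    def test_counts_tokens_of_significant_terms(self):
        res = self.result(["terpenoid biosynthesis", "terpenoid transport"], [0.01, 0.01])
        wf = cx.term_word_frequencies(res)
        assert wf.set_index("word").loc["terpenoid", "count"] == 2

    def test_no_significant_terms_empty(self):
        res = self.result(["anything"], [0.5])
        assert len(cx.term_word_frequencies(res)) == 0

    def test_stop_words_dropped_and_lowercased(self):
        res = self.result(["Regulation of Terpenoid process"], [0.001])
        words = set(cx.term_word_frequencies(res)["word"])
        assert words == {"terpenoid"}

    def test_matches_token_loop_oracle(self):
        rng = np.random.default_rng(6)
        vocab = ["alpha", "beta", "gamma", "delta", "of", "the"]
        names = [" ".join(rng.choice(vocab, size=3)) for _ in range(30)]
        fdrs = rng.uniform(size=30)
        res = self.result(names, fdrs)
        wf = cx.term_word_frequencies(res, 0.5).set_index("word")["count"]
        expected = {}
        for name, fdr in zip(names, fdrs):
            if fdr < 0.5:
                for tok in name.split():
                    if tok not in en.STOP_WORDS:
                        expected[tok] = expected.get(tok, 0) + 1
        assert wf.to_dict() == expected
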