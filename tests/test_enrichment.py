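"""Fold enrichment, Fisher exact test, BH adjustment and reporting rules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_fisher_two_tailed, stepup_bh
from variclust.embedding import PhenotypeAnnotation
from variclust.enrichment import (
    EnrichmentOptions,
    TermAnnotationDB,
    TermRecord,
    UndefinedTermError,
    bh_fdr,
    enrich_cluster,
    fisher_p,
    fold_enrichment,
    phenotype_fe,
    read_asd_gene_list,
    read_term_db,
    select_report,
    sfari_overlap,
)


class TestFoldEnrichment:
    def test_zero_overlap_is_zero(self):
        assert fold_enrichment(0, 50, 20, 1000) == 0.0

    def test_cluster_equal_background_is_one(self):
        assert fold_enrichment(20, 1000, 20, 1000) == pytest.approx(1.0)

    def test_stated_arithmetic(self):
        assert fold_enrichment(5, 50, 20, 1000) == pytest.approx(5.0)

    def test_undefined_for_empty_term_or_cluster(self):
        with pytest.raises(UndefinedTermError):
            fold_enrichment(0, 0, 20, 1000)
        with pytest.raises(UndefinedTermError):
            fold_enrichment(0, 50, 0, 1000)

    def test_mixture_property(self):
        # FE of a union of disjoint clusters is the n-weighted mixture of FEs
        k1, n1, k2, n2, K, N = 6, 30, 2, 50, 20, 500
        fe_union = fold_enrichment(k1 + k2, n1 + n2, K, N)
        fe1 = fold_enrichment(k1, n1, K, N)
        fe2 = fold_enrichment(k2, n2, K, N)
        lo, hi = sorted([fe1, fe2])
        assert lo <= fe_union <= hi


class TestFisherP:
    def test_independence_table_is_lattice_maximum(self):
        # k = n*K/N exactly: the observed table is the modal one
        assert fisher_p(2, 10, 20, 100) == pytest.approx(1.0)

    def test_margins_4_4_in_8(self):
        assert fisher_p(3, 4, 4, 8) == pytest.approx(34 / 70, abs=1e-12)

    def test_diagonal_2x2(self):
        # enumeration over margins (2,2) in N=4: probs 1/6, 4/6, 1/6
        assert fisher_p(2, 2, 2, 4) == pytest.approx(1 / 3, abs=1e-12)

    def test_negative_cell_fatal(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_p(0, 5, 5, 8)  # fourth cell N-n-K+k = -2

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_enumeration_for_small_n(self, data):
        N = data.draw(st.integers(5, 200))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        assert fisher_p(k, n, K, N) == pytest.approx(
            enumerate_fisher_two_tailed(k, n, K, N), abs=1e-12
        )


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.02]) == pytest.approx([0.02])

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_hand_executed_step_up(self):
        assert bh_fdr([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_literal_step_up_and_permutes(self, pvals):
        ours = bh_fdr(pvals)
        assert ours == pytest.approx(stepup_bh(pvals), abs=1e-12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pvals))
        assert bh_fdr(np.asarray(pvals)[perm]) == pytest.approx(ours[perm], abs=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15) and np.all(ours <= 1.0)


def _db(background, terms):
    return TermAnnotationDB(
        terms={tid: TermRecord(tid, tid, ns, frozenset(genes))
               for tid, ns, genes in terms},
        background=frozenset(background),
    )


class TestEnrichCluster:
    def test_constructed_counts(self):
        bg = [f"G{i}" for i in range(100)]
        term_genes = [f"G{i}" for i in range(10)]
        cluster = [f"G{i}" for i in range(8)] + ["G90", "G91"]
        db = _db(bg, [("T1", "biological_process", term_genes)])
        results = enrich_cluster(cluster, db)
        r = results[0]
        assert (r.k, r.n, r.K, r.N) == (8, 10, 10, 100)
        assert r.fold_enrichment == pytest.approx(8.0)
        assert r.p_value == pytest.approx(
            enumerate_fisher_two_tailed(8, 10, 10, 100), abs=1e-12
        )
        assert r.fdr == pytest.approx(r.p_value)  # single-term family

    def test_whole_background_term_never_primary(self):
        bg = [f"G{i}" for i in range(50)]
        db = _db(bg, [("ALL", "cellular_component", bg)])
        results = enrich_cluster(bg[:10], db)
        assert results[0].fold_enrichment == pytest.approx(1.0)
        assert results[0].report_tier != "primary"

    def test_no_significant_terms_gives_empty_report(self):
        bg = [f"G{i}" for i in range(40)]
        db = _db(bg, [("T1", "biological_process", bg[:20])])
        # overlap at exactly its expectation: FE = 1, p = 1, nothing to report
        cluster = bg[:5] + bg[20:25]
        results = enrich_cluster(cluster, db)
        assert select_report(results) == []

    def test_fallback_tier_when_significant_but_low_fe(self):
        # large overlap, FE barely above 1: significant yet below FE >= 1.5
        bg = [f"G{i}" for i in range(1000)]
        db = _db(bg, [("T1", "biological_process", bg[:600]),
                      ("T2", "molecular_function", bg[:5])])
        cluster = bg[:500]  # k=500 of K=600 -> FE = 500/(500*600/1000) = 1.67?
        results = enrich_cluster(cluster, db, EnrichmentOptions(fe_threshold=2.0))
        report = select_report(results, EnrichmentOptions(fe_threshold=2.0))
        assert report and all(r.report_tier == "fallback" for r in report)

    def test_empty_background_intersection_fatal(self):
        db = _db(["A", "B"], [("T1", "biological_process", ["A"])])
        with pytest.raises(ValueError, match="no overlap"):
            enrich_cluster(["ZZZ"], db)

    def test_one_bh_family_across_namespaces(self):
        bg = [f"G{i}" for i in range(60)]
        db = _db(bg, [("T1", "biological_process", bg[:10]),
                      ("T2", "cellular_component", bg[10:20]),
                      ("T3", "molecular_function", bg[20:30])])
        results = enrich_cluster(bg[:15], db)
        raw = {r.term_id: r.p_value for r in results}
        adj = {r.term_id: r.fdr for r in results}
        expect = stepup_bh([raw[t] for t in ("T1", "T2", "T3")])
        assert [adj[t] for t in ("T1", "T2", "T3")] == pytest.approx(expect, abs=1e-12)


class TestPhenotypeFE:
    def test_disjoint_cluster_filtered_out(self):
        bg = [f"G{i}" for i in range(100)]
        anns = [PhenotypeAnnotation("HP:1", "p", frozenset(bg[50:60]))]
        assert phenotype_fe(bg[:10], anns, frozenset(bg)) == []

    def test_identical_sets_fe_is_background_over_size(self):
        bg = [f"G{i}" for i in range(1000)]
        anns = [PhenotypeAnnotation("HP:1", "p", frozenset(bg[:10]))]
        out = phenotype_fe(bg[:10], anns, frozenset(bg))
        assert out[0].fold_enrichment == pytest.approx(100.0)

    def test_permutation_null_mean_fe_near_one(self):
        rng = np.random.default_rng(42)
        bg = [f"G{i}" for i in range(200)]
        anns = [PhenotypeAnnotation("HP:1", "p", frozenset(bg[:40]))]
        n, trials = 30, 1000
        fes = []
        for _ in range(trials):
            cluster = rng.choice(bg, size=n, replace=False)
            k = len(set(cluster) & anns[0].genes)
            fes.append(k / (n * 40 / 200))
        fes = np.asarray(fes)
        se = fes.std(ddof=1) / np.sqrt(trials)
        assert abs(fes.mean() - 1.0) < 3 * se


class TestSfariOverlap:
    def test_disjoint(self):
        assert sfari_overlap({"A"}, {"B"}) == (0, [])

    def test_subset(self):
        count, genes = sfari_overlap({"A", "B"}, {"A", "B", "C"})
        assert count == 2 and genes == ["A", "B"]

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(3)
        universe = [f"G{i}" for i in range(500)]
        a = set(rng.choice(universe, 80, replace=False))
        b = set(rng.choice(universe, 120, replace=False))
        count, genes = sfari_overlap(a, b)
        brute = sorted(x for x in a if x in b)  # independent scan
        assert genes == brute and count == len(brute)


class TestIO:
    def test_read_term_db_and_background_default(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text(
            "term_id\tnamespace\tname\tgene_symbol\n"
            "GO:1\tbiological_process\tfoo\tA\n"
            "GO:1\tbiological_process\tfoo\tB\n"
            "GO:2\tcellular_component\tbar\tB\n"
        )
        db = read_term_db(p)
        assert db.terms["GO:1"].genes == frozenset({"A", "B"})
        assert db.background == frozenset({"A", "B"})
        restricted = read_term_db(p, background=["A", "Z"])
        assert restricted.terms["GO:1"].genes == frozenset({"A"})

    def test_read_asd_list_plain_and_csv(self, tmp_path):
        plain = tmp_path / "genes.txt"
        plain.write_text("shank3\nCHD8\n")
        assert read_asd_gene_list(plain) == frozenset({"SHANK3", "CHD8"})
        sfari = tmp_path / "sfari.csv"
        sfari.write_text("status,gene-symbol,score\n1,SCN2A,1\n2,CHD8,1\n")
        assert read_asd_gene_list(sfari) == frozenset({"SCN2A", "CHD8"})
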