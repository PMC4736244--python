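import math
import random

import pytest

from phenoprior import (
    PhenotypeQuery,
    Session,
    SimulationConfig,
    VariantRecord,
    check_inheritance,
    gene_score_collapsed,
    gene_score_direct,
    qualify_diseases,
    query_term_weights,
    rank_variants,
    score_all_diseases,
    shared_phenotypes,
    simulate_case,
    suggest_phenotypes,
    transitive_gene_score,
)
from phenoprior.prioritize import HET, HOM, PrioritizeError

LN2 = math.log(2)


def mkvar(gene, zygosity=HET, pos=100, patho=None, maf=None, placeholder=False):
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="G", zygosity=zygosity,
        gene_symbol=gene, maf=maf, pathogenicity=patho, placeholder=placeholder,
    )


@pytest.fixture()
def t6_scored(t6, q_t3):
    dag, catalog = t6
    return score_all_diseases(q_t3, catalog, dag, "resnik")


class TestInheritance:
    """The stated genetic-model truth table."""

    @pytest.mark.parametrize(
        "variants,constraint,expected",
        [
            ([mkvar("G", HET)], "dominant", True),
            ([mkvar("G", HET)], "recessive", False),
            ([mkvar("G", HOM)], "dominant", True),
            ([mkvar("G", HOM)], "recessive", True),
            ([mkvar("G", HET, 100), mkvar("G", HET, 200)], "dominant", True),
            ([mkvar("G", HET, 100), mkvar("G", HET, 200)], "recessive", True),
        ],
    )
    def test_truth_table(self, t6_catalog, variants, constraint, expected):
        disease = t6_catalog.diseases["D1"]
        assert check_inheritance("G", variants, disease, constraint) is expected

    def test_no_constraint_always_passes(self, t6_catalog):
        assert check_inheritance("G", [], t6_catalog.diseases["D1"], "none")


class TestQualifyDiseases:
    def test_exome_link_filter(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, variants=[mkvar("GZ")], require_exome_link=True)
        kept = qualify_diseases(session, t6_scored, catalog, dag)
        assert [s.disease_id for s in kept] == ["D1", "D2"]
        assert [s.rank for s in kept] == [1, 2]

    def test_required_phenotype_uses_ancestral_match(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, required_terms={"T1"})
        kept = qualify_diseases(session, t6_scored, catalog, dag)
        assert {s.disease_id for s in kept} == {"D1", "D2", "D4"}

    def test_required_phenotype_exact_mode(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, required_terms={"T1"})
        kept = qualify_diseases(session, t6_scored, catalog, dag, exact_required_match=True)
        assert kept == []  # no disease annotates T1 itself

    def test_curation_exclusion(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, excluded_diseases={"D1"})
        kept = qualify_diseases(session, t6_scored, catalog, dag)
        assert "D1" not in {s.disease_id for s in kept}

    def test_gene_link_filter(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, require_gene_link=True)
        kept = qualify_diseases(session, t6_scored, catalog, dag)
        assert {s.disease_id for s in kept} == {"D1", "D2", "D4"}  # D3 has no gene

    def test_filters_preserve_relative_order(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, require_gene_link=True)
        kept = qualify_diseases(session, t6_scored, catalog, dag)
        scores = [s.score for s in kept]
        assert scores == sorted(scores, reverse=True)

    def test_recessive_constraint_filters_on_variant_content(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        # one het in GZ: no disease qualifies under recessive
        session = Session(query=q_t3, variants=[mkvar("GZ")], inheritance_constraint="recessive")
        assert qualify_diseases(session, t6_scored, catalog, dag) == []
        # hom in GZ: GZ-linked diseases survive
        session = Session(query=q_t3, variants=[mkvar("GZ", HOM)], inheritance_constraint="recessive")
        kept = qualify_diseases(session, t6_scored, catalog, dag)
        assert {s.disease_id for s in kept} == {"D1", "D2"}


class TestTransitiveGeneScore:
    @pytest.mark.parametrize(
        "agg,expected",
        [("max", LN2), ("mean", (LN2 + math.log(4 / 3)) / 2), ("sum", LN2 + math.log(4 / 3))],
    )
    def test_aggregations_on_fixture(self, t6, t6_scored, agg, expected):
        _, catalog = t6
        gs = transitive_gene_score("GZ", t6_scored, catalog, agg)
        assert gs.score == pytest.approx(expected, abs=1e-9)
        assert {d for d, _, _ in gs.supporting_diseases} == {"D1", "D2"}

    def test_curation_exclusion_propagates(self, t6, t6_scored, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, excluded_diseases={"D1"})
        qualified = qualify_diseases(session, t6_scored, catalog, dag)
        gs = transitive_gene_score("GZ", qualified, catalog, "max")
        assert gs.score == pytest.approx(math.log(4 / 3), abs=1e-9)  # falls to D2's score

    def test_unsupported_gene_is_unscored(self, t6, t6_scored):
        _, catalog = t6
        assert transitive_gene_score("NOGENE", t6_scored, catalog, "max") is None

    @pytest.mark.parametrize("seed", range(5))
    def test_per_gene_aggregation_inequalities(self, seed):
        # nonnegative supports: sum >= max >= mean, per gene
        case = simulate_case(SimulationConfig(seed=seed, n_decoy_genes=5))
        scored = score_all_diseases(case.query, case.catalog, case.dag, "resnik")
        for gene in sorted(case.catalog.gene_index):
            out = {
                agg: transitive_gene_score(gene, scored, case.catalog, agg).score
                for agg in ("max", "mean", "sum")
            }
            assert out["sum"] >= out["max"] - 1e-12
            assert out["max"] >= out["mean"] - 1e-12


class TestRankVariants:
    def test_fixture_gene_ordering(self, t6, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, variants=[mkvar("GZ", pos=10), mkvar("GX", pos=20)])
        ranked = rank_variants(session, catalog, dag)
        assert [(r.variant.gene_symbol, r.rank) for r in ranked] == [("GZ", 1), ("GX", 2)]
        assert ranked[0].gene_score.score == pytest.approx(LN2)
        assert ranked[1].gene_score.score == pytest.approx(0.5 * LN2 + 0.25 * LN2)

    def test_tied_genes_share_rank_competition_style(self, t6_dag, t6_catalog):
        # two genes supported by the same disease score tie at rank 1
        session = Session(
            query=PhenotypeQuery({"T3"}),
            variants=[mkvar("GZ"), mkvar("GW"), mkvar("GX")],
        )
        t6_catalog.gene_index.setdefault("GW", set()).add("D1")
        t6_catalog.diseases["D1"].gene_symbols.add("GW")
        try:
            ranked = rank_variants(session, t6_catalog, t6_dag)
            by_gene = {r.variant.gene_symbol: r.rank for r in ranked}
            assert by_gene["GW"] == by_gene["GZ"] == 1
            assert by_gene["GX"] == 3
        finally:  # session-scoped fixture: undo the mutation
            t6_catalog.gene_index.pop("GW")
            t6_catalog.diseases["D1"].gene_symbols.discard("GW")

    def test_variants_in_one_gene_share_score_and_order_by_pathogenicity(self, t6, q_t3):
        dag, catalog = t6
        session = Session(
            query=q_t3,
            variants=[mkvar("GZ", pos=10, patho=0.2), mkvar("GZ", pos=5, patho=0.9)],
        )
        ranked = rank_variants(session, catalog, dag)
        assert ranked[0].variant.pathogenicity == 0.9
        assert ranked[0].gene_score is ranked[1].gene_score

    def test_unscored_genes_trail_unranked(self, t6, q_t3):
        dag, catalog = t6
        session = Session(query=q_t3, variants=[mkvar("GZ"), mkvar("NOVELX")])
        ranked = rank_variants(session, catalog, dag)
        assert ranked[-1].variant.gene_symbol == "NOVELX"
        assert ranked[-1].rank is None and ranked[-1].gene_score is None

    def test_gene_list_refuses_inheritance_constraint(self, t6, q_t3):
        dag, catalog = t6
        session = Session(
            query=q_t3,
            variants=[mkvar("GZ", placeholder=True)],
            inheritance_constraint="recessive",
        )
        with pytest.raises(PrioritizeError, match="zygosity"):
            rank_variants(session, catalog, dag)

    def test_planted_causal_gene_recovered(self):
        case = simulate_case(SimulationConfig(seed=7, n_decoy_genes=20, n_diseases=60))
        session = Session(query=case.query, variants=case.variants)
        ranked = rank_variants(session, case.catalog, case.dag)
        assert ranked[0].variant.gene_symbol == case.truth["planted_gene"]
        assert ranked[0].rank == 1


class TestComparatorScores:
    def test_collapsed_union_on_fixture(self, t6, t6_ic, q_t3):
        dag, catalog = t6
        got = gene_score_collapsed("GZ", q_t3, catalog, dag, t6_ic)
        expected = 0.5 * LN2 + 0.5 * ((LN2 + math.log(4 / 3)) / 2)  # 0.59178
        assert got == pytest.approx(expected, abs=1e-9)

    def test_single_disease_gene_equals_disease_score(self, t6, t6_ic, q_t3, t6_scored):
        dag, catalog = t6
        d4_score = next(s.score for s in t6_scored if s.disease_id == "D4")
        assert gene_score_collapsed("GX", q_t3, catalog, dag, t6_ic) == pytest.approx(d4_score)

    def test_direct_table_scoring_and_absence(self, t6, t6_ic, q_t3):
        dag, catalog = t6
        table = {"GDIRECT": {"T3"}}
        assert gene_score_direct("GDIRECT", q_t3, table, dag, t6_ic) == pytest.approx(LN2)
        assert gene_score_direct("GMISSING", q_t3, table, dag, t6_ic) is None

    def test_direct_equals_collapsed_when_tables_match(self, t6, t6_ic, q_t3):
        dag, catalog = t6
        union_table = {"GZ": {"T3", "T4"}}
        assert gene_score_direct("GZ", q_t3, union_table, dag, t6_ic) == pytest.approx(
            gene_score_collapsed("GZ", q_t3, catalog, dag, t6_ic)
        )


class TestSuggestAndCuration:
    def test_suggestions_exclude_query_and_ancestry(self, t6, t6_ic, q_t3, t6_scored):
        dag, catalog = t6
        out = suggest_phenotypes(q_t3, t6_scored, catalog, dag, t6_ic, k=10, top_n=2)
        assert out == ["T5"]

    def test_suggestions_ordered_by_ic(self, t6, t6_ic, t6_scored):
        dag, catalog = t6
        q = PhenotypeQuery({"T5"})
        scored = score_all_diseases(q, catalog, dag, "resnik")
        out = suggest_phenotypes(q, scored, catalog, dag, t6_ic, k=1, top_n=4)
        assert out == ["T4"]  # ic(T4)=1.386 beats ic(T3)=0.693

    def test_no_candidates_gives_empty_list(self, t6, t6_ic, q_t3, t6_scored):
        dag, catalog = t6
        top_d1_only = [s for s in t6_scored if s.disease_id == "D1"]
        assert suggest_phenotypes(q_t3, top_d1_only, catalog, dag, t6_ic, k=5, top_n=1) == []

    @pytest.mark.parametrize(
        "disease,expected_shared,expected_only",
        [("D4", {"T3"}, {"T5"}), ("D3", set(), {"T5"})],
    )
    def test_shared_phenotypes_root_overlap_not_shared(self, t6, q_t3, disease, expected_shared, expected_only):
        dag, catalog = t6
        shared, only = shared_phenotypes(catalog.diseases[disease], q_t3, dag)
        assert (shared, only) == (expected_shared, expected_only)

    def test_own_terms_all_shared(self, t6):
        dag, catalog = t6
        d = catalog.diseases["D4"]
        shared, only = shared_phenotypes(d, PhenotypeQuery(set(d.phenotype_terms)), dag)
        assert shared == d.phenotype_terms and only == set()


class TestQueryTermWeights:
    def test_relative_weights(self, t6_ic):
        w = query_term_weights(PhenotypeQuery({"T3", "T4"}), t6_ic)
        assert w["T4"] == pytest.approx(1.0)
        assert w["T3"] == pytest.approx(0.5)

    def test_single_term_and_degenerate_guard(self, t6_ic):
        assert query_term_weights(PhenotypeQuery({"T5"}), t6_ic) == {"T5": 1.0}
        assert query_term_weights(PhenotypeQuery({"T0"}), t6_ic) == {"T0": 1.0}
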