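"""Transitive prioritization: from disease ranks to gene and variant ranks.

A gene G inherits its score from the diseases it is cataloged to cause:

    S_T(G, Q) = F( S(D_i, Q) for D_i in d{G} )

with aggregation F one of max (default), mean, or sum, applied to the
*qualified* disease list — the catalog ranking after the optional
restriction filters (gene-link, exome-link, inheritance model, required
phenotypes, curatorial exclusions).  Variants inherit the score of their
host gene, so curatorial exclusion of a disease propagates transitively
to genes and variants.

The recessive inheritance model qualifies a gene when it carries a
homozygous variant or when compound heterozygosity is *possible*: two or
more distinct variants in the gene (phase is unknown, so possibility
suffices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .catalog import DOMINANT, OTHER_UNKNOWN, RECESSIVE, CatalogIC, Disease, DiseaseCatalog
from .ontology import OntologyDAG
from .similarity import (
    PhenotypeQuery,
    ScoredDisease,
    rank_scores,
    resnik_similarity,
    score_all_diseases,
)

logger = logging.getLogger(__name__)

HET = "het"
HOM = "hom"

AGGREGATIONS = ("max", "mean", "sum")
CONSTRAINTS = ("none", DOMINANT, RECESSIVE)


class PrioritizeError(ValueError):
    pass


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str
    gene_symbol: str
    maf: Optional[float] = None
    pathogenicity: Optional[float] = None
    consequence: Optional[str] = None
    # True for records synthesized from a bare gene list (no zygosity info).
    placeholder: bool = False


@dataclass
class GeneScore:
    gene_symbol: str
    score: float
    supporting_diseases: list[tuple[str, float, int]]
    aggregation: str = "max"

    @property
    def top_supporting(self) -> tuple[str, float, int]:
        return max(self.supporting_diseases, key=lambda s: (s[1], s[0]))


@dataclass
class RankedVariant:
    variant: VariantRecord
    gene_score: Optional[GeneScore]
    rank: Optional[int]


@dataclass
class Session:
    """Complete, persistable analysis state."""

    query: PhenotypeQuery = field(default_factory=lambda: PhenotypeQuery(set()))
    variants: list[VariantRecord] = field(default_factory=list)
    excluded_diseases: set[str] = field(default_factory=set)
    required_terms: set[str] = field(default_factory=set)
    inheritance_constraint: str = "none"
    method: str = "resnik"
    aggregation: str = "max"
    m_neighbors: int = 5
    top_n: int = 50
    require_gene_link: bool = False
    require_exome_link: bool = False
    free_text: str = ""
    viz_settings: dict = field(default_factory=dict)
    discovery_settings: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def variant_genes(self) -> set[str]:
        return {v.gene_symbol for v in self.variants if v.gene_symbol}

    def variants_in(self, gene: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.gene_symbol == gene]


def check_inheritance(
    gene: str,
    variants: list[VariantRecord],
    disease: Disease,
    constraint: str,
) -> bool:
    """Does the gene's variant content satisfy the inheritance model?

    ``none`` is always satisfied.  ``dominant`` needs one variant.
    ``recessive`` needs a homozygous variant or >= 2 distinct variants
    (compound heterozygosity possible).
    """
    if constraint == "none":
        return True
    if constraint == DOMINANT:
        return len(variants) >= 1
    if constraint == RECESSIVE:
        return any(v.zygosity == HOM for v in variants) or len(variants) >= 2
    raise PrioritizeError(f"unknown inheritance constraint {constraint!r}")


def _disease_mode_compatible(disease: Disease, constraint: str) -> bool:
    # Diseases with no declared mode are unaffected by model filters.
    modes = disease.inheritance_modes - {OTHER_UNKNOWN}
    return not modes or constraint in modes


def qualify_diseases(
    session: Session,
    scored: list[ScoredDisease],
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    exact_required_match: bool = False,
) -> list[ScoredDisease]:
    """Apply the optional restriction filters, in order, and re-rank.

    1. gene-link filter (disease has cataloged genes), if requested;
    2. exome-link filter (a cataloged gene carries a patient variant);
    3. inheritance-model filter (declared disease mode compatible, and
       some exome-linked gene passes :func:`check_inheritance`);
    4. required-phenotype filter: every required term must appear in the
       disease's ancestral closure (approximate match; exact matching on
       the annotated set via ``exact_required_match``);
    5. curation filter: explicitly excluded diseases are removed.

    Every filter is a subset operation, so surviving diseases keep their
    relative score order; ranks are recomputed at the end.
    """
    required = {dag.resolve(t) for t in session.required_terms}
    variant_genes = session.variant_genes()
    kept: list[ScoredDisease] = []
    for sd in scored:
        disease = catalog.diseases[sd.disease_id]
        if session.require_gene_link and not disease.gene_symbols:
            continue
        if session.require_exome_link and not (disease.gene_symbols & variant_genes):
            continue
        if session.inheritance_constraint != "none":
            if not _disease_mode_compatible(disease, session.inheritance_constraint):
                continue
            linked = disease.gene_symbols & variant_genes
            if not any(
                check_inheritance(g, session.variants_in(g), disease, session.inheritance_constraint)
                for g in linked
            ):
                continue
        if required:
            hay = disease.phenotype_terms if exact_required_match else dag.ancestral_closure(disease.phenotype_terms)
            if not required <= hay:
                continue
        if sd.disease_id in session.excluded_diseases:
            continue
        kept.append(sd)
    return rank_scores({sd.disease_id: sd.score for sd in kept})


def transitive_gene_score(
    gene: str,
    qualified: list[ScoredDisease],
    catalog: DiseaseCatalog,
    aggregation: str = "max",
) -> Optional[GeneScore]:
    """Aggregate the gene's qualified supporting-disease scores into S_T.

    Returns None (unscored) when no qualified disease is cataloged to the
    gene.
    """
    if aggregation not in AGGREGATIONS:
        raise PrioritizeError(f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}")
    linked = catalog.gene_index.get(gene, set())
    support = [(sd.disease_id, sd.score, sd.rank) for sd in qualified if sd.disease_id in linked]
    if not support:
        return None
    values = [s[1] for s in support]
    if aggregation == "max":
        score = max(values)
    elif aggregation == "mean":
        score = sum(values) / len(values)
    else:
        score = sum(values)
    return GeneScore(gene_symbol=gene, score=score, supporting_diseases=support, aggregation=aggregation)


def _variant_sort_key(v: VariantRecord):
    # Within a gene: pathogenicity desc, then MAF asc (missing = rarest), then position.
    patho = v.pathogenicity if v.pathogenicity is not None else -1.0
    maf = v.maf if v.maf is not None else 0.0
    return (-patho, maf, v.chrom, v.pos)


def rank_variants(
    session: Session,
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    scored: Optional[list[ScoredDisease]] = None,
) -> list[RankedVariant]:
    """Full transitive pipeline: disease scores -> gene scores -> variants.

    Genes are ranked by descending S_T with competition ranking; each
    variant inherits its gene's score and rank.  Variants in genes with
    no qualified supporting disease are appended unranked.
    """
    if not session.variants:
        raise PrioritizeError("session has no variants to rank")
    if session.inheritance_constraint != "none" and any(v.placeholder for v in session.variants):
        raise PrioritizeError(
            "inheritance constraints require zygosity, which a bare gene "
            "list does not provide; supply a VCF or use --model none"
        )
    if scored is None:
        scored = score_all_diseases(session.query, catalog, dag, method=session.method)
    qualified = qualify_diseases(session, scored, catalog, dag)
    genes = sorted(session.variant_genes())
    scored_genes: list[GeneScore] = []
    unscored_genes: list[str] = []
    for gene in genes:
        gs = transitive_gene_score(gene, qualified, catalog, session.aggregation)
        if gs is None:
            unscored_genes.append(gene)
        else:
            scored_genes.append(gs)
    if not scored_genes:
        logger.warning("no variant gene maps to any qualified catalog disease")
    scored_genes.sort(key=lambda g: (-g.score, g.gene_symbol))
    ranks: dict[str, int] = {}
    for i, gs in enumerate(scored_genes):
        if i > 0 and gs.score == scored_genes[i - 1].score:
            ranks[gs.gene_symbol] = ranks[scored_genes[i - 1].gene_symbol]
        else:
            ranks[gs.gene_symbol] = i + 1
    out: list[RankedVariant] = []
    for gs in scored_genes:
        for v in sorted(session.variants_in(gs.gene_symbol), key=_variant_sort_key):
            out.append(RankedVariant(variant=v, gene_score=gs, rank=ranks[gs.gene_symbol]))
    for gene in unscored_genes:
        for v in sorted(session.variants_in(gene), key=_variant_sort_key):
            out.append(RankedVariant(variant=v, gene_score=None, rank=None))
    return out


def gene_score_collapsed(
    gene: str,
    q: PhenotypeQuery,
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    ic: CatalogIC,
) -> Optional[float]:
    """Comparator: Resnik score of Q against the union of the gene's
    disease phenotype sets, treated as one pseudo-disease."""
    union: set[str] = set()
    for did in catalog.gene_index.get(gene, set()):
        union |= catalog.diseases[did].phenotype_terms
    if not union:
        return None
    return resnik_similarity(q, union, ic, dag)


def gene_score_direct(
    gene: str,
    q: PhenotypeQuery,
    gene_term_map: dict[str, set[str]],
    dag: OntologyDAG,
    ic: CatalogIC,
) -> Optional[float]:
    """Comparator: Resnik score of Q against a direct term-to-gene
    annotation set; None when the gene is absent from the table."""
    terms = gene_term_map.get(gene)
    if not terms:
        return None
    return resnik_similarity(q, terms, ic, dag)


def suggest_phenotypes(
    q: PhenotypeQuery,
    scored: list[ScoredDisease],
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    ic: CatalogIC,
    k: int = 10,
    top_n: int = 10,
) -> list[str]:
    """Rarest non-query phenotypes of the diseases most similar to Q.

    Terms annotated to the ``top_n`` best-scoring diseases, minus the
    query terms and their ancestors, ordered by descending information
    content (ties by term id); at most ``k`` returned.
    """
    if not scored:
        raise PrioritizeError("no scored diseases to suggest from")
    q = q.resolved(dag)
    exclude = dag.ancestral_closure(q.terms)
    candidates: set[str] = set()
    for sd in scored[:top_n]:
        candidates |= catalog.diseases[sd.disease_id].phenotype_terms
    candidates -= exclude
    candidates &= ic.annotated_terms
    ordered = sorted(candidates, key=lambda t: (-ic.ic[t], t))
    return ordered[:k]


def shared_phenotypes(
    disease: Disease,
    q: PhenotypeQuery,
    dag: OntologyDAG,
) -> tuple[set[str], set[str]]:
    """Split a disease's terms into query-shared and disease-only.

    A disease term is shared when its ancestral closure meets the query's
    closure somewhere below the root (a root-only overlap is vacuous and
    does not count).  The disease-only remainder surfaces the hallmark
    features a curator checks against the patient.
    """
    q_closure = dag.ancestral_closure(q.resolved(dag).terms) - {dag.root_id}
    shared, only = set(), set()
    for t in disease.phenotype_terms:
        if dag.ancestors(t) & q_closure:
            shared.add(t)
        else:
            only.add(t)
    return shared, only


def query_term_weights(q: PhenotypeQuery, ic: CatalogIC) -> dict[str, float]:
    """Relative information content of each query term, in (0, 1].

    Weight(t) = ic(t) / max ic over the query (wordcloud sizing).  If no
    query term carries positive ic, all weights degenerate to 1.
    """
    raw = {t: ic.ic.get(t, 0.0) for t in q.terms}
    top = max(raw.values(), default=0.0)
    if top <= 0.0:
        return {t: 1.0 for t in q.terms}
    return {t: v / top for t, v in raw.items()}
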