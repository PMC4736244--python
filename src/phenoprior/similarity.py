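"""Semantic similarity between phenotype term sets and diseases.

Four metrics are provided:

``resnik``
    Symmetrized best-match-average Resnik score.  For each term in one
    set, find the most informative common ancestor (MICA) it shares with
    any term of the other set; average these best matches over the set;
    the final score is the mean of the two directional averages.

``ato``
    Ancestral term overlap: the number of ontology nodes shared between
    the two sets' ancestral closures.  Every shared node counts exactly
    once, however many input terms recruit it.

``ato_ic`` / ``ato_tic``
    The same shared-node set, weighted by annotation-based information
    content (catalog rareness) or by topological information content
    (reachability), summed instead of counted.

Catalog-weighted metrics (``resnik``, ``ato_ic``) are undefined on terms
with no catalog annotation at or below them; such query terms are
dropped with a log entry.

``class_signal_to_noise`` quantifies whether a pre-defined grouping of
diseases is visible to a metric: the ratio of mean within-class pairwise
similarity to mean member-vs-non-member similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .catalog import CatalogIC, Disease, DiseaseCatalog
from .ontology import OntologyDAG, TopologicalWeights

logger = logging.getLogger(__name__)

METHODS = ("resnik", "ato", "ato_ic", "ato_tic")


class SimilarityError(ValueError):
    pass


@dataclass
class PhenotypeQuery:
    terms: set[str]
    source: str = ""

    def resolved(self, dag: OntologyDAG) -> "PhenotypeQuery":
        """Remap alt_ids; raise on unresolvable or empty input."""
        if not self.terms:
            raise SimilarityError("phenotype query is empty")
        return PhenotypeQuery({dag.resolve(t) for t in self.terms}, self.source)


@dataclass
class ScoredDisease:
    disease_id: str
    score: float
    rank: int = 0


@dataclass
class ClassSNR:
    class_id: str
    within_mean: float
    between_mean: float
    snr: float


def _mica_ic(t1: str, t2: str, ic: dict[str, float], dag: OntologyDAG) -> float:
    """IC of the most informative common ancestor of t1 and t2.

    Common ancestors with no defined ic contribute nothing; two terms
    whose only shared ancestry is unannotated score 0.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    return max((ic.get(a, 0.0) for a in common), default=0.0)


def _annotated_subset(terms, ic: CatalogIC, what: str) -> list[str]:
    kept = [t for t in terms if t in ic.annotated_terms]
    dropped = set(terms) - set(kept)
    if dropped:
        logger.info("dropped %d unannotated %s term(s): %s", len(dropped), what, sorted(dropped))
    return kept


def resnik_similarity(
    q: PhenotypeQuery | set[str],
    d: Disease | set[str],
    ic: CatalogIC,
    dag: OntologyDAG,
) -> float:
    """Symmetrized best-match-average Resnik score (nats)."""
    q_terms = _annotated_subset(_term_set(q), ic, "query")
    d_terms = _annotated_subset(_term_set(d), ic, "disease")
    if not q_terms:
        raise SimilarityError(
            "no query term has catalog annotations; use an annotation-free "
            "metric (ato / ato_tic) or revise the query"
        )
    if not d_terms:
        return 0.0
    half_d = sum(
        max(_mica_ic(t1, t2, ic.ic, dag) for t2 in q_terms) for t1 in d_terms
    ) / len(d_terms)
    half_q = sum(
        max(_mica_ic(t1, t2, ic.ic, dag) for t2 in d_terms) for t1 in q_terms
    ) / len(q_terms)
    return 0.5 * half_d + 0.5 * half_q


def ato_similarity(q, d, dag: OntologyDAG) -> int:
    """Ancestral term overlap: ||A{D} ∩ A{Q}|| as an integer count."""
    return len(dag.ancestral_closure(_term_set(q)) & dag.ancestral_closure(_term_set(d)))


def weighted_ato_similarity(q, d, dag: OntologyDAG, weights: CatalogIC | TopologicalWeights | dict) -> float:
    """Sum of per-term weights over the shared ancestral closure.

    With :class:`CatalogIC` weights, unannotated shared nodes are
    excluded (they have no defined weight); with topological weights
    every node is covered.
    """
    shared = dag.ancestral_closure(_term_set(q)) & dag.ancestral_closure(_term_set(d))
    table = _weight_table(weights)
    return float(sum(table[t] for t in shared if t in table))


def _term_set(obj) -> set[str]:
    if isinstance(obj, PhenotypeQuery):
        return set(obj.terms)
    if isinstance(obj, Disease):
        return set(obj.phenotype_terms)
    return set(obj)


def _weight_table(weights) -> dict[str, float]:
    if isinstance(weights, CatalogIC):
        return weights.ic
    if isinstance(weights, TopologicalWeights):
        return weights.tic
    return weights


def similarity(
    q,
    d,
    method: str,
    dag: OntologyDAG,
    ic: CatalogIC | None = None,
    tw: TopologicalWeights | None = None,
) -> float:
    """Dispatch to one of the four metrics by name."""
    if method == "resnik":
        assert ic is not None
        return resnik_similarity(q, d, ic, dag)
    if method == "ato":
        return float(ato_similarity(q, d, dag))
    if method == "ato_ic":
        assert ic is not None
        return weighted_ato_similarity(q, d, dag, ic)
    if method == "ato_tic":
        assert tw is not None
        return weighted_ato_similarity(q, d, dag, tw)
    raise SimilarityError(f"unknown similarity method {method!r}; choose from {METHODS}")


def rank_scores(scores: dict[str, float]) -> list[ScoredDisease]:
    """Sort descending by score (ties: ascending id) with competition ranks."""
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[ScoredDisease] = []
    for i, (disease_id, score) in enumerate(ordered):
        if i > 0 and score == ordered[i - 1][1]:
            rank = out[-1].rank
        else:
            rank = i + 1
        out.append(ScoredDisease(disease_id=disease_id, score=score, rank=rank))
    return out


def score_all_diseases(
    q: PhenotypeQuery,
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    method: str = "resnik",
    ic: CatalogIC | None = None,
    tw: TopologicalWeights | None = None,
) -> list[ScoredDisease]:
    """Score the query against every annotated disease, ranked descending.

    ``ic`` / ``tw`` are computed on demand when the method needs them and
    none is supplied.
    """
    if catalog.N == 0:
        raise SimilarityError("catalog has no annotated diseases")
    q = q.resolved(dag)
    ic, tw = _ensure_weights(method, catalog, dag, ic, tw)
    scores = {
        did: similarity(q, catalog.diseases[did], method, dag, ic=ic, tw=tw)
        for did in catalog.annotated_ids()
    }
    return rank_scores(scores)


def _ensure_weights(method, catalog, dag, ic, tw):
    from .catalog import catalog_information_content
    from .ontology import topological_weights

    if method in ("resnik", "ato_ic") and ic is None:
        ic = catalog_information_content(catalog, dag)
    if method == "ato_tic" and tw is None:
        tw = topological_weights(dag)
    return ic, tw


def self_similarity(q: PhenotypeQuery, method: str, dag, ic=None, tw=None) -> float:
    """S(Q,Q) under the chosen metric (radar-plot normalizer)."""
    return similarity(q, q, method, dag, ic=ic, tw=tw)


def class_signal_to_noise(
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    classes: dict[str, set[str]],
    method: str = "resnik",
    min_class_size: int | None = None,
    ic: CatalogIC | None = None,
    tw: TopologicalWeights | None = None,
) -> list[ClassSNR]:
    """Within- vs between-class similarity ratio for each disease class.

    ``within_mean`` averages over unordered member pairs (each pair once,
    self-pairs excluded); ``between_mean`` over all (member, non-member)
    pairs.  Classes with fewer than 2 resolvable members (or below
    ``min_class_size`` when given) are skipped with a warning; a class
    whose between-class mean is 0 raises (its SNR is undefined).
    """
    ic, tw = _ensure_weights(method, catalog, dag, ic, tw)
    annotated = set(catalog.annotated_ids())
    sim_cache: dict[tuple[str, str], float] = {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in sim_cache:
            sim_cache[key] = similarity(
                catalog.diseases[key[0]].phenotype_terms,
                catalog.diseases[key[1]].phenotype_terms,
                method, dag, ic=ic, tw=tw,
            )
        return sim_cache[key]

    out: list[ClassSNR] = []
    for class_id in sorted(classes):
        members = sorted(classes[class_id] & annotated)
        if len(members) < 2 or (min_class_size and len(members) < min_class_size):
            logger.warning("class %s skipped (%d resolvable members)", class_id, len(members))
            continue
        others = sorted(annotated - set(members))
        within = [sim(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
        between = [sim(a, b) for a in members for b in others]
        within_mean = sum(within) / len(within)
        if not between:
            logger.warning("class %s skipped (no non-members)", class_id)
            continue
        between_mean = sum(between) / len(between)
        if between_mean == 0:
            raise SimilarityError(f"class {class_id}: between-class mean is 0, SNR undefined")
        out.append(ClassSNR(class_id, within_mean, between_mean, within_mean / between_mean))
    return out
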