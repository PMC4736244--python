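"""Phenotype ontology as a rooted DAG.

Terms are linked by ``is_a`` edges (child -> parent).  The two closure
operations defined here are the primitives every similarity metric builds
on: ``ancestors(t)`` is the reflexive-transitive ancestor set A{t} and
``descendants(t)`` the reflexive-transitive descendant set C{t}.

Topological weights implement a reachability-based information measure
that needs no annotation catalog: the root has topological position
characteristic (TPC) 1, and each term inherits the product over its
parents of ``tpc(parent) / n_children(parent)``.  The topological
information content is TIC = -log(TPC); terms whose TPC underflows to
zero are clamped to a tiny positive TIC so downstream weighting stays
finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: TIC assigned to terms whose topological position characteristic
#: underflows to exactly 0 (the double-precision minimum normal).
TIC_CLAMP = 2.225074e-308

SYNTHETIC_ROOT_ID = "SYNTHETIC:ROOT"


class OntologyError(ValueError):
    """Raised for structural problems in the ontology input."""


class UnknownTermError(KeyError):
    """Raised when a term id cannot be resolved in the DAG."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep a sentence
        return f"unknown ontology term id: {self.term_id!r}"


@dataclass
class Term:
    id: str
    name: str = ""
    parent_ids: set[str] = field(default_factory=set)
    is_obsolete: bool = False
    alt_ids: set[str] = field(default_factory=set)


class OntologyDAG:
    """Rooted DAG of phenotype terms with closure operations.

    Parameters
    ----------
    terms:
        Mapping id -> :class:`Term` for every non-obsolete term.
        ``parent_ids`` define the child -> parent ``is_a`` edges.
    allow_synthetic_root:
        If the term set has more than one parentless term, insert a
        synthetic super-root above all of them instead of refusing.
    """

    def __init__(self, terms: dict[str, Term], *, allow_synthetic_root: bool = False):
        self.terms: dict[str, Term] = dict(terms)
        self._validate_parents()
        self._check_acyclic()
        self.root_id = self._resolve_root(allow_synthetic_root)
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for t in self.terms.values():
            for p in t.parent_ids:
                self._children[p].add(t.id)
        self._alt_index: dict[str, str] = {}
        for t in self.terms.values():
            for alt in t.alt_ids:
                if alt in self._alt_index and self._alt_index[alt] != t.id:
                    raise OntologyError(
                        f"alt_id {alt!r} maps to both {self._alt_index[alt]!r} and {t.id!r}"
                    )
                self._alt_index[alt] = t.id
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _validate_parents(self) -> None:
        for t in self.terms.values():
            for p in t.parent_ids:
                if p == t.id:
                    raise OntologyError(f"self-loop on term {t.id!r}")
                if p not in self.terms:
                    raise OntologyError(f"term {t.id!r} has unknown parent {p!r}")

    def _resolve_root(self, allow_synthetic_root: bool) -> str:
        roots = sorted(t.id for t in self.terms.values() if not t.parent_ids)
        if not roots:
            raise OntologyError("no root term (every term has a parent: cyclic input?)")
        if len(roots) == 1:
            return roots[0]
        if not allow_synthetic_root:
            raise OntologyError(
                f"multiple parentless terms {roots}; pass allow_synthetic_root=True "
                "to insert a synthetic super-root"
            )
        self.terms[SYNTHETIC_ROOT_ID] = Term(id=SYNTHETIC_ROOT_ID, name="synthetic root")
        for r in roots:
            self.terms[r].parent_ids.add(SYNTHETIC_ROOT_ID)
        logger.info("inserted synthetic super-root above %d parentless terms", len(roots))
        return SYNTHETIC_ROOT_ID

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (t.id, p) for t in self.terms.values() for p in t.parent_ids
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        child, parent = cycle[0][0], cycle[0][1]
        raise OntologyError(f"ontology contains a cycle through edge {child!r} is_a {parent!r}")

    # -- queries ---------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Resolve ``term_id`` to a primary id, remapping alt_ids.

        Raises :class:`UnknownTermError` if the id is neither primary nor
        an alt_id of a primary term.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self._alt_index:
            primary = self._alt_index[term_id]
            logger.debug("remapped alt_id %s -> %s", term_id, primary)
            return primary
        raise UnknownTermError(term_id)

    def children(self, term_id: str) -> set[str]:
        """Direct children of ``term_id``."""
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return set(self._children[term_id])

    def ancestors(self, term_id: str) -> set[str]:
        """A{t}: ``term_id`` plus every term reachable via parent edges."""
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            out = {term_id}
            stack = list(self.terms[term_id].parent_ids)
            while stack:
                p = stack.pop()
                if p not in out:
                    out.add(p)
                    stack.extend(self.terms[p].parent_ids)
            cached = frozenset(out)
            self._ancestor_cache[term_id] = cached
        return set(cached)

    def descendants(self, term_id: str) -> set[str]:
        """C{t}: ``term_id`` plus every term from which it is reachable."""
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        cached = self._descendant_cache.get(term_id)
        if cached is None:
            out = {term_id}
            stack = list(self._children[term_id])
            while stack:
                c = stack.pop()
                if c not in out:
                    out.add(c)
                    stack.extend(self._children[c])
            cached = frozenset(out)
            self._descendant_cache[term_id] = cached
        return set(cached)

    def ancestral_closure(self, term_ids) -> set[str]:
        """Union of ``ancestors(t)`` over ``term_ids``; empty for empty input."""
        out: set[str] = set()
        for t in term_ids:
            out |= self.ancestors(t)
        return out

    def topological_order(self) -> list[str]:
        """Term ids ordered so every parent precedes its children."""
        ts = TopologicalSorter(
            {t.id: set(t.parent_ids) for t in self.terms.values()}
        )
        return list(ts.static_order())


@dataclass
class TopologicalWeights:
    """Reachability-based term weights (no annotation catalog needed)."""

    tpc: dict[str, float]
    tic: dict[str, float]


def topological_weights(dag: OntologyDAG) -> TopologicalWeights:
    """Compute TPC/TIC for every term.

    ``tpc(root) = 1``; for a non-root term t,
    ``tpc(t) = prod over parents p of tpc(p) / |children(p)|``,
    evaluated in topological order.  ``tic = -log(tpc)``, with terms whose
    TPC underflows to exactly 0 clamped to :data:`TIC_CLAMP`.
    """
    import math

    tpc: dict[str, float] = {}
    for term_id in dag.topological_order():
        if term_id == dag.root_id:
            tpc[term_id] = 1.0
            continue
        val = 1.0
        for p in dag.terms[term_id].parent_ids:
            val *= tpc[p] / len(dag._children[p])
        tpc[term_id] = val
    tic = {
        t: (TIC_CLAMP if v == 0.0 else -math.log(v))
        for t, v in tpc.items()
    }
    return TopologicalWeights(tpc=tpc, tic=tic)


def load_ontology(path, *, allow_synthetic_root: bool = False) -> OntologyDAG:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only ``is_a`` edges are used.  Obsolete terms are excluded from the
    graph (their ids are unusable; ids listed as ``alt_id`` on live terms
    are remapped).  Exactly one root is required unless
    ``allow_synthetic_root`` is set.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    # Parents referenced by is_a but never declared in a [Term] stanza show
    # up as attribute-less nodes; treat them as hard errors.
    phantom = sorted(n for n, d in graph.nodes(data=True) if not d)
    if phantom:
        raise OntologyError(f"is_a references undeclared term(s): {phantom}")
    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        parents = set()
        for _, parent, key in graph.out_edges(node, keys=True):
            if key == "is_a":
                parents.add(parent)
        terms[node] = Term(
            id=node,
            name=data.get("name", ""),
            parent_ids=parents,
            alt_ids=set(data.get("alt_id", [])),
        )
    if not terms:
        raise OntologyError(f"no [Term] stanzas found in {path}")
    return OntologyDAG(terms, allow_synthetic_root=allow_synthetic_root)
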