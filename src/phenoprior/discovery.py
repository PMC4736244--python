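"""PPI-network-driven disease gene discovery.

When no variant gene matches the catalog, a phenotype query can still
implicate genes through prior knowledge: the diseases most similar to
the query define a *training* gene set, and patient variant genes that
are highly connected to training genes in a protein-protein interaction
network become discovery candidates.  Two candidate scores are kept:
the count of training-gene neighbors, and the fraction of a candidate's
interactions that are training genes (the default ordering).

``neighbor_distance_validation`` checks the premise: genes of
semantically nearest-neighbor diseases should sit closer in PPI space
than genes of randomly paired diseases (two-sample KS statistic on the
shortest-path distance distributions).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import ks_2samp

from .catalog import DiseaseCatalog
from .ontology import OntologyDAG
from .similarity import ScoredDisease, similarity, _ensure_weights

logger = logging.getLogger(__name__)


class DiscoveryError(ValueError):
    pass


@dataclass
class PPINetwork:
    """Undirected PPI graph over gene symbols (no self-edges)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges, alias_table: dict[str, str] | None = None) -> "PPINetwork":
        alias_table = alias_table or {}
        g = nx.Graph()
        for a, b in edges:
            a, b = alias_table.get(a, a), alias_table.get(b, b)
            if a and b and a != b:
                g.add_edge(a, b)
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))


def _strip_db_prefix(token: str) -> str:
    return token.split(":", 1)[1] if ":" in token else token


def load_ppi(path, alias_table: dict[str, str] | None = None) -> PPINetwork:
    """Read a PPI edge list: two-column TSV, or PSI-MITAB (>= 11 columns,
    interactor ids taken from columns 1-2 with their ``db:`` prefix
    stripped).  Symbols are remapped via the alias table before the graph
    is built; self-edges are dropped."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 11:  # PSI-MITAB row
                edges.append((_strip_db_prefix(parts[0]), _strip_db_prefix(parts[1])))
            elif len(parts) >= 2:
                edges.append((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise DiscoveryError(f"no PPI edges parsed from {path}")
    return PPINetwork.from_edges(edges, alias_table)


@dataclass
class DiscoveryCandidate:
    gene_symbol: str
    n_training_links: int
    degree: int
    fraction_training: float
    training_neighbors: list[str]


def training_genes(
    scored: list[ScoredDisease],
    catalog: DiseaseCatalog,
    top_m: int = 10,
) -> set[str]:
    """Genes of the top_m gene-linked diseases most similar to the query.

    Diseases without gene links are passed over without consuming one of
    the top_m slots.
    """
    if top_m < 1:
        raise DiscoveryError("top_m must be >= 1")
    out: set[str] = set()
    taken = 0
    for sd in scored:
        genes = catalog.diseases[sd.disease_id].gene_symbols
        if not genes:
            continue
        out |= genes
        taken += 1
        if taken >= top_m:
            break
    if not out:
        raise DiscoveryError("no gene-linked disease among the scored list")
    return out


def discover_candidates(
    variant_genes: set[str],
    training: set[str],
    ppi: PPINetwork,
    min_links: int = 1,
) -> list[DiscoveryCandidate]:
    """Rank patient variant genes by connectivity to the training set.

    Training genes themselves are not candidates (they are prioritization
    hits, not discoveries).  Candidates keep ``n_training_links >=
    min_links`` and are ordered by fraction_training desc, then count
    desc, then symbol.
    """
    if not training:
        raise DiscoveryError("training gene set is empty")
    if min_links < 1:
        raise DiscoveryError("min_links must be >= 1")
    absent = sorted(g for g in variant_genes if g not in ppi.nodes)
    if absent:
        logger.info("%d variant gene(s) absent from the PPI network: %s", len(absent), absent)
    out: list[DiscoveryCandidate] = []
    for gene in sorted(variant_genes):
        if gene in training or gene not in ppi.nodes:
            continue
        nbrs = ppi.neighbors(gene)
        train_nbrs = sorted(nbrs & training)
        if len(train_nbrs) < min_links:
            continue
        degree = len(nbrs)
        out.append(
            DiscoveryCandidate(
                gene_symbol=gene,
                n_training_links=len(train_nbrs),
                degree=degree,
                fraction_training=len(train_nbrs) / degree,
                training_neighbors=train_nbrs,
            )
        )
    out.sort(key=lambda c: (-c.fraction_training, -c.n_training_links, c.gene_symbol))
    return out


def _component_diameter(graph: nx.Graph) -> int:
    return max(
        (nx.diameter(graph.subgraph(c)) for c in nx.connected_components(graph)),
        default=0,
    )


def neighbor_distance_validation(
    catalog: DiseaseCatalog,
    dag: OntologyDAG,
    ppi: PPINetwork,
    method: str = "resnik",
    n_background_pairs: int = 200,
    rng_seed: int = 0,
) -> tuple[float, list[int], list[int]]:
    """KS comparison of PPI distances: semantic neighbors vs random pairs.

    For every gene-linked disease, its nearest semantic neighbor disease
    (best-scoring other linked disease) contributes the shortest-path
    distances between the two diseases' gene sets; the background sample
    draws the same distances for seeded random disease pairs.  Gene pairs
    in different PPI components get distance diameter+1.  Returns the
    two-sample KS statistic and both samples.
    """
    linked = sorted(
        d.disease_id
        for d in catalog.diseases.values()
        if d.phenotype_terms and (d.gene_symbols & ppi.nodes)
    )
    if len(linked) < 2:
        raise DiscoveryError("need at least 2 gene-linked diseases in the PPI network")
    ic, tw = _ensure_weights(method, catalog, dag, None, None)
    unreachable = _component_diameter(ppi.graph) + 1

    def gene_distances(a: str, b: str) -> list[int]:
        ga = sorted(catalog.diseases[a].gene_symbols & ppi.nodes)
        gb = sorted(catalog.diseases[b].gene_symbols & ppi.nodes)
        dists = []
        for x in ga:
            lengths = nx.single_source_shortest_path_length(ppi.graph, x)
            for y in gb:
                dists.append(lengths.get(y, unreachable))
        return dists

    neighbor_sample: list[int] = []
    for did in linked:
        best, best_score = None, None
        for other in linked:
            if other == did:
                continue
            s = similarity(
                catalog.diseases[did].phenotype_terms,
                catalog.diseases[other].phenotype_terms,
                method, dag, ic=ic, tw=tw,
            )
            if best_score is None or s > best_score or (s == best_score and other < best):
                best, best_score = other, s
        neighbor_sample.extend(gene_distances(did, best))

    rng = random.Random(rng_seed)
    background_sample: list[int] = []
    while len(background_sample) < n_background_pairs:
        a, b = rng.sample(linked, 2)
        background_sample.extend(gene_distances(a, b))
    if neighbor_sample == background_sample:
        return 0.0, neighbor_sample, background_sample
    stat = float(ks_2samp(neighbor_sample, background_sample).statistic)
    return stat, neighbor_sample, background_sample
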