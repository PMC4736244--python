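"""Disease catalog: phenotype annotations, gene links, information content.

The catalog mirrors how Mendelian disease compendia are distributed:
one tab-separated annotation file linking disease ids to ontology terms
(one term per row), and one gene-map file linking disease ids to the
genes in which causal variants are reported, optionally with an
inheritance mode.

The annotation-based information content of a term t is

    ic(t) = -log( ||d{C{t}}|| / N )

where d{C{t}} is the set of diseases annotated at or below t (i.e. with
at least one term in the descendant closure of t) and N the number of
annotated diseases.  Rarer terms carry more information; the root, which
every annotated disease sits below, has ic 0.  Terms with no annotation
at or below them have no defined ic and are excluded from
catalog-weighted similarity.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .ontology import OntologyDAG, UnknownTermError

logger = logging.getLogger(__name__)

DOMINANT = "dominant"
RECESSIVE = "recessive"
OTHER_UNKNOWN = "other/unknown"

_INHERITANCE_ALIASES = {
    "ad": DOMINANT,
    "autosomal dominant": DOMINANT,
    "dominant": DOMINANT,
    "ar": RECESSIVE,
    "autosomal recessive": RECESSIVE,
    "recessive": RECESSIVE,
}


class CatalogError(ValueError):
    """Raised for unusable catalog input."""


@dataclass
class Disease:
    disease_id: str
    name: str = ""
    phenotype_terms: set[str] = field(default_factory=set)
    inheritance_modes: set[str] = field(default_factory=set)
    gene_symbols: set[str] = field(default_factory=set)


@dataclass
class DiseaseCatalog:
    diseases: dict[str, Disease] = field(default_factory=dict)
    term_index: dict[str, set[str]] = field(default_factory=dict)
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    @property
    def N(self) -> int:
        """Number of diseases with at least one phenotype annotation."""
        return sum(1 for d in self.diseases.values() if d.phenotype_terms)

    def annotated_ids(self) -> list[str]:
        return sorted(d.disease_id for d in self.diseases.values() if d.phenotype_terms)

    def add_annotation(self, disease_id: str, name: str, term_id: str) -> None:
        d = self.diseases.setdefault(disease_id, Disease(disease_id=disease_id, name=name))
        if name and not d.name:
            d.name = name
        d.phenotype_terms.add(term_id)
        self.term_index.setdefault(term_id, set()).add(disease_id)

    def link_gene(self, disease_id: str, gene: str) -> None:
        self.diseases[disease_id].gene_symbols.add(gene)
        self.gene_index.setdefault(gene, set()).add(disease_id)


@dataclass
class CatalogIC:
    """Annotation-based information content, defined on annotated terms only."""

    ic: dict[str, float]
    annotated_terms: set[str]


def load_annotations(path, dag: OntologyDAG) -> DiseaseCatalog:
    """Read an HPOA-like TSV (disease_id, disease_name, term_id per row).

    Lines starting with ``#`` are comments.  Term ids are remapped through
    the ontology's alt_id index; rows whose term cannot be resolved are
    dropped (counted in one log line).  Repeated rows for one disease
    accumulate into a single term set.
    """
    catalog = DiseaseCatalog()
    n_rows = n_dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("skipping malformed annotation row: %r", line)
                continue
            disease_id, name, term_id = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if not disease_id or not term_id:
                logger.warning("skipping malformed annotation row: %r", line)
                continue
            n_rows += 1
            try:
                resolved = dag.resolve(term_id)
            except UnknownTermError:
                n_dropped += 1
                continue
            catalog.add_annotation(disease_id, name, resolved)
    if n_rows == 0:
        raise CatalogError(f"annotation file {path} contains no usable rows")
    if n_dropped:
        logger.warning("dropped %d annotation rows with unresolvable terms", n_dropped)
    return catalog


# A disease id is the last comma-separated chunk of the phenotype label,
# after stripping a trailing mapping-key "(n)".
_TRAILING_KEY = re.compile(r"\s*\(\d+\)\s*$")


def parse_morbid_label(label: str) -> str:
    """Extract the disease id from a Morbidmap-style phenotype label."""
    label = _TRAILING_KEY.sub("", label.strip())
    chunk = label.rsplit(",", 1)[-1].strip()
    return chunk


def load_gene_map(path, catalog: DiseaseCatalog, alias_table: dict[str, str] | None = None) -> DiseaseCatalog:
    """Read a Morbidmap-like TSV into ``catalog`` (in place; also returned).

    Columns: phenotype label (containing the disease id, optionally with a
    trailing ``(n)`` mapping key), comma-separated gene symbols, optional
    inheritance annotation (AD/AR/...).  Gene symbols are remapped through
    ``alias_table`` before indexing.  Rows whose disease id is absent from
    the catalog are skipped with a warning.
    """
    alias_table = alias_table or {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                logger.warning("skipping malformed gene-map row: %r", line)
                continue
            disease_id = parse_morbid_label(parts[0])
            if not disease_id or disease_id not in catalog.diseases:
                logger.warning("gene-map row for unknown disease %r skipped", disease_id)
                continue
            genes = [g.strip() for g in parts[1].split(",") if g.strip()]
            for gene in genes:
                catalog.link_gene(disease_id, alias_table.get(gene, gene))
            if len(parts) >= 3 and parts[2].strip():
                mode = _INHERITANCE_ALIASES.get(parts[2].strip().lower(), OTHER_UNKNOWN)
                catalog.diseases[disease_id].inheritance_modes.add(mode)
    return catalog


def load_alias_table(path) -> dict[str, str]:
    """Two-column TSV: alias -> approved gene symbol."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                table[parts[0].strip()] = parts[1].strip()
    return table


def diseases_at_or_below(catalog: DiseaseCatalog, dag: OntologyDAG, term_id: str) -> set[str]:
    """d{C{t}}: diseases annotated with any term in the descendant closure of t."""
    out: set[str] = set()
    for s in dag.descendants(term_id):
        out |= catalog.term_index.get(s, set())
    return out


def catalog_information_content(catalog: DiseaseCatalog, dag: OntologyDAG) -> CatalogIC:
    """Compute ic(t) = -log(||d{C{t}}|| / N) for every annotated term.

    Computed bottom-up in a single pass: each term's at-or-below disease
    set is the union of its own annotations and its children's sets.
    """
    n = catalog.N
    if n == 0:
        raise CatalogError("catalog has no annotated diseases (N = 0)")
    below: dict[str, set[str]] = {}
    for term_id in reversed(dag.topological_order()):
        acc = set(catalog.term_index.get(term_id, ()))
        for c in dag.children(term_id):
            acc |= below[c]
        below[term_id] = acc
    ic = {
        t: -math.log(len(ds) / n) + 0.0  # +0.0 normalizes -0.0 at the root
        for t, ds in below.items()
        if ds
    }
    return CatalogIC(ic=ic, annotated_terms=set(ic))
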