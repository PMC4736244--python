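"""Readers, writers, and session persistence.

Variant ingestion accepts a VCF 4.x file (one record emitted per ALT
allele carried by the sample) or a bare gene list (placeholder records
with no zygosity, so inheritance models are refused downstream).  Gene
symbols come, in order of precedence, from a user-curated sidecar
per-variant gene map, a ``GENE=`` INFO key, or the first entry of an
ANN/CSQ annotation field.  MAF comes from a sidecar table or an AF-like
INFO key; pathogenicity only from a sidecar.  Exonic frameshift variants
with no pathogenicity score are assigned 1.0 at load time.

Sessions round-trip through a single JSON document; unknown top-level
keys are preserved opaquely for forward compatibility.
"""

from __future__ import annotations

import json
import logging
import re
from typing import Optional

import numpy as np
from cyvcf2 import VCF

from .mapping import MapLayout, RadarPoint
from .prioritize import HET, HOM, RankedVariant, Session, VariantRecord
from .similarity import PhenotypeQuery, ScoredDisease
from .discovery import DiscoveryCandidate

logger = logging.getLogger(__name__)

SESSION_SCHEMA_VERSION = 1

_SESSION_FIELDS = (
    "query", "variants", "excluded_diseases", "required_terms",
    "inheritance_constraint", "method", "aggregation", "m_neighbors",
    "top_n", "require_gene_link", "require_exome_link", "free_text",
    "viz_settings", "discovery_settings",
)


class IOFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sidecar tables: (chrom, pos, ref, alt) -> value

def load_variant_sidecar(path, value_type=str) -> dict[tuple, object]:
    """TSV with columns chrom, pos, ref, alt, value."""
    table: dict[tuple, object] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                logger.warning("skipping malformed sidecar row: %r", line)
                continue
            key = (parts[0], int(parts[1]), parts[2], parts[3])
            table[key] = value_type(parts[4])
    return table


def _apply_frameshift_rule(v: VariantRecord) -> VariantRecord:
    if v.pathogenicity is None and v.consequence and "frameshift" in v.consequence.lower():
        v.pathogenicity = 1.0
    return v


def _csq_symbol_index(raw_header: str) -> Optional[int]:
    m = re.search(r'ID=CSQ.*?Format: ([^">]+)', raw_header)
    if not m:
        return None
    fields = m.group(1).split("|")
    for name in ("SYMBOL", "Gene", "Gene_Name"):
        if name in fields:
            return fields.index(name)
    return None


def read_vcf(
    path,
    alias_table: dict[str, str] | None = None,
    gene_sidecar: dict[tuple, str] | None = None,
    maf_sidecar: dict[tuple, float] | None = None,
    pathogenicity_sidecar: dict[tuple, float] | None = None,
) -> list[VariantRecord]:
    """Read sample variants from a VCF, one record per carried ALT allele.

    Records with genotype 0/0 or missing are skipped.  A record is
    homozygous when both sample alleles equal the same ALT index.
    Multi-allelic genotypes (e.g. 1/2) yield one het record per ALT.
    """
    alias_table = alias_table or {}
    gene_sidecar = gene_sidecar or {}
    maf_sidecar = maf_sidecar or {}
    pathogenicity_sidecar = pathogenicity_sidecar or {}
    vcf = VCF(str(path))
    csq_idx = _csq_symbol_index(vcf.raw_header)
    records: list[VariantRecord] = []
    n_skipped = 0
    for var in vcf:
        if not var.genotypes:
            n_skipped += 1
            continue
        alleles = [a for a in var.genotypes[0][:-1] if a is not None and a >= 0]
        if not alleles:
            n_skipped += 1
            continue
        for alt_index, alt in enumerate(var.ALT, start=1):
            if alt_index not in alleles:
                continue
            zygosity = HOM if all(a == alt_index for a in alleles) else HET
            key = (var.CHROM, var.POS, var.REF, alt)
            gene, consequence = _annotation_fields(var, alt, csq_idx)
            if key in gene_sidecar:  # user-curated sidecar wins
                gene = gene_sidecar[key]
            if gene is None:
                raise IOFormatError(
                    f"no gene symbol for variant {var.CHROM}:{var.POS} {var.REF}>{alt}; "
                    "annotate the VCF (ANN/CSQ or GENE= INFO key) or supply a "
                    "per-variant gene sidecar"
                )
            gene = alias_table.get(gene, gene)
            maf = maf_sidecar.get(key, _info_maf(var, alt_index))
            patho = pathogenicity_sidecar.get(key)
            records.append(
                _apply_frameshift_rule(
                    VariantRecord(
                        chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                        zygosity=zygosity, gene_symbol=gene,
                        maf=maf, pathogenicity=patho, consequence=consequence,
                    )
                )
            )
    if n_skipped:
        logger.warning("skipped %d VCF records without usable genotypes", n_skipped)
    return records


def _annotation_fields(var, alt: str, csq_idx: Optional[int]):
    gene = var.INFO.get("GENE")
    consequence = var.INFO.get("CONSEQ")
    ann = var.INFO.get("ANN")
    if ann:
        first = str(ann).split(",")[0].split("|")
        if gene is None and len(first) > 3:
            gene = first[3]
        if consequence is None and len(first) > 1:
            consequence = first[1]
    csq = var.INFO.get("CSQ")
    if csq and gene is None and csq_idx is not None:
        first = str(csq).split(",")[0].split("|")
        if len(first) > csq_idx:
            gene = first[csq_idx]
    return (gene or None), (consequence or None)


def _info_maf(var, alt_index: int) -> Optional[float]:
    for key in ("AF", "MAF", "EXAC_AF"):
        val = var.INFO.get(key)
        if val is None:
            continue
        if isinstance(val, (tuple, list)):
            val = val[alt_index - 1] if len(val) >= alt_index else val[0]
        try:
            return float(val)
        except (TypeError, ValueError):
            continue
    return None


def read_gene_list(path) -> list[VariantRecord]:
    """One gene symbol per line; duplicates yield one record each.

    The records are zygosity-free placeholders, so downstream inheritance
    constraints other than "none" are refused.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            records.append(
                VariantRecord(
                    chrom="NA", pos=1, ref="N", alt="N",
                    zygosity=HET, gene_symbol=sym, placeholder=True,
                )
            )
    if not records:
        raise IOFormatError(f"gene list {path} is empty")
    return records


# ---------------------------------------------------------------------------
# session persistence

def _variant_to_dict(v: VariantRecord) -> dict:
    return {
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "zygosity": v.zygosity, "gene_symbol": v.gene_symbol,
        "maf": v.maf, "pathogenicity": v.pathogenicity,
        "consequence": v.consequence, "placeholder": v.placeholder,
    }


def _variant_from_dict(d: dict) -> VariantRecord:
    return VariantRecord(**d)


def save_session(session: Session, path) -> None:
    doc = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "query": {"terms": sorted(session.query.terms), "source": session.query.source},
        "variants": [_variant_to_dict(v) for v in session.variants],
        "excluded_diseases": sorted(session.excluded_diseases),
        "required_terms": sorted(session.required_terms),
        "inheritance_constraint": session.inheritance_constraint,
        "method": session.method,
        "aggregation": session.aggregation,
        "m_neighbors": session.m_neighbors,
        "top_n": session.top_n,
        "require_gene_link": session.require_gene_link,
        "require_exome_link": session.require_exome_link,
        "free_text": session.free_text,
        "viz_settings": session.viz_settings,
        "discovery_settings": session.discovery_settings,
    }
    doc.update(session.extra)  # opaque forward-compatible keys
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_session(path) -> Session:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise IOFormatError(f"session file {path} is not valid JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != SESSION_SCHEMA_VERSION:
        raise IOFormatError(
            f"session schema version {version!r} not supported (expected {SESSION_SCHEMA_VERSION})"
        )
    extra = {
        k: v for k, v in doc.items()
        if k not in _SESSION_FIELDS and k != "schema_version"
    }
    return Session(
        query=PhenotypeQuery(set(doc["query"]["terms"]), doc["query"].get("source", "")),
        variants=[_variant_from_dict(d) for d in doc["variants"]],
        excluded_diseases=set(doc["excluded_diseases"]),
        required_terms=set(doc["required_terms"]),
        inheritance_constraint=doc["inheritance_constraint"],
        method=doc["method"],
        aggregation=doc["aggregation"],
        m_neighbors=doc["m_neighbors"],
        top_n=doc["top_n"],
        require_gene_link=doc.get("require_gene_link", False),
        require_exome_link=doc.get("require_exome_link", False),
        free_text=doc.get("free_text", ""),
        viz_settings=doc.get("viz_settings", {}),
        discovery_settings=doc.get("discovery_settings", {}),
        extra=extra,
    )


# ---------------------------------------------------------------------------
# TSV output and matrix I/O
#
# Writers accept a filesystem path or an open text stream (e.g. stdout).

from contextlib import contextmanager


@contextmanager
def _open_write(path_or_file):
    if hasattr(path_or_file, "write"):
        yield path_or_file
    else:
        with open(path_or_file, "w") as fh:
            yield fh


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6f}"
    return str(x)


def write_scored_diseases(path, scored: list[ScoredDisease], catalog, method: str) -> None:
    with _open_write(path) as fh:
        fh.write("rank\tdisease_id\tname\tscore\tmethod\n")
        for sd in scored:
            name = catalog.diseases[sd.disease_id].name if sd.disease_id in catalog.diseases else ""
            fh.write(f"{sd.rank}\t{sd.disease_id}\t{name}\t{_fmt(sd.score)}\t{method}\n")


def write_ranked_variants(path, ranked: list[RankedVariant], aggregation: str) -> None:
    cols = (
        "rank\tgene\tscore\taggregation\ttop_supporting_disease\tdisease_rank\t"
        "chrom\tpos\tref\talt\tzygosity\tmaf\tpathogenicity\n"
    )
    with _open_write(path) as fh:
        fh.write(cols)
        for rv in ranked:
            v = rv.variant
            if rv.gene_score is not None:
                top = rv.gene_score.top_supporting
                fields = [rv.rank, v.gene_symbol, rv.gene_score.score, aggregation, top[0], top[2]]
            else:
                fields = [None, v.gene_symbol, None, aggregation, None, None]
            fields += [v.chrom, v.pos, v.ref, v.alt, v.zygosity, v.maf, v.pathogenicity]
            fh.write("\t".join(_fmt(f) for f in fields) + "\n")


def write_radar(path, points: list[RadarPoint]) -> None:
    with _open_write(path) as fh:
        fh.write("disease_id\tr\ttheta\tsize_value\tcolor_value\texcluded\n")
        for p in points:
            fh.write(
                f"{p.disease_id}\t{_fmt(p.r)}\t{_fmt(p.theta)}\t"
                f"{_fmt(p.size_value)}\t{_fmt(p.color_value)}\t{int(p.excluded)}\n"
            )


def write_layout(path, layout: MapLayout) -> None:
    k = layout.coords.shape[1]
    header = "disease_id\t" + "\t".join("xyz"[:k][i] for i in range(k))
    with _open_write(path) as fh:
        fh.write(header + "\n")
        for i, did in enumerate(layout.ids):
            fh.write(did + "\t" + "\t".join(_fmt(float(c)) for c in layout.coords[i]) + "\n")


def write_candidates(path, candidates: list[DiscoveryCandidate]) -> None:
    with _open_write(path) as fh:
        fh.write("gene\tn_training_links\tdegree\tfraction_training\ttraining_neighbors\n")
        for c in candidates:
            fh.write(
                f"{c.gene_symbol}\t{c.n_training_links}\t{c.degree}\t"
                f"{_fmt(c.fraction_training)}\t{','.join(c.training_neighbors)}\n"
            )


def write_similarity_matrix(path, ids: list[str], values: np.ndarray) -> None:
    """Square TSV with a header row and a leading id column."""
    with _open_write(path) as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, did in enumerate(ids):
            fh.write(did + "\t" + "\t".join(f"{v:.10g}" for v in values[i]) + "\n")


def read_similarity_matrix(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = header[1:]
        rows = []
        row_ids = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if row_ids != ids:
        raise IOFormatError("similarity matrix row ids do not match header ids")
    return ids, np.array(rows, dtype=float)
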