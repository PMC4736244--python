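"""Seeded generators for every input the pipeline consumes.

Nothing here is downloaded: the generators emulate the shape of the real
inputs (a rooted phenotype DAG, an annotated disease catalog with gene
links and inheritance modes, a patient VCF with a planted causal
variant, a PPI network with a planted discovery candidate) at desk
scale, with every draw fixed by one seed.

The ontology is a balanced tree of configurable depth and branching,
with occasional extra within-branch parents so closures are exercised on
a true DAG.  The children of the root partition the terms into
*branches*; each disease class draws its terms from one branch, which
makes class structure (and its absence, at coherence 0) well defined,
and lets query noise come from a branch disjoint from the planted
disease so truth recovery is unambiguous.

Generated MAFs are log-uniform in [1e-6, 1e-2]: every variant would
survive the conventional >1 % population-frequency pre-filter, matching
the expectation that the input variant set arrives pre-filtered.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .catalog import DOMINANT, RECESSIVE, DiseaseCatalog
from .discovery import PPINetwork
from .ontology import OntologyDAG, Term
from .prioritize import HET, HOM, VariantRecord
from .similarity import PhenotypeQuery

ROOT = "S:0000000"
HUB = "HUB"


class SyntheticError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    ontology_depth: int = 4
    branching_factor: int = 4
    extra_parent_prob: float = 0.1
    n_diseases: int = 24
    terms_per_disease: tuple[int, int] = (3, 6)
    n_classes: int = 3
    class_coherence: int = 3
    n_decoy_genes: int = 20
    # incidental terms drawn from any branch; keeps between-class
    # similarity nonzero, as with real diseases sharing minor features
    cross_branch_noise: int = 1
    planted_causal: bool = True
    planted_zygosity: str = HOM  # or "comphet"
    query_noise_terms: int = 0
    ppi_size: int = 0  # extra filler genes attached to the hub
    planted_candidate_links: int = 2
    n_decoy_candidates: int = 5

    def validate(self) -> None:
        if self.n_diseases < 1 or self.n_classes < 1 or self.branching_factor < 2:
            raise SyntheticError("counts must be >= 1 (branching >= 2)")
        if self.n_classes > self.branching_factor:
            raise SyntheticError("need one root branch per class")
        if self.query_noise_terms and self.n_classes >= self.branching_factor:
            raise SyntheticError("query noise needs a root branch unused by classes")


@dataclass
class SimulatedCase:
    dag: OntologyDAG
    catalog: DiseaseCatalog
    variants: list[VariantRecord]
    query: PhenotypeQuery
    ppi: PPINetwork
    classes: dict[str, set[str]]
    truth: dict = field(default_factory=dict)


def make_fixture_t6() -> tuple[OntologyDAG, DiseaseCatalog]:
    """The canonical 6-term worked-example fixture.

    Ontology: T0 root; T1, T2 below it; T3, T4 below T1; T5 below T2.
    Diseases: D1{T3}, D2{T4}, D3{T5}, D4{T3, T5}.
    Genes: GZ -> {D1, D2}, GX -> {D4}.
    """
    terms = {
        "T0": Term("T0", "root"),
        "T1": Term("T1", "left", {"T0"}),
        "T2": Term("T2", "right", {"T0"}),
        "T3": Term("T3", "left-a", {"T1"}),
        "T4": Term("T4", "left-b", {"T1"}),
        "T5": Term("T5", "right-a", {"T2"}),
    }
    dag = OntologyDAG(terms)
    catalog = DiseaseCatalog()
    for did, ts in [("D1", {"T3"}), ("D2", {"T4"}), ("D3", {"T5"}), ("D4", {"T3", "T5"})]:
        for t in sorted(ts):
            catalog.add_annotation(did, f"disease {did}", t)
    for gene, dids in [("GZ", ["D1", "D2"]), ("GX", ["D4"])]:
        for did in dids:
            catalog.link_gene(did, gene)
    return dag, catalog


def _tid(i: int) -> str:
    return f"S:{i:07d}"


def build_random_dag(rng: random.Random, depth: int, branching: int, extra_parent_prob: float = 0.1) -> tuple[OntologyDAG, dict[str, list[str]]]:
    """Balanced tree plus occasional second parents within a branch.

    Returns the DAG and a map root-child-id -> term ids of that branch
    (the branch partition used by the disease generator).
    """
    terms: dict[str, Term] = {ROOT: Term(ROOT, "root")}
    counter = 1
    levels: list[list[str]] = [[ROOT]]
    branch_of: dict[str, str] = {}
    for level in range(1, depth + 1):
        current: list[str] = []
        for parent in levels[-1]:
            for _ in range(branching):
                tid = _tid(counter)
                counter += 1
                terms[tid] = Term(tid, f"term {counter}", {parent})
                branch_of[tid] = tid if level == 1 else branch_of[parent]
                current.append(tid)
        levels.append(current)
    # extra within-branch parents keep branches disjoint below the root
    for level in range(2, depth + 1):
        for tid in levels[level]:
            if rng.random() < extra_parent_prob:
                pool = [
                    p for p in levels[level - 1]
                    if branch_of[p] == branch_of[tid] and p not in terms[tid].parent_ids
                ]
                if pool:
                    terms[tid].parent_ids.add(rng.choice(pool))
    branches: dict[str, list[str]] = {b: [] for b in levels[1]}
    for tid, b in branch_of.items():
        branches[b].append(tid)
    for b in branches:
        branches[b] = sorted(set(branches[b]) | {b})
    return OntologyDAG(terms), branches


def _did(i: int) -> str:
    return f"DZ{i:04d}"


def simulate_case(cfg: SimulationConfig) -> SimulatedCase:
    """Generate a complete synthetic case from one seed.

    Diseases are split round-robin into classes; each class draws from
    its own root branch and classmates share ``class_coherence`` fixed
    terms.  At coherence 0 every disease draws uniformly from the whole
    term set instead, which erases class structure by construction.
    The planted disease's term set becomes the query (plus optional
    noise terms from an unused branch); its gene carries the causal
    variant; decoy genes carry single het variants.  The PPI wires the
    planted discovery candidate to training-class genes and decoy
    candidates to at most one.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)
    dag, branches = build_random_dag(rng, cfg.ontology_depth, cfg.branching_factor, cfg.extra_parent_prob)
    branch_ids = sorted(branches)
    class_ids = [f"class{k}" for k in range(cfg.n_classes)]
    all_terms = sorted(t for t in dag.terms if t != dag.root_id)

    lo, hi = cfg.terms_per_disease
    if hi > min(len(branches[b]) for b in branch_ids[: cfg.n_classes]):
        raise SyntheticError("terms_per_disease exceeds the branch term pool")

    # class-coherent shared terms
    shared: dict[str, list[str]] = {}
    for k, cid in enumerate(class_ids):
        pool = branches[branch_ids[k]]
        shared[cid] = sorted(rng.sample(pool, cfg.class_coherence)) if cfg.class_coherence else []

    catalog = DiseaseCatalog()
    classes: dict[str, set[str]] = {cid: set() for cid in class_ids}
    member_index: dict[str, int] = {}
    for i in range(cfg.n_diseases):
        cid = class_ids[i % cfg.n_classes]
        did = _did(i)
        classes[cid].add(did)
        member_index[did] = len(classes[cid]) - 1
        n_terms = rng.randint(lo, hi)
        if cfg.class_coherence:
            pool = branches[branch_ids[class_ids.index(cid)]]
            terms = set(shared[cid])
            extras = [t for t in pool if t not in terms]
            # the planted disease (i == 0) stays branch-pure so the query
            # derived from it shares no incidental ancestry with decoys
            cross = 0 if (cfg.planted_causal and i == 0) else cfg.cross_branch_noise
            n_branch = max(0, n_terms - len(terms) - cross)
            terms |= set(rng.sample(extras, min(n_branch, len(extras))))
            if cross:
                terms |= set(rng.sample(all_terms, cross))
        else:
            terms = set(rng.sample(all_terms, n_terms))
        for t in sorted(terms):
            catalog.add_annotation(did, f"synthetic disease {i}", t)
        # genes shared by consecutive classmates so aggregation matters
        k = class_ids.index(cid)
        gene = f"G{k:02d}_{member_index[did] // 2:03d}"
        catalog.link_gene(did, gene)
        catalog.diseases[did].inheritance_modes.add(rng.choice([DOMINANT, RECESSIVE]))

    # planted disease and query
    truth: dict = {}
    planted_did = sorted(classes[class_ids[0]])[0]
    query_terms = set(catalog.diseases[planted_did].phenotype_terms)
    if cfg.query_noise_terms:
        noise_pool = branches[branch_ids[cfg.n_classes]]  # branch unused by classes
        query_terms |= set(rng.sample(sorted(noise_pool), cfg.query_noise_terms))
    query = PhenotypeQuery(terms=query_terms, source=f"synthetic seed {cfg.seed}")

    # variants: causal in the planted gene, het decoys elsewhere
    variants: list[VariantRecord] = []
    pos = 1000

    def add_variant(gene: str, zygosity: str, consequence: str = "missense_variant"):
        nonlocal pos
        pos += 137
        variants.append(
            VariantRecord(
                chrom="1", pos=pos, ref="A", alt="G", zygosity=zygosity,
                gene_symbol=gene,
                maf=10 ** rng.uniform(-6, -2),
                pathogenicity=round(rng.uniform(0.5, 1.0), 4),
                consequence=consequence,
            )
        )

    planted_gene = None
    if cfg.planted_causal:
        planted_gene = sorted(catalog.diseases[planted_did].gene_symbols)[0]
        if cfg.planted_zygosity == "comphet":
            add_variant(planted_gene, HET)
            add_variant(planted_gene, HET)
        else:
            add_variant(planted_gene, HOM)
    decoy_pool = sorted(
        g for g in catalog.gene_index
        if not (catalog.gene_index[g] & classes[class_ids[0]])
    )
    if cfg.n_decoy_genes > len(decoy_pool):
        raise SyntheticError(
            f"requested {cfg.n_decoy_genes} decoy genes but only {len(decoy_pool)} "
            "catalog genes lie outside the planted class"
        )
    decoys = rng.sample(decoy_pool, cfg.n_decoy_genes)
    for g in sorted(decoys):
        add_variant(g, HET)

    # PPI: class gene cliques joined through a hub two hops away, so
    # within-class gene distances are 1 and cross-class distances >= 4
    ppi_edges: list[tuple[str, str]] = []
    for k, cid in enumerate(class_ids):
        genes = sorted({g for did in classes[cid] for g in catalog.diseases[did].gene_symbols})
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                ppi_edges.append((a, b))
        rep = genes[0]
        linker = f"LNK{k:02d}"
        ppi_edges.append((rep, linker))
        ppi_edges.append((linker, HUB))
        if len(genes) == 1:
            ppi_edges.append((rep, f"PAD{k:02d}"))
    for i in range(cfg.ppi_size):
        ppi_edges.append((f"FILL{i:03d}", HUB))

    # planted discovery candidate: variant gene outside the catalog,
    # wired only to training-class genes
    planted_candidate = None
    if cfg.planted_candidate_links:
        training_pool = sorted(
            {g for did in classes[class_ids[0]] for g in catalog.diseases[did].gene_symbols}
        )
        if cfg.planted_candidate_links > len(training_pool):
            raise SyntheticError("planted_candidate_links exceeds planted-class gene count")
        planted_candidate = "NOVEL1"
        for g in training_pool[: cfg.planted_candidate_links]:
            ppi_edges.append((planted_candidate, g))
        add_variant(planted_candidate, HET)
        other_genes = sorted(
            g for g in catalog.gene_index
            if not (catalog.gene_index[g] & classes[class_ids[0]])
        )
        for j in range(cfg.n_decoy_candidates):
            cand = f"NOVD{j:02d}"
            # exactly one catalog-gene link (hence <= 1 training link),
            # padded with non-catalog neighbors
            if j % 2 == 0:
                ppi_edges.append((cand, training_pool[j % len(training_pool)]))
            else:
                ppi_edges.append((cand, other_genes[j % len(other_genes)]))
            ppi_edges.append((cand, f"PADC{j:02d}a"))
            ppi_edges.append((cand, f"PADC{j:02d}b"))
            add_variant(cand, HET)

    ppi = PPINetwork.from_edges(ppi_edges)
    truth.update(
        planted_disease=planted_did if cfg.planted_causal else None,
        planted_gene=planted_gene,
        planted_class=class_ids[0],
        planted_candidate=planted_candidate,
    )
    return SimulatedCase(
        dag=dag, catalog=catalog, variants=variants, query=query,
        ppi=ppi, classes=classes, truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission (all plain text, deterministic given the config)

def write_obo(dag: OntologyDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotype\n")
        for tid in sorted(dag.terms):
            t = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {t.id}\nname: {t.name}\n")
            for alt in sorted(t.alt_ids):
                fh.write(f"alt_id: {alt}\n")
            for p in sorted(t.parent_ids):
                fh.write(f"is_a: {p} ! {dag.terms[p].name}\n")


def write_annotations(catalog: DiseaseCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("#disease_id\tdisease_name\tterm_id\n")
        for did in sorted(catalog.diseases):
            d = catalog.diseases[did]
            for t in sorted(d.phenotype_terms):
                fh.write(f"{did}\t{d.name}\t{t}\n")


_MODE_OUT = {DOMINANT: "AD", RECESSIVE: "AR"}


def write_gene_map(catalog: DiseaseCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("#phenotype\tgene_symbols\tinheritance\n")
        for did in sorted(catalog.diseases):
            d = catalog.diseases[did]
            if not d.gene_symbols:
                continue
            modes = ",".join(sorted(_MODE_OUT.get(m, "") for m in d.inheritance_modes if m in _MODE_OUT))
            fh.write(f"{d.name}, {did} (3)\t{', '.join(sorted(d.gene_symbols))}\t{modes}\n")


def write_vcf(variants: list[VariantRecord], path) -> None:
    """Minimal single-sample VCF 4.2 with GENE/AF/CONSEQ INFO keys."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Consequence class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCASE",
    ]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        info = f"GENE={v.gene_symbol}"
        if v.maf is not None:
            info += f";AF={v.maf:.6g}"
        if v.consequence:
            info += f";CONSEQ={v.consequence}"
        gt = "1/1" if v.zygosity == HOM else "0/1"
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pathogenicity_sidecar(variants: list[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tpathogenicity\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            if v.pathogenicity is not None:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.pathogenicity}\n")


def write_ppi(ppi: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_query(query: PhenotypeQuery, path) -> None:
    Path(path).write_text("\n".join(sorted(query.terms)) + "\n")


def write_case(case: SimulatedCase, outdir) -> dict[str, Path]:
    """Write every artifact of a simulated case into ``outdir``.

    Returns the path of each file by role.  Output is byte-identical for
    identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "gene_map": outdir / "morbidmap.tsv",
        "vcf": outdir / "variants.vcf",
        "pathogenicity": outdir / "pathogenicity.tsv",
        "ppi": outdir / "ppi.tsv",
        "query": outdir / "query.txt",
    }
    write_obo(case.dag, paths["ontology"])
    write_annotations(case.catalog, paths["annotations"])
    write_gene_map(case.catalog, paths["gene_map"])
    write_vcf(case.variants, paths["vcf"])
    write_pathogenicity_sidecar(case.variants, paths["pathogenicity"])
    write_ppi(case.ppi, paths["ppi"])
    write_query(case.query, paths["query"])
    return paths
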