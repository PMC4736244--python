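# phenoprior

Phenotype-driven prioritization of diseases, genes, and variants for
genome-wide diagnostics — as a scriptable library and CLI.

Clinical exomes routinely leave hundreds of rare, plausibly deleterious
variants on the table after frequency filtering. `phenoprior` ranks them
against the patient's phenotypes by routing every comparison through
*medically recognized disease intermediates*: the patient's phenotype
term set is scored against an ontology-annotated disease catalog, each
candidate gene inherits the scores of the diseases it is cataloged to
cause, and each variant inherits its gene's score. Because the disease
differential stays visible, a clinician can exclude ruled-out diseases,
impose inheritance models, or require mandatory phenotypes, and the gene
and variant ranks update transitively.

## The model

Let *Q* be the query term set, *D* a disease's annotated term set, and
*A{t}* the reflexive ancestral closure of *t* in the phenotype ontology.
Four semantic similarity metrics are implemented:

- **Symmetrized Resnik** (best-match average): for each term in one set,
  take the information content of the most informative common ancestor
  (MICA) shared with any term of the other set; average per side and
  take the mean of the two sides. Information content is
  `ic(t) = −log(‖d{C{t}}‖ / N)`, the negative log fraction of catalog
  diseases annotated at or below *t*.
- **ATO** (ancestral term overlap): `‖A{D} ∩ A{Q}‖` — each shared
  ontology node counts exactly once.
- **IC-weighted ATO** and **topologically weighted ATO**: the same
  shared-node set, summed under catalog IC or under the reachability
  information `tic(t) = −log(tpc(t))` with
  `tpc(t) = Π_p tpc(p)/|children(p)|`.

A gene *G* cataloged to cause diseases *d{G}* receives the transitive
score `S_T(G,Q) = F(S(D_i,Q), D_i ∈ d{G})` with `F ∈ {max, mean, sum}`
(max is the default). Curatorial exclusion of a disease removes it from
`d{G}` before aggregation, so exclusions propagate to variant ranks.

Around this core the package provides: a classical-MDS disease map with
similarity-weighted convex query projection; a radar layout placing each
candidate disease at exact radial dissimilarity
`r_D = (S(Q,Q) − S(Q,D)) / S(Q,Q)` with 1-D-MDS angles and variant
MAF/pathogenicity encodings; phenotype suggestion (rarest non-query
terms of the top diseases); and PPI-based disease gene discovery
(patient variant genes highly connected to the genes of the query's
semantic disease neighborhood).

## Worked example

Generate a complete synthetic case (ontology, annotated catalog, gene
map, patient VCF with a planted homozygous causal variant, PPI network)
and rank the variants:

```sh
phenoprior simulate --seed 11 --outdir case/
phenoprior rank \
    --ontology case/ontology.obo --annotations case/annotations.tsv \
    --morbidmap case/morbidmap.tsv --query-file case/query.txt \
    --vcf case/variants.vcf --patho-sidecar case/pathogenicity.tsv
```

```
rank  gene     score     aggregation  top_supporting_disease  disease_rank  chrom  pos   ref  alt  zygosity  maf       pathogenicity
1     G00_000  2.022809  max          DZ0000                  1             1      1137  A    G    hom       0.000007  0.920100
2     G02_000  0.806500  max          DZ0005                  9             1      1822  A    G    het       0.002383  0.590600
...
```

The planted gene `G00_000` ranks first with Resnik score 2.0228 (nats),
inherited from its top supporting disease `DZ0000`, whose term set the
query was built from; decoy genes trail with the scores of their own,
less similar, diseases. The same session can then drive the radar
layout, phenotype suggestions, or PPI discovery — e.g.
`phenoprior discover ... --ppi case/ppi.tsv --top-m 5` reports the
planted non-catalog candidate `NOVEL1` first with `fraction_training
1.0` (every one of its interactions is a training gene).

As a library:

```python
from phenoprior import (PhenotypeQuery, Session, make_fixture_t6,
                        catalog_information_content, score_all_diseases)

dag, catalog = make_fixture_t6()
ic = catalog_information_content(catalog, dag)
scored = score_all_diseases(PhenotypeQuery({"T3"}), catalog, dag, "resnik", ic=ic)
print([(s.disease_id, round(s.score, 5), s.rank) for s in scored])
# [('D1', 0.69315, 1), ('D4', 0.51986, 2), ('D2', 0.28768, 3), ('D3', 0.0, 4)]
```

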