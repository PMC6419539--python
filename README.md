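# litcohesion

Literature-cohesion scoring of gene sets and co-expression-based microarray
probe benchmarking.

The package builds a latent-semantic-indexing concept space over per-gene
literature documents (log-entropy weighted term-by-gene matrix, truncated
SVD, cosine similarities), scores gene sets with a sampled right-tailed
Fisher's exact *literature cohesion p-value* (LPv), extracts nested top-N
co-expression windows around seed probes from a strains expression panel,
and benchmarks those windows against gold-standard gene sets
(precision/recall/F), category enrichment (hypergeometric + BH), exon/intron
probe separation (Wilcoxon rank-sum) and a mean −log10(LPv) probe-quality
cutoff. A synthetic-data generator with planted functional modules provides
ground truth for every stage.

## Modules

| module | role |
|---|---|
| `litcohesion.synthetic_data` | corpora, expression matrices, probe annotations and gold standards with planted structure |
| `litcohesion.corpus_lsi` | gene documents, log-entropy weighting, truncated-SVD concept space, cosines |
| `litcohesion.cohesion` | background threshold T, sampled counts A–D, right-tailed Fisher's exact LPv |
| `litcohesion.coexpression` | seed-probe correlation rankings and nested top-N gene windows |
| `litcohesion.benchmark` | F-measure, enrichment, BH adjustment, LPv–F correlation, rank-sum, probe classification |
| `litcohesion.pipeline` | end-to-end orchestration from a single YAML config |

## CLI

```bash
# generate a synthetic dataset (writes corpus, expression, gold standards,
# categories, ground truth and a ready-to-use run.yaml)
litcohesion simulate --out sim/ --seed 1

# run the full workflow
litcohesion run --config sim/run.yaml
# -> sim/results/{records.tsv, fmeasure.tsv, enrichment.tsv, summary.json, manifest.json}

# individual stages
litcohesion build-space --gene2pubmed sim/gene2pubmed.tsv \
    --abstracts sim/abstracts.tsv --rank 500 --out space.npz
litcohesion lpv --space space.npz --genes sim/gold_standards.gmt \
    --percentile 95 --k 50 --n 1000 --bg-n 1000 --seed 1 --out lpv.json
litcohesion coexpress --expr sim/expression.tsv --annot sim/probes.tsv \
    --seed-probe g00000_ex0 --sizes 100:1000:100 --out windows/
litcohesion benchmark --windows windows/windows.gmt \
    --gold sim/gold_standards.gmt --categories sim/categories.gmt \
    --universe genes.txt --out bench.tsv
```

Input formats are plain text: gene2pubmed-style TSV (`tax_id  GeneID
PubMed_ID`), a `pmid<TAB>text` abstract table, expression TSV (first column
probe id, header row of strain names, empty cell = missing), probe
annotation TSV (`probe_id  gene_id  region` with region `exon`/`intron`),
and GMT gene sets.

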