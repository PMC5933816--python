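# ltrforest

Identification and superfamily classification of LTR retrotransposons
(Copia / Gypsy / Bel-Pao) from conserved protein-domain architectures,
using relational random forests.

The pipeline has three stages:

1. **Window** — tile the genome with overlapping fixed-length windows
   (default 10 kb, 1 kb overlap).
2. **Annotate** — combine the windows with conserved-domain hits
   (RPS-Blast-style tabular reports over a 26-subdomain vocabulary) into
   boundary-trimmed candidate elements: windows sharing a hit in their
   overlap are merged, mixed-strand regions are split per strand, and each
   candidate runs from its first to its last domain hit.
3. **Classify** — score every candidate with one relational random forest
   per superfamily. Tree nodes test first-order properties of the hit bag:
   domain occurrence (with e-value ceilings and optional length bounds),
   domain-before-domain order, and occurrence counts of general domains —
   10,947 distinct tests under the default grids. Per-family probabilities
   are combined by argmax with a *None* category below a threshold.

A synthetic-data module generates training corpora and genomes with planted
elements (domain architectures, e-value distributions, dropout/spurious
noise, both strands), so the whole pipeline is testable offline. An
evaluator implements overlap-based matching (100 nt minimum overlap or
mutual containment), per-family and combined precision–recall curves,
max-F1, and exclusive-find comparisons between methods.

## CLI

Everything is exposed through one entry point with per-stage subcommands:

```sh
# synthetic data with ground truth
ltrforest simulate --kind corpus --out-dir work/corpus --n-per-class 100 --seed 1
ltrforest simulate --kind genome --out-dir work/genome --n-insertions 10 \
    --genome-length 200000 --minus-strand-prob 0.5 --seed 2

# train one forest per superfamily (versioned JSON model files)
ltrforest train work/corpus/corpus.fa work/corpus/corpus_hits.tsv \
    work/corpus/corpus_labels.tsv --target Gypsy --out gypsy.model.json \
    --n-trees 100 --seed 1

# end-to-end prediction (writes GFF3 + a reproducibility manifest)
ltrforest predict work/genome/genome.fa work/genome/genome_hits.tsv \
    --forest Copia=copia.model.json --forest Gypsy=gypsy.model.json \
    --forest Bel-Pao=belpao.model.json --out preds.gff3 --seed 2

# evaluation against reference annotations
ltrforest evaluate preds.gff3 work/genome/truth.gff3 --superfamily combined
ltrforest compare preds_a.gff3 preds_b.gff3 work/genome/truth.gff3 --superfamily Copia
```

`window` and `annotate` expose the intermediate stages; `--config FILE`
supplies a JSON run configuration (file values take precedence over flags).

Input formats: FASTA genomes/corpora; tab-separated hit tables
(`query_id  subject_id  q_start  q_end  strand  evalue`, 1-based inclusive;
reversed coordinates are normalized to minus-strand); GFF3 for predictions
and reference annotations; a tab-separated `id → superfamily` label map for
training.

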