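# phloemscan

Phloem sieve elements transport full-length mRNAs as long-distance signals,
and RNA-binding proteins (RBPs) chaperone those transcripts by binding
conserved elements in their 3' untranslated regions. `phloemscan` screens a
genome for the binding elements of four such RBPs — Pumilio, Nova, the
polypyrimidine tract-binding protein (PTB) and its phloem ortholog RBP50 —
and crosses the target calls with RNA-seq expression classes, so that
abundant, phloem-expressed, motif-carrying transcripts (candidate mobile
mRNAs) can be short-listed *in silico*.

Because 3' UTR annotations are unreliable in many plant genomes, motifs are
searched in the **downstream sequence (DSS)**: a fixed window of 1000, 500
or 200 nt immediately 3' of the stop codon of each gene's representative
transcript, extracted strand-aware from a genome FASTA + GFF3 annotation.

## What it computes

* **Motif screens** over each DSS (sense strand only — these are RNA
  elements):
  * Pumilio consensus `UGUA[UCA]AUA` and Nova consensus `[UCA]CAUUUCA[CU]`,
    with every overlapping occurrence counted;
  * PTB: a transcript is a target when its 200-nt DSS contains a cluster of
    ≥ 4 maximal CU runs (C/T in DNA) of ≥ 4 nt each;
  * RBP50: the 15-mer `UUCUCUCUccuUCUU`, lowercase positions weakly
    conserved (pyrimidine-ambiguous by default), screened within the
    PTB-positive pool;
  * optional position-weight-matrix scanning (summed log-odds ≥ threshold)
    for user-supplied matrices.
* **Motif statistics**: per-gene multiplicity histograms, co-occurrence
  tables over all motif combinations (inclusion and exclusive counts), and
  positional profiles with a Pearson χ² goodness-of-fit test of binned hit
  starts against the uniform expectation
  (χ² = Σ (Oᵢ − E)²/E, df = window/bin − 1).
* **Expression classes** from a gene × library count table: each library is
  scaled by s·ḡ/s_ℓ where s_ℓ is the 0.75 quantile of its nonzero counts and
  ḡ the geometric mean of all s_ℓ (upper-quartile normalization); replicate
  means per group are then classified by strict read thresholds
  (>10, >500, >1000) and by tissue specificity (unique / common / absent).
* **Joined reports**: motif-positive gene counts stratified by the whole
  genome, abundance strata, user gene lists (e.g. transcription factors)
  and optional differential-expression labels.
* A **synthetic-data generator** that plants motifs at known DSS offsets on
  both strands and draws negative-binomial counts with replicate structure,
  so the whole pipeline is testable against ground truth without downloads.

## Worked example

Simulate a 12-gene study with one Pumilio gene, one Nova gene and one
PTB-cluster gene, then run the full pipeline:

```bash
cat > spec.yaml <<'EOF'
n_contigs: 2
contig_length: 40000
n_genes: 12
frac_minus_strand: 0.5
planted_motifs:
  - [pumilio, 0, 10]
  - [nova, 1, 40]
  - [cu_run, 2, 0]
  - [cu_run, 2, 25]
  - [cu_run, 2, 50]
  - [cu_run, 2, 75]
background_alphabet: AG
dss_window: 1000
seed: 5
EOF
phloemscan simulate --spec spec.yaml --out study

cat > run.yaml <<'EOF'
genome_fasta: study/genome.fasta
annotation_gff: study/genes.gff3
counts_tsv: study/counts.tsv
design_tsv: study/design.tsv
out_dir: out
seed: 5
EOF
phloemscan all --config run.yaml
```

`out/joined_report.tsv` then reads:

```
motif	whole_genome	>10_either	>500_either
pumilio	1	1	0
nova	1	1	0
ptb	1	1	0
rbp50	0	0	0
```

— exactly one gene per planted motif class, each expressed above 10 but not
500 mean reads (the simulated mean is 100), and no RBP50 target since none
was planted. `out/multiplicity_ptb.tsv` shows one gene with 4 CU runs (the
planted cluster, a PTB target) and one with a single run (the Nova element
`UCAUUUCAU` itself contains the 4-nt pyrimidine run `UUUC`, which is below
the 4-run cluster threshold):

```
hits_per_gene	n_genes
1	1
4	1
```

The same operations are available as a library
(`phloemscan.scan_consensus`, `ptb_cluster_call`,
`upper_quantile_normalize`, `category_join`, ...), and
`phloemscan extract-dss / scan / expression` run individual stages.

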