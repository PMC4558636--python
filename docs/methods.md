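# Methods

## Downstream sequences as a 3'-UTR proxy

Gene models are reduced from GFF3 to one representative transcript per gene.
The default representative is the transcript with the largest summed CDS
length (ties broken by lexicographically smallest transcript id); a
`"first"` rule is available for annotations that encode their own
representative choice in the id ordering. The coding end is the last CDS
base in transcript orientation: the maximal CDS end on the plus strand, the
minimal CDS start on the minus strand.

The downstream sequence (DSS) of a gene at window *w* is the genomic
interval `[coding_end+1, coding_end+w]` on the plus strand, or
`[coding_end−w, coding_end−1]` reverse-complemented on the minus strand —
always 5'→3' as the transcript reads it, starting at the base immediately
after the stop codon (the stop codon belongs to the CDS and is excluded).
Intervals are clipped at contig boundaries and the `truncated` flag records
any shortening; a coding end at the contig edge yields an empty, truncated
DSS rather than an error. A shorter window is by construction the prefix of
a longer one, so all windows are derived from a single maximal extraction.
`N` bases are retained and can never match any motif position.

Annotated 3' UTRs are deliberately not used even when present: fixed
windows make target calls comparable across genes regardless of annotation
completeness.

## Motif screens

All screens run on the sense-strand DSS only, since the elements are
recognized on the mRNA. Motif definitions written in RNA letters are mapped
U→T at load time.

* **Degenerate consensus** (Pumilio `UGUA[UCA]AUA`, Nova `[UCA]CAUUUCA[CU]`,
  and any user pattern with bracket degeneracy): a hit at offset *i* iff
  every motif position admits the base at *i+j*. Overlapping matches are
  all counted — per-gene multiplicities are meaningful, and no
  de-overlapping rule is imposed. Implementation uses a compiled
  lookahead regex; tests compare it against a per-offset brute-force
  oracle.
* **PWM scanning**: hit iff the summed per-position log-odds score meets
  the threshold; any non-ACGT base under the window disqualifies the
  offset. Matrices load from a whitespace table with an `A C G T` header,
  either as log-odds scores or as probabilities converted to log2 odds
  against a uniform background with a pseudocount (default 1e-3). When no
  absolute threshold is given it defaults to 0.8 × the maximal attainable
  score — PWM sources rarely publish their thresholds, so the cut-off is
  explicit configuration rather than a hidden constant.
* **PTB CU-run cluster**: a CU run is a *maximal* run of consecutive C/T of
  at least `min_run_length` (default 4) — one long pyrimidine tract is a
  single run, never several. A transcript is a PTB target when its
  `window`-nt DSS (default 200) contains at least `min_runs` (default 4)
  such runs, with no spacing constraint between runs. All three parameters
  are configuration.
* **RBP50 15-mer** `UUCUCUCUccuUCUU`: uppercase positions are fixed;
  lowercase positions mark weak conservation and default to
  pyrimidine-ambiguous `{C,U}`, with `exact` and `any` policies selectable.
  The screen is intended for the PTB-positive pool, and the pipeline
  restricts it accordingly; the scanning function itself is
  pool-agnostic. The pipeline screens RBP50 over the longest configured
  window (1000 nt by default), since the pool definition — not a shorter
  window — is what makes this screen exclusive.

## Motif statistics

* **Multiplicity**: histogram of per-gene hit counts over genes with ≥ 1
  hit; mixing motifs in one histogram is rejected.
* **Co-occurrence**: for every non-empty subset of the screened motifs,
  both the *inclusion* count (genes positive for at least that subset) and
  the *exclusive* count (genes positive for exactly it). Both are reported
  because inclusion counts are what headline statements like "N transcripts
  contain all three motifs" mean, while exclusive counts partition the gene
  universe.
* **Positional profile**: hit start offsets binned at `bin_width` (default
  100 nt) across the window, tested against the uniform expectation with a
  Pearson chi-square statistic on `window/bin_width − 1` degrees of
  freedom. A profile with zero hits is all-zero with p = 1. The chi-square
  approximation assumes a reasonable total hit count (the usual ≥ ~5
  expected per bin); with genome-scale hit counts this is comfortably met,
  and the null calibration is verified by simulation in the tests.

## Expression classification

* **Upper-quartile normalization**: per library, the scale factor s_ℓ is
  the q-quantile (default 0.75, linear interpolation) of that library's
  *nonzero* counts; normalized counts are raw × ḡ/s_ℓ with ḡ the geometric
  mean of all factors. Using nonzero counts makes the factor insensitive to
  how many genes were detected at all; the geometric-mean rescaling keeps
  normalized values on the raw-count scale and makes the map idempotent.
  An all-zero library is an error naming the library. Post-normalization,
  the q-quantile of nonzero counts is identical across libraries (a tested
  invariant, tolerance 1e-9 relative).
* **Group means**: arithmetic means over each group's replicate libraries.
* **Abundance**: strict `>` comparisons against thresholds 10/500/1000
  (configurable); per-group counts plus an "either group exceeds t" union
  column. The boundary value (exactly 10 reads) is excluded by the strict
  inequality; the choice is configuration, since presence calls at the
  boundary are inherently arbitrary.
* **Specificity** (pairwise): unique-to-A iff mean_A > present_threshold
  (default 10) and mean_B ≤ absent_threshold (default 0); common iff both
  exceed the presence threshold; absent iff neither does; the remaining
  zone (present in one group, nonzero but sub-threshold in the other) is
  labelled `ambiguous` and counted separately rather than silently folded
  into another class. The default absence threshold of exactly zero is the
  conservative reading of "uniquely expressed"; both thresholds are
  configuration.
* **Category join**: boolean motif-target calls are crossed with the
  abundance strata, user gene lists (and their intersections with the
  strata) and optional externally computed differential-expression labels.
  DE inference itself is out of scope — labels are consumed, never
  computed. Genes present in motif calls but absent from the expression
  table are logged and excluded from stratified counts.

## Synthetic data

The generator emulates the study conditions the pipeline is meant for: a
multi-contig DNA genome, genes on both strands (default half minus-strand),
motifs planted at known DSS offsets, and negative-binomial counts with
replicate groups and unequal library depths.

* Genes sit in slots of `gene_length + 2·dss_window` nt with the CDS
  centered, so every DSS fits untruncated on either strand and truncation
  behavior is exercised only by dedicated hand-built fixtures. Each
  synthetic gene has exactly one transcript; multi-transcript
  representative selection is tested with hand-written GFF3 fixtures.
  Requesting more genes than fit is a generation error with a diagnostic.
* Background bases are i.i.d. with configurable GC content, or drawn from a
  restricted alphabet. The purine alphabet `AG` is the adversarial-off
  mode: no CU run and none of the four study motifs can arise by chance, so
  scanner output must equal the planted truth exactly. The alphabet
  guarantee applies to the DSS *as the transcript reads it*: minus-strand
  DSS regions are drawn from the complement alphabet on the forward strand.
* Planted instances are concrete draws from the motif's degenerate pattern;
  overlapping plantings within one gene are rejected. Note that any Nova
  instance contains the 4-nt CU run `UUUC` and an RBP50 instance is a 15-nt
  pyrimidine tract, so CU-run ground truth is exact only on genes where
  only CU runs were planted — the test suite partitions genes by motif type
  accordingly, and the acceptance study plants CU-run clusters in its RBP50
  genes precisely so they fall inside the PTB-positive pool, as real RBP50
  targets do.
* Counts: gene × library negative binomial with mean
  `nb_mean × library_size_factor` (per-gene means overridable), dispersion
  `nb_dispersion` (size parameter r, variance μ + μ²/r; `inf` selects the
  Poisson limit), and group-unique genes implemented as mean zero in the
  off group. Defaults — mean 100, dispersion 5, three replicates per group
  — are in the range typical of moderately expressed genes in bulk RNA-seq
  with biological replicates.

What passing on synthetic data does *not* show: robustness to misannotated
stop codons, amplification bias, multi-mapping artifacts, or non-i.i.d.
background composition (real 3' regions are AT-rich and repeat-laden, so
genome-scale motif counts on real data depend on base composition in a way
the uniform background does not reproduce).

## Pipeline and determinism

The `all` run extracts DSS at every configured window (longest first,
shorter windows as prefixes), scans Pumilio/Nova at each window, calls PTB
at its own 200-nt window, screens RBP50 over the PTB-positive pool,
computes multiplicity/co-occurrence/positional statistics at the target
call windows (500 nt for Pumilio/Nova, 200 for PTB), normalizes and
classifies expression, and writes the joined report. All outputs are TSV
(or FASTA), written with fixed float formatting; the manifest records the
config hash, input checksums, seed and row counts, and deliberately
excludes wall-clock timings and the output path so that two runs on
identical inputs are byte-identical. The pipeline itself consumes no
randomness; the seed exists for the simulator and is recorded for
provenance.

Problem sizes in the test suite and acceptance script (hundreds of genes,
thousands of random oracle sequences, 200-replicate null calibrations) are
chosen to exercise every code path at desk scale; all of them complete in
well under a minute on one CPU.
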