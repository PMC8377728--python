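# hivemzt

Analysis of the maternal-to-zygotic transition (MZT) in honeybee
(*Apis mellifera*) embryos from single-embryo RNA-seq, built as a fully
tested pipeline that can be exercised end to end on synthetic data with
known ground truth.

Honeybees are haplodiploid: unfertilized haploid eggs develop into
males, fertilized diploid eggs into females. Profiling single embryos
of both sexes at 24, 48 and 72 h after egg laying (AEL) exposes how the
two ploidies activate their genomes: diploid females show three zygotic
genome activation (ZGA) waves — genes switched on between 24–48 h and
re-silenced (wave 1), switched on and sustained (wave 2), or activated
only between 48–72 h (wave 3) — alongside degradation of maternal
transcripts, which proceeds more slowly in haploid males. The same
waves carry thousands of long non-coding RNAs (lncRNAs), most of them
transcribed from the long (> 2,000 nt) introns typical of this genome
and largely independent of their host genes.

## What the package computes

* **Expression** (`hivemzt.expression`) — read counting by majority
  exonic overlap, RPKM/TPM, DESeq-style median-of-ratios size factors,
  detection at RPKM > 0.1, an exact conditional negative-binomial test
  for differential expression (fold change > 2 or < 0.5 with p < 0.01,
  or FDR < 0.05 with |log2FC| > 1), activation-wave assignment from the
  three pairwise timepoint contrasts, and the 2^-ddCt qPCR utility.
* **lncRNA discovery** (`hivemzt.lncrna`) — coverage-contig plus
  junction-chain assembly of candidate transcripts, a logistic coding
  potential score (CPS) over ORF, TESTCODE and hexamer features trained
  on annotated mRNAs versus dinucleotide-shuffled decoys, the paired
  500/1,000-nt single-exon length thresholds, genomic locus
  classification (intronic / intergenic / antisense / exonic overlap)
  and sex-specific expression calls.
* **Poly(A) sites** (`hivemzt.polya`) — soft-clipped tail detection
  (> 10 nt at <= 10% error), raw-read tail-length measurement,
  internal-priming removal by genomic A-content beyond the anchor,
  20-bp single-linkage clustering of anchors into polyadenylation sites
  (PAS), and lncRNA transcription-direction inference from flanking PAS.
* **Splicing** (`hivemzt.splicing`) — junction extraction with 8-nt
  boundary flanks, known/novel annotation, classification into nine
  alternative-splicing event types (ES, CE, A5SS, A3SS, MXE, AFE, ALE,
  IR, other), splicing efficiency, events per 100 junctions, and a
  Fisher exact test for alternative-polyadenylation usage shifts.
* **Co-expression** (`hivemzt.coexpr`) — Pearson correlation with
  t-transform p-values, lncRNA–host relation classification, partner
  sets, and sample-similarity matrices.
* **Synthetic data** (`hivemzt.simulate`) — a deterministic generator
  for the full study design (2 sexes x 3 timepoints x 2 queens x 3
  embryos) with planted waves, lncRNAs, tails, PAS, AS events and
  internal-priming artifacts, plus complete truth tables; and
  `hivemzt.evaluate` to score recovery.

The `hivemzt` CLI (`hivemzt demo|run|expr|lncrna|polya|splice|coexpr`)
wraps the pipeline; the numbered drivers under `analysis/` walk through
the study step by step and write their tables under `results/`.

## Worked example

```
$ python analysis/01_simulate_dataset.py
$ python analysis/02_expression_waves.py
female wave calls:
wave
none                    16
wave1                    5
maternal_degradation     5
wave3                    5
wave2                    5

recovery of planted wave/MD labels: 100.0% over 20 genes; 100.0% of
constant genes correctly left unlabelled
male embryos: 5 wave-labelled genes (5 maternal degradation) — haploid
activation is weak by design
```

Every planted wave-1/2/3 and maternal-degradation gene is recovered by
the exact NB test plus the wave decision table, constant genes stay
unlabelled, and the male samples show only maternal decline — the
haplodiploid asymmetry the design plants. Continuing:

```
$ python analysis/04_polya_directions.py
tails detected: 60285, kept after internal-priming filter: 59177
  artifact removal: 100.0%, true-tail retention: 99.9%
PAS clusters (support >= 3): 57, 100.0% within 10 nt of a planted site
direction assigned for 20 matched lncRNAs, accuracy 95.0%
```

All genomically templated A-run artifacts are discarded while 99.9% of
true tails survive; clustered PAS land on the planted cleavage sites,
and 19 of 20 discovered lncRNAs get the correct strand from the PAS
geometry alone.

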