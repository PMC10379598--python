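# lncannotate

Identification, genome-location classification and annotation of plant long
non-coding RNAs (lncRNAs) in assembled transcriptomes.

Long non-coding RNAs are transcripts longer than 200 nt with no
protein-coding capacity. Finding them in an assembled transcriptome is a
cascade problem: separate coding from noncoding sequences, align the
candidates to the reference genome, discard assembly noise and transposable
element (TE) transcripts, classify what remains by its position relative to
annotated genes, and then annotate the survivors — conservation against
known-lncRNA libraries, exon/intron structure, and tissue specificity of
expression. `lncannotate` implements that whole cascade as a Python library
with a thin command-line interface, for researchers analysing plant
RNA-seq assemblies (de novo or reference-based) who want every stage
native, seeded and testable.

## What it computes

**Classifier.** A trainable lncRNA-vs-mRNA sequence classifier (a small
seeded feed-forward network; logistic-regression fallback) over
hexamer-usage, spectral and composition features. Training follows a
balanced replicate protocol: all known lncRNAs are kept and twice as many
mRNAs are sampled without replacement; each class is split 80/20 into
train/test; the whole procedure runs in five independently seeded
replicates and the replicate with maximal F1 is kept. With lncRNAs as the
positive class,

    SN = TP/(TP+FN)   PR = TP/(TP+FP)   SP = TN/(TN+FP)
    F1 = 2·SN·PR/(SN+PR)

**Descriptors.** Per-transcript longest forward-strand ATG-initiated ORF,
ORF coverage, the Fickett TESTCODE statistic (published position/composition
lookup tables) and the isoelectric point of the translated ORF
(Henderson–Hasselbalch with the Bjellqvist pKa set, solved by bisection).

**Genome location.** Loci are maximal merged regions covered by aligned
candidates. A noise filter drops short fragments that do not match their
locus representative; a TE filter drops transcripts whose exons overlap a
TE by ≥ 1 bp. Each surviving transcript gets one of the 14 single-character
class codes (`= c k m n j e o s x i y p u`) against the reference
annotation, and a decision table maps codes to verdicts: complete matches
to mRNAs and sense-exonic overlaps are excluded, `e/s/p/y` are treated as
artefacts, and `i`/`x`/`u` survive as novel intronic, antisense and
intergenic lncRNAs.

**Annotation.** Conservation labels from a known-lncRNA library (best local
alignment ≥ 50% identity in another species ⇒ conserved), greedy identity
clustering, exon/intron structure summaries (transcripts with introns
< 60 bp are excluded from structure statistics only), per-chromosome locus
densities, antisense exon-ordinal profiles, and expression tissue
specificity: for each RNA type and tissue, the number of transcripts with
TPM > 1 in that tissue, normalised by the type's expressed-transcript count
and the tissue's library count.

A seeded generator (`lncannotate.fixtures`) builds a complete miniature
input world — genome, annotation, TEs, candidate transcripts, expression
matrix, homology library — with a machine-checkable truth table, so every
stage is testable without downloads.

## Worked example

```bash
python examples/03_genome_location.py
```

```
query                 code  verdict
exact copy            =     known_mrna_excluded
inside exon (sense)   c     sense_exonic_excluded
inside intron         i     intronic
antisense over exon   x     antisense
straddles boundary    e     artefact_excluded
run-on downstream     p     artefact_excluded
far intergenic        u     intergenic
```

Each query transcript is compared against a three-exon coding gene: the
exact copy is recognised as a known mRNA (a prediction error to discard), a
fragment inside an intron becomes an intronic lncRNA, an opposite-strand
exon overlap an antisense lncRNA, and a transcript far from any gene an
intergenic lncRNA. The other examples cover training and prediction
(`01`), ORF descriptors (`02`), conservation labelling and clustering
(`04`), expression specificity (`05`), report arithmetic on the bundled
maize case-study counts (`06`) and the full pipeline on the toy world
(`07`). The same stages are available as shell subcommands:

```bash
lncannotate make-fixtures --seed 1 --out world/
lncannotate run-all --config config.yaml --out results/
```

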