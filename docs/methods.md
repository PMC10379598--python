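# Methods

This note documents the models, conventions and numerical choices behind
`lncannotate`, and what the synthetic test world does and does not show
about real data.

## Coordinates and formats

All genomic intervals are 0-based half-open internally; GFF3/GTF 1-based
inclusive coordinates are converted only at the I/O boundary, so interval
arithmetic (overlap, containment, gaps) is uniform everywhere. DNA is
normalised at read time — uppercase, U→T, IUPAC ambiguity codes → N —
because the hexamer and ORF machinery assumes a 4+1 letter alphabet.
GTF attribute syntax is sniffed per line. Transcript ids are taken from
`ID`/`transcript_id`; for spliced-aligner GFF3 (which suffixes mRNA IDs
with `.mrna1` and keeps the input id in `Name`) the readers accept
`prefer_name=True`. Exons of a transcript must be strictly separated:
touching exons would imply a zero-length intron and are rejected.

## Classifier

Training data are built by the balanced replicate protocol: every known
lncRNA is kept and `ratio` (default 2) times as many mRNAs are sampled
without replacement; each class is split independently (stratified) into
`floor(0.8·n)` training and the remaining test sequences; five replicates
are seeded as `seed + replicate_index`, so replicates are independent yet
reproducible. Per replicate a hexamer table is rebuilt from the training
split only (overlapping hexamer counts per class, pseudocount 1,
normalised), which keeps test information out of the features.

The feature vector has six dimensions: the mean log-ratio of
coding/noncoding hexamer frequencies over the sequence's overlapping
hexamers; the mean, variance and 75th percentile of the periodogram of the
EIIP-encoded sequence (electron-ion interaction pseudopotentials A 0.1260,
C 0.1340, G 0.0806, T 0.1335; the period-3 structure of codons shows up in
this spectrum); log10 length; and GC fraction. Features are standardised
on the training split. The default backend is a one-hidden-layer
(16 units) scikit-learn MLP with a fixed `random_state`; a logistic
regression sits behind the same interface. The decision threshold is 0.5
on P(noncoding), configurable. Secondary-structure features are
deliberately not computed: folding roughly doubles runtime for about a
one-percent accuracy gain, so the interface stub raises
`NotImplementedError`.

Metric conventions: lncRNA is the positive class; any 0/0 metric is NA,
and F1 is NA when SN or PR is NA or SN+PR = 0. Model selection is argmax
F1 with ties to the lowest replicate index. Models serialise via joblib
and reload with bit-identical predictions.

Chance level under this protocol: the held-out set is 1:2
lncRNA:mRNA, so a truth-independent classifier that predicts noncoding at
rate q has expected SN = q, PR = 1/3 and F1 = 2q/3 / (q + 1/3) — at most
1/3 for q ≤ 1/3 and 0.5 only in the degenerate all-noncoding limit. On a
zero-separation fixture the seeded network predicts near the 1/3 prior and
mean F1 sits near 0.28; that, not 0.5, is the correct no-signal baseline
for this design.

## ORF descriptors

The longest ORF is ATG-initiated, forward-strand, over the three forward
frames; its length counts ATG through stop inclusive; without an in-frame
stop the ORF runs to the last complete codon and is flagged stop-less.
Ties in length break to the smallest start offset. The Fickett TESTCODE
score is computed on the full transcript (not the ORF) from the published
position-asymmetry and composition lookup tables; Ns count toward length
but not toward any base, and every score lies inside the bounds implied by
the tables. The isoelectric point uses the Bjellqvist pKa set (N-term 7.5,
C-term 3.55; D 4.05, E 4.45, H 5.98, C 9.0, Y 10.0, K 10.0, R 12.0;
swappable via the `pka` argument) and bisection on [0, 14] until
|charge| < 1e-4 or the bracket is narrower than 1e-5 pH units — the tight
bracket keeps the residual charge below 1e-3 even for long, heavily
charged peptides whose titration curve is steep at the crossing. It is
reported only when the ORF spans at least two codons.

## Genome location

Loci merge aligned candidate spans transitively wherever they overlap by
≥ 1 bp, ignoring strand (whether lncRNA loci should be strand-aware is
genuinely open; strandless merging is the more conservative grouping).
Bookended spans stay separate. Merging is idempotent and partitions the
transcripts.

The noise filter reads "matches its locus" operationally: the locus
representative is its longest member (summed exon length, ties by id);
multi-exon members must reproduce the representative's intron chain, and
single-exon members must cover ≥ 80% (configurable) of the locus span.
This removes short fragmentary isoforms while always keeping the longest
one; a transcript alone in its locus is always kept.

The 14 class codes are assigned by testing predicates in the fixed
priority order `= c k m n j e o s x i y p u` and keeping the first match;
the best reference is the one yielding the highest-priority code, ties
broken by span distance then lexicographic id. Operational definitions:
`=` is intron-chain identity (single-exon pairs: reciprocal span overlap
≥ 80%, since exact boundary equality is unrealistic for aligned
assemblies); `c` containment in the reference's exons with every query
intron present in the reference; `k` the reference's intron chain as a
contiguous subchain of the query's; `m`/`n` the query span covering the
reference with all/some reference introns retained inside query exons;
`j` a shared splice junction (an exact intron); `e` a single-exon query
straddling an exon–intron boundary; `o` any other sense exonic overlap;
`s`/`x` the antisense counterparts (shared intron / exonic overlap);
`i`/`y` containment inside an intron (either strand, both directions);
`p` a same-strand neighbour within 2,000 bp (configurable) with no
overlap; `u` everything else. The TE filter tests exon blocks, not the
genomic span: a TE wholly inside an intron is not transcribed and does not
trigger removal. Overlap thresholds are strict ≥ 1 bp; bookended intervals
do not overlap.

The decision table: `=` against an mRNA is a prediction error (excluded);
`=` against an annotated lncRNA is a known lncRNA; `c k j m n o` may be
unannotated isoforms of coding genes (excluded); `e s p y` are treated as
assembly artefacts; `i`, `x`, `u` are the novel intronic, antisense and
intergenic lncRNAs.

## Conservation

The native search seeds with shared 11-mers (both orientations by
default, since lncRNA databases mix strands) and scores each candidate
pair with a local Smith–Waterman alignment (match +1, mismatch −1,
gap −2); identity is matches over alignment columns, gaps included. At
most one hit — the best (score, identity), ties to the lexicographically
smaller subject id — is reported per query. E-values are not re-derived;
the significance gate is identity ≥ 50% (inclusive) plus an alignment
covering ≥ 50% of the query. Precomputed 12-column blast-tab hits can be
ingested instead, gated at E ≤ 1e-50 and the same identity threshold. A
best hit in another species ⇒ conserved; only in the reference species ⇒
non-conserved; none ⇒ unmatched. Greedy clustering canonicalises input to
length-descending order (ties by id), so cluster membership is independent
of input order.

## Annotation statistics

"Expressed in a tissue" means TPM strictly greater than the threshold
(default 1) in at least one library of that tissue; the specificity cell
for (type, tissue) divides the expressed count by N_type (transcripts of
the type expressed in ≥ 1 tissue) and L_tissue (libraries of the tissue).
A type with N_type = 0 yields an NA row. Structure summaries exclude
transcripts with any intron < 60 bp (strict; such introns are implausible
splicing and typically de novo assembly artefacts) — the exclusion affects
structure statistics only, never expression or homology sets. Chromosome
densities are loci per megabase; windowed counts bin by interval midpoint
so totals are conserved. Antisense exon ordinals follow the reference's
transcription direction (exon 1 is 5′-most on the reference strand), and a
transcript overlapping several reference exons contributes one count per
overlapped exon.

Published-style report tables truncate percentages to integers (floor);
the exact fractions are emitted alongside, and the cascade table carries
both the share-of-input and share-of-previous-step conventions because
both are in circulation for tables of this kind.

## Synthetic data

`make_toy_world` emulates the shape of a real survey at desk scale: three
~100 kb chromosomes with mild AT-biased background, GC-rich coding exons,
~44 annotated genes, and 78 candidate transcripts placed so that every
verdict (known mRNA/lncRNA matches, sense-exonic, artefact, intronic,
antisense, intergenic) and every filter fate (noise fragment, TE overlap
— including an exactly-1-bp boundary case — and a < 60 bp intron, plus an
exactly-60 bp boundary) has at least five exemplars with a recorded,
machine-checkable expected outcome. Because transcripts are genome
substrings, alignments are emitted directly in the spliced-aligner GFF3
dialect rather than by running an aligner. The expression matrix spans
three tissues × two libraries with pollen-leaning values and cells exactly
at the TPM threshold; the homology library contains 10%-mutated
other-species homologs, same-species exact copies and decoys. Everything
derives from one `numpy` generator, so regeneration under a seed is
bit-identical.

The end-to-end truth test feeds the pipeline the generator's prediction
labels (the mRNA-copy candidates are deliberate "prediction errors" so the
`=`-against-mRNA branch is exercised); the classifier itself is validated
separately on `make_classifier_fixture`, whose mRNA-like sequences are
codon-structured (purine-biased first codon position, GC-biased third)
with probability `separation` and whose lncRNA-like sequences are AT-biased
i.i.d. — at separation 0 both classes collapse to the same uniform
generator. What passing these tests shows is that the interval algebra,
filters, thresholds and protocol arithmetic are exactly right and that a
separable signal is recovered; what they cannot show is real-world
classifier accuracy, since real mRNA/lncRNA discrimination is far noisier
than the synthetic composition gap, and the toy world has no alignment
error, no multi-isoform loci beyond the constructed cases, and no
sequencing noise.

## Problem sizes and determinism

Default experiment sizes — 600 sequences per class for classifier
recovery, 10,000 random geometries for the class-code oracle sweep, a
78-transcript toy world — were chosen so the whole validation suite runs
in a few minutes on one core while leaving every code path and boundary
exercised. All randomness flows from explicit integer seeds (replicates
use `seed + index`); reruns of the pipeline with an unchanged config are
detected via a hash manifest and skipped, and rerunning from scratch is
byte-identical.

## Known limitations

The classifier is not a re-implementation of any published tool's exact
feature algebra; it is a documented, reproducible feature set in the same
spirit. Alignment consumes a spliced aligner's GFF3 (best path only);
chimeric or multi-path alignments are out of scope. BLAST statistics
(E-values) are not reproduced natively. The noise filter is an operational
reading of "fragments that do not match their locus" — other readings
(e.g. strand-aware loci) are plausible and the thresholds are exposed as
configuration.
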