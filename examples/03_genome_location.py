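"""Classify aligned transcripts by genome location relative to a coding gene.

A three-exon reference gene is probed with queries in characteristic
positions; each receives one of the 14 single-character class codes and the
keep/exclude verdict used by the pipeline (novel lncRNAs are the intronic
'i', antisense 'x' and intergenic 'u' classes).
"""

from lncannotate.core import GenomicInterval, TranscriptModel
from lncannotate.location import apply_decision_table, assign_class_code


def make(tid, strand, exons, biotype="unknown"):
    return TranscriptModel(
        tid, tid, "chr1", strand,
        [GenomicInterval("chr1", s, e, strand) for s, e in exons], biotype,
    )


reference = [make("gene1.t1", "+", [(1000, 1300), (1700, 1950), (2300, 2600)], "mRNA")]

queries = {
    "exact copy":           make("q1", "+", [(1000, 1300), (1700, 1950), (2300, 2600)]),
    "inside exon (sense)":  make("q2", "+", [(1750, 1900)]),
    "inside intron":        make("q3", "+", [(1400, 1600)]),
    "antisense over exon":  make("q4", "-", [(1100, 1250)]),
    "straddles boundary":   make("q5", "+", [(1200, 1400)]),
    "run-on downstream":    make("q6", "+", [(3100, 3400)]),
    "far intergenic":       make("q7", "+", [(9000, 9400)]),
}

print(f"{'query':<22}{'code':<6}{'verdict'}")
for name, q in queries.items():
    code = assign_class_code(q, reference)
    verdict = apply_decision_table(code.code, "mRNA" if code.reference_id else None)
    print(f"{name:<22}{code.code:<6}{verdict}")
print(
    "\n'=' complete matches to mRNAs and sense-exonic/artefact classes are "
    "excluded;\n'i'/'x'/'u' survive as novel intronic, antisense and "
    "intergenic lncRNAs."
)
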