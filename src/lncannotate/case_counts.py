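"""Published step counts from a 15-library maize transcriptome case study.

These integer counts — the per-stage cascade for a de novo (Trinity) and a
reference-based (Hisat2/StringTie) assembly, the genome-location class
counts and the external-database similarity counts — are worked-example
inputs for the reporting helpers in :mod:`lncannotate.reports`.  They are
inputs, not outputs: nothing in this package recomputes them.
"""

TRINITY_CASCADE = {
    "input": 656_289,
    "length_filtering": 656_289,
    "predicted_noncoding": 450_504,
    "genome_alignment": 441_733,
    "noise_filtered": 101_207,
    "te_filtered": 40_203,
    "lncRNA_candidate_transcripts": 61_004,
    "lncRNA_candidate_loci": 52_526,
}

HISAT_CASCADE = {
    "input": 91_721,
    "length_filtering": 91_721,
    "predicted_noncoding": 21_186,
    "genome_alignment": 18_428,
    "noise_filtered": 9_837,
    "te_filtered": 6_128,
    "lncRNA_candidate_transcripts": 3_706,
    "lncRNA_candidate_loci": 3_583,
}

TRINITY_CLASS_COUNTS = {"antisense": 34_611, "intron": 17_043, "intergenic": 9_350}
HISAT_CLASS_COUNTS = {"antisense": 1_590, "intron": 180, "intergenic": 1_936}
TRINITY_KNOWN_LNCRNA = 306
HISAT_KNOWN_LNCRNA = 297

TRINITY_CONSERVATION = {
    "candidates": 61_004,
    "homologous": 8_808,
    "same_species": 8_165,
    "other_species": 643,
}
HISAT_CONSERVATION = {
    "candidates": 3_706,
    "homologous": 1_136,
    "same_species": 1_081,
    "other_species": 55,
}

# Training-set sizes of the maize reference annotation used for the
# balanced-dataset worked example.
KNOWN_LNCRNAS = 2_535
KNOWN_MRNAS = 33_725
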