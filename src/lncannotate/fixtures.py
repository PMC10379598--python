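"""Seeded synthetic toy data with machine-checkable ground truth.

:func:`make_toy_world` builds a miniature genome (3 chromosomes, ~100 kb
each), a reference annotation of protein-coding and lncRNA genes, TE
intervals, candidate transcripts drawn from the genome with controlled
perturbations, exact alignments, an expression matrix and a known-lncRNA
library — every input the pipeline needs — together with a truth table
recording each transcript's expected fate through every filter and the
final verdict.  Regeneration under the same seed is bit-identical.

:func:`make_classifier_fixture` builds the two-class sequence sets used to
test the coding/noncoding classifier: mRNA-like sequences with long,
codon-biased ORFs versus lncRNA-like sequences without them, with a
``separation`` dial from indistinguishable (0) to cleanly separable (1).

The generated transcripts are genome substrings, so alignments are emitted
directly in the spliced-aligner GFF3 dialect instead of invoking an
aligner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    reverse_complement,
)
from . import io as lio

__all__ = ["ToySizes", "ToyWorld", "make_toy_world", "make_classifier_fixture"]

BASES = np.array(list("ACGT"))

# Background (intergenic / intronic / lncRNA) base composition: mild AT bias.
NONCODING_P = np.array([0.30, 0.20, 0.20, 0.30])
# Coding exon base composition: GC-rich.
CODING_P = np.array([0.20, 0.30, 0.30, 0.20])


def _random_seq(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    return "".join(rng.choice(BASES, size=length, p=p))


def spliced_sequence(genome: dict[str, str], t: TranscriptModel) -> str:
    """Transcript sequence from the genome (reverse-complemented on '-')."""
    seq = "".join(genome[t.chrom][e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


@dataclass
class ToySizes:
    """Exemplar counts per category; every verdict and filter fate gets >= 5."""

    n_mrna_copy: int = 6          # '=' against an mRNA -> excluded
    n_lnc_copy: int = 6           # '=' against a known lncRNA
    n_coding_like: int = 8        # predicted coding, exits before alignment
    n_sense_exonic: int = 6       # 'c' inside a coding exon, sense
    n_artefact_e: int = 3         # 'e' straddling an exon-intron boundary
    n_artefact_p: int = 3         # 'p' run-on within 2 kb downstream
    n_intronic: int = 6           # 'i'
    n_antisense: int = 6          # 'x'
    n_intergenic: int = 6         # 'u', single exon
    n_noise_pairs: int = 6        # full-length keeper + short fragment
    n_short_intron: int = 6       # intron < 60 bp: structure-stats exclusion
    n_intron_boundary: int = 2    # intron exactly 60 bp: included
    n_te_overlap: int = 6         # exon overlaps a TE -> removed
    n_te_intron_safe: int = 2     # TE wholly inside an intron -> kept
    n_library_decoys: int = 4
    n_chromosomes: int = 3
    min_chrom_length: int = 100_000


@dataclass
class ToyWorld:
    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    annotation: list[TranscriptModel]
    te_intervals: list[GenomicInterval]
    candidates: list[TranscriptModel]       # aligned candidate transcripts
    transcripts: list[SequenceRecord]       # spliced candidate sequences
    predictions: pd.DataFrame               # transcript_id, score, label
    expression: ExpressionMatrix
    library: list[SequenceRecord]
    library_species: dict[str, str]
    truth: pd.DataFrame
    reference_species: str = "maize"


class _Placer:
    """Sequential slot allocator: round-robins chromosomes, keeps gaps."""

    def __init__(self, n_chroms: int, gap: int = 3000):
        self.chroms = [f"chr{i + 1}" for i in range(n_chroms)]
        self.cursor = {c: gap for c in self.chroms}
        self.gap = gap
        self._rr = itertools.cycle(self.chroms)

    def place(self, length: int) -> tuple[str, int]:
        chrom = next(self._rr)
        start = self.cursor[chrom] + self.gap
        self.cursor[chrom] = start + length
        return chrom, start

    def extend(self, chrom: str, end: int) -> None:
        self.cursor[chrom] = max(self.cursor[chrom], end)


def _mrna_gene(chrom: str, start: int, strand: str, gid: str) -> TranscriptModel:
    """Three-exon coding gene: 300/250/300 bp exons, 400/350 bp introns."""
    e1 = GenomicInterval(chrom, start, start + 300, strand)
    e2 = GenomicInterval(chrom, start + 700, start + 950, strand)
    e3 = GenomicInterval(chrom, start + 1300, start + 1600, strand)
    return TranscriptModel(f"{gid}.t1", gid, chrom, strand, [e1, e2, e3], "mRNA")


def _lnc_gene(chrom: str, start: int, strand: str, gid: str, multi: bool) -> TranscriptModel:
    if multi:
        exons = [
            GenomicInterval(chrom, start, start + 220, strand),
            GenomicInterval(chrom, start + 370, start + 620, strand),
        ]
    else:
        exons = [GenomicInterval(chrom, start, start + 420, strand)]
    return TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons, "lncRNA")


def make_toy_world(
    seed: int = 1,
    sizes: Optional[ToySizes] = None,
    out_dir: Optional[str | Path] = None,
) -> ToyWorld:
    """Generate the default toy world (optionally writing all files).

    See the module docstring; the truth table covers all seven verdicts and
    the noise, TE and short-intron filter fates.
    """
    sizes = sizes or ToySizes()
    rng = np.random.default_rng(seed)
    placer = _Placer(sizes.n_chromosomes)

    annotation: list[TranscriptModel] = []
    candidates: list[TranscriptModel] = []
    te_intervals: list[GenomicInterval] = []
    truth_rows: list[dict] = []
    gene_no = 0

    def new_gid() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"G{gene_no:04d}"

    def add_truth(tid, category, label, code, fate, structural_excluded=False,
                  conservation="NA"):
        truth_rows.append(
            {
                "transcript_id": tid,
                "category": category,
                "predicted_label": label,
                "class_code": code,
                "fate": fate,
                "structural_excluded": structural_excluded,
                "conservation": conservation,
            }
        )

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # --- candidates anchored on host coding genes -------------------------
    for i in range(sizes.n_mrna_copy):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        tid = f"T_mrnacopy_{i + 1}"
        candidates.append(
            TranscriptModel(tid, tid, host.chrom, host.strand, list(host.exons))
        )
        add_truth(tid, "mrna_copy", "noncoding", "=", "known_mrna_excluded")

    for i in range(sizes.n_lnc_copy):
        gid = new_gid()
        multi = i % 2 == 0
        length = 620 if multi else 420
        chrom, start = placer.place(length)
        host = _lnc_gene(chrom, start, strand(), gid, multi)
        annotation.append(host)
        tid = f"T_lnccopy_{i + 1}"
        candidates.append(
            TranscriptModel(tid, tid, host.chrom, host.strand, list(host.exons))
        )
        add_truth(tid, "lnc_copy", "noncoding", "=", "known_lncrna")

    coding_like_hosts = []
    for i in range(sizes.n_coding_like):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        coding_like_hosts.append(host)
        tid = f"T_codinglike_{i + 1}"
        candidates.append(
            TranscriptModel(tid, tid, host.chrom, host.strand, list(host.exons))
        )
        add_truth(tid, "coding_like", "coding", "NA", "predicted_coding")

    for i in range(sizes.n_sense_exonic):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        e2 = host.exons[1]
        tid = f"T_sense_{i + 1}"
        # 210 bp wholly inside the middle exon, same strand -> 'c'
        exon = GenomicInterval(host.chrom, e2.start + 20, e2.start + 230, host.strand)
        candidates.append(TranscriptModel(tid, tid, host.chrom, host.strand, [exon]))
        add_truth(tid, "sense_exonic", "noncoding", "c", "sense_exonic_excluded")

    for i in range(sizes.n_artefact_e):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        e1 = host.exons[0]
        tid = f"T_straddle_{i + 1}"
        # 260 bp crossing the first exon-intron boundary, same strand -> 'e'
        exon = GenomicInterval(host.chrom, e1.end - 140, e1.end + 120, host.strand)
        candidates.append(TranscriptModel(tid, tid, host.chrom, host.strand, [exon]))
        add_truth(tid, "artefact_e", "noncoding", "e", "artefact_excluded")

    for i in range(sizes.n_artefact_p):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        tid = f"T_runon_{i + 1}"
        gap = int(rng.integers(100, 1500))
        start = host.span.end + gap
        exon = GenomicInterval(host.chrom, start, start + 300, host.strand)
        candidates.append(TranscriptModel(tid, tid, host.chrom, host.strand, [exon]))
        placer.extend(host.chrom, exon.end)
        add_truth(tid, "artefact_p", "noncoding", "p", "artefact_excluded")

    for i in range(sizes.n_intronic):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        intron1 = host.introns[0]  # 400 bp
        tid = f"T_intronic_{i + 1}"
        s = "+" if i % 2 == 0 else "-"
        exon = GenomicInterval(host.chrom, intron1.start + 60, intron1.start + 310, s)
        candidates.append(TranscriptModel(tid, tid, host.chrom, s, [exon]))
        add_truth(tid, "intronic", "noncoding", "i", "intronic",
                  conservation="unmatched")

    for i in range(sizes.n_antisense):
        host = _mrna_gene(*placer.place(1600), strand(), new_gid())
        annotation.append(host)
        e1 = host.exons[0]
        anti = "-" if host.strand == "+" else "+"
        tid = f"T_antisense_{i + 1}"
        # inside the first exon, opposite strand -> 'x'
        exon = GenomicInterval(host.chrom, e1.start + 30, e1.start + 260, anti)
        candidates.append(TranscriptModel(tid, tid, host.chrom, anti, [exon]))
        add_truth(tid, "antisense", "noncoding", "x", "antisense")

    # --- isolated intergenic slots ---------------------------------------
    conserved_ids: list[str] = []
    nonconserved_ids: list[str] = []

    for i in range(sizes.n_intergenic):
        chrom, start = placer.place(450)
        s = strand()
        tid = f"T_intergenic_{i + 1}"
        exon = GenomicInterval(chrom, start, start + 450, s)
        candidates.append(TranscriptModel(tid, tid, chrom, s, [exon]))
        conserved_ids.append(tid)
        add_truth(tid, "intergenic", "noncoding", "u", "intergenic",
                  conservation="conserved")

    for i in range(sizes.n_noise_pairs):
        chrom, start = placer.place(500)
        s = strand()
        full_id, frag_id = f"T_noisefull_{i + 1}", f"T_noisefrag_{i + 1}"
        candidates.append(
            TranscriptModel(full_id, full_id, chrom, s,
                            [GenomicInterval(chrom, start, start + 500, s)])
        )
        candidates.append(
            TranscriptModel(frag_id, frag_id, chrom, s,
                            [GenomicInterval(chrom, start, start + 200, s)])
        )
        add_truth(full_id, "noise_full", "noncoding", "u", "intergenic",
                  conservation="unmatched")
        add_truth(frag_id, "noise_fragment", "noncoding", "NA", "noise_removed")

    for i in range(sizes.n_short_intron):
        chrom, start = placer.place(550)
        s = strand()
        tid = f"T_shortintron_{i + 1}"
        exons = [
            GenomicInterval(chrom, start, start + 250, s),
            GenomicInterval(chrom, start + 300, start + 550, s),  # intron 50 bp
        ]
        candidates.append(TranscriptModel(tid, tid, chrom, s, exons))
        add_truth(tid, "short_intron", "noncoding", "u", "intergenic",
                  structural_excluded=True, conservation="unmatched")

    for i in range(sizes.n_intron_boundary):
        chrom, start = placer.place(560)
        s = strand()
        tid = f"T_intron60_{i + 1}"
        exons = [
            GenomicInterval(chrom, start, start + 250, s),
            GenomicInterval(chrom, start + 310, start + 560, s),  # intron 60 bp
        ]
        candidates.append(TranscriptModel(tid, tid, chrom, s, exons))
        add_truth(tid, "intron_boundary", "noncoding", "u", "intergenic",
                  conservation="unmatched")

    for i in range(sizes.n_te_overlap):
        chrom, start = placer.place(300)
        s = strand()
        tid = f"T_teoverlap_{i + 1}"
        exon = GenomicInterval(chrom, start, start + 300, s)
        candidates.append(TranscriptModel(tid, tid, chrom, s, [exon]))
        if i == 0:
            # boundary exemplar: exactly 1 bp of overlap
            te_intervals.append(GenomicInterval(chrom, start - 99, start + 1))
        else:
            te_intervals.append(GenomicInterval(chrom, start + 50, start + 170))
        add_truth(tid, "te_overlap", "noncoding", "NA", "te_removed")

    for i in range(sizes.n_te_intron_safe):
        chrom, start = placer.place(800)
        s = strand()
        tid = f"T_tesafe_{i + 1}"
        exons = [
            GenomicInterval(chrom, start, start + 300, s),
            GenomicInterval(chrom, start + 500, start + 800, s),  # intron 200 bp
        ]
        candidates.append(TranscriptModel(tid, tid, chrom, s, exons))
        te_intervals.append(GenomicInterval(chrom, start + 350, start + 450))
        nonconserved_ids.append(tid)
        add_truth(tid, "te_intron_safe", "noncoding", "u", "intergenic",
                  conservation="non_conserved_same_species")

    # antisense exemplars are the same-species homolog set
    for row in truth_rows:
        if row["category"] == "antisense":
            row["conservation"] = "non_conserved_same_species"
            nonconserved_ids.append(row["transcript_id"])

    # --- genome sequence ---------------------------------------------------
    chrom_lengths = {
        c: max(placer.cursor[c] + placer.gap, sizes.min_chrom_length)
        for c in placer.chroms
    }
    genome: dict[str, str] = {}
    for chrom in placer.chroms:
        arr = np.array(list(_random_seq(rng, chrom_lengths[chrom], NONCODING_P)))
        for t in annotation:
            if t.biotype == "mRNA" and t.chrom == chrom:
                for e in t.exons:
                    arr[e.start : e.end] = list(_random_seq(rng, len(e), CODING_P))
        genome[chrom] = "".join(arr)

    transcripts = [
        SequenceRecord(t.transcript_id, spliced_sequence(genome, t))
        for t in candidates
    ]
    seq_of = {r.id: r.seq for r in transcripts}

    # --- predictions (ground truth route) ---------------------------------
    predictions = pd.DataFrame(
        [
            {
                "transcript_id": row["transcript_id"],
                "score": 0.05 if row["predicted_label"] == "coding" else 0.95,
                "label": row["predicted_label"],
            }
            for row in truth_rows
        ]
    )

    # --- known-lncRNA library ---------------------------------------------
    library: list[SequenceRecord] = []
    library_species: dict[str, str] = {}

    def mutate(seq: str, rate: float) -> str:
        out = list(seq)
        for j in range(len(out)):
            if rng.random() < rate:
                out[j] = str(rng.choice(BASES[BASES != out[j]]))
        return "".join(out)

    for i, tid in enumerate(conserved_ids):
        sid = f"LIB_sorghum_{i + 1}"
        library.append(SequenceRecord(sid, mutate(seq_of[tid], 0.10)))
        library_species[sid] = "sorghum"
    for i, tid in enumerate(nonconserved_ids):
        sid = f"LIB_maize_{i + 1}"
        library.append(SequenceRecord(sid, seq_of[tid]))
        library_species[sid] = "maize"
    for i in range(sizes.n_library_decoys):
        sid = f"LIB_decoy_{i + 1}"
        library.append(SequenceRecord(sid, _random_seq(rng, 400, NONCODING_P)))
        library_species[sid] = "sorghum"

    # --- expression matrix -------------------------------------------------
    tissue_libs = {
        "leaf": ["leaf_1", "leaf_2"],
        "root": ["root_1", "root_2"],
        "pollen": ["pollen_1", "pollen_2"],
    }
    libraries = [l for libs in tissue_libs.values() for l in libs]
    tids = [r.id for r in transcripts]
    values = pd.DataFrame(0.0, index=tids, columns=libraries)
    for tid in tids:
        for tissue, libs in tissue_libs.items():
            # pollen-heavy expression; some transcripts silent in a tissue
            base = {"leaf": 1.5, "root": 1.0, "pollen": 6.0}[tissue]
            for lib in libs:
                if rng.random() < 0.35:
                    continue
                values.loc[tid, lib] = round(float(rng.gamma(2.0, base)), 3)
    # boundary cells: TPM exactly at the default threshold (not expressed)
    for tid in tids[:3]:
        values.loc[tid, :] = 0.0
        values.loc[tid, "leaf_1"] = 1.0
    expression = ExpressionMatrix(values, {l: t for t, ls in tissue_libs.items() for l in ls})

    truth = pd.DataFrame(truth_rows)
    world = ToyWorld(
        genome=genome,
        chrom_lengths=chrom_lengths,
        annotation=annotation,
        te_intervals=te_intervals,
        candidates=candidates,
        transcripts=transcripts,
        predictions=predictions,
        expression=expression,
        library=library,
        library_species=library_species,
        truth=truth,
    )
    if out_dir is not None:
        write_toy_world(world, out_dir)
    return world


def write_toy_world(world: ToyWorld, out_dir: str | Path) -> dict[str, Path]:
    """Emit every toy-world file in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("genome", "genome.fasta"),
        ("annotation", "annotation.gff3"),
        ("alignments", "alignments.gff3"),
        ("te", "te.gff3"),
        ("transcripts", "transcripts.fasta"),
        ("predictions", "predictions.tsv"),
        ("expression", "expression.tsv"),
        ("library_meta", "libraries.tsv"),
        ("lncrna_library", "lncrna_library.fasta"),
        ("species_map", "library_species.tsv"),
        ("chrom_lengths", "chrom_lengths.tsv"),
        ("truth", "truth_table.tsv"),
    ]}

    lio.write_fasta(
        [SequenceRecord(c, s) for c, s in world.genome.items()], paths["genome"]
    )
    lio.write_annotation_gff3(world.annotation, paths["annotation"])
    lio.write_transcripts_gff3(world.candidates, paths["alignments"], source="aligner")
    with open(paths["te"], "w") as fh:
        fh.write("##gff-version 3\n")
        for i, te in enumerate(world.te_intervals, start=1):
            fh.write(
                f"{te.chrom}\ttoy\ttransposable_element\t{te.start + 1}\t{te.end}"
                f"\t.\t.\t.\tID=TE{i:04d}\n"
            )
    lio.write_fasta(world.transcripts, paths["transcripts"])
    world.predictions.to_csv(paths["predictions"], sep="\t", index=False)
    world.expression.values.to_csv(paths["expression"], sep="\t", index_label="transcript_id")
    pd.DataFrame(
        {"library": list(world.expression.library_meta),
         "tissue": list(world.expression.library_meta.values())}
    ).to_csv(paths["library_meta"], sep="\t", index=False)
    with open(paths["lncrna_library"], "w") as fh:
        for rec in world.library:
            fh.write(f">{rec.id} species={world.library_species[rec.id]}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")
    pd.DataFrame(
        {"subject_id": list(world.library_species),
         "species": list(world.library_species.values())}
    ).to_csv(paths["species_map"], sep="\t", index=False)
    pd.DataFrame(
        {"chrom": list(world.chrom_lengths),
         "length": list(world.chrom_lengths.values())}
    ).to_csv(paths["chrom_lengths"], sep="\t", index=False)
    world.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# --- classifier fixture ----------------------------------------------------

_CODON_BASES = list("ACGT")


def _coding_sequence(rng: np.random.Generator, length: int) -> str:
    """Codon-structured sequence: 5' UTR + ATG + biased codons + stop + 3' UTR.

    Codon bias (purine-rich first position, GC-rich third position) gives
    the hexamer and period-3 spectral signal typical of real coding
    sequence.
    """
    pos1 = np.array([0.35, 0.15, 0.35, 0.15])  # A,C,G,T
    pos2 = np.array([0.25, 0.25, 0.25, 0.25])
    pos3 = np.array([0.10, 0.40, 0.40, 0.10])
    utr5 = int(rng.integers(10, 50))
    utr3_min = 10
    n_codons = max(30, (length - utr5 - utr3_min - 6) // 3)
    codons = []
    while len(codons) < n_codons:
        codon = "".join(
            str(rng.choice(BASES, p=p)) for p in (pos1, pos2, pos3)
        )
        if codon not in ("TAA", "TAG", "TGA"):
            codons.append(codon)
    seq = (
        _random_seq(rng, utr5, NONCODING_P)
        + "ATG"
        + "".join(codons)
        + "TAA"
    )
    if len(seq) < length:
        seq += _random_seq(rng, length - len(seq), NONCODING_P)
    return seq[:length] if len(seq) > length else seq


def make_classifier_fixture(
    seed: int = 1,
    n_per_class: int = 600,
    separation: float = 1.0,
    min_length: int = 200,
    max_length: int = 900,
    mrna_factor: int = 2,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two-class training fixture: ``(lncrna_records, mrna_records)``.

    ``mrna_factor`` x as many mRNAs as lncRNAs are emitted so the balanced
    1:2 sampling protocol has a full pool to draw from.

    Each mRNA-like sequence is codon-structured with probability
    ``separation`` (otherwise uniform random); each lncRNA-like sequence is
    drawn from the AT-biased noncoding composition with probability
    ``separation``.  At separation 0 both classes are the identical uniform
    generator (no signal); at 1 they are cleanly separable.  All sequences
    are at least ``min_length`` (>= 200 nt, the lncRNA length convention).
    """
    if n_per_class < 50:
        raise ValueError("n_per_class must be >= 50")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    uniform = np.full(4, 0.25)

    mrnas, lncrnas = [], []
    for i in range(mrna_factor * n_per_class):
        length = int(rng.integers(min_length, max_length + 1))
        if rng.random() < separation:
            seq = _coding_sequence(rng, length)
        else:
            seq = _random_seq(rng, length, uniform)
        mrnas.append(SequenceRecord(f"MRNA_{i + 1:04d}", seq))
    for i in range(n_per_class):
        length = int(rng.integers(min_length, max_length + 1))
        p = NONCODING_P if rng.random() < separation else uniform
        lncrnas.append(SequenceRecord(f"LNC_{i + 1:04d}", _random_seq(rng, length, p)))
    return lncrnas, mrnas
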