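"""Readers and writers for the external formats the pipeline touches.

Supported formats: FASTA (sequences), GFF3/GTF (reference annotation,
spliced-aligner output, TE intervals), the 12-column tab-separated homology
hit dialect (blast ``-outfmt 6``), and the TSV expression matrix with its
2-column library-metadata table.

GFF3/GTF coordinates (1-based, inclusive) are converted to the internal
0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.feature import feature_from_line

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    HomologyHit,
    SequenceRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "BiotypeRules",
    "read_gff3_transcripts",
    "read_gff3_intervals",
    "write_transcripts_gff3",
    "write_annotation_gff3",
    "write_loci_bed",
    "write_loci_gff3",
    "read_tabular_hits",
    "read_expression",
]


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` s.

    The id is the header token before the first whitespace.  DNA sequences
    are uppercased with U->T and IUPAC ambiguity codes collapsed to N.
    Duplicate ids raise; an empty file returns an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet=alphabet))
    if not records:
        logger.warning("FASTA file %s contains no sequences", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class BiotypeRules:
    """Configurable assignment of transcript biotypes from GFF3/GTF records.

    Precedence: an attribute rule (``attribute_key`` whose value is looked up
    in ``attribute_map``) wins over the feature-type rule; unmatched
    transcripts get ``default``.  Annotation dialects differ in which
    attribute marks known lncRNAs, so both layers are user-configurable.
    """

    feature_type_map: dict[str, str] = field(
        default_factory=lambda: {
            "mRNA": "mRNA",
            "lnc_RNA": "lncRNA",
            "lncRNA": "lncRNA",
            "lincRNA": "lncRNA",
            "ncRNA": "lncRNA",
        }
    )
    attribute_key: Optional[str] = "biotype"
    attribute_map: dict[str, str] = field(
        default_factory=lambda: {
            "protein_coding": "mRNA",
            "lncRNA": "lncRNA",
            "lincRNA": "lncRNA",
            "antisense": "lncRNA",
        }
    )
    default: str = "unknown"

    def biotype_of(self, featuretype: str, attributes) -> str:
        if self.attribute_key and self.attribute_key in attributes:
            value = attributes[self.attribute_key][0]
            if value in self.attribute_map:
                return self.attribute_map[value]
        return self.feature_type_map.get(featuretype, self.default)


DEFAULT_TRANSCRIPT_TYPES = (
    "mRNA",
    "lnc_RNA",
    "lncRNA",
    "lincRNA",
    "ncRNA",
    "transcript",
)


def _first_attr(attributes, *keys: str) -> Optional[str]:
    for key in keys:
        if key in attributes and attributes[key]:
            return attributes[key][0]
    return None


def read_gff3_transcripts(
    path: str | Path,
    feature_types: Sequence[str] = DEFAULT_TRANSCRIPT_TYPES,
    biotype_rules: Optional[BiotypeRules] = None,
    prefer_name: bool = False,
) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or GTF.

    Transcript-level features (``feature_types``) are collected with their
    ``exon`` children, linked through Parent/transcript_id attributes; GTF
    attribute syntax is sniffed per line by gffutils.  Transcripts lacking
    exon children become single-exon models over their span.  Exons whose
    parent cannot be resolved are skipped (count logged).  Transcript id
    precedence: ``ID``/``transcript_id`` attribute, then ``Parent`` plus a
    running index.  Spliced aligners suffix their mRNA feature IDs (e.g.
    ``.mrna1``) and keep the input transcript id in ``Name``; pass
    ``prefer_name=True`` to recover the original ids.
    """
    rules = biotype_rules or BiotypeRules()
    wanted = set(feature_types)
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    alias: dict[str, str] = {}  # raw feature ID -> canonical transcript id
    orphan_exons = 0
    anon = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.end < feat.start:
                raise ValueError(f"{path}:{lineno}: end < start")
            strand = feat.strand if feat.strand in "+-" else "+"
            if feat.featuretype in wanted:
                if prefer_name:
                    tid = _first_attr(feat.attributes, "Name", "ID", "transcript_id")
                else:
                    tid = _first_attr(feat.attributes, "ID", "transcript_id")
                if tid is None:
                    parent = _first_attr(feat.attributes, "Parent", "gene_id")
                    anon += 1
                    tid = f"{parent or 'transcript'}.{anon}"
                raw_id = _first_attr(feat.attributes, "ID", "transcript_id")
                if raw_id:
                    alias[raw_id] = tid
                gene = _first_attr(feat.attributes, "Parent", "gene_id", "geneID") or tid
                transcripts[tid] = {
                    "gene_id": gene,
                    "chrom": feat.seqid,
                    "strand": strand,
                    "span": GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand),
                    "biotype": rules.biotype_of(feat.featuretype, feat.attributes),
                }
            elif feat.featuretype == "exon":
                parent = _first_attr(feat.attributes, "Parent", "transcript_id")
                if parent is None:
                    orphan_exons += 1
                    continue
                for pid in (
                    feat.attributes["Parent"]
                    if "Parent" in feat.attributes
                    else [parent]
                ):
                    exons.setdefault(alias.get(pid, pid), []).append(
                        GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
                    )

    dangling = sum(1 for pid in exons if pid not in transcripts)
    if orphan_exons or dangling:
        logger.warning(
            "%s: skipped %d exon rows without a resolvable Parent",
            path,
            orphan_exons + dangling,
        )

    models = []
    for tid, info in transcripts.items():
        chain = exons.get(tid) or [info["span"]]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=chain,
                biotype=info["biotype"],
            )
        )
    return models


def read_gff3_intervals(path: str | Path, feature_types: Optional[set[str]] = None) -> list[GenomicInterval]:
    """Read plain intervals (e.g. TE annotations) from a GFF3 file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.end < feat.start:
                raise ValueError(f"{path}:{lineno}: end < start")
            if feature_types and feat.featuretype not in feature_types:
                continue
            strand = feat.strand if feat.strand in "+-" else "."
            out.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand))
    return out


def write_transcripts_gff3(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncannotate",
) -> None:
    """Write transcript models as gene/mRNA/exon GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            span = t.span
            fh.write(
                f"{t.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\tID={t.gene_id}.path1;Name={t.gene_id}\n"
            )
            fh.write(
                f"{t.chrom}\t{source}\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id}.mrna1;Name={t.transcript_id};"
                f"Parent={t.gene_id}.path1\n"
            )
            for i, e in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id}.mrna1.exon{i};"
                    f"Name={t.transcript_id};Parent={t.transcript_id}.mrna1\n"
                )


def write_annotation_gff3(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncannotate",
) -> None:
    """Write a reference annotation: gene + mRNA/lnc_RNA + exon per model.

    The transcript feature type follows the biotype (``lnc_RNA`` for
    lncRNA, ``mRNA`` otherwise), which the default :class:`BiotypeRules`
    round-trips.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            span = t.span
            ttype = "lnc_RNA" if t.biotype == "lncRNA" else "mRNA"
            fh.write(
                f"{t.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\tID={t.gene_id}\n"
            )
            fh.write(
                f"{t.chrom}\t{source}\t{ttype}\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for i, e in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                )


def write_loci_bed(loci, path: str | Path) -> None:
    """Write loci as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{locus.locus_id}\t{len(locus.members)}\t.\n")


def write_loci_gff3(loci, path: str | Path, source: str = "lncannotate") -> None:
    """Write loci as strandless GFF3 features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            iv = locus.interval
            fh.write(
                f"{iv.chrom}\t{source}\tlncRNA_locus\t{iv.start + 1}\t{iv.end}\t.\t.\t.\t"
                f"ID={locus.locus_id};transcripts={','.join(locus.members)}\n"
            )


_HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_tabular_hits(path: str | Path) -> list[HomologyHit]:
    """Read 12-column blast-tab (``-outfmt 6``) homology hits.

    No filtering is applied at parse time; identity/E-value thresholds are
    downstream concerns.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            row = dict(zip(_HIT_COLUMNS, fields))
            hits.append(
                HomologyHit(
                    query_id=row["query"],
                    subject_id=row["subject"],
                    percent_identity=float(row["pident"]),
                    alignment_length=int(row["length"]),
                    evalue=float(row["evalue"]),
                )
            )
    return hits


def read_expression(path_matrix: str | Path, path_meta: str | Path) -> ExpressionMatrix:
    """Read a transcripts x libraries TPM matrix and its library->tissue map.

    Libraries present in the matrix must appear in the metadata; extra
    metadata rows are accepted with a warning.
    """
    values = pd.read_csv(path_matrix, sep="\t", index_col=0)
    meta = pd.read_csv(path_meta, sep="\t", header=0)
    if meta.shape[1] < 2:
        raise ValueError(f"{path_meta}: expected 2 columns (library, tissue)")
    library_meta = dict(zip(meta.iloc[:, 0].astype(str), meta.iloc[:, 1].astype(str)))
    missing = [c for c in values.columns if c not in library_meta]
    if missing:
        raise ValueError(f"libraries missing from {path_meta}: {missing}")
    unused = [l for l in library_meta if l not in set(values.columns)]
    if unused:
        logger.warning("metadata lists %d libraries absent from the matrix: %s", len(unused), unused)
    return ExpressionMatrix(values, library_meta)
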