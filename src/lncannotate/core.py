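"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based half-open internally; conversion to and
from the 1-based inclusive GFF3/GTF convention happens only at I/O
boundaries (:mod:`lncannotate.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_DNA_NORMALISE = str.maketrans(
    {
        "U": "T",
        "R": "N", "Y": "N", "S": "N", "W": "N", "K": "N", "M": "N",
        "B": "N", "D": "N", "H": "N", "V": "N", "X": "N", "-": "N", ".": "N",
    }
)


def normalise_dna(seq: str) -> str:
    """Uppercase, U->T, and collapse IUPAC ambiguity codes to N."""
    return seq.upper().translate(_DNA_NORMALISE)


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide (or peptide) sequence."""

    id: str
    seq: str
    alphabet: str = "dna"  # {"dna", "protein"}

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if self.alphabet == "dna":
            norm = normalise_dna(self.seq)
            object.__setattr__(self, "seq", norm)
            if norm and set(norm) - set("ACGTN"):
                raise ValueError(f"invalid DNA characters in record {self.id!r}")
        else:
            object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp; 0 for different chromosomes or bookended intervals."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An exon chain on one chromosome and strand.

    Exons are sorted, disjoint ``GenomicInterval`` s; introns are the gaps
    between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = "unknown"  # {mRNA, lncRNA, other, unknown}

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            # touching exons would imply a zero-length intron
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping or touching "
                    f"exons [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom} != {self.chrom}"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns)

    @property
    def length(self) -> int:
        """Transcript length = sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1


class ExpressionMatrix:
    """TPM values per transcript x library plus a library -> tissue map."""

    def __init__(self, values: pd.DataFrame, library_meta: Mapping[str, str]):
        missing = [c for c in values.columns if c not in library_meta]
        if missing:
            raise ValueError(f"libraries missing from metadata: {missing}")
        if (values.to_numpy() < 0).any():
            bad = values.columns[(values < 0).any(axis=0)].tolist()
            raise ValueError(f"negative TPM values in libraries {bad}")
        self.values = values.astype(float)
        self.library_meta = {c: library_meta[c] for c in values.columns}

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.library_meta.values():
            seen.setdefault(t)
        return list(seen)

    def libraries_of(self, tissue: str) -> list[str]:
        return [l for l, t in self.library_meta.items() if t == tissue]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.equals(other.values)
            and self.library_meta == other.library_meta
        )


@dataclass(frozen=True)
class HomologyHit:
    """Best-scoring local alignment of a query against a library sequence."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: Optional[float] = None
    subject_species: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"identity {self.percent_identity} out of [0, 100]")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be >= 0")
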