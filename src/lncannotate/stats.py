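"""Downstream annotation statistics.

Expression tissue specificity (expressed transcripts per library per
tissue), exon/intron structural summaries with the short-intron exclusion,
per-chromosome locus density with windowed counts, and the antisense
exon-ordinal profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenomicInterval, TranscriptModel
from .location import Locus

__all__ = [
    "expression_specificity",
    "StructuralSummary",
    "structural_stats",
    "chromosome_density",
    "antisense_exon_profile",
]

RNA_TYPES = ("conserved_lncRNA", "non_conserved_lncRNA", "mRNA")


def expression_specificity(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Expressed-transcripts-per-library-per-tissue, per RNA type.

    A transcript is expressed in a tissue when its TPM is strictly greater
    than ``threshold`` in at least one library of that tissue.  Cell value
    for (type, tissue) = expressed_count / (N_type * L_tissue) where N_type
    is the number of transcripts of that type expressed in >= 1 tissue and
    L_tissue the number of libraries mapped to the tissue.  A type with
    N_type = 0 yields an all-NA row.
    """
    missing = [t for t in groups if t not in set(matrix.transcripts)]
    if missing:
        raise ValueError(f"grouped transcripts absent from matrix: {missing[:10]}")
    tissues = matrix.tissues
    for tissue in tissues:
        if not matrix.libraries_of(tissue):
            raise ValueError(f"tissue {tissue!r} has no libraries")

    types = sorted(set(groups.values()))
    expressed_in: dict[str, dict[str, bool]] = {}
    for tid in groups:
        row = matrix.values.loc[tid]
        expressed_in[tid] = {
            tissue: bool((row[matrix.libraries_of(tissue)] > threshold).any())
            for tissue in tissues
        }

    out = pd.DataFrame(index=types, columns=tissues, dtype=float)
    for rna_type in types:
        members = [t for t, g in groups.items() if g == rna_type]
        n_type = sum(1 for t in members if any(expressed_in[t].values()))
        for tissue in tissues:
            if n_type == 0:
                out.loc[rna_type, tissue] = float("nan")
                continue
            count = sum(1 for t in members if expressed_in[t][tissue])
            out.loc[rna_type, tissue] = count / (n_type * len(matrix.libraries_of(tissue)))
    return out


@dataclass
class StructuralSummary:
    """Exon/intron statistics of a transcript set.

    Transcripts carrying any intron shorter than the minimum are excluded
    from this summary only; they remain in expression and homology
    analyses.
    """

    n_transcripts: int
    excluded: dict[str, str]  # transcript_id -> reason
    exon_count_histogram: dict[int, int]
    exon_lengths: list[int]
    intron_lengths: list[int]
    mean_transcript_length: float

    def _dist(self, values: list[int]) -> dict[str, float]:
        if not values:
            return {"mean": float("nan"), "median": float("nan"),
                    "min": float("nan"), "max": float("nan")}
        arr = np.asarray(values)
        return {
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    def table(self) -> pd.Series:
        """The nine-row structural characteristics table."""
        exon = self._dist(self.exon_lengths)
        intron = self._dist(self.intron_lengths)
        return pd.Series(
            {
                "Mean exon length": exon["mean"],
                "Max. exon length": exon["max"],
                "Min. exon length": exon["min"],
                "Median exon length": exon["median"],
                "Mean transcript length": self.mean_transcript_length,
                "Mean intron length": intron["mean"],
                "Max. intron length": intron["max"],
                "Min. intron length": intron["min"],
                "Median intron length": intron["median"],
            }
        )


def structural_stats(
    transcripts: Sequence[TranscriptModel], min_intron: int = 60
) -> StructuralSummary:
    """Exon/intron distributions over transcripts without suspicious introns.

    Introns shorter than ``min_intron`` (default 60 bp, strict <) are
    implausible splicing and usually de novo assembly artefacts; their
    transcripts are listed in ``excluded`` and left out of the summary.
    """
    excluded: dict[str, str] = {}
    kept: list[TranscriptModel] = []
    for t in transcripts:
        short = [len(i) for i in t.introns if len(i) < min_intron]
        if short:
            excluded[t.transcript_id] = f"intron < {min_intron} bp (shortest {min(short)})"
        else:
            kept.append(t)

    exon_lengths = [len(e) for t in kept for e in t.exons]
    intron_lengths = [len(i) for t in kept for i in t.introns]
    histogram: dict[int, int] = {}
    for t in kept:
        histogram[len(t.exons)] = histogram.get(len(t.exons), 0) + 1
    mean_len = float(np.mean([t.length for t in kept])) if kept else float("nan")
    return StructuralSummary(
        n_transcripts=len(kept),
        excluded=excluded,
        exon_count_histogram=dict(sorted(histogram.items())),
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        mean_transcript_length=mean_len,
    )


def chromosome_density(
    loci: Sequence[Locus],
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
    gene_spans: Optional[Sequence[GenomicInterval]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome locus density and fixed-window counts.

    Density is loci per megabase.  Windowed counts bin each locus (and,
    when given, each protein-coding gene span) by the midpoint of its
    interval, so totals are conserved.
    """
    for locus in loci:
        if locus.interval.chrom not in chrom_lengths:
            raise ValueError(f"locus on unknown chromosome {locus.interval.chrom!r}")

    density_rows = []
    for chrom in sorted(chrom_lengths):
        n = sum(1 for l in loci if l.interval.chrom == chrom)
        density_rows.append(
            {
                "chrom": chrom,
                "length_bp": chrom_lengths[chrom],
                "loci": n,
                "density_per_mb": n / (chrom_lengths[chrom] / 1e6),
            }
        )

    window_rows = []
    def midpoint_bin(iv: GenomicInterval) -> int:
        return ((iv.start + iv.end) // 2) // window

    for chrom in sorted(chrom_lengths):
        n_windows = max(1, math.ceil(chrom_lengths[chrom] / window))
        locus_counts = np.zeros(n_windows, dtype=int)
        gene_counts = np.zeros(n_windows, dtype=int)
        for l in loci:
            if l.interval.chrom == chrom:
                locus_counts[min(midpoint_bin(l.interval), n_windows - 1)] += 1
        for g in gene_spans or []:
            if g.chrom == chrom:
                gene_counts[min(midpoint_bin(g), n_windows - 1)] += 1
        for w in range(n_windows):
            window_rows.append(
                {
                    "chrom": chrom,
                    "window_start": w * window,
                    "lncRNA_loci": int(locus_counts[w]),
                    "protein_coding_genes": int(gene_counts[w]),
                }
            )
    return pd.DataFrame(density_rows), pd.DataFrame(window_rows)


def antisense_exon_profile(
    antisense_transcripts: Sequence[TranscriptModel],
    matched_reference: Mapping[str, str],
    annotation: Sequence[TranscriptModel],
) -> pd.DataFrame:
    """Histogram of overlapped reference exon ordinals for antisense lncRNAs.

    Exon 1 is the 5'-most exon in the reference's transcription direction.
    Every reference exon overlapped by the antisense transcript contributes
    one count at its ordinal; counts are also reported as fractions.
    """
    ref_by_id = {t.transcript_id: t for t in annotation}
    counts: dict[int, int] = {}
    for t in antisense_transcripts:
        ref_id = matched_reference.get(t.transcript_id)
        if ref_id is None or ref_id not in ref_by_id:
            raise ValueError(
                f"antisense transcript {t.transcript_id!r} has no matched reference"
            )
        ref = ref_by_id[ref_id]
        exons = ref.exons if ref.strand == "+" else list(reversed(ref.exons))
        for ordinal, exon in enumerate(exons, start=1):
            if any(exon.overlap(qe) > 0 for qe in t.exons):
                counts[ordinal] = counts.get(ordinal, 0) + 1
    total = sum(counts.values())
    rows = [
        {"exon_ordinal": k, "count": v, "fraction": v / total if total else float("nan")}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["exon_ordinal", "count", "fraction"])
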