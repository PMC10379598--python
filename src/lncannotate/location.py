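"""Interval and strand algebra over aligned candidate transcripts.

Covers locus construction, the assembly-noise filter, the transposable
element filter, gffcompare-style class-code assignment (the 14
single-character location classes) and the keep/exclude decision table that
turns a class code into a lncRNA verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "ClassCode",
    "CLASS_CODE_PRIORITY",
    "VERDICTS",
    "build_loci",
    "assign_class_code",
    "noise_filter",
    "te_filter",
    "apply_decision_table",
]

# Priority order in which class predicates are tested; the first match wins.
CLASS_CODE_PRIORITY = "=ckmnjeosxiypu"

VERDICTS = (
    "known_mrna_excluded",
    "known_lncrna",
    "sense_exonic_excluded",
    "artefact_excluded",
    "intronic",
    "antisense",
    "intergenic",
)


@dataclass
class Locus:
    """A maximal merged (strandless) genomic region covered by candidates."""

    locus_id: str
    interval: GenomicInterval
    members: list[str]


def build_loci(aligned: Sequence[TranscriptModel]) -> list[Locus]:
    """Merge aligned spans transitively wherever they overlap by >= 1 bp.

    Strand is ignored; bookended (touching) spans stay separate.  Every
    transcript lands in exactly one locus; output is sorted by
    (chrom, start).  Idempotent: merging the locus spans again reproduces
    the same loci.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in aligned:
        by_chrom.setdefault(t.chrom, []).append(t)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: (t.span.start, t.span.end, t.transcript_id))
        cur_start, cur_end, cur_members = None, None, []
        for t in ts:
            s, e = t.span.start, t.span.end
            if cur_start is None or s >= cur_end:  # bookended -> new locus
                if cur_start is not None:
                    loci.append(
                        Locus("", GenomicInterval(chrom, cur_start, cur_end), cur_members)
                    )
                cur_start, cur_end, cur_members = s, e, [t.transcript_id]
            else:
                cur_end = max(cur_end, e)
                cur_members.append(t.transcript_id)
        if cur_start is not None:
            loci.append(Locus("", GenomicInterval(chrom, cur_start, cur_end), cur_members))

    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"LOC{i:06d}"
    return loci


# --- class codes ----------------------------------------------------------


@dataclass(frozen=True)
class ClassCode:
    """One of the 14 single-character location classes plus its reference."""

    code: str
    reference_id: Optional[str]  # None only for 'u'


def _exonic_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    return any(qe.overlap(re) > 0 for qe in q.exons for re in r.exons)


def _contained_in_exons(q: TranscriptModel, r: TranscriptModel) -> bool:
    return all(any(re.contains(qe) for re in r.exons) for qe in q.exons)


def _is_subchain(sub: tuple, chain: tuple) -> bool:
    """True when ``sub`` appears as a contiguous run inside ``chain``."""
    if not sub:
        return False
    n, m = len(chain), len(sub)
    return any(chain[i : i + m] == sub for i in range(n - m + 1))


def _span_distance(q: TranscriptModel, r: TranscriptModel) -> int:
    qs, rs = q.span, r.span
    if qs.overlap(rs) > 0:
        return 0
    return max(rs.start - qs.end, qs.start - rs.end, 0)


def code_for_pair(
    q: TranscriptModel,
    r: TranscriptModel,
    run_on_distance: int = 2000,
    single_exon_match_fraction: float = 0.8,
) -> str:
    """Class code of query ``q`` against a single reference ``r``.

    Predicates are evaluated in :data:`CLASS_CODE_PRIORITY` order.
    """
    if q.chrom != r.chrom:
        return "u"
    same = q.strand == r.strand
    q_introns = q.intron_chain
    r_introns = r.intron_chain
    span_overlap = q.span.overlap(r.span)

    # '=': identical intron chain; single-exon pairs need reciprocal
    # span overlap >= single_exon_match_fraction.
    if same:
        if q_introns and r_introns and q_introns == r_introns:
            return "="
        if not q_introns and not r_introns:
            if (
                span_overlap >= single_exon_match_fraction * len(q.span)
                and span_overlap >= single_exon_match_fraction * len(r.span)
            ):
                return "="
        # 'c': query contained in reference exons, intron-compatible.
        if _contained_in_exons(q, r) and all(i in r_introns for i in q_introns):
            return "c"
        # 'k': query contains the reference intron chain.
        if r_introns and _is_subchain(r_introns, q_introns):
            return "k"
        covers = q.span.start <= r.span.start and q.span.end >= r.span.end
        if covers and r_introns:
            retained = sum(
                1 for ri in r.introns if any(qe.contains(ri) for qe in q.exons)
            )
            # 'm': all reference introns retained inside query exons.
            if retained == len(r_introns):
                return "m"
            # 'n': some but not all retained.
            if retained >= 1:
                return "n"
        # 'j': shares at least one splice junction.
        if q_introns and r_introns and set(q_introns) & set(r_introns):
            return "j"
        # 'e': single-exon query straddling an exon-intron boundary.
        if not q_introns and any(qe.overlap(re) > 0 for qe in q.exons for re in r.exons) and any(
            qe.overlap(ri) > 0 for qe in q.exons for ri in r.introns
        ):
            return "e"
        # 'o': any other same-strand exonic overlap.
        if _exonic_overlap(q, r):
            return "o"
    else:
        # 's': a query intron exactly matches a reference intron (antisense).
        if q_introns and r_introns and set(q_introns) & set(r_introns):
            return "s"
        # 'x': exonic overlap on the opposite strand.
        if _exonic_overlap(q, r):
            return "x"
    # 'i': query fully inside one reference intron (either strand).
    if any(ri.contains(q.span) for ri in r.introns):
        return "i"
    # 'y': reference fully inside a query intron (either strand).
    if any(qi.contains(r.span) for qi in q.introns):
        return "y"
    # 'p': same-strand run-on within run_on_distance, no overlap.
    if same and span_overlap == 0 and _span_distance(q, r) <= run_on_distance:
        return "p"
    return "u"


def assign_class_code(
    query: TranscriptModel,
    annotation: Sequence[TranscriptModel],
    run_on_distance: int = 2000,
    single_exon_match_fraction: float = 0.8,
) -> ClassCode:
    """Best class code of a query against a reference annotation.

    Every reference transcript is scored with :func:`code_for_pair`; the
    reference yielding the highest-priority code wins, ties broken by span
    distance and then lexicographic reference id.  No sense-making
    reference leaves the query intergenic ('u').
    """
    best: Optional[tuple[int, int, str, str]] = None
    for r in annotation:
        if r.chrom != query.chrom:
            continue
        code = code_for_pair(query, r, run_on_distance, single_exon_match_fraction)
        if code == "u":
            continue
        key = (
            CLASS_CODE_PRIORITY.index(code),
            _span_distance(query, r),
            r.transcript_id,
            code,
        )
        if best is None or key < best:
            best = key
    if best is None:
        return ClassCode("u", None)
    return ClassCode(best[3], best[2])


# --- filters --------------------------------------------------------------


def noise_filter(
    aligned: Sequence[TranscriptModel],
    loci: Sequence[Locus],
    min_locus_coverage: float = 0.8,
) -> list[TranscriptModel]:
    """Drop short assembly fragments that do not match their locus.

    The locus representative is its longest member (by summed exon length,
    ties by id).  Multi-exon members are kept iff their intron chain equals
    the representative's; single-exon members are kept iff their span covers
    at least ``min_locus_coverage`` of the locus span.  Removal counts are
    logged per chromosome.
    """
    if not 0.0 < min_locus_coverage <= 1.0:
        raise ValueError("min_locus_coverage must be in (0, 1]")
    by_id = {t.transcript_id: t for t in aligned}
    kept: list[TranscriptModel] = []
    removed_per_chrom: dict[str, int] = {}
    for locus in loci:
        members = [by_id[m] for m in locus.members]
        rep = max(members, key=lambda t: (t.length, t.transcript_id))
        for t in members:
            if t.is_multi_exon:
                ok = t.intron_chain == rep.intron_chain
            else:
                ok = len(t.span) >= min_locus_coverage * len(locus.interval)
            if ok:
                kept.append(t)
            else:
                removed_per_chrom[t.chrom] = removed_per_chrom.get(t.chrom, 0) + 1
    for chrom, n in sorted(removed_per_chrom.items()):
        logger.info("noise filter removed %d transcripts on %s", n, chrom)
    order = {t.transcript_id: i for i, t in enumerate(aligned)}
    return sorted(kept, key=lambda t: order[t.transcript_id])


def te_filter(
    transcripts: Sequence[TranscriptModel],
    te_intervals: Sequence[GenomicInterval],
) -> list[TranscriptModel]:
    """Remove transcripts whose exons overlap any TE interval by >= 1 bp.

    Strand is ignored.  The test is against exon blocks, not the genomic
    span: a TE wholly inside an intron does not appear in the transcript
    and does not trigger removal.
    """
    trees: dict[str, IntervalTree] = {}
    for te in te_intervals:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end)
    kept = []
    for t in transcripts:
        tree = trees.get(t.chrom)
        if tree is None or not any(tree.overlap(e.start, e.end) for e in t.exons):
            kept.append(t)
    return kept


_DECISION = {
    "c": "sense_exonic_excluded",
    "k": "sense_exonic_excluded",
    "j": "sense_exonic_excluded",
    "m": "sense_exonic_excluded",
    "n": "sense_exonic_excluded",
    "o": "sense_exonic_excluded",
    "e": "artefact_excluded",
    "s": "artefact_excluded",
    "p": "artefact_excluded",
    "y": "artefact_excluded",
    "i": "intronic",
    "x": "antisense",
    "u": "intergenic",
}


def apply_decision_table(class_code: str, matched_biotype: Optional[str] = None) -> str:
    """Map a class code (plus the matched reference's biotype for '=') to a
    keep/exclude verdict.

    Complete matches to known mRNAs are prediction errors and excluded;
    complete matches to annotated lncRNAs are known lncRNAs.  Sense exonic
    overlaps (c,k,j,m,n,o) may be unannotated isoforms of coding genes and
    are excluded; e,s,p,y are treated as assembly artefacts.  i/x/u are the
    novel intronic, antisense and intergenic lncRNAs.
    """
    if class_code == "=":
        return "known_lncrna" if matched_biotype == "lncRNA" else "known_mrna_excluded"
    try:
        return _DECISION[class_code]
    except KeyError:
        raise ValueError(f"unknown class code {class_code!r}") from None
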