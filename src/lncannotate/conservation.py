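"""Conservation labelling of novel lncRNAs and identity-based clustering.

Novel lncRNAs are compared against a library of known lncRNA sequences
whose species is carried in a ``species=`` FASTA header key (or supplied as
a mapping).  A query with a best hit of >= 50% identity in another species
is conserved; a best hit only within the reference species makes it
non-conserved; no hit leaves it unmatched.

The native search is k-mer seeded (default k = 11): only library sequences
sharing at least one seed with the query (in either orientation) are
aligned, with a library-backed local (Smith-Waterman) alignment scoring
match +1 / mismatch -1 / gap -2.  Identity is matches divided by alignment
columns, times 100.  E-values are not re-derived; the significance gate is
a minimum alignment-length fraction of the query.  Precomputed blast-tab
hits can be ingested instead via :func:`lncannotate.io.read_tabular_hits`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from Bio import Align

from .core import HomologyHit, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationLabel",
    "identity_search",
    "label_conservation",
    "greedy_cluster",
    "species_from_header",
    "align_identity",
    "conservation_summary",
]

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP
    aligner.extend_gap_score = GAP
    return aligner


def align_identity(query: str, subject: str) -> tuple[float, int, float]:
    """Best local alignment of two sequences.

    Returns ``(percent_identity, alignment_columns, score)``; identity is
    matches over alignment columns (gaps included) times 100.  Returns
    ``(0.0, 0, 0.0)`` when no positive-scoring local alignment exists.
    """
    aligner = _aligner()
    if not query or not subject:
        return 0.0, 0, 0.0
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, 0, 0.0
    alignment = next(iter(aligner.align(query, subject)))
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return identity, columns, float(score)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def species_from_header(description: str) -> Optional[str]:
    """Parse a ``species=<name>`` key from a FASTA header/description."""
    for token in description.replace(";", " ").split():
        if token.startswith("species="):
            return token.split("=", 1)[1]
    return None


def identity_search(
    queries: Sequence[SequenceRecord],
    library: Sequence[SequenceRecord],
    min_identity: float = 50.0,
    seed_k: int = 11,
    min_length_fraction: float = 0.5,
    both_strands: bool = True,
    species_of: Optional[Mapping[str, str]] = None,
) -> list[HomologyHit]:
    """Best library hit per query by seeded local alignment.

    At most one hit per query (the single best subject); hits must reach
    ``min_identity`` percent and align over at least ``min_length_fraction``
    of the query.  Deterministic: ties go to higher identity, then
    lexicographically smaller subject id.
    """
    if not library:
        raise ValueError("empty library")
    shortest = min(len(q.seq) for q in queries) if queries else seed_k
    if seed_k > shortest:
        raise ValueError(f"seed k={seed_k} exceeds shortest query length {shortest}")

    index: dict[str, set[int]] = {}
    for j, subject in enumerate(library):
        for kmer in _kmers(subject.seq, seed_k):
            index.setdefault(kmer, set()).add(j)

    hits: list[HomologyHit] = []
    for q in queries:
        candidates: set[int] = set()
        strands = [q.seq, reverse_complement(q.seq)] if both_strands else [q.seq]
        for seq in strands:
            for kmer in _kmers(seq, seed_k):
                candidates |= index.get(kmer, set())
        best: Optional[tuple[float, float, str, int]] = None
        # Subjects visited in lexicographic id order; a later subject only
        # replaces the incumbent on a strictly better (score, identity).
        for j in sorted(candidates, key=lambda j: library[j].id):
            subject = library[j]
            for seq in strands:
                identity, columns, score = align_identity(seq, subject.seq)
                if identity < min_identity or columns < min_length_fraction * len(q.seq):
                    continue
                if best is None or (score, identity) > (best[0], best[1]):
                    best = (score, identity, subject.id, columns)
        if best is not None:
            score, identity, subject_id, columns = best
            hits.append(
                HomologyHit(
                    query_id=q.id,
                    subject_id=subject_id,
                    percent_identity=identity,
                    alignment_length=columns,
                    score=score,
                    subject_species=(species_of or {}).get(subject_id),
                )
            )
    return hits


@dataclass(frozen=True)
class ConservationLabel:
    """Partition label of one query: conserved / non-conserved / unmatched."""

    query_id: str
    label: str  # {conserved, non_conserved_same_species, unmatched}
    best_hit: Optional[HomologyHit] = None


def label_conservation(
    queries: Sequence[SequenceRecord],
    hits: Sequence[HomologyHit],
    reference_species: str,
    min_identity: float = 50.0,
) -> list[ConservationLabel]:
    """Label each query from its best (already thresholded) hit.

    A best hit at >= ``min_identity`` in a species other than
    ``reference_species`` means conserved; a best hit within the reference
    species only means non-conserved; no hit means unmatched.  The 50%
    boundary is inclusive.
    """
    known = {q.id for q in queries}
    best_of: dict[str, HomologyHit] = {}
    for hit in hits:
        if hit.query_id not in known:
            raise ValueError(f"hit references unknown query {hit.query_id!r}")
        prev = best_of.get(hit.query_id)
        if prev is None or (hit.score or 0.0, hit.percent_identity) > (
            prev.score or 0.0, prev.percent_identity
        ):
            best_of[hit.query_id] = hit

    labels = []
    for q in queries:
        hit = best_of.get(q.id)
        if hit is None or hit.percent_identity < min_identity:
            labels.append(ConservationLabel(q.id, "unmatched"))
        elif hit.subject_species is not None and hit.subject_species != reference_species:
            labels.append(ConservationLabel(q.id, "conserved", hit))
        else:
            labels.append(ConservationLabel(q.id, "non_conserved_same_species", hit))
    return labels


def conservation_summary(labels: Sequence[ConservationLabel]) -> dict[str, int]:
    """Counts mirroring the homologous / same-species / other-species rows."""
    conserved = sum(1 for l in labels if l.label == "conserved")
    same = sum(1 for l in labels if l.label == "non_conserved_same_species")
    return {
        "queries": len(labels),
        "homologous": conserved + same,
        "non_conserved_same_species": same,
        "conserved_other_species": conserved,
        "unmatched": len(labels) - conserved - same,
    }


def greedy_cluster(
    sequences: Sequence[SequenceRecord],
    identity_threshold: float = 0.5,
    seed_k: int = 11,
) -> list[list[str]]:
    """Greedy centroid clustering by pairwise identity.

    Sequences are visited longest first (ties by id); each joins the first
    centroid it matches at >= ``identity_threshold`` (fraction of alignment
    columns, both orientations tried), else founds a new cluster.  The
    length-descending canonical order makes the result independent of input
    order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(sequences, key=lambda s: (-len(s.seq), s.id))
    centroids: list[SequenceRecord] = []
    clusters: list[list[str]] = []
    for seq in ordered:
        assigned = False
        variants = [seq.seq, reverse_complement(seq.seq)]
        for ci, centroid in enumerate(centroids):
            if not _kmers(centroid.seq, seed_k) & (
                _kmers(variants[0], seed_k) | _kmers(variants[1], seed_k)
            ):
                continue
            identity = max(
                align_identity(v, centroid.seq)[0] for v in variants
            )
            if identity >= 100.0 * identity_threshold:
                clusters[ci].append(seq.id)
                assigned = True
                break
        if not assigned:
            centroids.append(seq)
            clusters.append([seq.id])
    return clusters
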