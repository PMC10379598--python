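"""Per-transcript coding descriptors: longest ORF, ORF coverage, the Fickett
TESTCODE statistic and the isoelectric point of the translated ORF.

These descriptors are reported alongside the classifier output as
additional information; they do not feed into the lncRNA prediction itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .core import SequenceRecord

__all__ = [
    "find_longest_orf",
    "fickett_score",
    "isoelectric_point",
    "describe_transcript",
    "OrfDescriptor",
    "BJELLQVIST_PKA",
    "FICKETT_MIN_SCORE",
    "FICKETT_MAX_SCORE",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def find_longest_orf(seq: str) -> tuple[int, int]:
    """Longest ATG-initiated forward-strand ORF over the 3 forward frames.

    Returns ``(start_offset, length_nt)``; the length runs from the ATG
    through the stop codon inclusive.  When no in-frame stop exists the ORF
    extends to the last complete codon.  With no ATG at all, ``(0, 0)``.
    Ties in length are broken by the smallest start offset.
    """
    start, length, _ = _longest_orf_detail(seq)
    return start, length


def _longest_orf_detail(seq: str) -> tuple[int, int, bool]:
    n = len(seq)
    best = (0, 0, True)  # (start, length, has_stop)

    def better(start: int, length: int) -> bool:
        # longest wins; equal lengths resolve to the smallest start offset
        return length > best[1] or (length == best[1] and start < best[0])

    for frame in range(3):
        pos = frame
        open_start: Optional[int] = None
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if better(open_start, length):
                    best = (open_start, length, True)
                open_start = None
            pos += 3
        if open_start is not None:  # stop-less ORF to the last complete codon
            last = open_start + ((n - open_start) // 3) * 3
            length = last - open_start
            if better(open_start, length):
                best = (open_start, length, False)
    return best


# --- Fickett (1982) TESTCODE lookup tables -------------------------------
# Position parameter: for each base B, counts in the three codon positions
# give max/(min+1); content parameter: the base's overall fraction.  Each
# value maps through the published probability tables and weights.

FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
FICKETT_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
FICKETT_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

FICKETT_MIN_SCORE = sum(
    min(FICKETT_POSITION_PROB[b]) * FICKETT_POSITION_WEIGHT[b]
    + min(FICKETT_CONTENT_PROB[b]) * FICKETT_CONTENT_WEIGHT[b]
    for b in "ACGT"
)
FICKETT_MAX_SCORE = sum(
    max(FICKETT_POSITION_PROB[b]) * FICKETT_POSITION_WEIGHT[b]
    + max(FICKETT_CONTENT_PROB[b]) * FICKETT_CONTENT_WEIGHT[b]
    for b in "ACGT"
)


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE coding-potential statistic on the raw sequence.

    Sum over the four bases of position-asymmetry and composition
    probability values times their weights.  Ns contribute to sequence
    length but not to any base's counts, matching the published tables'
    4-letter alphabet.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [
            sum(1 for i in range(offset, n, 3) if seq[i] == base) for offset in range(3)
        ]
        position_value = max(counts) / (min(counts) + 1.0)
        content_value = sum(counts) / n
        score += _lookup(position_value, FICKETT_POSITION_PARA, FICKETT_POSITION_PROB[base]) * FICKETT_POSITION_WEIGHT[base]
        score += _lookup(content_value, FICKETT_CONTENT_PARA, FICKETT_CONTENT_PROB[base]) * FICKETT_CONTENT_WEIGHT[base]
    return score


# --- isoelectric point ----------------------------------------------------
# Bjellqvist pKa set: generic termini plus the seven ionisable side chains.
BJELLQVIST_PKA = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "C": 9.0,
    "Y": 10.0,
    "K": 10.0,
    "R": 12.0,
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def peptide_charge(peptide: str, ph: float, pka: dict[str, float] = BJELLQVIST_PKA) -> float:
    """Net charge at ``ph`` via Henderson-Hasselbalch."""
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in "HKR":
        charge += peptide.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in "DECY":
        charge -= peptide.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(peptide: str, pka: dict[str, float] = BJELLQVIST_PKA) -> float:
    """pH in [0, 14] at which the peptide's net charge is zero.

    Bisection until |charge| < 1e-4 or the pH step drops below 1e-5; the
    tight step limit keeps the residual charge below 1e-3 even for long,
    heavily charged peptides whose titration curve is steep at the
    crossing.  Non-standard residues raise.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = sorted(set(peptide) - _STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residues: {''.join(bad)}")
    lo, hi = 0.0, 14.0
    ph = 7.0
    while hi - lo > 1e-5:
        ph = (lo + hi) / 2.0
        charge = peptide_charge(peptide, ph, pka)
        if abs(charge) < 1e-4:
            return ph
        if charge > 0:
            lo = ph
        else:
            hi = ph
    return ph


def translate_orf(seq: str, start: int, length: int) -> str:
    """Translate an ORF, dropping the terminal stop codon and unknown codons."""
    peptide = []
    for pos in range(start, start + length - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        aa = CODON_TABLE.get(codon)
        if aa:
            peptide.append(aa)
    return "".join(peptide)


@dataclass(frozen=True)
class OrfDescriptor:
    transcript_id: str
    orf_start: int  # 0-based offset
    orf_length: int  # nt, includes the stop codon when present
    orf_coverage: float
    fickett_score: float
    isoelectric_point: Optional[float]  # None when no usable ORF
    has_stop: bool = True


def describe_transcript(record: SequenceRecord) -> OrfDescriptor:
    """Assemble the four descriptors for one transcript.

    The Fickett score is computed on the full transcript.  The isoelectric
    point is reported only when the ORF spans at least two codons
    (``orf_length >= 6``); shorter ORFs translate to nothing useful.
    """
    start, length, has_stop = _longest_orf_detail(record.seq)
    coverage = length / len(record.seq) if record.seq else 0.0
    pi: Optional[float] = None
    if length >= 6:
        peptide = translate_orf(record.seq, start, length)
        if peptide:
            pi = isoelectric_point(peptide)
    return OrfDescriptor(
        transcript_id=record.id,
        orf_start=start,
        orf_length=length,
        orf_coverage=coverage,
        fickett_score=fickett_score(record.seq),
        isoelectric_point=pi,
        has_stop=has_stop,
    )


def descriptors_table(records) -> "pd.DataFrame":
    """Descriptor TSV table; orf_start is reported 1-based."""
    import pandas as pd

    rows = []
    for rec in records:
        d = describe_transcript(rec)
        rows.append(
            {
                "transcript_id": d.transcript_id,
                "orf_start": d.orf_start + 1 if d.orf_length else 0,
                "orf_length": d.orf_length,
                "orf_coverage": round(d.orf_coverage, 6),
                "fickett_score": round(d.fickett_score, 4),
                "isoelectric_point": (
                    round(d.isoelectric_point, 3) if d.isoelectric_point is not None else "NA"
                ),
                "has_stop": d.has_stop,
            }
        )
    return pd.DataFrame(rows)
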