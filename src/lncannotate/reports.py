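"""Reporting helpers: cascade, class-count and conservation summary tables.

Percentages in the published-style tables are integer-truncated (floor);
exact fractions are reported alongside.  The cascade table carries both the
fraction-of-input and fraction-of-previous-step conventions because both
are in circulation for tables of this kind.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "pct_floor",
    "cascade_report",
    "class_count_report",
    "conservation_report",
    "transcripts_per_locus",
]

CASCADE_STEPS = (
    "input",
    "length_filtering",
    "predicted_noncoding",
    "genome_alignment",
    "noise_filtered",
    "te_filtered",
    "lncRNA_candidate_transcripts",
    "lncRNA_candidate_loci",
)


def pct_floor(count: int, total: int) -> Optional[int]:
    """Integer-truncated percentage; ``None`` for an empty denominator."""
    if total <= 0:
        return None
    return math.floor(100.0 * count / total)


def cascade_report(counts: Mapping[str, int]) -> pd.DataFrame:
    """Step-count cascade with percentages of the input and of the previous
    step.

    ``counts`` maps step names (in pipeline order) to transcript counts;
    any subset of :data:`CASCADE_STEPS` is accepted, and extra steps are
    carried through in the given order.
    """
    steps = list(counts)
    total = counts[steps[0]]
    rows = []
    prev = None
    for step in steps:
        n = counts[step]
        rows.append(
            {
                "step": step,
                "count": n,
                "pct_of_input": pct_floor(n, total),
                "pct_of_previous": pct_floor(n, prev) if prev is not None else 100,
                "fraction_of_input": n / total if total else float("nan"),
            }
        )
        prev = n
    return pd.DataFrame(rows)


def class_count_report(class_counts: Mapping[str, int], known: Optional[int] = None) -> pd.DataFrame:
    """Antisense/intronic/intergenic counts with their shares of the novel
    total; the known-lncRNA row (class '=') is listed without a percentage.
    """
    total = sum(class_counts.values())
    rows = [
        {
            "class": name,
            "count": n,
            "pct_of_candidates": pct_floor(n, total),
        }
        for name, n in class_counts.items()
    ]
    if known is not None:
        rows.append({"class": "known_lncRNA_loci", "count": known, "pct_of_candidates": None})
    return pd.DataFrame(rows)


def conservation_report(
    n_candidates: int,
    n_homologous: int,
    n_same_species: int,
    n_other_species: int,
) -> pd.DataFrame:
    """Similarity summary rows: homologous, same-species, other-species."""
    rows = [
        ("homologous_sequences", n_homologous),
        ("homologs_same_species_non_conserved", n_same_species),
        ("homologs_other_species_conserved", n_other_species),
    ]
    return pd.DataFrame(
        [
            {"row": name, "count": n, "pct_of_candidates": pct_floor(n, n_candidates)}
            for name, n in rows
        ]
    )


def transcripts_per_locus(n_transcripts: int, n_loci: int) -> float:
    """Mean number of candidate transcripts expressed per locus."""
    if n_loci <= 0:
        raise ValueError("no loci")
    return n_transcripts / n_loci
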