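"""Label novel lncRNAs conserved / non-conserved against a known-lncRNA
library.

The library carries each sequence's species; a best hit at >= 50% identity
in another species makes the query conserved, a hit only within the
reference species non-conserved, and no hit leaves it unmatched.
"""

import numpy as np

from lncannotate.core import SequenceRecord
from lncannotate.conservation import (
    conservation_summary,
    greedy_cluster,
    identity_search,
    label_conservation,
)

rng = np.random.default_rng(1)
seq = lambda n: "".join(rng.choice(list("ACGT"), size=n))


def mutate(s, rate):
    return "".join(
        c if rng.random() > rate else str(rng.choice([b for b in "ACGT" if b != c]))
        for c in s
    )


queries = [SequenceRecord(f"novel_{i}", seq(300)) for i in range(4)]
library = [
    SequenceRecord("sb1", mutate(queries[0].seq, 0.10)),  # sorghum homolog
    SequenceRecord("zm1", queries[1].seq),                # maize (same species)
    SequenceRecord("sb2", seq(300)),                      # unrelated
]
species = {"sb1": "sorghum", "zm1": "maize", "sb2": "sorghum"}

hits = identity_search(queries, library, species_of=species)
labels = label_conservation(queries, hits, reference_species="maize")
for l in labels:
    detail = (
        f"{l.best_hit.subject_id} ({l.best_hit.subject_species}, "
        f"{l.best_hit.percent_identity:.1f}% identity)" if l.best_hit else "-"
    )
    print(f"{l.query_id:<10} {l.label:<28} {detail}")
print("summary:", conservation_summary(labels))

clusters = greedy_cluster(queries + library, identity_threshold=0.5)
print(f"\n{len(clusters)} identity clusters at 50%:", clusters)
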