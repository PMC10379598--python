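"""Tissue specificity of expression: expressed transcripts per library per
tissue.

A transcript is expressed in a tissue when TPM > 1 in at least one of the
tissue's libraries.  Each (RNA type, tissue) cell is the expressed count
normalised by the number of transcripts of the type expressed anywhere and
by the number of libraries for that tissue, so types and tissues of
different sizes are comparable.
"""

import pandas as pd

from lncannotate.core import ExpressionMatrix
from lncannotate.stats import expression_specificity

values = pd.DataFrame(
    {
        "leaf_1":   [0.0, 2.5, 0.0, 12.0, 3.1],
        "leaf_2":   [0.2, 1.8, 0.0, 15.0, 2.2],
        "pollen_1": [8.0, 0.0, 6.5, 30.0, 0.0],
        "pollen_2": [9.1, 0.3, 7.2, 28.0, 0.4],
    },
    index=["lnc_a", "lnc_b", "lnc_c", "mrna_a", "mrna_b"],
)
matrix = ExpressionMatrix(
    values,
    {"leaf_1": "leaf", "leaf_2": "leaf", "pollen_1": "pollen", "pollen_2": "pollen"},
)
groups = {
    "lnc_a": "non_conserved_lncRNA",
    "lnc_b": "non_conserved_lncRNA",
    "lnc_c": "conserved_lncRNA",
    "mrna_a": "mRNA",
    "mrna_b": "mRNA",
}
table = expression_specificity(matrix, groups, threshold=1.0)
print(table.round(3).to_string())
print(
    "\nRows are RNA types, columns tissues; higher values mean the type's "
    "expression\nconcentrates in that tissue (here the lncRNAs lean to pollen)."
)
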