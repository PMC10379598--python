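import numpy as np
import pandas as pd
import pytest

from lncannotate.core import ExpressionMatrix, GenomicInterval, TranscriptModel
from lncannotate.location import Locus
from lncannotate import stats


def make_t(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, tid, chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


@pytest.fixture()
def matrix():
    values = pd.DataFrame(
        {
            "leaf_1": [2.0, 0.0, 1.0, 9.0, 0.0],
            "leaf_2": [0.5, 0.0, 0.0, 9.0, 0.0],
            "root_1": [0.0, 3.0, 0.0, 9.0, 0.0],
        },
        index=["t1", "t2", "t3", "t4", "t5"],
    )
    meta = {"leaf_1": "leaf", "leaf_2": "leaf", "root_1": "root"}
    return ExpressionMatrix(values, meta)


class TestExpressionSpecificity:
    def test_formula_substitution(self, matrix):
        groups = {"t1": "lnc", "t2": "lnc", "t4": "mRNA"}
        out = stats.expression_specificity(matrix, groups, threshold=1.0)
        # lnc: both expressed somewhere (N=2); leaf has 2 libraries
        assert out.loc["lnc", "leaf"] == pytest.approx(1 / (2 * 2))  # only t1
        assert out.loc["lnc", "root"] == pytest.approx(1 / (2 * 1))  # only t2
        assert out.loc["mRNA", "leaf"] == pytest.approx(1 / (1 * 2))

    def test_tpm_exactly_threshold_not_expressed(self, matrix):
        # t3 has TPM exactly 1.0 in leaf_1 and nothing else: strict >
        out = stats.expression_specificity(matrix, {"t3": "lnc"}, threshold=1.0)
        assert np.isnan(out.loc["lnc"]).all()

    def test_all_zero_type_gives_na_row(self, matrix):
        out = stats.expression_specificity(matrix, {"t5": "lnc", "t1": "mRNA"})
        assert np.isnan(out.loc["lnc"]).all()
        assert not np.isnan(out.loc["mRNA"]).any()

    def test_brute_force_agreement(self, matrix, rng):
        """Cells agree exactly with a direct recount over the raw matrix."""
        tids = list(matrix.transcripts)
        groups = {t: ("A" if i % 2 else "B") for i, t in enumerate(tids)}
        out = stats.expression_specificity(matrix, groups, threshold=1.0)
        for rna_type in ("A", "B"):
            members = [t for t in tids if groups[t] == rna_type]
            n_type = 0
            for t in members:
                row = matrix.values.loc[t]
                if (row > 1.0).any():
                    n_type += 1
            for tissue in matrix.tissues:
                libs = matrix.libraries_of(tissue)
                count = sum(
                    1 for t in members if (matrix.values.loc[t, libs] > 1.0).any()
                )
                cell = out.loc[rna_type, tissue]
                if n_type == 0:
                    assert np.isnan(cell)
                else:
                    assert cell == count / (n_type * len(libs))

    def test_unknown_transcript_rejected(self, matrix):
        with pytest.raises(ValueError, match="ghost"):
            stats.expression_specificity(matrix, {"ghost": "lnc"})


class TestStructuralStats:
    def test_short_intron_exclusion_boundary(self):
        t59 = make_t("t59", [(0, 100), (159, 300)])    # intron 59 -> excluded
        t60 = make_t("t60", [(0, 100), (160, 300)])    # intron 60 -> included
        summary = stats.structural_stats([t59, t60], min_intron=60)
        assert list(summary.excluded) == ["t59"]
        assert summary.n_transcripts == 1
        assert summary.intron_lengths == [60]

    def test_hand_computed_summary(self):
        ts = [
            make_t("a", [(0, 100)]),                       # exon 100
            make_t("b", [(0, 200), (300, 400)]),           # exons 200,100; intron 100
            make_t("c", [(10, 210), (280, 480), (560, 660)]),  # 200,200,100; introns 70,80
        ]
        s = stats.structural_stats(ts)
        table = s.table()
        assert table["Mean exon length"] == pytest.approx(np.mean([100, 200, 100, 200, 200, 100]))
        assert table["Median intron length"] == pytest.approx(np.median([100, 70, 80]))
        assert table["Min. exon length"] == 100 and table["Max. exon length"] == 200
        assert table["Mean transcript length"] == pytest.approx(np.mean([100, 300, 500]))
        assert s.exon_count_histogram == {1: 1, 2: 1, 3: 1}

    def test_distribution_ordering(self, rng):
        ts = [
            make_t(f"t{i}", [(0, int(rng.integers(80, 500)))])
            for i in range(20)
        ]
        t = stats.structural_stats(ts).table()
        assert t["Min. exon length"] <= t["Median exon length"] <= t["Max. exon length"]


class TestChromosomeDensity:
    def _loci(self):
        return [
            Locus(f"L{i}", GenomicInterval("chr1", i * 1000, i * 1000 + 500), [f"t{i}"])
            for i in range(10)
        ]

    def test_density_per_mb(self):
        density, _ = stats.chromosome_density(self._loci(), {"chr1": 10_000_000, "chr2": 5_000_000})
        d = density.set_index("chrom")
        assert d.loc["chr1", "density_per_mb"] == pytest.approx(1.0)
        assert d.loc["chr2", "density_per_mb"] == 0.0

    def test_window_counts_conserve_totals(self):
        loci = self._loci()
        genes = [GenomicInterval("chr1", 2000, 3000), GenomicInterval("chr1", 9_999_000, 10_000_000)]
        _, windows = stats.chromosome_density(loci, {"chr1": 10_000_000}, window=4096, gene_spans=genes)
        assert windows["lncRNA_loci"].sum() == len(loci)
        assert windows["protein_coding_genes"].sum() == len(genes)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chr1"):
            stats.chromosome_density(self._loci(), {"chr9": 1_000_000})


class TestAntisenseExonProfile:
    REF_PLUS = make_t("ref+", [(100, 200), (300, 400), (500, 600)])
    REF_MINUS = make_t("ref-", [(100, 200), (300, 400), (500, 600)], strand="-")

    def test_ordinals_follow_reference_strand(self):
        q = make_t("q", [(150, 180)], strand="-")
        out = stats.antisense_exon_profile([q], {"q": "ref+"}, [self.REF_PLUS])
        assert out.to_dict("records") == [{"exon_ordinal": 1, "count": 1, "fraction": 1.0}]
        # on a '-' reference the 5'-most exon is the right-most one
        out2 = stats.antisense_exon_profile([q], {"q": "ref-"}, [self.REF_MINUS])
        assert list(out2["exon_ordinal"]) == [3]

    def test_multi_exon_overlap_counts_each_ordinal(self):
        q = make_t("q", [(150, 350)], strand="-")
        out = stats.antisense_exon_profile([q], {"q": "ref+"}, [self.REF_PLUS])
        assert list(out["exon_ordinal"]) == [1, 2]
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        q = make_t("q", [(150, 180)], strand="-")
        with pytest.raises(ValueError, match="matched reference"):
            stats.antisense_exon_profile([q], {}, [self.REF_PLUS])
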