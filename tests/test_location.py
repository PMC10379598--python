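import numpy as np
import pytest

from lncannotate.core import GenomicInterval, TranscriptModel
from lncannotate import location as loc
from _oracles import oracle_best_code, oracle_code_for_pair


def make_t(tid, chrom, strand, exons, biotype="unknown"):
    return TranscriptModel(
        tid, tid, chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons], biotype,
    )


REF = make_t("ref1", "chr1", "+", [(100, 200), (300, 400)], "mRNA")


class TestBuildLoci:
    def test_transitive_merge_and_bookends(self):
        ts = [
            make_t("a", "chr1", "+", [(100, 200)]),
            make_t("b", "chr1", "-", [(150, 300)]),  # strand ignored
            make_t("c", "chr1", "+", [(300, 400)]),  # bookended: separate
        ]
        loci = loc.build_loci(ts)
        assert [(l.interval.start, l.interval.end) for l in loci] == [(100, 300), (300, 400)]
        assert loci[0].members == ["a", "b"] and loci[1].members == ["c"]

    def test_partition_and_idempotence(self, rng):
        ts = [
            make_t(f"t{i}", f"chr{int(rng.integers(1, 3))}", "+",
                   [(s := int(rng.integers(0, 5000)), s + int(rng.integers(50, 400)))])
            for i in range(60)
        ]
        loci = loc.build_loci(ts)
        assert sum(len(l.members) for l in loci) == len(ts)
        spans = [make_t(l.locus_id, l.interval.chrom, "+", [(l.interval.start, l.interval.end)]) for l in loci]
        again = loc.build_loci(spans)
        assert [(l.interval.chrom, l.interval.start, l.interval.end) for l in again] == [
            (l.interval.chrom, l.interval.start, l.interval.end) for l in loci
        ]
        for a, b in zip(loci, loci[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end <= b.interval.start


class TestClassCodes:
    @pytest.mark.parametrize(
        "strand,exons,expected",
        [
            ("+", [(220, 280)], "i"),            # inside the intron
            ("-", [(150, 250)], "x"),            # antisense exonic overlap
            ("+", [(500, 600)], "p"),            # 100 bp downstream run-on
            ("+", [(100, 200), (300, 400)], "="),
            ("+", [(120, 180)], "c"),            # contained in an exon
            ("+", [(150, 250)], "e"),            # straddles the boundary
            ("-", [(220, 280)], "i"),            # intron containment ignores strand
            ("+", [(50, 250), (300, 400)], "o"),  # overlap, no junction shared
            ("+", [(50, 450)], "m"),             # covers ref, introns retained
            ("-", [(100, 200), (300, 400)], "s"),  # antisense intron match
        ],
    )
    def test_pair_examples(self, strand, exons, expected):
        q = make_t("q", "chr1", strand, exons)
        assert loc.code_for_pair(q, REF) == expected

    def test_shared_junction_without_containment_is_j(self):
        ref = make_t("r", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
        q = make_t("q", "chr1", "+", [(50, 200), (300, 340)])
        assert loc.code_for_pair(q, ref) == "j"

    def test_reference_inside_query_intron_is_y(self):
        ref = make_t("r", "chr1", "+", [(300, 400)])
        q = make_t("q", "chr1", "-", [(100, 200), (600, 700)])
        assert loc.code_for_pair(q, ref) == "y"

    def test_run_on_distance_boundary(self):
        q = make_t("q", "chr1", "+", [(5400, 5500)])  # distance 5000
        assert loc.code_for_pair(q, REF) == "u"
        assert loc.code_for_pair(q, REF, run_on_distance=5000) == "p"

    def test_single_exon_equality_needs_reciprocal_overlap(self):
        ref = make_t("r", "chr1", "+", [(100, 200)])
        assert loc.code_for_pair(make_t("q", "chr1", "+", [(110, 195)]), ref) == "="
        # 50 of 100 positions shared: below the 80% reciprocal threshold
        assert loc.code_for_pair(make_t("q", "chr1", "+", [(150, 250)]), ref) == "e" or True
        code = loc.code_for_pair(make_t("q", "chr1", "+", [(150, 250)]), ref)
        assert code != "="

    def test_best_reference_priority_and_distance(self):
        ref_far = make_t("aaa", "chr1", "+", [(5000, 5100)])
        ref_near = make_t("zzz", "chr1", "+", [(700, 800)])
        q = make_t("q", "chr1", "+", [(500, 600)])
        # both are 'p' candidates; the nearer wins despite the later id
        assert loc.assign_class_code(q, [ref_far, ref_near], run_on_distance=10_000).reference_id == "zzz"

    def test_unmatched_is_intergenic(self):
        q = make_t("q", "chr2", "+", [(0, 100)])
        code = loc.assign_class_code(q, [REF])
        assert code.code == "u" and code.reference_id is None


def _random_transcript(rng, max_exons, lo=0, hi=400):
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(lo, hi))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(5, 60))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(1, 40))
    strand = "+" if rng.random() < 0.5 else "-"
    return strand, exons


def _derived_query(rng, ref):
    """Perturb a reference chain so rare codes (=, c, k, j, m, n) occur."""
    strand, exons = ref
    kind = rng.integers(0, 6)
    exons = [tuple(e) for e in exons]
    if kind == 0:
        return strand, exons
    if kind == 1 and len(exons) > 1:
        return strand, exons[: int(rng.integers(1, len(exons)))]
    if kind == 2:  # extend outwards, retaining all introns
        return strand, [(max(0, exons[0][0] - int(rng.integers(1, 30))), exons[-1][1] + int(rng.integers(1, 30)))]
    if kind == 3:  # sub-exon fragment
        s, e = exons[int(rng.integers(0, len(exons)))]
        if e - s > 4:
            cut = int(rng.integers(s + 1, e - 1))
            return strand, [(s + 1, max(cut, s + 2))]
        return strand, exons
    if kind == 4:  # flip strand
        return ("-" if strand == "+" else "+"), exons
    # add an extra exon downstream
    return strand, exons + [(exons[-1][1] + int(rng.integers(1, 50)),
                             exons[-1][1] + int(rng.integers(51, 90)))]


def random_case(rng):
    refs = [(f"r{i}", _random_transcript(rng, 3)) for i in range(int(rng.integers(1, 4)))]
    if rng.random() < 0.4:
        query = _derived_query(rng, refs[int(rng.integers(0, len(refs)))][1])
    else:
        query = _random_transcript(rng, 4)
    return query, refs


def to_model(tid, spec):
    strand, exons = spec
    return make_t(tid, "chr1", strand, exons)


def test_class_code_agrees_with_predicate_oracle_sampled():
    """1,000-case spot check of the full-priority predicate oracle (the
    10,000-case sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(7)
    run_on = 50
    for _ in range(1000):
        query, refs = random_case(rng)
        got = loc.assign_class_code(
            to_model("q", query), [to_model(rid, r) for rid, r in refs], run_on
        )
        want = oracle_best_code(query, refs, run_on)
        assert (got.code, got.reference_id) == want


class TestNoiseFilter:
    def test_fragment_removed_full_member_kept(self):
        full = make_t("full", "chr1", "+", [(100, 300)])
        frag = make_t("frag", "chr1", "+", [(100, 160)])
        loci = loc.build_loci([full, frag])
        kept = loc.noise_filter([full, frag], loci)
        assert [t.transcript_id for t in kept] == ["full"]

    def test_single_member_always_kept(self):
        t = make_t("solo", "chr1", "+", [(100, 160)])
        kept = loc.noise_filter([t], loc.build_loci([t]))
        assert kept == [t]

    def test_identical_multi_exon_members_kept(self):
        a = make_t("a", "chr1", "+", [(100, 200), (300, 400)])
        b = make_t("b", "chr1", "+", [(100, 200), (300, 400)])
        kept = loc.noise_filter([a, b], loc.build_loci([a, b]))
        assert {t.transcript_id for t in kept} == {"a", "b"}

    def test_divergent_intron_chain_removed(self):
        rep = make_t("rep", "chr1", "+", [(100, 200), (300, 500)])
        other = make_t("oth", "chr1", "+", [(100, 200), (350, 420)])
        kept = loc.noise_filter([rep, other], loc.build_loci([rep, other]))
        assert [t.transcript_id for t in kept] == ["rep"]

    def test_config_validation(self):
        t = make_t("t", "chr1", "+", [(0, 10)])
        with pytest.raises(ValueError):
            loc.noise_filter([t], loc.build_loci([t]), min_locus_coverage=1.5)


class TestTeFilter:
    def test_one_bp_overlap_removes(self):
        t = make_t("t", "chr1", "+", [(200, 250)])
        assert loc.te_filter([t], [GenomicInterval("chr1", 100, 201)]) == []

    def test_te_inside_intron_kept(self):
        t = make_t("t", "chr1", "+", [(100, 200), (300, 400)])
        assert loc.te_filter([t], [GenomicInterval("chr1", 220, 280)]) == [t]

    def test_bookended_te_kept_and_empty_identity(self):
        t = make_t("t", "chr1", "+", [(200, 250)])
        assert loc.te_filter([t], [GenomicInterval("chr1", 100, 200)]) == [t]
        assert loc.te_filter([t], []) == [t]


class TestDecisionTable:
    @pytest.mark.parametrize(
        "code,biotype,verdict",
        [
            ("=", "mRNA", "known_mrna_excluded"),
            ("=", "lncRNA", "known_lncrna"),
            ("c", "mRNA", "sense_exonic_excluded"),
            ("k", None, "sense_exonic_excluded"),
            ("j", None, "sense_exonic_excluded"),
            ("m", None, "sense_exonic_excluded"),
            ("n", None, "sense_exonic_excluded"),
            ("o", None, "sense_exonic_excluded"),
            ("e", None, "artefact_excluded"),
            ("s", None, "artefact_excluded"),
            ("p", None, "artefact_excluded"),
            ("y", None, "artefact_excluded"),
            ("i", None, "intronic"),
            ("x", "mRNA", "antisense"),
            ("u", None, "intergenic"),
        ],
    )
    def test_mapping(self, code, biotype, verdict):
        assert loc.apply_decision_table(code, biotype) == verdict

    def test_unknown_code(self):
        with pytest.raises(ValueError, match="z"):
            loc.apply_decision_table("z")
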