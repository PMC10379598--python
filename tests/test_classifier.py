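import numpy as np
import pytest

from lncannotate import classifier as clf
from lncannotate.core import SequenceRecord
from lncannotate.fixtures import make_classifier_fixture


def _dummy_records(prefix, n):
    return [SequenceRecord(f"{prefix}{i}", "ACGTACGTAC") for i in range(n)]


CONFIG = clf.TrainingConfig(seed=1)


class TestBalancedDataset:
    def test_ratio_and_counts(self):
        lnc, mrna = _dummy_records("l", 2535), _dummy_records("m", 33725)
        sampled, kept = clf.build_balanced_dataset(lnc, mrna, CONFIG, seed=1)
        assert len(sampled) == 5070 and len(kept) == 2535
        assert len({r.id for r in sampled}) == 5070  # without replacement

    def test_too_few_mrnas(self):
        with pytest.raises(ValueError, match="20"):
            clf.build_balanced_dataset(
                _dummy_records("l", 10), _dummy_records("m", 19), CONFIG, seed=1
            )

    def test_seed_determinism(self):
        lnc, mrna = _dummy_records("l", 50), _dummy_records("m", 200)
        a, _ = clf.build_balanced_dataset(lnc, mrna, CONFIG, seed=7)
        b, _ = clf.build_balanced_dataset(lnc, mrna, CONFIG, seed=7)
        c, _ = clf.build_balanced_dataset(lnc, mrna, CONFIG, seed=8)
        assert [r.id for r in a] == [r.id for r in b]
        assert [r.id for r in a] != [r.id for r in c]


class TestSplit:
    def test_stratified_sizes(self):
        lnc, mrna = _dummy_records("l", 2535), _dummy_records("m", 5070)
        train, test = clf.split_train_test((mrna, lnc), CONFIG, seed=1)
        assert (len(train["lncrna"]), len(test["lncrna"])) == (2028, 507)
        assert (len(train["mrna"]), len(test["mrna"])) == (4056, 1014)

    def test_disjoint_union(self):
        lnc, mrna = _dummy_records("l", 37), _dummy_records("m", 74)
        train, test = clf.split_train_test((mrna, lnc), CONFIG, seed=3)
        for cls in ("mrna", "lncrna"):
            tr = {r.id for r in train[cls]}
            te = {r.id for r in test[cls]}
            assert not tr & te
            assert tr | te == {r.id for r in (mrna if cls == "mrna" else lnc)}

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            clf.split_train_test(
                (_dummy_records("m", 100), _dummy_records("l", 4)), CONFIG, seed=1
            )


class TestHexamerTable:
    def test_frequencies_sum_to_one_and_positive(self, rng):
        mrna = [SequenceRecord(f"m{i}", "".join(rng.choice(list("ACGT"), size=100))) for i in range(5)]
        lnc = [SequenceRecord(f"l{i}", "".join(rng.choice(list("ACGT"), size=100))) for i in range(5)]
        table = clf.build_hexamer_table(mrna, lnc)
        assert table.f_coding.sum() == pytest.approx(1.0, abs=1e-9)
        assert table.f_noncoding.sum() == pytest.approx(1.0, abs=1e-9)
        assert (table.f_coding > 0).all() and (table.f_noncoding > 0).all()

    def test_order_independence(self, rng):
        recs = [SequenceRecord(f"m{i}", "".join(rng.choice(list("ACGT"), size=80))) for i in range(6)]
        t1 = clf.build_hexamer_table(recs, recs[:3])
        t2 = clf.build_hexamer_table(list(reversed(recs)), list(reversed(recs[:3])))
        np.testing.assert_array_equal(t1.f_coding, t2.f_coding)

    def test_class_specific_hexamer_dominates(self):
        mrna = [SequenceRecord("m", "AAAAAAAAAA")]
        lnc = [SequenceRecord("l", "CGCGCGCGCG")]
        table = clf.build_hexamer_table(mrna, lnc)
        idx = clf.HEXAMERS.index("AAAAAA")
        assert table.f_coding[idx] == table.f_coding.max()


class TestFeatures:
    def test_hexamer_score_sign_and_symmetry(self):
        mrna = [SequenceRecord("m", "AAAAAAAAAAAA")]
        lnc = [SequenceRecord("l", "CGCGCGCGCGCG")]
        table = clf.build_hexamer_table(mrna, lnc)
        assert clf.extract_features(SequenceRecord("q", "AAAAAAAA"), table)[0] > 0
        flat = clf.HexamerTable(table.f_coding, table.f_coding, 1.0)
        assert clf.extract_features(SequenceRecord("q", "AAAAAAAA"), flat)[0] == 0.0

    def test_fixed_dimension_and_short_sequence_error(self, rng):
        table = clf.build_hexamer_table(
            [SequenceRecord("m", "ACGTACGTAC")], [SequenceRecord("l", "TTTTTTTTTT")]
        )
        dims = {
            clf.extract_features(
                SequenceRecord(f"q{i}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 500))))),
                table,
            ).shape
            for i in range(100)
        }
        assert dims == {(len(clf.FEATURE_NAMES),)}
        with pytest.raises(ValueError, match="shorter"):
            clf.extract_features(SequenceRecord("q", "ACGT"), table)


class TestEvaluate:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 0, 20, 0), (1.0, 1.0, 1.0, 1.0)),
            ((9, 3, 17, 1), (0.9, 0.75, 0.85, 2 * 0.9 * 0.75 / 1.65)),
        ],
    )
    def test_hand_arithmetic(self, counts, expected):
        m = clf.evaluate(clf.ConfusionCounts(*counts))
        assert (m.SN, m.PR, m.SP, m.F1) == pytest.approx(expected)

    def test_degenerate_na(self):
        m = clf.evaluate(clf.ConfusionCounts(TP=0, FP=0, TN=5, FN=0))
        assert m.PR is None and m.SN is None and m.F1 is None and m.SP == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            clf.evaluate(clf.ConfusionCounts(0, 0, 0, 0))


def test_select_best_model_tie_break():
    class Fake:
        def __init__(self, i, f1):
            self.replicate_index = i
            self.metrics = clf.MetricsReport(None, None, None, f1)

    models = [Fake(0, 0.80), Fake(1, 0.91), Fake(2, 0.85), Fake(3, 0.91), Fake(4, 0.70)]
    assert clf.select_best_model(models).replicate_index == 1
    assert clf.select_best_model([Fake(0, 0.5)]).replicate_index == 0
    with pytest.raises(ValueError):
        clf.select_best_model([Fake(0, None)])


@pytest.fixture(scope="module")
def small_trained():
    lnc, mrna = make_classifier_fixture(seed=2, n_per_class=60)
    config = clf.TrainingConfig(seed=2, n_replicates=2)
    models = clf.train_replicates(lnc, mrna, config)
    return lnc, mrna, models


def test_metrics_csv_shape(small_trained, tmp_path):
    _, _, models = small_trained
    df = clf.metrics_csv(models, tmp_path / "metrics.csv")
    assert list(df.columns) == ["replicate", "SN", "PR", "SP", "F1"]
    assert len(df) == 2


def test_predict_deterministic_and_order_equivariant(small_trained, rng):
    lnc, mrna, models = small_trained
    model = clf.select_best_model(models)
    records = (lnc[:10] + mrna[:10])[::-1]
    a = clf.predict(records, model)
    b = clf.predict(records, model)
    assert a.equals(b)
    perm = list(rng.permutation(len(records)))
    c = clf.predict([records[i] for i in perm], model)
    assert list(c["transcript_id"]) == [records[i].id for i in perm]
    merged = a.set_index("transcript_id").loc[c["transcript_id"]]
    np.testing.assert_allclose(merged["score"].to_numpy(), c.set_index("transcript_id")["score"].to_numpy())


def test_predict_flags_too_short_sequences(small_trained):
    _, _, models = small_trained
    model = clf.select_best_model(models)
    out = clf.predict([SequenceRecord("tiny", "ACG"), SequenceRecord("ok", "ACGTACGTACGTACGT")], model)
    assert out.loc[out["transcript_id"] == "tiny", "label"].item() == "NA"
    assert out.loc[out["transcript_id"] == "ok", "label"].item() in {"coding", "noncoding"}


def test_model_serialisation_round_trip(small_trained, tmp_path, rng):
    """A reloaded model predicts identically to the in-memory one."""
    lnc, mrna, models = small_trained
    model = clf.select_best_model(models)
    path = tmp_path / "model.joblib"
    model.save(path)
    reloaded = clf.TrainedModel.load(path)
    records = [
        SequenceRecord(f"q{i}", "".join(rng.choice(list("ACGT"), size=300)))
        for i in range(100)
    ]
    np.testing.assert_array_equal(model.score_records(records), reloaded.score_records(records))


def test_label_noise_degrades_f1():
    """Swapping 20% of the labels strictly lowers mean replicate F1."""
    lnc, mrna = make_classifier_fixture(seed=3, n_per_class=75)
    config = clf.TrainingConfig(seed=3, n_replicates=3)
    clean = clf.train_replicates(lnc, mrna, config)
    k = len(lnc) // 5
    noisy_lnc = mrna[:k] + lnc[k:]
    noisy_mrna = lnc[:k] + mrna[k:]
    noisy = clf.train_replicates(noisy_lnc, noisy_mrna, config)

    def mean_f1(models):
        vals = [m.metrics.F1 for m in models if m.metrics.F1 is not None]
        return float(np.mean(vals))

    assert mean_f1(noisy) < mean_f1(clean)


def test_structure_features_stub():
    with pytest.raises(NotImplementedError):
        clf.structure_features(SequenceRecord("x", "ACGTACGT"))
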