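"""Trainable lncRNA-vs-mRNA sequence classifier.

The training protocol mirrors the balanced-replicate scheme used for
plant-genome model fitting: all known lncRNAs are kept, twice as many mRNAs
are sampled without replacement, each class is split 80/20 into train/test,
and the whole procedure is repeated in five independently seeded replicates.
The replicate with the highest held-out F1 is kept for prediction.

Features are LncFinder-inspired: a hexamer usage log-ratio score, spectral
summaries of the electron-ion interaction pseudopotential (EIIP) encoding,
and length/GC terms.  Secondary-structure features are deliberately not
implemented (see :func:`structure_features`).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "ConfusionCounts",
    "MetricsReport",
    "HexamerTable",
    "TrainedModel",
    "build_balanced_dataset",
    "split_train_test",
    "build_hexamer_table",
    "extract_features",
    "evaluate",
    "train_replicates",
    "select_best_model",
    "predict",
    "metrics_csv",
]

HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEXAMER_INDEX = {h: i for i, h in enumerate(HEXAMERS)}

# Electron-ion interaction pseudopotential per nucleotide.
EIIP = {"A": 0.1260, "G": 0.0806, "T": 0.1335, "C": 0.1340, "N": 0.0}

MIN_SEQUENCE_LENGTH = 6

FEATURE_NAMES = [
    "hexamer_score",
    "eiip_mean",
    "eiip_var",
    "eiip_q75",
    "log10_length",
    "gc_fraction",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the balanced replicate training protocol."""

    mrna_to_lncrna_ratio: int = 2
    train_fraction: float = 0.8
    n_replicates: int = 5
    seed: int = 1
    classifier: str = "mlp"  # {"mlp", "logistic"}
    hidden_layer_size: int = 16
    max_iter: int = 500
    decision_threshold: float = 0.5
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.mrna_to_lncrna_ratio <= 0:
            raise ValueError("mrna_to_lncrna_ratio must be > 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    """lncRNA is the positive class: TP = lncRNA predicted as lncRNA."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """SN, PR, SP, F1; ``None`` encodes an undefined (0/0) metric."""

    SN: Optional[float]
    PR: Optional[float]
    SP: Optional[float]
    F1: Optional[float]


def evaluate(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, precision, specificity and F1 from a confusion table.

    SN = TP/(TP+FN); PR = TP/(TP+FP); SP = TN/(TN+FP);
    F1 = 2*SN*PR/(SN+PR).  Any 0/0 yields ``None``, and F1 is ``None``
    whenever SN or PR is undefined or SN+PR = 0.
    """
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    sn = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else None
    pr = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else None
    sp = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else None
    if sn is None or pr is None or sn + pr == 0:
        f1 = None
    else:
        f1 = 2.0 * sn * pr / (sn + pr)
    return MetricsReport(SN=sn, PR=pr, SP=sp, F1=f1)


def build_balanced_dataset(
    lncrnas: Sequence[SequenceRecord],
    mrnas: Sequence[SequenceRecord],
    config: TrainingConfig,
    seed: int,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Keep every lncRNA; sample ratio x as many mRNAs without replacement.

    Returns ``(sampled_mrnas, all_lncrnas)``; deterministic for a fixed
    seed.  Raises when the mRNA pool is too small.
    """
    needed = config.mrna_to_lncrna_ratio * len(lncrnas)
    if len(mrnas) < needed:
        raise ValueError(
            f"need {needed} mRNAs to balance {len(lncrnas)} lncRNAs "
            f"at ratio {config.mrna_to_lncrna_ratio}, got {len(mrnas)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(mrnas), size=needed, replace=False)
    sampled = [mrnas[i] for i in sorted(idx)]
    return sampled, list(lncrnas)


def _split_one_class(
    records: Sequence[SequenceRecord], train_fraction: float, rng: np.random.Generator
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    n = len(records)
    if n < 5:
        raise ValueError(f"class with {n} members is too small to split (need >= 5)")
    n_train = math.floor(train_fraction * n)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [records[i] for i in range(n) if i in train_idx]
    test = [records[i] for i in range(n) if i not in train_idx]
    return train, test


def split_train_test(
    dataset: tuple[Sequence[SequenceRecord], Sequence[SequenceRecord]],
    config: TrainingConfig,
    seed: int,
) -> tuple[dict, dict]:
    """Stratified 80/20 split, performed independently within each class.

    ``dataset`` is ``(mrnas, lncrnas)`` as returned by
    :func:`build_balanced_dataset`; returns two dicts with keys ``mrna`` and
    ``lncrna``.  Train sizes are ``floor(train_fraction * n)`` per class.
    """
    mrnas, lncrnas = dataset
    rng = np.random.default_rng(seed)
    mrna_train, mrna_test = _split_one_class(mrnas, config.train_fraction, rng)
    lnc_train, lnc_test = _split_one_class(lncrnas, config.train_fraction, rng)
    return (
        {"mrna": mrna_train, "lncrna": lnc_train},
        {"mrna": mrna_test, "lncrna": lnc_test},
    )


class HexamerTable:
    """Smoothed relative frequencies of the 4096 hexamers per class."""

    def __init__(self, f_coding: np.ndarray, f_noncoding: np.ndarray, pseudocount: float):
        self.f_coding = f_coding
        self.f_noncoding = f_noncoding
        self.pseudocount = pseudocount
        self.log_ratio = np.log(f_coding) - np.log(f_noncoding)

    @staticmethod
    def _count(records: Iterable[SequenceRecord]) -> np.ndarray:
        counts = np.zeros(len(HEXAMERS), dtype=np.float64)
        for rec in records:
            seq = rec.seq
            for i in range(len(seq) - 5):
                idx = _HEXAMER_INDEX.get(seq[i : i + 6])
                if idx is not None:  # hexamers containing N are skipped
                    counts[idx] += 1
        return counts


def build_hexamer_table(
    train_mrnas: Iterable[SequenceRecord],
    train_lncrnas: Iterable[SequenceRecord],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Count overlapping hexamers per class, smooth and normalise."""
    coding = HexamerTable._count(train_mrnas) + pseudocount
    noncoding = HexamerTable._count(train_lncrnas) + pseudocount
    return HexamerTable(
        coding / coding.sum(), noncoding / noncoding.sum(), pseudocount
    )


def extract_features(record: SequenceRecord, table: HexamerTable) -> np.ndarray:
    """Fixed-dimension feature vector for one sequence.

    hexamer_score: mean log(f_coding/f_noncoding) over the sequence's
    overlapping hexamers; eiip_*: mean, variance and 75th percentile of the
    EIIP periodogram; plus log10 length and GC fraction.
    """
    seq = record.seq
    if len(seq) < MIN_SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence {record.id!r} shorter than {MIN_SEQUENCE_LENGTH} nt"
        )
    idxs = [
        _HEXAMER_INDEX[seq[i : i + 6]]
        for i in range(len(seq) - 5)
        if seq[i : i + 6] in _HEXAMER_INDEX
    ]
    hexamer_score = float(np.mean(table.log_ratio[idxs])) if idxs else 0.0

    signal = np.array([EIIP[b] for b in seq], dtype=np.float64)
    signal = signal - signal.mean()
    power = np.abs(np.fft.rfft(signal)) ** 2 / len(signal)
    spectrum = power[1:] if len(power) > 1 else power
    eiip_mean = float(spectrum.mean())
    eiip_var = float(spectrum.var())
    eiip_q75 = float(np.quantile(spectrum, 0.75))

    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return np.array(
        [hexamer_score, eiip_mean, eiip_var, eiip_q75, math.log10(len(seq)), gc]
    )


def structure_features(record: SequenceRecord):
    """Secondary-structure features are intentionally not computed.

    Folding-derived parameters roughly double runtime for about a one
    percent gain in recognition performance, so the classifier runs on
    sequence-derived features only.  The hook exists so a future backend can
    slot in without interface changes.
    """
    raise NotImplementedError("secondary-structure features are not implemented")


def _feature_matrix(records: Sequence[SequenceRecord], table: HexamerTable) -> np.ndarray:
    return np.vstack([extract_features(r, table) for r in records])


@dataclass
class TrainedModel:
    """A fitted replicate: hexamer table, scaler, classifier and metadata."""

    table: HexamerTable
    scaler: StandardScaler
    estimator: object
    decision_threshold: float
    seed: int
    replicate_index: int
    metrics: Optional[MetricsReport] = None

    def score_records(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        """P(noncoding) per record."""
        x = self.scaler.transform(_feature_matrix(records, self.table))
        return self.estimator.predict_proba(x)[:, 1]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        return joblib.load(path)


def _make_estimator(config: TrainingConfig, seed: int):
    if config.classifier == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(config.hidden_layer_size,),
            max_iter=config.max_iter,
            random_state=seed,
        )
    if config.classifier == "logistic":
        return LogisticRegression(max_iter=config.max_iter, random_state=seed)
    raise ValueError(f"unknown classifier kind {config.classifier!r}")


def _train_one(
    lncrnas: Sequence[SequenceRecord],
    mrnas: Sequence[SequenceRecord],
    config: TrainingConfig,
    replicate_index: int,
) -> TrainedModel:
    seed = config.seed + replicate_index
    dataset = build_balanced_dataset(lncrnas, mrnas, config, seed)
    train, test = split_train_test(dataset, config, seed)
    table = build_hexamer_table(train["mrna"], train["lncrna"], config.pseudocount)

    x_train = np.vstack(
        [_feature_matrix(train["mrna"], table), _feature_matrix(train["lncrna"], table)]
    )
    y_train = np.concatenate(
        [np.zeros(len(train["mrna"])), np.ones(len(train["lncrna"]))]
    )
    scaler = StandardScaler().fit(x_train)
    estimator = _make_estimator(config, seed).fit(scaler.transform(x_train), y_train)

    model = TrainedModel(
        table=table,
        scaler=scaler,
        estimator=estimator,
        decision_threshold=config.decision_threshold,
        seed=seed,
        replicate_index=replicate_index,
    )
    scores = model.score_records(test["mrna"] + test["lncrna"])
    pred = scores > config.decision_threshold
    truth = np.concatenate([np.zeros(len(test["mrna"])), np.ones(len(test["lncrna"]))]) == 1
    counts = ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        FP=int(np.sum(pred & ~truth)),
        TN=int(np.sum(~pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )
    model.metrics = evaluate(counts)
    return model


def train_replicates(
    lncrnas: Sequence[SequenceRecord],
    mrnas: Sequence[SequenceRecord],
    config: TrainingConfig,
) -> list[TrainedModel]:
    """Run ``n_replicates`` independently seeded sample/split/train rounds."""
    models = []
    for i in range(config.n_replicates):
        model = _train_one(lncrnas, mrnas, config, i)
        m = model.metrics
        logger.info(
            "replicate %d: SN=%s PR=%s SP=%s F1=%s", i, m.SN, m.PR, m.SP, m.F1
        )
        models.append(model)
    return models


def metrics_csv(models: Sequence[TrainedModel], path: str | Path) -> pd.DataFrame:
    """Per-replicate performance table, written as CSV."""
    def fmt(v):
        return "NA" if v is None else round(v, 6)

    df = pd.DataFrame(
        {
            "replicate": [m.replicate_index for m in models],
            "SN": [fmt(m.metrics.SN) for m in models],
            "PR": [fmt(m.metrics.PR) for m in models],
            "SP": [fmt(m.metrics.SP) for m in models],
            "F1": [fmt(m.metrics.F1) for m in models],
        }
    )
    df.to_csv(path, index=False)
    return df


def select_best_model(replicates: Sequence[TrainedModel]) -> TrainedModel:
    """Replicate with maximal F1; ties go to the lowest replicate index."""
    scored = [m for m in replicates if m.metrics and m.metrics.F1 is not None]
    if not scored:
        raise ValueError("no replicate has a defined F1")
    return max(scored, key=lambda m: (m.metrics.F1, -m.replicate_index))


def predict(
    records: Sequence[SequenceRecord], model: TrainedModel
) -> pd.DataFrame:
    """Label records coding/noncoding; noncoding ones are lncRNA candidates.

    Sequences shorter than 6 nt cannot be featurised: they get label NA and
    are excluded downstream (logged).
    """
    usable = [r for r in records if len(r.seq) >= MIN_SEQUENCE_LENGTH]
    skipped = [r for r in records if len(r.seq) < MIN_SEQUENCE_LENGTH]
    if skipped:
        logger.warning(
            "%d sequences shorter than %d nt labelled NA: %s",
            len(skipped), MIN_SEQUENCE_LENGTH, [r.id for r in skipped][:10],
        )
    score_of = {}
    if usable:
        scores = model.score_records(usable)
        score_of = {r.id: s for r, s in zip(usable, scores)}
    rows = []
    for r in records:
        if r.id in score_of:
            s = score_of[r.id]
            label = "noncoding" if s > model.decision_threshold else "coding"
            rows.append({"transcript_id": r.id, "score": float(s), "label": label})
        else:
            rows.append({"transcript_id": r.id, "score": float("nan"), "label": "NA"})
    return pd.DataFrame(rows)
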