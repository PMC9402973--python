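"""Evaluation metrics and the leakage-safe cross-validation harness.

Metrics are the standard quartet for imbalanced residue-level prediction:

    Sn  = TP / (TP + FN) * 100          (sensitivity / recall, %)
    Sp  = TN / (TN + FP) * 100          (specificity, %)
    Acc = (TP + TN) / total * 100       (accuracy, %)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator in Sn or Sp yields NaN with an explanatory flag (not 0);
a zero MCC denominator yields 0 with a flag, the usual convention.

``cross_validate`` runs the whole pipeline under stratified k-fold
cross-validation at the fragment level (chain-level splitting available):
for each fold the feature encoders (propensity tables, weight matrices) and
the standardizer are fitted on the training fragments only, a leakage
assertion checks the test fragments never touched the fitted encoders, and
pooled plus per-fold metrics are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .annotations import AnnotatedChain, LigandProfile
from .discretizers import ResidueClasses, DEFAULT_CLASSES, discretize_chain
from .encoders import FragmentFeaturizer
from .model import NetConfig, WindowNet
from .windows import fragments_from_chains, fragment_labels


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts; positives are binding residues."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


@dataclass
class Metrics:
    """Sn/Sp/Acc in percent, MCC in [-1, 1]; NaN marks undefined values."""

    sn: float
    sp: float
    acc: float
    mcc: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc,
                "flags": list(self.flags)}


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """The four evaluation metrics from confusion counts."""
    if c.total == 0:
        raise ValueError("no evaluated items")
    flags = []
    if c.tp + c.fn > 0:
        sn = 100.0 * c.tp / (c.tp + c.fn)
    else:
        sn = math.nan
        flags.append("Sn undefined: no positive items")
    if c.tn + c.fp > 0:
        sp = 100.0 * c.tn / (c.tn + c.fp)
    else:
        sp = math.nan
        flags.append("Sp undefined: no negative items")
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        flags.append("MCC denominator zero: 0 by convention")
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc, flags=tuple(flags))


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class MetricReport:
    """Per-fold and pooled (micro) cross-validation metrics."""

    per_fold: list[FoldResult]
    pooled: Metrics
    mean: Metrics  # nan-aware mean of the per-fold metrics
    pooled_counts: ConfusionCounts = field(default=None)

    def as_dict(self) -> dict:
        return {
            "pooled": self.pooled.as_dict(),
            "mean": self.mean.as_dict(),
            "pooled_counts": vars(self.pooled_counts),
            "per_fold": [
                {
                    "fold": fr.fold,
                    "counts": vars(fr.counts),
                    "metrics": fr.metrics.as_dict(),
                }
                for fr in self.per_fold
            ],
        }


def _mean_metrics(folds: Sequence[FoldResult]) -> Metrics:
    def nanmean(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else math.nan

    return Metrics(
        sn=nanmean([f.metrics.sn for f in folds]),
        sp=nanmean([f.metrics.sp for f in folds]),
        acc=nanmean([f.metrics.acc for f in folds]),
        mcc=nanmean([f.metrics.mcc for f in folds]),
        flags=tuple(
            sorted({flag for f in folds for flag in f.metrics.flags})
        ),
    )


def _fold_indices(fragments, labels, folds, seed, split):
    """Seeded fold assignment: stratified by label, or grouped by chain."""
    n = len(fragments)
    if split == "fragment":
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(n), labels))
    if split == "chain":
        chains = sorted({f.chain_id for f in fragments})
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(chains))
        assignment = {chains[j]: int(order[j] % folds) for j in range(len(chains))}
        fold_of = np.array([assignment[f.chain_id] for f in fragments])
        return [
            (np.nonzero(fold_of != k)[0], np.nonzero(fold_of == k)[0])
            for k in range(folds)
        ]
    raise ValueError(f"unknown split mode {split!r}")


def cross_validate(
    chains: Sequence[AnnotatedChain],
    profile: LigandProfile,
    feature_set: str = "full",
    config: NetConfig = NetConfig(),
    folds: int = 5,
    seed: int = 0,
    split: str = "fragment",
    standardize: bool = True,
    classes: ResidueClasses = DEFAULT_CLASSES,
) -> MetricReport:
    """k-fold cross-validated evaluation of the full pipeline.

    Per fold, the featurizer (propensity tables + weight matrices) and the
    standardizer are fitted on the training fragments only; a leakage
    assertion verifies the disjointness before scoring the held-out fold.
    """
    discretized = [discretize_chain(c, classes) for c in chains]
    fragments = fragments_from_chains(discretized, profile.window_length)
    labels = fragment_labels(fragments)
    if labels.sum() < folds:
        import warnings

        warnings.warn(
            f"only {int(labels.sum())} positive fragments for {folds} folds; "
            "some folds may have undefined sensitivity",
            stacklevel=2,
        )

    per_fold: list[FoldResult] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for k, (tr, te) in enumerate(_fold_indices(fragments, labels, folds, seed, split)):
        train_frags = [fragments[i] for i in tr]
        test_frags = [fragments[i] for i in te]

        featurizer = FragmentFeaturizer(feature_set=feature_set).fit(train_frags)
        featurizer.assert_disjoint(test_frags)
        X_tr = featurizer.transform(train_frags)
        X_te = featurizer.transform(test_frags)
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)

        net = WindowNet(
            hidden_layers=config.hidden_layers,
            hidden_nodes=config.hidden_nodes,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.patience,
            learning_rate=config.learning_rate,
            weight_decay=config.weight_decay,
            validation_fraction=config.validation_fraction,
            positive_weight=config.positive_weight,
            random_state=config.seed + k,
        ).fit(X_tr, labels[tr])

        counts = confusion_from_predictions(labels[te], net.predict(X_te))
        per_fold.append(FoldResult(fold=k, counts=counts, metrics=compute_metrics(counts)))
        pooled_counts = pooled_counts + counts

    return MetricReport(
        per_fold=per_fold,
        pooled=compute_metrics(pooled_counts),
        mean=_mean_metrics(per_fold),
        pooled_counts=pooled_counts,
    )
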