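"""Binary classification metrics and cross-validation sweeps.

Metrics are the four standard ones of the 6mA-prediction literature,
computed from the confusion counts (TP = correctly predicted 6mA,
TN = correctly predicted non-6mA):

    ACC = (TP + TN) / (TP + FN + TN + FP)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)

MCC returns 0 when its denominator vanishes (the uninformative-
classifier value); SN/SP return NaN when their class is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from methylvote.encoders import encode_matrix, get_encoder
from methylvote.ensemble import BaseClassifierSpec, train_base
from methylvote.sequence_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionMatrix:
    """The four counts TP/TN/FP/FN of a binary evaluation."""

    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_tn, self.n_fp, self.n_fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn


@dataclass
class MetricsReport:
    """ACC/MCC/SN/SP, optionally with per-fold values and provenance."""

    acc: float
    mcc: float
    sn: float
    sp: float
    folds: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"ACC": self.acc, "MCC": self.mcc, "SN": self.sn, "SP": self.sp}

    def __str__(self) -> str:  # 3 decimals, the field's reporting convention
        return "  ".join(f"{k}={v:.3f}" for k, v in self.as_dict().items())


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN from parallel true and predicted 0/1 labels."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size == 0:
        raise ValueError(
            f"label vectors must be equal-length and non-empty "
            f"(got {yt.shape} vs {yp.shape})"
        )
    return ConfusionMatrix(
        n_tp=int(np.sum((yt == 1) & (yp == 1))),
        n_tn=int(np.sum((yt == 0) & (yp == 0))),
        n_fp=int(np.sum((yt == 0) & (yp == 1))),
        n_fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(cm: ConfusionMatrix, metadata: dict | None = None) -> MetricsReport:
    """ACC, MCC, SN, SP from a confusion matrix (see module docstring)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    tp, tn, fp, fn = cm.n_tp, cm.n_tn, cm.n_fp, cm.n_fn
    acc = (tp + tn) / cm.total
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fn * fp) / denom if denom > 0 else 0.0
    sn = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return MetricsReport(acc=acc, mcc=mcc, sn=sn, sp=sp,
                         metadata=dict(metadata or {}))


def evaluate_predictions(y_true, y_pred, metadata: dict | None = None) -> MetricsReport:
    """Convenience: confusion counts + metrics in one call."""
    return compute_metrics(confusion_counts(y_true, y_pred), metadata)


def kfold_cv(
    data: LabeledDataset,
    encoder,
    spec: BaseClassifierSpec,
    folds: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of one encoder x classifier pair.

    Each sample is tested exactly once; the report carries per-fold
    metrics plus their means. Deterministic under ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = data.label_array()
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds}-fold CV")
    if isinstance(encoder, str):
        encoder = get_encoder(encoder)
    X = encode_matrix(data, encoder)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports: list[dict] = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        clf = train_base(spec, X[tr], y[tr])
        rep = evaluate_predictions(y[te], clf.predict(X[te]))
        fold_reports.append({"fold": i, **rep.as_dict()})
    means = {k: float(np.mean([f[k] for f in fold_reports]))
             for k in ("ACC", "MCC", "SN", "SP")}
    return MetricsReport(
        acc=means["ACC"], mcc=means["MCC"], sn=means["SN"], sp=means["SP"],
        folds=fold_reports,
        metadata={"encoder": encoder.name, "classifier": spec.algorithm,
                  "folds": folds, "seed": seed},
    )


def sweep(
    data: LabeledDataset,
    encoders: Sequence,
    specs: Sequence[BaseClassifierSpec],
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated metrics for every encoder x classifier combination.

    Returns a table shaped like the field's benchmark tables: one row per
    (classifier, metric), one column per encoder, identical folds and
    seed in every cell.
    """
    if not encoders or not specs:
        raise ValueError("need at least one encoder and one classifier spec")
    encoders = [get_encoder(e) if isinstance(e, str) else e for e in encoders]
    cells: dict[str, dict[tuple[str, str], float]] = {}
    for enc in encoders:
        col: dict[tuple[str, str], float] = {}
        for spec in specs:
            rep = kfold_cv(data, enc, spec, folds=folds, seed=seed)
            for metric, value in rep.as_dict().items():
                col[(spec.algorithm, metric)] = value
        cells[enc.name] = col
    index = pd.MultiIndex.from_tuples(
        [(s.algorithm, m) for s in specs for m in ("ACC", "SN", "SP", "MCC")],
        names=["classifier", "metric"],
    )
    table = pd.DataFrame(
        {name: [col[key] for key in index] for name, col in cells.items()},
        index=index,
    )
    return table
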