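"""Per-class metrics, confusion matrices and the comparison harnesses.

The report mirrors how beat-classification results are conventionally
tabulated: per-class precision/recall/F1 with supports, a confusion
matrix with true classes on the rows, overall accuracy with the
misclassified count, and macro averages.  "Macro" here averages over
classes with non-zero support only — a synthetic run may not realize
all 16 classes.

Two protocols are provided on top of plain evaluation: a preprocessing
comparison (same integration, split seed and training budget for every
operator, so rows differ only in the normalization) and the held-out
database protocol, where an entire foreign database — processed with
the identical window and operator — serves as the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .beats import WindowSpec
from .errors import ConfigurationError
from .integration import (
    ClassMap,
    DatabaseSource,
    IntegrationResult,
    build_class_map,
    integrate,
    stratified_split,
)
from .models import FcNetworkSpec, Network, TrainConfig, build_fc, train
from .preprocessing import BeatDataset


def percent(correct: int, total: int, decimals: int) -> float:
    """A count ratio as a percentage rounded to the printed precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * correct / total, decimals)


@dataclass
class EvalReport:
    per_class: pd.DataFrame  # class_id, precision, recall, f1, support
    confusion: np.ndarray  # rows = true class, columns = predicted
    overall_accuracy: float
    misclassified_count: int
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_total: int

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, n_classes: int = 16
    ) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if len(y_true) != len(y_pred) or len(y_true) == 0:
            raise ValueError("y_true and y_pred must be equal-length, non-empty")
        labels = np.arange(n_classes)
        conf = confusion_matrix(y_true, y_pred, labels=labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-support classes
            prec, rec, f1, supp = precision_recall_fscore_support(
                y_true, y_pred, labels=labels, zero_division=0
            )
        per_class = pd.DataFrame(
            {
                "class_id": labels,
                "precision": prec,
                "recall": rec,
                "f1": f1,
                "support": supp,
            }
        )
        present = supp > 0
        n_total = len(y_true)
        trace = int(np.trace(conf))
        return cls(
            per_class=per_class,
            confusion=conf,
            overall_accuracy=trace / n_total,
            misclassified_count=n_total - trace,
            macro_precision=float(prec[present].mean()),
            macro_recall=float(rec[present].mean()),
            macro_f1=float(f1[present].mean()),
            n_total=n_total,
        )

    def recall_percent(self, class_id: int, decimals: int = 3) -> float:
        """Recall of one class as a percentage, from the confusion counts."""
        support = int(self.confusion[class_id].sum())
        return percent(int(self.confusion[class_id, class_id]), support, decimals)

    def accuracy_percent(self, decimals: int = 2) -> float:
        return percent(self.n_total - self.misclassified_count, self.n_total,
                       decimals)

    def table(self, class_map: Optional[ClassMap] = None) -> pd.DataFrame:
        """Human-readable per-class table, rounded to 2 decimals."""
        df = self.per_class.copy()
        if class_map is not None:
            df.insert(1, "abbr", [class_map.abbr(c) for c in df["class_id"]])
        for col in ("precision", "recall", "f1"):
            df[col] = df[col].round(2)
        return df


def evaluate(model: Network, test_set: BeatDataset,
             n_classes: Optional[int] = None) -> EvalReport:
    """Deterministic inference over a test split + full metric report."""
    n_classes = n_classes or model.n_classes
    if test_set.A.shape[1] == 0 or len(test_set) == 0:
        raise ValueError("empty test set")
    if int(test_set.labels.max()) >= n_classes:
        raise ConfigurationError(
            "test labels exceed the model's class count — class scheme mismatch"
        )
    y_pred = model.predict(test_set.A)
    return EvalReport.from_predictions(test_set.labels, y_pred, n_classes)


def compare_preprocessing(
    databases: Sequence[DatabaseSource],
    methods: Sequence[str],
    window: WindowSpec = WindowSpec(),
    class_map: Optional[ClassMap] = None,
    train_config: TrainConfig = TrainConfig(max_epochs=30),
    fc_spec: Optional[FcNetworkSpec] = None,
    test_fraction: float = 0.2,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate the FC classifier once per preprocessing operator.

    The integration inputs, split seed, network initialization and
    training budget are identical across rows, so the table isolates
    the effect of the normalization alone.
    """
    deduped = list(dict.fromkeys(methods))
    if len(deduped) < len(methods):
        warnings.warn("duplicate preprocessing methods removed", stacklevel=2)
    methods = deduped
    if len(methods) < 2:
        raise ValueError("need at least 2 distinct methods to compare")
    if class_map is None:
        class_map = build_class_map()
    rows = []
    for method in methods:
        result = integrate(databases, window, class_map, preprocessor=method)
        split = stratified_split(result.dataset, test_fraction, seed=split_seed)
        spec = fc_spec or FcNetworkSpec(
            input_units=window.L, n_classes=class_map.n_classes
        )
        model = build_fc(spec, seed=train_config.seed)
        model, _ = train(model, split.train, train_config)
        report = evaluate(model, split.test)
        rows.append(
            {
                "method": method,
                "misclassified": report.misclassified_count,
                "accuracy": report.overall_accuracy,
                "macro_recall": report.macro_recall,
                "macro_precision": report.macro_precision,
                "macro_f1": report.macro_f1,
            }
        )
    return pd.DataFrame(rows)


def holdout_database_eval(
    model: Network,
    holdout: DatabaseSource,
    window: WindowSpec = WindowSpec(),
    class_map: Optional[ClassMap] = None,
    preprocessor: str = "self",
) -> EvalReport:
    """Inter-patient-style protocol: every extractable beat of a wholly
    held-out database is test data, processed exactly like training."""
    result: IntegrationResult = integrate(
        [holdout], window, class_map or build_class_map(), preprocessor
    )
    return evaluate(model, result.dataset)


def save_report(report: EvalReport, out_dir,
                class_map: Optional[ClassMap] = None) -> None:
    """Write report.json, confusion.csv and per_class.csv."""
    import json
    from pathlib import Path

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    (d / "report.json").write_text(
        json.dumps(
            {
                "overall_accuracy": report.overall_accuracy,
                "misclassified_count": report.misclassified_count,
                "n_total": report.n_total,
                "macro_precision": report.macro_precision,
                "macro_recall": report.macro_recall,
                "macro_f1": report.macro_f1,
            },
            indent=1,
        )
    )
    np.savetxt(d / "confusion.csv", report.confusion, fmt="%d", delimiter=",")
    report.table(class_map).to_csv(d / "per_class.csv", index=False)
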