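"""RBF-kernel SVM for hairpin classification, with CV and metric reporting.

The model is an RBF support vector machine (C = 8.0, gamma = 0.03125 by
default) trained on [-1, 1] min-max rescaled feature matrices, with sigmoid
probability calibration so that candidates can be filtered at a probability
cutoff (0.8 by default for novel-miRNA triage).  Evaluation reports
sensitivity, specificity, accuracy (percent) and Matthews correlation, plus
pooled ROC points, from leave-one-out or stratified k-fold cross-validation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_C = 8.0
DEFAULT_GAMMA = 0.03125


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the RBF-SVM: kernel width gamma and penalty C."""

    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    probability_calibration: bool = True

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature min/max for svm-scale style rescaling to [-1, 1].

    Constant features map to 0; unseen values extrapolate beyond the
    interval (no clipping), matching LIBSVM's svm-scale behaviour.
    """

    feature_names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        x = matrix[list(self.feature_names)].to_numpy(dtype=float)
        span = self.maxima - self.minima
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = -1.0 + 2.0 * (x - self.minima) / span
        scaled[:, span == 0] = 0.0
        return pd.DataFrame(scaled, index=matrix.index, columns=self.feature_names)


def fit_scaler(matrix: pd.DataFrame) -> ScalingParams:
    if len(matrix) < 1:
        raise ValueError("cannot fit a scaler on an empty matrix")
    x = matrix.to_numpy(dtype=float)
    return ScalingParams(
        feature_names=tuple(matrix.columns),
        minima=x.min(axis=0),
        maxima=x.max(axis=0),
    )


@dataclass
class HairpinClassifier:
    """A trained scaler + SVM bundle keyed to a fixed feature-name order."""

    spec: ModelSpec
    scaler: ScalingParams
    svm: SVC
    seed: int
    n_pos: int
    n_neg: int

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.scaler.feature_names

    def predict_score(self, matrix: pd.DataFrame) -> np.ndarray:
        """Calibrated positive-class probability for each row, in [0, 1]."""
        missing = set(self.feature_names) - set(matrix.columns)
        extra = set(matrix.columns) - set(self.feature_names)
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        scaled = self.scaler.apply(matrix)
        pos_col = list(self.svm.classes_).index(1)
        return self.svm.predict_proba(scaled.to_numpy())[:, pos_col]

    def predict(self, matrix: pd.DataFrame, cutoff: float = 0.5) -> np.ndarray:
        """+1/-1 labels at a probability cutoff."""
        return np.where(self.predict_score(matrix) >= cutoff, 1, -1)


def train(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> HairpinClassifier:
    """Fit the scaler and the SVM on a labelled feature matrix.

    Labels are +1 (real hairpin) / -1 (pseudo hairpin); both classes must be
    present.  Deterministic for a given seed (the seed drives the internal
    calibration CV).
    """
    spec = spec or ModelSpec()
    labels = np.asarray(labels)
    classes = set(np.unique(labels))
    if classes != {1, -1}:
        raise ValueError(f"need both classes +1 and -1, got {sorted(classes)}")
    scaler = fit_scaler(matrix)
    scaled = scaler.apply(matrix)
    # libsvm's built-in Platt sigmoid fit; sklearn 1.9 deprecates the flag in
    # favour of CalibratedClassifierCV but the native path matches svm-train -b
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        svm = SVC(
            C=spec.C,
            gamma=spec.gamma,
            kernel="rbf",
            probability=spec.probability_calibration,
            random_state=seed,
        )
        svm.fit(scaled.to_numpy(), labels)
    return HairpinClassifier(
        spec=spec,
        scaler=scaler,
        svm=svm,
        seed=seed,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == -1).sum()),
    )


MODEL_FORMAT = "srnakit-svm/1"


def save_model(model: HairpinClassifier, path) -> None:
    """Persist the scaler + SVM bundle with a format tag (joblib archive)."""
    import joblib

    joblib.dump({"format": MODEL_FORMAT, "model": model}, path)


def load_model(path) -> HairpinClassifier:
    import joblib

    payload = joblib.load(path)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"unknown model format: {payload.get('format')!r}")
    return payload["model"]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts with Sn/Sp/Ac in percent, MCC, and ROC points."""

    tp: int
    fp: int
    tn: int
    fn: int
    roc: tuple[tuple[float, float], ...] = field(default=())
    auc: float = float("nan")

    @property
    def sn(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def sp(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def ac(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else 0.0

    @property
    def mcc(self) -> float:
        den = (
            (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tp + self.fp)
            * (self.tn + self.fn)
        )
        if den == 0:
            return 0.0
        return (self.tp * self.tn - self.fn * self.fp) / math.sqrt(den)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sn": self.sn,
            "sp": self.sp,
            "ac": self.ac,
            "mcc": self.mcc,
            "auc": self.auc,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Build a report from confusion counts (all >= 0, total > 0)."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("confusion counts must be non-negative with total > 0")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_rates(sn_pct: float, sp_pct: float, n_pos: int, n_neg: int) -> MetricsReport:
    """Reconstruct confusion counts from printed Sn/Sp at known class sizes.

    TP = round(n_pos * Sn), TN = round(n_neg * Sp); useful for re-deriving
    accuracy and MCC from published sensitivity/specificity pairs.
    """
    tp = round(n_pos * sn_pct / 100.0)
    tn = round(n_neg * sp_pct / 100.0)
    return confusion_metrics(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def cross_validate(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    folds: int | None = 10,
    loo: bool = False,
    spec: ModelSpec | None = None,
    seed: int = 0,
    cutoff: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold (or leave-one-out) CV with pooled confusion counts.

    The scaler is fitted inside each training fold only; ROC points come
    from the pooled held-out probability scores.  ``folds == n`` is
    equivalent to LOO.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if loo or folds == n:
        splits = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    else:
        if folds is None or folds < 2:
            raise ValueError("folds must be >= 2 (or use loo=True)")
        counts = pd.Series(labels).value_counts()
        if folds > counts.min():
            raise ValueError(
                f"fold count {folds} exceeds smallest class size {counts.min()}"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), labels))

    scores = np.empty(n)
    for train_idx, test_idx in splits:
        model = train(
            matrix.iloc[list(train_idx)], labels[list(train_idx)], spec=spec, seed=seed
        )
        scores[list(test_idx)] = model.predict_score(matrix.iloc[list(test_idx)])

    predicted = np.where(scores >= cutoff, 1, -1)
    tp = int(((predicted == 1) & (labels == 1)).sum())
    fp = int(((predicted == 1) & (labels == -1)).sum())
    tn = int(((predicted == -1) & (labels == -1)).sum())
    fn = int(((predicted == -1) & (labels == 1)).sum())
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        roc=tuple(zip(fpr.tolist(), tpr.tolist())),
        auc=float(_auc(fpr, tpr)),
    )
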