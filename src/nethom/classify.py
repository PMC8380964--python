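"""Patient-vs-control classification from a single region's NH.

A Gaussian-kernel (RBF) soft-margin SVM is evaluated by leave-one-out
cross-validation: for each of the X subjects the classifier is
trained on the other X-1 (features z-scored with training-fold
statistics) and predicts the held-out subject. Hyperparameters (cost
C and kernel width gamma) are chosen from a log2 grid by maximal LOO
accuracy, ties broken by smallest C then smallest gamma. Patients are
the positive class, so sensitivity is the fraction of patients
detected.

Selecting (C, gamma) on the same LOO loop that reports accuracy is
optimistic; ``nested=True`` provides honest nested-CV estimates at
quadratic cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .types import NethomError

__all__ = [
    "ClassificationResult",
    "default_grid",
    "confusion_metrics",
    "loo_svm_single_region",
]


def default_grid() -> list[float]:
    """C and gamma candidates: 2^-5, 2^-3, ..., 2^5."""
    return [2.0**e for e in range(-5, 6, 2)]


@dataclass
class ClassificationResult:
    region: str
    sensitivity: float  # percent
    specificity: float
    accuracy: float
    patients_correct: int
    n_patients: int
    controls_correct: int
    n_controls: int
    C: float
    gamma: float

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.accuracy):
            if not 0.0 <= v <= 100.0:
                raise NethomError("metrics must be percentages in [0, 100]")
        # accuracy identity in counts
        total_correct = self.patients_correct + self.controls_correct
        total = self.n_patients + self.n_controls
        if round(self.accuracy * total) != round(100.0 * total_correct):
            raise NethomError("accuracy inconsistent with confusion counts")

    def counts(self) -> dict[str, str]:
        return {
            "sensitivity": f"{self.patients_correct}/{self.n_patients}",
            "specificity": f"{self.controls_correct}/{self.n_controls}",
            "accuracy": (
                f"{self.patients_correct + self.controls_correct}/"
                f"{self.n_patients + self.n_controls}"
            ),
        }


def confusion_metrics(predicted, truth, positive_class: str = "patient") -> dict:
    """Sensitivity/specificity/accuracy (percent) with k/n count strings."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise NethomError("predicted and truth labels differ in length")
    pos = truth == positive_class
    if pos.sum() == 0:
        raise NethomError(f"no members of positive class {positive_class!r}")
    if (~pos).sum() == 0:
        raise NethomError("no negative-class members; specificity undefined")
    tp = int((predicted[pos] == positive_class).sum())
    tn = int((predicted[~pos] != positive_class).sum())
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    return {
        "sensitivity": 100.0 * tp / n_pos,
        "specificity": 100.0 * tn / n_neg,
        "accuracy": 100.0 * (tp + tn) / (n_pos + n_neg),
        "counts": {
            "sensitivity": f"{tp}/{n_pos}",
            "specificity": f"{tn}/{n_neg}",
            "accuracy": f"{tp + tn}/{n_pos + n_neg}",
        },
    }


def _loo_predictions(x: np.ndarray, y: np.ndarray, C: float, gamma: float) -> np.ndarray:
    n = x.shape[0]
    pred = np.empty(n, dtype=y.dtype)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        xt = x[tr]
        mu, sd = xt.mean(axis=0), xt.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        clf = SVC(C=C, kernel="rbf", gamma=gamma)
        clf.fit((xt - mu) / sd, y[tr])
        pred[i] = clf.predict(((x[i] - mu) / sd)[None, :])[0]
    return pred


def loo_svm_single_region(
    features: pd.DataFrame,
    labels,
    region: str,
    grid: list[float] | None = None,
    nested: bool = False,
) -> ClassificationResult:
    """LOO RBF-SVM on one region-mean NH feature.

    ``features`` is subjects x regions; ``labels`` the group label per
    subject in the same order. ``nested=True`` selects (C, gamma) by
    an inner LOO within each outer training fold instead of on the
    reporting loop.
    """
    if region not in features.columns:
        raise NethomError(f"region {region!r} not in features {list(features.columns)}")
    if grid is None:
        grid = default_grid()
    if len(grid) == 0:
        raise NethomError("empty hyperparameter grid")
    y = np.asarray(labels)
    x = features[region].to_numpy(dtype=float)[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise NethomError("single-class input")
    if counts.min() < 3:
        raise NethomError("need at least 3 subjects per class")

    pairs = [(C, g) for C in sorted(grid) for g in sorted(grid)]

    if nested:
        n = x.shape[0]
        pred = np.empty(n, dtype=y.dtype)
        best_pair = None
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            accs = [
                (np.mean(_loo_predictions(x[tr], y[tr], C, g) == y[tr]), -C, -g, C, g)
                for C, g in pairs
            ]
            accs.sort(key=lambda a: (-a[0], -a[1], -a[2]))
            _, _, _, C, g = accs[0]
            best_pair = (C, g)
            mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            clf = SVC(C=C, kernel="rbf", gamma=g).fit((x[tr] - mu) / sd, y[tr])
            pred[i] = clf.predict(((x[i] - mu) / sd)[None, :])[0]
        best_C, best_g = best_pair
        best_pred = pred
    else:
        best = None
        for C, g in pairs:
            pred = _loo_predictions(x, y, C, g)
            acc = float(np.mean(pred == y))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, g, pred)
        _, best_C, best_g, best_pred = best

    m = confusion_metrics(best_pred, y, positive_class="patient")
    pos = y == "patient"
    return ClassificationResult(
        region=region,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        patients_correct=int((best_pred[pos] == "patient").sum()),
        n_patients=int(pos.sum()),
        controls_correct=int((best_pred[~pos] != "patient").sum()),
        n_controls=int((~pos).sum()),
        C=best_C,
        gamma=best_g,
    )
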