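"""Monte Carlo balanced-subsample SVM classification of subjects.

Each subject is represented by two features: mean saccadic latency in the
Landolt task and in the color task.  Because the patient group (n = 13) is
smaller than the pooled comparison groups, every Monte Carlo iteration
draws a balanced subsample of 26 subjects (13 per class), runs
leave-one-out cross-validation with a radial-basis-kernel SVM, and
accumulates the confusion counts.  Sensitivity is the patient detection
rate; specificity the rate at which non-patients are cleared.

Three classification schemes are supported:

- ``P_vs_C``   patients vs healthy controls,
- ``P_vs_RC``  patients vs pooled relatives + controls,
- ``PR_vs_C``  pooled patients + relatives vs healthy controls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

POSITIVE_LABEL = 1
SUBSAMPLE_PER_CLASS = 13

#: scheme id -> (positive-class groups, negative-class groups)
SCHEMES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "P_vs_C": (("patient",), ("control",)),
    "P_vs_RC": (("patient",), ("control", "relative")),
    "PR_vs_C": (("patient", "relative"), ("control",)),
}


@dataclass(frozen=True)
class SVMConfig:
    """Radial-kernel SVM settings (the defaults of a standard SVM package:
    cost 1, kernel width 1/n_features, features standardized with
    training-fold statistics)."""

    cost: float = 1.0
    gamma: str | float = "auto"
    standardize: bool = True


@dataclass
class ClassificationResult:
    """Aggregated sensitivity/specificity over Monte Carlo iterations.

    Confusion counts are means over iterations (each iteration's counts
    sum to 26); ``confusion_rounded`` gives them as integers for
    reporting.  ``convergence`` holds (iteration, running accuracy) pairs.
    """

    scheme: str
    iterations: int
    mean_sensitivity: float
    mean_specificity: float
    mean_tp: float
    mean_fp: float
    mean_tn: float
    mean_fn: float
    seed: int | None = None
    convergence: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        total = self.mean_tp + self.mean_fp + self.mean_tn + self.mean_fn
        return 100.0 * (self.mean_tp + self.mean_tn) / total

    @property
    def confusion_rounded(self) -> dict:
        return {k: int(round(v)) for k, v in
                [("tp", self.mean_tp), ("fp", self.mean_fp),
                 ("tn", self.mean_tn), ("fn", self.mean_fn)]}

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "iterations": self.iterations,
            "mean_sensitivity_pct": 100.0 * self.mean_sensitivity,
            "mean_specificity_pct": 100.0 * self.mean_specificity,
            "mean_accuracy_pct": self.mean_accuracy,
            "mean_confusion": {"tp": self.mean_tp, "fp": self.mean_fp,
                               "tn": self.mean_tn, "fn": self.mean_fn},
            "confusion_rounded": self.confusion_rounded,
            "seed": self.seed,
            "convergence": self.convergence,
        }

    def to_json(self, path=None) -> str | None:
        text = json.dumps(self.to_dict(), indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def summary(self) -> str:
        c = self.confusion_rounded
        return (f"scheme {self.scheme}: {self.iterations} iterations, "
                f"sensitivity {100 * self.mean_sensitivity:.0f}%, "
                f"specificity {100 * self.mean_specificity:.0f}%, "
                f"accuracy {self.mean_accuracy:.0f}% "
                f"(TP {c['tp']}, FP {c['fp']}, TN {c['tn']}, FN {c['fn']})")


def build_features(summaries: pd.DataFrame) -> pd.DataFrame:
    """One (SL_landolt, SL_color) feature vector per subject.

    ``summaries`` is the per-subject table from ``stats.task_means`` (or
    any frame with ``group, sl_color, sl_landolt`` indexed or keyed by
    subject).  Subjects with a missing task mean are dropped with a
    warning; duplicated subject ids are rejected.
    """
    df = summaries.reset_index() if summaries.index.name == "subject_id" else summaries.copy()
    required = {"subject_id", "group", "sl_color", "sl_landolt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject id in feature table")
    bad = ~(np.isfinite(df["sl_color"]) & np.isfinite(df["sl_landolt"])
            & (df["sl_color"] > 0) & (df["sl_landolt"] > 0))
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} subject(s) with missing or "
                      "non-positive task means", stacklevel=2)
        df = df[~bad]
    return df[["subject_id", "group", "sl_landolt", "sl_color"]].reset_index(drop=True)


def draw_subsample(features: pd.DataFrame, scheme: str,
                   rng: np.random.Generator | int | None = None):
    """Draw a balanced 26-subject subsample (13 per class) for one iteration.

    Positive-class members (patients, plus relatives under ``PR_vs_C``)
    and negative-class members are sampled without replacement from their
    pools.  Returns ``(X, y, subject_ids)`` with X columns
    (SL_landolt, SL_color) and y = 1 for the positive (patient) class.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos_groups, neg_groups = SCHEMES[scheme]
    pos_pool = features.index[features["group"].isin(pos_groups)].to_numpy()
    neg_pool = features.index[features["group"].isin(neg_groups)].to_numpy()
    for pool, side in ((pos_pool, "positive"), (neg_pool, "negative")):
        if len(pool) < SUBSAMPLE_PER_CLASS:
            raise ValueError(
                f"{side} pool has {len(pool)} subjects, need {SUBSAMPLE_PER_CLASS}")
    pos = rng.choice(pos_pool, SUBSAMPLE_PER_CLASS, replace=False)
    neg = rng.choice(neg_pool, SUBSAMPLE_PER_CLASS, replace=False)
    idx = np.concatenate([pos, neg])
    X = features.loc[idx, ["sl_landolt", "sl_color"]].to_numpy(dtype=float)
    y = np.concatenate([np.ones(SUBSAMPLE_PER_CLASS, dtype=int),
                        np.zeros(SUBSAMPLE_PER_CLASS, dtype=int)])
    return X, y, features.loc[idx, "subject_id"].to_numpy()


def loocv_svm(X: np.ndarray, y: np.ndarray, config: SVMConfig | None = None) -> np.ndarray:
    """Leave-one-out predictions with a radial-kernel SVM.

    For each held-out subject the SVM is trained on the remaining 25,
    with features standardized using training-fold statistics, and the
    held-out subject is predicted.  Returns the predicted labels.
    """
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate (constant) features")
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        xte = X[i:i + 1]
        if config.standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            xte = (xte - mu) / sd
        clf = SVC(C=config.cost, kernel="rbf", gamma=config.gamma)
        clf.fit(Xtr, ytr)
        preds[i] = clf.predict(xte)[0]
    return preds


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) with the patient class (label 1) positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == POSITIVE_LABEL) & (y_pred == POSITIVE_LABEL)))
    fp = int(np.sum((y_true != POSITIVE_LABEL) & (y_pred == POSITIVE_LABEL)))
    tn = int(np.sum((y_true != POSITIVE_LABEL) & (y_pred != POSITIVE_LABEL)))
    fn = int(np.sum((y_true == POSITIVE_LABEL) & (y_pred != POSITIVE_LABEL)))
    return tp, fp, tn, fn


def confusion_metrics(tp: float, fp: float, tn: float, fn: float) -> dict:
    """Accuracy, sensitivity and specificity in percent from confusion counts."""
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")
    return {
        "accuracy_pct": 100.0 * (tp + tn) / total,
        "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
    }


def monte_carlo(features: pd.DataFrame, scheme: str, iterations: int = 10_000,
                seed: int | None = None, config: SVMConfig | None = None,
                convergence_points: int = 20) -> ClassificationResult:
    """Monte Carlo balanced-subsampling LOOCV, averaged over iterations.

    Sensitivity and specificity are computed per iteration and averaged
    (per-iteration averaging).  The running mean accuracy is recorded at
    ``convergence_points`` checkpoints as a convergence diagnostic.
    Fully reproducible from (features, scheme, iterations, seed).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    config = config or SVMConfig()
    rng = np.random.default_rng(seed)
    sens = np.empty(iterations)
    spec = np.empty(iterations)
    conf = np.zeros(4)
    acc = np.empty(iterations)
    for it in range(iterations):
        X, y, _ = draw_subsample(features, scheme, rng)
        preds = loocv_svm(X, y, config)
        tp, fp, tn, fn = confusion_counts(y, preds)
        sens[it] = tp / (tp + fn)
        spec[it] = tn / (tn + fp)
        acc[it] = (tp + tn) / (tp + fp + tn + fn)
        conf += (tp, fp, tn, fn)
    step = max(1, iterations // convergence_points)
    running = np.cumsum(acc) / np.arange(1, iterations + 1)
    convergence = [(int(i + 1), float(running[i]))
                   for i in range(step - 1, iterations, step)]
    conf /= iterations
    return ClassificationResult(
        scheme=scheme, iterations=iterations,
        mean_sensitivity=float(sens.mean()), mean_specificity=float(spec.mean()),
        mean_tp=conf[0], mean_fp=conf[1], mean_tn=conf[2], mean_fn=conf[3],
        seed=seed, convergence=convergence)


class SubsampledSVMClassifier:
    """Model-style wrapper: features in, ``ClassificationResult`` out.

    ``decision_surface`` exports the decision function of a single
    subsample's SVM on a feature grid, for plotting the classifier's
    regions in (SL_landolt, SL_color) space.
    """

    def __init__(self, features: pd.DataFrame, scheme: str = "P_vs_RC",
                 iterations: int = 10_000, seed: int | None = None,
                 config: SVMConfig | None = None):
        self.features = build_features(features)
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.scheme = scheme
        self.iterations = iterations
        self.seed = seed
        self.config = config or SVMConfig()

    @classmethod
    def from_results(cls, results, **kwargs) -> "SubsampledSVMClassifier":
        """Build from ``LatencyModulationResults`` subject summaries."""
        return cls(results.subject_summaries, **kwargs)

    def fit(self) -> ClassificationResult:
        return monte_carlo(self.features, self.scheme, self.iterations,
                           self.seed, self.config)

    def decision_surface(self, seed: int | None = None, grid_size: int = 60):
        """(landolt_grid, color_grid, decision_values, X, y) for one subsample."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        X, y, _ = draw_subsample(self.features, self.scheme, rng)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        clf = SVC(C=self.config.cost, kernel="rbf", gamma=self.config.gamma)
        clf.fit((X - mu) / sd if self.config.standardize else X, y)
        pad = 0.1 * (X.max(axis=0) - X.min(axis=0))
        gx = np.linspace(X[:, 0].min() - pad[0], X[:, 0].max() + pad[0], grid_size)
        gy = np.linspace(X[:, 1].min() - pad[1], X[:, 1].max() + pad[1], grid_size)
        xx, yy = np.meshgrid(gx, gy)
        grid = np.column_stack([xx.ravel(), yy.ravel()])
        if self.config.standardize:
            grid = (grid - mu) / sd
        zz = clf.decision_function(grid).reshape(xx.shape)
        return xx, yy, zz, X, y

    def plot_decision_surface(self, ax=None, **kwargs):
        """Plot one subsample's decision regions (requires matplotlib)."""
        import matplotlib.pyplot as plt

        xx, yy, zz, X, y = self.decision_surface(**kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ax.contourf(xx, yy, zz > 0, alpha=0.3, cmap="coolwarm")
        ax.scatter(X[y == 1, 0], X[y == 1, 1], c="crimson", label="patients")
        ax.scatter(X[y == 0, 0], X[y == 0, 1], c="navy", label="comparison")
        ax.set_xlabel("SL Landolt (ms)")
        ax.set_ylabel("SL color (ms)")
        ax.legend()
        return ax
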