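"""Metrics, the paired t-test, and the four-model experiment runner.

Metric conventions
------------------
Confusion matrices are oriented rows = predicted class, columns = actual
class (so a class's column sums to its number of evaluated instances).
Accuracy is trace/total. Sensitivity and specificity are one-vs-rest per
class — TPR_c is the fraction of class-c instances predicted c, TNR_c comes
from the collapsed 2x2 table — and reported as unweighted (macro) means
over classes, alongside the per-class values.

Experiment runner
-----------------
:class:`ExperimentModel` is built from a labelled dataset plus a pipeline
configuration (affine transform, window geometry, HOG geometry, classifier
and its hyperparameters). ``fit(seed)`` executes the full pipeline —
indicator encoding, affine transform, windowed RGB image, BT.601 grayscale,
36-element HOG, classifier training on a stratified 70/15/15 split — and
returns an :class:`ExperimentResults` carrying the confusion matrix, the
metric suite and a ``summary()`` table. The four canonical pipelines are::

    1: Z-curve     + HOG + MLP
    2: tetrahedron + HOG + MLP
    3: Z-curve     + HOG + RBF
    4: tetrahedron + HOG + RBF
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifiers import (
    MlpConfig,
    MlpNetwork,
    RbfConfig,
    RbfNetwork,
    mlp_predict,
    rbf_predict,
    train_mlp,
    train_rbf,
)
from .encoding import affine_transform, voss_encode
from .features import HogConfig, hog_features
from .imaging import ImagingConfig, signal_to_image
from .sequences import NORMAL_CLASS, LabeledDataset, split_dataset

__all__ = [
    "ConfusionMatrix",
    "TTestResult",
    "confusion_matrix",
    "accuracy_from_cm",
    "macro_metrics",
    "mse_score",
    "roc_curves",
    "paired_t_test",
    "extract_features",
    "one_hot",
    "gene_of_class",
    "gene_level_accuracy",
    "mutant_gene_recovery",
    "MODEL_PIPELINES",
    "ExperimentModel",
    "ExperimentResults",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# Confusion matrix and scalar metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """KxK counts, rows = predicted class, columns = actual class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.class_names)
        if c.shape != (k, k):
            raise ValueError("counts must be KxK matching class_names")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


def confusion_matrix(y_true, y_pred, class_names: list[str]) -> ConfusionMatrix:
    index = {c: i for i, c in enumerate(class_names)}
    k = len(class_names)
    counts = np.zeros((k, k), dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    for actual, predicted in zip(y_true, y_pred):
        try:
            counts[index[predicted], index[actual]] += 1
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None
    return ConfusionMatrix(counts, list(class_names))


def accuracy_from_cm(cm: ConfusionMatrix) -> float:
    """Trace over grand total: the fraction of correctly classified instances."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, dict]:
    """One-vs-rest sensitivity/specificity per class plus their macro means.

    TPR_c = counts[c, c] / column-c total (0 when the column is empty);
    TNR_c = TN / (TN + FP) from the collapsed 2x2 table.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    col = c.sum(axis=0)  # actual-class totals
    row = c.sum(axis=1)  # predicted-class totals
    diag = np.diag(c)
    tpr = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    tn = total - col - row + diag
    negatives = total - col
    tnr = np.divide(tn, negatives, out=np.ones_like(tn), where=negatives > 0)
    per_class = {
        name: {"sensitivity": float(tpr[i]), "specificity": float(tnr[i])}
        for i, name in enumerate(cm.class_names)
    }
    return float(tpr.mean()), float(tnr.mean()), per_class


def mse_score(targets: np.ndarray, outputs: np.ndarray) -> float:
    """Mean squared difference between expected and actual outputs, over all
    m*K entries."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise ValueError("shape mismatch between targets and outputs")
    return float(np.mean((targets - outputs) ** 2))


def roc_curves(scores: np.ndarray, y_true, class_names: list[str]) -> dict:
    """One-vs-rest ROC per class: threshold sweep over the class scores with
    trapezoidal AUC. A class with no positive (or no negative) instances has
    no defined curve and is reported with ``auc = None``."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    out = {}
    for i, name in enumerate(class_names):
        positive = (y_true == name).astype(int)
        if positive.sum() == 0 or positive.sum() == len(positive):
            out[name] = {"fpr": None, "tpr": None, "auc": None}
            continue
        fpr, tpr, _ = _sk_roc_curve(positive, scores[:, i])
        out[name] = {"fpr": fpr, "tpr": tpr, "auc": float(_sk_auc(fpr, tpr))}
    return out


# ---------------------------------------------------------------------------
# Paired t-test


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    sd: float
    n: int
    t: float
    p: float
    ci95: tuple[float, float]
    degenerate: bool = False


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired t-test on differences d = b - a.

    M = mean(d), SD = sample standard deviation (n-1 denominator),
    t = M / (SD / sqrt(n)), p two-tailed from Student's t with n-1 degrees
    of freedom, and a 95% confidence interval M +- t_crit * SD / sqrt(n).
    A zero SD is degenerate: t = 0 and p = 1 when M = 0, else p = 0 with
    the degeneracy flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = b - a
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if m == 0.0:
            return TTestResult(m, sd, n, 0.0, 1.0, (0.0, 0.0), degenerate=True)
        sign = np.sign(m)
        return TTestResult(m, sd, n, float(sign * np.inf), 0.0, (m, m),
                           degenerate=True)
    se = sd / np.sqrt(n)
    t = m / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    t_crit = float(stats.t.ppf(0.975, df=n - 1))
    return TTestResult(m, sd, n, float(t), p, (m - t_crit * se, m + t_crit * se))


# ---------------------------------------------------------------------------
# Pipeline: sequences -> HOG feature matrix


def extract_features(
    ds: LabeledDataset,
    transform: str,
    imaging: ImagingConfig = ImagingConfig(),
    hog: HogConfig = HogConfig(),
    cumulative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Run every sample through encode -> transform -> image -> grayscale ->
    HOG, returning the n x 36 feature matrix and the label array."""
    rows = []
    labels = []
    for s in ds.samples:
        signal = affine_transform(voss_encode(s), transform, cumulative=cumulative)
        img = signal_to_image(signal, imaging)
        rows.append(hog_features(img.gray, hog))
        labels.append(s.label)
    return np.vstack(rows), np.asarray(labels)


def one_hot(labels, class_names: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    y = np.zeros((len(labels), len(class_names)))
    for r, lab in enumerate(labels):
        y[r, index[lab]] = 1.0
    return y


def gene_of_class(class_name: str) -> str:
    """Map a class label to its gene ('Normal' maps to itself)."""
    if class_name == NORMAL_CLASS:
        return NORMAL_CLASS
    return class_name.rpartition(" ")[0]


def gene_level_accuracy(y_true, y_pred) -> float:
    """Accuracy after collapsing each class to its gene, so confusing the
    substitution and deletion classes of the same gene is not penalised.
    The normal class, having no gene, collapses to itself."""
    hits = sum(
        gene_of_class(t) == gene_of_class(p) for t, p in zip(y_true, y_pred)
    )
    return hits / len(y_true)


def mutant_gene_recovery(y_true, y_pred) -> float:
    """Gene recovery over the truly mutated samples only: the fraction whose
    predicted class names the correct mutated gene. A normal prediction for
    a mutated sample counts as a miss. This is the screening question the
    pipeline exists for — *which* biomarker gene carries the mutation — and
    it is well defined even though the normal class maps to no gene."""
    pairs = [
        (t, p) for t, p in zip(y_true, y_pred) if t != NORMAL_CLASS
    ]
    if not pairs:
        raise ValueError("no mutated samples to evaluate")
    hits = sum(
        p != NORMAL_CLASS and gene_of_class(t) == gene_of_class(p)
        for t, p in pairs
    )
    return hits / len(pairs)


# ---------------------------------------------------------------------------
# Experiment runner


MODEL_PIPELINES: dict[int, tuple[str, str]] = {
    1: ("zcurve", "mlp"),
    2: ("tetrahedron", "mlp"),
    3: ("zcurve", "rbf"),
    4: ("tetrahedron", "rbf"),
}


@dataclass
class ExperimentResults:
    """Fitted pipeline results: metrics, confusion matrix, trained network."""

    model: "ExperimentModel"
    network: RbfNetwork | MlpNetwork
    confusion: ConfusionMatrix
    accuracy: float
    mse: float
    macro_sensitivity: float
    macro_specificity: float
    per_class: dict
    gene_accuracy: float
    gene_recovery: float
    roc: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    split_sizes: tuple[int, int, int]
    seed: int

    def summary(self) -> str:
        m = self.model
        n_tr, n_val, n_te = self.split_sizes
        lines = [
            "Experiment results",
            "==================",
            f"transform:          {m.transform}",
            f"classifier:         {m.classifier}",
            f"evaluated on:       {m.eval_on} ({len(self.y_true)} samples)",
            f"split (tr/val/te):  {n_tr}/{n_val}/{n_te}",
            f"seed:               {self.seed}",
            "",
            f"accuracy:           {self.accuracy:.4f}",
            f"MSE:                {self.mse:.4f}",
            f"macro sensitivity:  {self.macro_sensitivity:.4f}",
            f"macro specificity:  {self.macro_specificity:.4f}",
            f"gene-level accuracy:{self.gene_accuracy:.4f}",
            f"mutated-gene recovery:{self.gene_recovery:.4f}",
        ]
        if isinstance(self.network, RbfNetwork):
            lines.append(f"RBF hidden neurons: {self.network.n_centers}")
        return "\n".join(lines)


@dataclass
class ExperimentModel:
    """A full classification pipeline bound to a labelled dataset.

    ``eval_on`` selects the scoring set: the held-out ``"test"`` split
    (default) or the ``"full"`` dataset (whose per-class totals match the
    class sizes, the convention behind published whole-corpus matrices).
    """

    dataset: LabeledDataset
    transform: str = "zcurve"
    classifier: str = "rbf"
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    hog: HogConfig = field(default_factory=HogConfig)
    rbf: RbfConfig = field(default_factory=RbfConfig)
    mlp: MlpConfig = field(default_factory=MlpConfig)
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    eval_on: str = "test"
    cumulative: bool = False

    def __post_init__(self) -> None:
        if self.transform not in ("zcurve", "tetrahedron"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.classifier not in ("rbf", "mlp"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.eval_on not in ("test", "full"):
            raise ValueError("eval_on must be 'test' or 'full'")

    @classmethod
    def from_model_id(cls, model_id: int, dataset: LabeledDataset,
                      **kwargs) -> "ExperimentModel":
        try:
            transform, classifier = MODEL_PIPELINES[model_id]
        except KeyError:
            raise ValueError(f"model_id must be 1..4, got {model_id}") from None
        return cls(dataset, transform=transform, classifier=classifier, **kwargs)

    def fit(self, seed: int = 0) -> ExperimentResults:
        ds = self.dataset
        names = ds.class_names
        try:
            x_all, labels_all = extract_features(
                ds, self.transform, self.imaging, self.hog, self.cumulative
            )
        except Exception as e:
            raise RuntimeError(f"feature-extraction stage failed: {e}") from e
        train, val, test = split_dataset(ds, self.fractions, seed=seed)
        idx_of = {id(s): i for i, s in enumerate(ds.samples)}
        tr = [idx_of[id(s)] for s in train.samples]
        va = [idx_of[id(s)] for s in val.samples]
        te = [idx_of[id(s)] for s in test.samples]

        y_all = one_hot(labels_all, names)
        try:
            if self.classifier == "rbf":
                net = train_rbf(
                    x_all[tr], y_all[tr], self.rbf, seed=seed,
                    class_names=names,
                    x_val=x_all[va] if va else None,
                    y_val=y_all[va] if va else None,
                )
                predict = rbf_predict
            else:
                net = train_mlp(
                    x_all[tr], y_all[tr], self.mlp, seed=seed,
                    class_names=names,
                    x_val=x_all[va] if va else None,
                    y_val=y_all[va] if va else None,
                )
                predict = mlp_predict
        except Exception as e:
            raise RuntimeError(f"classifier-training stage failed: {e}") from e

        ev = list(range(len(ds))) if self.eval_on == "full" else te
        scores, y_pred = predict(net, x_all[ev])
        y_true = labels_all[ev]
        cm = confusion_matrix(y_true, y_pred, names)
        sens, spec, per_class = macro_metrics(cm)
        return ExperimentResults(
            model=self,
            network=net,
            confusion=cm,
            accuracy=accuracy_from_cm(cm),
            mse=mse_score(one_hot(y_true, names), scores),
            macro_sensitivity=sens,
            macro_specificity=spec,
            per_class=per_class,
            gene_accuracy=gene_level_accuracy(y_true, y_pred),
            gene_recovery=mutant_gene_recovery(y_true, y_pred),
            roc=roc_curves(scores, y_true, names),
            y_true=y_true,
            y_pred=np.asarray(y_pred),
            scores=scores,
            split_sizes=(len(tr), len(va), len(te)),
            seed=seed,
        )

    def fit_seeds(self, seeds) -> tuple[list[ExperimentResults], dict]:
        """Fit once per seed; returns all results plus mean +- sd of the
        headline metrics across seeds."""
        results = [self.fit(seed=s) for s in seeds]
        agg = {}
        for attr in ("accuracy", "mse", "macro_sensitivity",
                     "macro_specificity", "gene_accuracy"):
            vals = np.array([getattr(r, attr) for r in results])
            agg[attr] = (float(vals.mean()),
                         float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return results, agg


def run_experiment(model_id: int, dataset: LabeledDataset, seed: int = 0,
                   **kwargs) -> ExperimentResults:
    """Fit one of the four canonical pipelines on the dataset."""
    return ExperimentModel.from_model_id(model_id, dataset, **kwargs).fit(seed=seed)
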