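"""Stroke-type classification from multiport S-matrices.

A reciprocal 10x10 S-matrix has 55 independent complex channels; stacking
real then imaginary parts gives a 110-dimensional feature vector.  The
pipeline mirrors a standard radar-feature classifier: per-feature
standardization, PCA to 20 components, then a Gaussian-kernel one-vs-one SVM
over the three classes {iStroke, hStroke, noStroke}, with the kernel scale
and box constraint chosen by seeded 5-fold cross-validated grid search.
Evaluation reports the confusion matrix, overall accuracy, per-class recall
and Cohen's kappa.

Standardization is on by default (``standardize=False`` gives centering-only
PCA): the differential signals span more than two orders of magnitude
between channels near and far from the lesion, and a single Gaussian kernel
bandwidth on unstandardized features is dominated by the few strongest
channels.

Model/results pattern: :class:`StrokeClassifier` holds the training data and
configuration; ``fit`` returns :class:`StrokeClassifierResults`, whose
``evaluate`` scores held-out data without ever touching the fitted state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .forward import SMatrix, pack_channels
from .scenario import CLASSES

N_FEATURES = 110
DEFAULT_COMPONENTS = 20


def extract_features(s: SMatrix, reciprocity_tol: float = 1e-8) -> np.ndarray:
    """110-feature vector: upper-triangle channels, real parts then imaginary.

    Raises if the matrix is not reciprocal within tolerance — a symptom of a
    channel-ordering mix-up upstream.
    """
    s.check_reciprocity(reciprocity_tol)
    v = pack_channels(s.entries)
    feats = np.concatenate([v.real, v.imag])
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite S-matrix entries")
    return feats


def features_from_dataset(
    ds: LabeledDataset, differential: bool = False, reference: SMatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, 110) and label array for a dataset.

    ``differential=True`` subtracts a reference (stroke-free) S-matrix before
    feature extraction — an ablation; the default uses raw S-matrices.
    """
    X = np.stack([extract_features(s.s_matrix) for s in ds.samples])
    if differential:
        if reference is None:
            raise ValueError("differential features need a reference S-matrix")
        X = X - extract_features(reference)
    return X, ds.labels


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` comes from the row/column marginals.  The degenerate case
    ``p_e = 1`` (all mass in one row-column cell) is defined as 0 with a
    warning.
    """
    C = np.asarray(confusion, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0) or C.sum() <= 0:
        raise ValueError("confusion matrix needs nonnegative counts, sum > 0")
    total = C.sum()
    p_o = np.trace(C) / total
    p_e = float((C.sum(axis=1) / total) @ (C.sum(axis=0) / total))
    if np.isclose(p_e, 1.0):
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix (rows = true, columns = predicted) and summary scores."""

    confusion: pd.DataFrame
    accuracy: float
    recall: dict
    kappa: float

    @property
    def n_samples(self) -> int:
        return int(self.confusion.values.sum())

    def to_dict(self) -> dict:
        return dict(
            classes=list(self.confusion.index),
            confusion=self.confusion.values.tolist(),
            accuracy=self.accuracy,
            recall=dict(self.recall),
            kappa=self.kappa,
        )

    def summary(self) -> str:
        lines = ["Stroke classification evaluation", ""]
        lines.append(self.confusion.to_string())
        lines.append("")
        lines.append(f"  overall accuracy : {100 * self.accuracy:.1f}%")
        for c, r in self.recall.items():
            lines.append(f"  recall {c:<9} : {100 * r:.1f}%")
        lines.append(f"  Cohen's kappa    : {self.kappa:.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Confusion-matrix heatmap; returns the axes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        C = self.confusion.values
        ax.imshow(C, cmap="Blues")
        classes = list(self.confusion.index)
        ax.set_xticks(range(len(classes)), classes)
        ax.set_yticks(range(len(classes)), classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(C.shape[0]):
            for j in range(C.shape[1]):
                ax.text(j, i, str(C[i, j]), ha="center", va="center",
                        color="white" if C[i, j] > C.max() / 2 else "black")
        ax.set_title(f"accuracy {100*self.accuracy:.1f}%, kappa {self.kappa:.2f}")
        return ax


def _fix_component_signs(pca: PCA) -> None:
    # deterministic orientation: largest-|loading| coordinate positive
    comp = pca.components_
    idx = np.argmax(np.abs(comp), axis=1)
    signs = np.sign(comp[np.arange(comp.shape[0]), idx])
    signs[signs == 0] = 1.0
    pca.components_ = comp * signs[:, None]


class StrokeClassifier:
    """PCA + Gaussian-SVM stroke-type classifier (model object).

    Parameters
    ----------
    features : (n, 110) array
    labels : (n,) array of {iStroke, hStroke, noStroke}
    n_components : int
        PCA dimensionality (default 20).
    standardize : bool
        Per-feature z-scoring before PCA (default True); False gives
        centering-only PCA.
    """

    def __init__(
        self,
        features,
        labels,
        n_components: int = DEFAULT_COMPONENTS,
        standardize: bool = True,
    ):
        X = np.asarray(features, float)
        y = np.asarray(labels)
        if X.ndim != 2:
            raise ValueError("features must be 2-D")
        counts = {c: int(np.sum(y == c)) for c in CLASSES}
        missing = [c for c, k in counts.items() if k == 0]
        if missing:
            raise ValueError(f"missing class(es) {missing}; class counts: {counts}")
        if X.shape[0] <= n_components:
            raise ValueError(
                f"need more than {n_components} training samples, got {X.shape[0]}"
            )
        self.X = X
        self.y = y
        self.n_components = n_components
        self.standardize = standardize

    @classmethod
    def from_dataset(cls, ds: LabeledDataset, n_components: int = DEFAULT_COMPONENTS,
                     standardize: bool = True, differential: bool = False, reference=None):
        X, y = features_from_dataset(ds, differential=differential, reference=reference)
        return cls(X, y, n_components=n_components, standardize=standardize)

    def fit(
        self,
        k: int = 5,
        seed: int = 0,
        c_grid=None,
        gamma_grid=None,
    ) -> "StrokeClassifierResults":
        """Fit the scaler and PCA, then grid-search the SVM with seeded k-fold CV.

        The search grid is log-spaced: box constraint C over 1e-1..1e5 and
        kernel width gamma over two decades around sklearn's 'scale'
        heuristic for the projected training data.
        """
        scaler = None
        X = self.X
        if self.standardize:
            scaler = StandardScaler().fit(X)
            X = scaler.transform(X)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        _fix_component_signs(pca)
        Z = (X - pca.mean_) @ pca.components_.T  # project with fixed signs

        var = Z.var()
        g0 = 1.0 / (Z.shape[1] * var) if var > 0 else 1.0
        if c_grid is None:
            c_grid = np.logspace(-1, 5, 13)
        if gamma_grid is None:
            gamma_grid = g0 * np.logspace(-2, 2, 13)

        n_min = min(np.bincount(pd.factorize(self.y)[0]))
        if n_min < 2:
            # too few replicates for CV: fit directly at the grid center
            svm = SVC(kernel="rbf", C=1.0, gamma=g0, decision_function_shape="ovo")
            svm.fit(Z, self.y)
            best = {"C": 1.0, "gamma": g0}
            cv_acc = float(np.mean(svm.predict(Z) == self.y))
            return StrokeClassifierResults(self, scaler, pca, svm, best, cv_acc, 1, seed)

        k_eff = min(k, n_min)
        cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        search = GridSearchCV(
            SVC(kernel="rbf", decision_function_shape="ovo"),
            param_grid={"C": list(c_grid), "gamma": list(gamma_grid)},
            cv=cv,
            scoring="accuracy",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(Z, self.y)
        svm = search.best_estimator_
        return StrokeClassifierResults(
            model=self,
            scaler=scaler,
            pca=pca,
            svm=svm,
            best_params=dict(search.best_params_),
            cv_accuracy=float(search.best_score_),
            k=k_eff,
            seed=seed,
        )


class StrokeClassifierResults:
    """Fitted classifier: scaler + PCA basis + SVM, hyperparameters, CV score.

    ``evaluate`` applies the training scaler/mean/loadings to the test
    features and never modifies the fitted state (train/test separation by
    construction).
    """

    def __init__(self, model, scaler, pca, svm, best_params, cv_accuracy, k, seed):
        self.model = model
        self.scaler = scaler
        self.pca = pca
        self.svm = svm
        self.best_params = best_params
        self.cv_accuracy = cv_accuracy
        self.k = k
        self.seed = seed

    @property
    def kernel_scale(self) -> float:
        """Gaussian kernel scale s with K = exp(-||x-y||^2 / s^2) = 1/sqrt(gamma)."""
        return float(1.0 / np.sqrt(self.best_params["gamma"]))

    @property
    def box_constraint(self) -> float:
        return float(self.best_params["C"])

    def transform(self, features) -> np.ndarray:
        X = np.asarray(features, float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return (X - self.pca.mean_) @ self.pca.components_.T

    def predict(self, features) -> np.ndarray:
        return self.svm.predict(self.transform(features))

    def evaluate(self, features, labels) -> EvaluationReport:
        """Score held-out data: confusion matrix, accuracy, recalls, kappa."""
        y = np.asarray(labels)
        unseen = set(np.unique(y)) - set(CLASSES)
        if unseen:
            raise ValueError(f"unseen label(s) in test data: {sorted(unseen)}")
        pred = self.predict(features)
        classes = list(CLASSES)
        C = np.zeros((3, 3), dtype=int)
        for t, p in zip(y, pred):
            C[classes.index(t), classes.index(p)] += 1
        conf = pd.DataFrame(C, index=classes, columns=classes)
        acc = float(np.trace(C) / C.sum())
        recall = {
            c: float(C[i, i] / C[i].sum()) if C[i].sum() else float("nan")
            for i, c in enumerate(classes)
        }
        return EvaluationReport(conf, acc, recall, cohens_kappa(C))

    def evaluate_dataset(self, ds: LabeledDataset, differential=False, reference=None):
        X, y = features_from_dataset(ds, differential=differential, reference=reference)
        return self.evaluate(X, y)

    def summary(self) -> str:
        n_train = self.model.X.shape[0] if self.model is not None else "?"
        return "\n".join(
            [
                "PCA + Gaussian-SVM stroke classifier",
                f"  training samples   : {n_train}",
                f"  PCA components     : {self.pca.n_components_} "
                f"(explained variance {100 * self.pca.explained_variance_ratio_.sum():.1f}%)",
                f"  kernel scale       : {self.kernel_scale:.4g}",
                f"  box constraint C   : {self.box_constraint:.4g}",
                f"  {self.k}-fold CV accuracy : {100 * self.cv_accuracy:.1f}%",
            ]
        )

    def save(self, path) -> None:
        """Persist as a joblib bundle + JSON metadata sidecar."""
        from pathlib import Path

        path = Path(path)
        joblib.dump({"scaler": self.scaler, "pca": self.pca, "svm": self.svm}, path)
        meta = dict(
            best_params={k: float(v) for k, v in self.best_params.items()},
            cv_accuracy=self.cv_accuracy,
            k=self.k,
            seed=self.seed,
            classes=list(CLASSES),
        )
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "StrokeClassifierResults":
        from pathlib import Path

        path = Path(path)
        bundle = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            model=None,
            scaler=bundle.get("scaler"),
            pca=bundle["pca"],
            svm=bundle["svm"],
            best_params=meta["best_params"],
            cv_accuracy=meta["cv_accuracy"],
            k=meta["k"],
            seed=meta["seed"],
        )
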