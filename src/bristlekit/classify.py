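"""SVM-defined wild-type patterning region and per-mutant penetrance.

Features are first z-scaled against a designated reference (control)
group — each axis becomes "standard deviations away from control" — so
the decision boundary lives in a biologically interpretable space. A
soft-margin SVM separates control patterns (class 0) from perturbed
ones (class 1): the predicted-class-0 set is the wild-type patterning
region, and a mutant group's *penetrance* is the fraction of its
patterns falling outside that region.

Hyperparameters are chosen by an owned grid search — kernels linear,
polynomial and RBF, C ∈ {0.1, 1, 10, 100, 1000}, γ ∈ {0.001, 0.01,
0.1, 1, 10}, degree ∈ {2, 3, 4} — scored by stratified k-fold accuracy
on a 60% training split; the winner is refitted on the whole training
portion and reported against the 40% held-out split. Ties prefer the
simpler kernel (linear, then polynomial, then RBF), then smaller C, γ
and degree, so a rerun with the same split seed reproduces the model
exactly. The quadratic-programming core is delegated to a standard SVC
solver; splitting, cross-validation, the grid loop and all reporting
live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .stats import Cohort

__all__ = [
    "DEFAULT_FEATURE_PAIR",
    "ScalerStats",
    "SVMGridSpec",
    "BoundaryModel",
    "ControlScaler",
    "WildTypeBoundary",
    "fit_scaler",
    "train_boundary",
    "penetrance",
    "boundary_grid",
]

#: Feature pair defining the default wild-type region axes.
DEFAULT_FEATURE_PAIR = ("RSA", "CSV")

_KERNEL_ORDER = {"linear": 0, "poly": 1, "rbf": 2}

# Iteration cap for the SVC solver: ill-conditioned corners of the grid
# (large C with large gamma) can otherwise cycle near-indefinitely; at
# cohort sizes (10^2 patterns) any useful fit converges far below this.
_SVC_MAX_ITER = 200_000


def _make_svc(cand: dict) -> SVC:
    return SVC(max_iter=_SVC_MAX_ITER, **cand)


@dataclass
class ScalerStats:
    """Reference-group feature means and standard deviations."""

    feature_names: list[str]
    means: np.ndarray
    stds: np.ndarray
    reference_group: str

    def transform(self, values: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(values, pd.DataFrame):
            values = values[self.feature_names].to_numpy(dtype=float)
        return (np.asarray(values, dtype=float) - self.means) / self.stds


@dataclass
class SVMGridSpec:
    """Search space and evaluation protocol for the decision boundary."""

    kernels: tuple[str, ...] = ("linear", "poly", "rbf")
    C_values: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    gamma_values: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)
    degrees: tuple[int, ...] = (2, 3, 4)
    cv_folds: int = 5
    train_fraction: float = 0.6
    split_seed: int = 0

    def __post_init__(self) -> None:
        bad = [k for k in self.kernels if k not in _KERNEL_ORDER]
        if bad:
            raise ValueError(f"unknown kernel(s) {bad}")
        if not self.kernels or not self.C_values:
            raise ValueError("kernel and C grids must be non-empty")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be ≥ 2")

    def candidates(self) -> list[dict]:
        """Expanded hyperparameter grid, in deterministic tie-break order."""
        out = []
        for kernel in sorted(self.kernels, key=_KERNEL_ORDER.__getitem__):
            if kernel == "linear":
                for C in sorted(self.C_values):
                    out.append({"kernel": "linear", "C": C})
            elif kernel == "rbf":
                for C, gamma in product(
                    sorted(self.C_values), sorted(self.gamma_values)
                ):
                    out.append({"kernel": "rbf", "C": C, "gamma": gamma})
            else:  # poly
                for C, gamma, degree in product(
                    sorted(self.C_values),
                    sorted(self.gamma_values),
                    sorted(self.degrees),
                ):
                    out.append(
                        {"kernel": "poly", "C": C, "gamma": gamma, "degree": degree}
                    )
        return out


class ControlScaler:
    """Z-scaler whose statistics come from one reference group only.

    ``fit`` takes the cohort feature table; means and standard
    deviations (ddof = 1) are computed on the reference group's rows and
    then applied to every group, so all patterns are expressed in
    control standard deviations.
    """

    def __init__(
        self,
        reference_group: str = "control-White",
        feature_names: Sequence[str] = DEFAULT_FEATURE_PAIR,
    ):
        self.reference_group = reference_group
        self.feature_names = list(feature_names)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "reference_group": self.reference_group,
            "feature_names": self.feature_names,
        }

    def set_params(self, **params) -> "ControlScaler":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, features: pd.DataFrame, y=None) -> "ControlScaler":
        ref = features[features["group"] == self.reference_group]
        if len(ref) < 2:
            raise ValueError(
                f"reference group {self.reference_group!r} needs ≥ 2 patterns"
            )
        vals = ref[self.feature_names].to_numpy(dtype=float)
        means = vals.mean(axis=0)
        stds = vals.std(axis=0, ddof=1)
        for name, s in zip(self.feature_names, stds):
            if not (s > 0):
                raise ValueError(
                    f"feature {name!r} is constant in the reference group"
                )
        self.stats_ = ScalerStats(
            feature_names=list(self.feature_names),
            means=means,
            stds=stds,
            reference_group=self.reference_group,
        )
        return self

    def transform(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.stats_.transform(features)

    def fit_transform(self, features: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(features).transform(features)


def fit_scaler(
    cohort: Cohort,
    reference_group: str,
    feature_names: Sequence[str] = DEFAULT_FEATURE_PAIR,
) -> ScalerStats:
    """Reference-group scaling statistics for the cohort."""
    return ControlScaler(reference_group, feature_names).fit(cohort.features).stats_


class WildTypeBoundary:
    """Grid-searched soft-margin SVM classifier (sklearn estimator shape).

    ``fit(X, y)`` performs the stratified train/test split internally
    (the held-out accuracy is part of the model report), searches the
    grid by stratified k-fold CV accuracy on the training portion with
    the documented tie-breaking, and refits the winner on the full
    training portion.

    Fitted attributes: ``kernel_``, ``C_``, ``gamma_``, ``degree_``,
    ``cv_accuracy_``, ``train_accuracy_``, ``test_accuracy_``,
    ``estimator_`` (the refitted SVC).
    """

    def __init__(self, spec: SVMGridSpec | None = None):
        self.spec = spec

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "WildTypeBoundary":
        if set(params) - {"spec"}:
            raise ValueError("only 'spec' is a parameter")
        self.spec = params.get("spec", self.spec)
        return self

    def fit(self, X: np.ndarray, y: Sequence[int]):
        spec = self.spec if self.spec is not None else SVMGridSpec()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("both classes must be present")
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=spec.train_fraction,
            random_state=spec.split_seed,
            stratify=y,
        )
        if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
            raise ValueError("a class is absent from the stratified split")

        folds = min(spec.cv_folds, int(np.bincount(y_tr).min()))
        if folds < 2:
            raise ValueError("too few training samples per class for CV")
        skf = StratifiedKFold(n_splits=folds, shuffle=False)
        splits = list(skf.split(X_tr, y_tr))

        best_acc = -1.0
        best_cand: dict | None = None
        warnings.filterwarnings(
            "ignore", message=".*max_iter.*", category=UserWarning
        )
        for cand in spec.candidates():  # candidate order encodes tie-breaks
            correct = 0
            total = 0
            for tr_idx, va_idx in splits:
                clf = _make_svc(cand)
                clf.fit(X_tr[tr_idx], y_tr[tr_idx])
                pred = clf.predict(X_tr[va_idx])
                correct += int((pred == y_tr[va_idx]).sum())
                total += va_idx.size
            acc = correct / total
            if acc > best_acc:
                best_acc = acc
                best_cand = cand
        assert best_cand is not None

        final = _make_svc(best_cand).fit(X_tr, y_tr)
        self.estimator_ = final
        self.kernel_ = best_cand["kernel"]
        self.C_ = best_cand["C"]
        self.gamma_ = best_cand.get("gamma")
        self.degree_ = best_cand.get("degree")
        self.cv_accuracy_ = float(best_acc)
        self.train_accuracy_ = float((final.predict(X_tr) == y_tr).mean())
        self.test_accuracy_ = float((final.predict(X_te) == y_te).mean())
        self.n_train_ = int(y_tr.size)
        self.n_test_ = int(y_te.size)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator_.predict(np.asarray(X, dtype=float))


@dataclass
class BoundaryModel:
    """A trained wild-type region: scaler, classifier, and its report."""

    scaler: ScalerStats
    feature_names: list[str]
    classifier: WildTypeBoundary
    class_map: dict[str, int]
    train_accuracy: float
    test_accuracy: float
    cv_accuracy: float
    outside_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def kernel(self) -> str:
        return self.classifier.kernel_

    def predict_pattern(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Class per row: 0 = inside the wild-type region, 1 = outside."""
        return self.classifier.predict(self.scaler.transform(features))

    def summary(self) -> dict:
        return {
            "reference_group": self.scaler.reference_group,
            "feature_names": self.feature_names,
            "scaler_means": self.scaler.means.tolist(),
            "scaler_stds": self.scaler.stds.tolist(),
            "kernel": self.classifier.kernel_,
            "C": self.classifier.C_,
            "gamma": self.classifier.gamma_,
            "degree": self.classifier.degree_,
            "cv_accuracy": self.cv_accuracy,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "class_map": self.class_map,
            "outside_fraction": self.outside_fraction,
        }


def train_boundary(
    cohort: Cohort,
    class_map: Mapping[str, int],
    spec: SVMGridSpec | None = None,
    feature_names: Sequence[str] = DEFAULT_FEATURE_PAIR,
    *,
    reference_group: str | None = None,
) -> BoundaryModel:
    """Train the wild-type/perturbed decision boundary on a cohort.

    *class_map* sends each participating group label to 0 (wild type)
    or 1 (perturbed); groups not in the map are excluded from training
    but still receive an outside-region fraction in the report. The
    scaler reference defaults to the first class-0 group.
    """
    spec = spec if spec is not None else SVMGridSpec()
    classes = set(class_map.values())
    if classes != {0, 1}:
        raise ValueError("class_map must use both classes 0 and 1")
    if reference_group is None:
        reference_group = next(
            g for g in cohort.groups if class_map.get(g) == 0
        )
    feature_names = list(feature_names)
    df = cohort.features.dropna(subset=feature_names)
    scaler = ControlScaler(reference_group, feature_names).fit(df).stats_

    train_df = df[df["group"].isin(class_map)]
    X = scaler.transform(train_df)
    y = train_df["group"].map(class_map).to_numpy(dtype=int)
    clf = WildTypeBoundary(spec).fit(X, y)

    outside = {}
    for g in dict.fromkeys(df["group"]):
        sub = df[df["group"] == g]
        pred = clf.predict(scaler.transform(sub))
        outside[g] = float(pred.mean())

    return BoundaryModel(
        scaler=scaler,
        feature_names=feature_names,
        classifier=clf,
        class_map=dict(class_map),
        train_accuracy=clf.train_accuracy_,
        test_accuracy=clf.test_accuracy_,
        cv_accuracy=clf.cv_accuracy_,
        outside_fraction=outside,
    )


def penetrance(model: BoundaryModel, cohort: Cohort, mutant_group: str) -> float:
    """Fraction of a group's patterns classified outside the wild-type region."""
    sub = cohort.features[cohort.features["group"] == mutant_group]
    sub = sub.dropna(subset=model.feature_names)
    if len(sub) == 0:
        raise ValueError(f"group {mutant_group!r} has no usable patterns")
    return float(model.predict_pattern(sub).mean())


def boundary_grid(
    model: BoundaryModel,
    limits: tuple[float, float, float, float] = (-4.0, 4.0, -4.0, 4.0),
    resolution: int = 101,
) -> pd.DataFrame:
    """Dense lattice evaluation of the boundary in scaled feature space.

    Returns a DataFrame of (scaled feature 1, scaled feature 2,
    predicted class) suitable for plotting the wild-type region.
    """
    if len(model.feature_names) != 2:
        raise ValueError("boundary grid export requires exactly 2 features")
    x0, x1, y0, y1 = limits
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pred = model.classifier.predict(pts)
    f1, f2 = model.feature_names
    return pd.DataFrame(
        {f"scaled_{f1}": pts[:, 0], f"scaled_{f2}": pts[:, 1], "predicted_class": pred}
    )
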