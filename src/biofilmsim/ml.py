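"""Random-forest morphology classification and parameter-importance regression.

Feature extraction turns a coverage-vs-depth curve into a fixed-length
vector: coverage sampled every 1 um and normalised to sum to 1 (so curves of
different total biomass are comparable), prefixed by one scalar feature.
Two variants are supported:

* ``"age"`` — sample age plus 21 coverage samples from 0 to 20 um, for
  experimental-style slices where acquisition time is known;
* ``"biomass"`` — total biomass plus coverage from 2 to 20 um (the first
  2 um are dropped because coverslip-adjacent structure is the least
  comparable between model and image data), for simulator output.

Classification distinguishes heterotrophic-like from photoheterotrophic-like
morphologies; performance is measured by the out-of-bag (OOB) error of the
forest and compared against a naive prior-frequency baseline.  A random
forest regression of classification probability on the sweep parameters
ranks which parameters shape the morphology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .metrics import CoverageProfile

__all__ = [
    "ForestSpec",
    "slice_features",
    "build_feature_table",
    "train_forest",
    "naive_baseline",
    "classify_model_output",
    "importance_regression",
    "SWEEP_PARAM_FEATURES",
]

#: sweep columns used as regression features, including the derived scarcity
SWEEP_PARAM_FEATURES = ("s", "b", "r", "p", "i_half", "n_half", "alpha", "beta", "inv_ns")


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest configuration.

    Defaults: classification uses 1000 trees, Gini impurity, at most 5
    features per split; regression uses 500 trees with a squared-error
    criterion.  Both report out-of-bag estimates.
    """

    task: str = "classify"
    n_estimators: int | None = None
    criterion: str | None = None
    max_features: int | None = None
    oob: bool = True

    def build(self, seed: int):
        if self.task == "classify":
            return RandomForestClassifier(
                n_estimators=self.n_estimators or 1000,
                criterion=self.criterion or "gini",
                max_features=self.max_features or 5,
                oob_score=self.oob,
                random_state=seed,
                n_jobs=1,
            )
        if self.task == "regress":
            return RandomForestRegressor(
                n_estimators=self.n_estimators or 500,
                criterion=self.criterion or "squared_error",
                max_features=self.max_features or 1.0,
                oob_score=self.oob,
                random_state=seed,
                n_jobs=1,
            )
        raise ValueError(f"unknown task {self.task!r}")


def _coverage_depths(variant: str, include_20um: bool = True) -> np.ndarray:
    if variant == "age":
        return np.arange(0, 21, dtype=float)
    if variant == "biomass":
        hi = 21 if include_20um else 20
        return np.arange(2, hi, dtype=float)
    raise ValueError(f"unknown feature variant {variant!r}")


def slice_features(
    coverage: CoverageProfile,
    scalar: float,
    variant: str = "age",
    include_20um: bool = True,
) -> np.ndarray:
    """Feature vector: scalar (age or biomass) + normalised coverage samples.

    Raises ``ValueError`` on an all-zero coverage block (normalisation is
    undefined); callers exclude such slices from datasets.
    """
    depths = _coverage_depths(variant, include_20um)
    block = coverage.sample(depths)
    total = block.sum()
    if total <= 0:
        raise ValueError("all-zero coverage curve: slice excluded")
    return np.concatenate([[scalar], block / total])


def feature_names(variant: str = "age", include_20um: bool = True) -> list[str]:
    scalar = "age" if variant == "age" else "biomass"
    return [scalar] + [f"cov_{int(d)}" for d in _coverage_depths(variant, include_20um)]


def build_feature_table(
    curves: list[CoverageProfile],
    scalars,
    labels=None,
    variant: str = "age",
    include_20um: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Assemble a feature table, excluding zero-coverage slices.

    Returns the table (with a ``label`` column when labels are given) and the
    number of excluded slices.
    """
    rows, kept_labels = [], []
    excluded = 0
    for i, (curve, scalar) in enumerate(zip(curves, scalars)):
        try:
            rows.append(slice_features(curve, scalar, variant, include_20um))
        except ValueError:
            excluded += 1
            continue
        if labels is not None:
            kept_labels.append(labels[i])
    table = pd.DataFrame(rows, columns=feature_names(variant, include_20um))
    if labels is not None:
        table["label"] = kept_labels
    return table, excluded


def train_forest(features, target, spec: ForestSpec, seed: int = 0):
    """Fit a random forest; returns (model, OOB error or OOB R^2).

    For classification the OOB estimate is the misclassification rate; for
    regression it is the out-of-bag R^2.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target)
    if spec.task == "classify" and len(np.unique(y)) < 2:
        raise ValueError("classification requires at least two classes")
    model = spec.build(seed)
    model.fit(X, y)
    if spec.task == "classify":
        return model, 1.0 - float(model.oob_score_)
    # OOB R^2 = 1 - MSE_oob / Var(y); a zero-variance target has no
    # explainable variance, so its score is 0
    var = float(np.var(y.astype(float)))
    if var == 0.0:
        return model, 0.0
    mse = float(np.mean((y.astype(float) - model.oob_prediction_) ** 2))
    return model, 1.0 - mse / var


def naive_baseline(labels) -> float:
    """Accuracy of always guessing the most frequent class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / counts.sum())


def classify_model_output(
    model, features, positive_label="heterotrophic"
) -> np.ndarray:
    """Per-sample probability of the heterotrophic-like morphology class."""
    X = np.asarray(features, dtype=float)
    col = list(model.classes_).index(positive_label)
    return model.predict_proba(X)[:, col]


def importance_regression(
    sweep_table: pd.DataFrame,
    probabilities,
    spec: ForestSpec | None = None,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """Regress classification probability on the sweep parameters.

    Returns relative feature importances (summing to 1, indexed by parameter
    name, sorted descending) and the forest's out-of-bag R^2.
    """
    spec = spec or ForestSpec(task="regress")
    if spec.task != "regress":
        raise ValueError("importance regression requires a regression spec")
    cols = [c for c in SWEEP_PARAM_FEATURES if c in sweep_table.columns]
    model, r2 = train_forest(sweep_table[cols], probabilities, spec, seed)
    imp = pd.Series(model.feature_importances_, index=cols).sort_values(ascending=False)
    return imp, r2
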