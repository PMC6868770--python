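"""Survival-time regression and cross-validated evaluation.

Four model families predict survival months from the enriched feature
matrix: support vector regression with RBF, linear and polynomial kernels,
and decision-tree regression.  Evaluation is seeded k-fold
cross-validation reporting mean and SD over folds of four metrics — R²,
explained variance, negative mean absolute error and negative median
absolute error — on the held-out folds and, separately labelled, on the
training folds.  The ablation grid crosses the composite clinical feature
against its separate components and the relation network against
clinical-only features.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    explained_variance_score,
    mean_absolute_error,
    median_absolute_error,
    r2_score,
)
from sklearn.compose import TransformedTargetRegressor
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .enrichment import extract_survival_months, _zscore_columns
from .network import IntegratedNetwork, patients_by_protein
from .ticf import TICFTable, stratify

logger = logging.getLogger(__name__)

FAMILIES = ("svr_rbf", "svr_linear", "svr_poly", "dtr")

METRICS = (
    "r2",
    "explained_variance",
    "negative_mean_absolute_error",
    "negative_median_absolute_error",
)

#: Hyperparameter defaults; surfaced through ModelSpec.hyperparameters.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "svr_rbf": {"C": 1.0, "epsilon": 0.1, "gamma": "scale"},
    "svr_linear": {"C": 1.0, "epsilon": 0.1},
    # coef0=1 gives the standard inhomogeneous polynomial kernel, which
    # spans all degrees up to `degree` rather than the cubic terms alone.
    "svr_poly": {"C": 1.0, "epsilon": 0.1, "degree": 3, "gamma": "scale", "coef0": 1.0},
    "dtr": {"max_depth": None},
}


@dataclass(frozen=True)
class ModelSpec:
    """One model family with its hyperparameters and seed."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")
        allowed = set(DEFAULT_HYPERPARAMETERS[self.family])
        extra = set(self.hyperparameters) - allowed
        if extra:
            raise ValueError(
                f"hyperparameters {sorted(extra)} not applicable to {self.family}"
            )

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


def default_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family=f, seed=seed) for f in FAMILIES]


def make_estimator(spec: ModelSpec):
    """Estimator for one spec.

    Support-vector regression is scale-sensitive in the target as well as
    the features (epsilon and C are expressed in target units), so the SVR
    families fit on a standardized target and predictions are transformed
    back to months.  Trees are scale-equivariant and fit months directly.
    """
    params = spec.resolved()
    kernels = {"svr_rbf": "rbf", "svr_linear": "linear", "svr_poly": "poly"}
    if spec.family in kernels:
        return TransformedTargetRegressor(
            regressor=SVR(kernel=kernels[spec.family], **params),
            transformer=StandardScaler(),
        )
    return DecisionTreeRegressor(random_state=spec.seed, **params)


def fit(spec: ModelSpec, feature_matrix, targets):
    """Fit one model; deterministic given the spec's seed."""
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows with targets to fit")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("feature matrix and targets must not contain missing values")
    if np.ptp(y) == 0:
        logger.warning("degenerate all-equal targets; model will predict a constant")
    model = make_estimator(spec)
    model.fit(X, y)
    return model


def predict(model, feature_matrix) -> np.ndarray:
    """Predict survival months row-wise; empty input yields empty output."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2:
        X = np.atleast_2d(X)
    if X.shape[0] == 0:
        return np.empty(0)
    expected = getattr(model, "n_features_in_", None)
    if expected is not None and X.shape[1] != expected:
        raise ValueError(
            f"feature dimension mismatch: model expects {expected}, got {X.shape[1]}"
        )
    return np.asarray(model.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _score(y_true, y_pred) -> dict[str, float]:
    return {
        "r2": float(r2_score(y_true, y_pred)),
        "explained_variance": float(explained_variance_score(y_true, y_pred)),
        "negative_mean_absolute_error": -float(mean_absolute_error(y_true, y_pred)),
        "negative_median_absolute_error": -float(median_absolute_error(y_true, y_pred)),
    }


@dataclass
class CVReport:
    """Mean±SD of the four metrics per model, held-out and training folds."""

    k: int
    n: int
    seed: int
    models: dict[str, dict] = field(default_factory=dict)
    fold_test_indices: list[list[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "seed": self.seed,
            "models": self.models,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def mean_test_r2(self, family: str) -> float:
        return self.models[family]["test"]["r2"]["mean"]


def fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """The seeded shuffled-once k-fold partition used everywhere."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


def cross_validate(
    feature_matrix,
    targets,
    specs: Optional[Sequence[ModelSpec]] = None,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Seeded k-fold cross-validation of every model spec.

    The sample is shuffled once and partitioned into k near-equal folds;
    each fold serves as the validation set exactly once.  Fold means and
    population SDs are reported per metric, separately for held-out and
    training folds.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    if specs is None:
        specs = default_specs(seed)
    folds = fold_indices(n, k, seed)
    all_idx = np.arange(n)

    report = CVReport(k=k, n=n, seed=seed, fold_test_indices=[f.tolist() for f in folds])
    for spec in specs:
        per_fold = {"test": {m: [] for m in METRICS}, "train": {m: [] for m in METRICS}}
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = fit(spec, X[train_idx], y[train_idx])
            for split, idx in (("train", train_idx), ("test", test_idx)):
                scores = _score(y[idx], predict(model, X[idx]))
                for m in METRICS:
                    per_fold[split][m].append(scores[m])
        summary: dict[str, dict] = {"per_fold": {}, "test": {}, "train": {}}
        for split in ("test", "train"):
            summary["per_fold"][split] = {m: list(per_fold[split][m]) for m in METRICS}
            for m in METRICS:
                xs = np.asarray(per_fold[split][m])
                summary[split][m] = {
                    "mean": float(xs.mean()),
                    "sd": float(xs.std(ddof=0)),
                }
        report.models[spec.family] = summary
    return report


# ---------------------------------------------------------------------------
# ablation grid
# ---------------------------------------------------------------------------

ABLATION_CONFIGS = (
    "ticf_network",      # composite TICF + relation-network indicators (main)
    "separate_network",  # stage/size/age as separate columns + network
    "ticf_only",         # composite TICF, no network enrichment
    "separate_only",     # separate clinical columns, no network
)


def _indicator_proteins(network: IntegratedNetwork) -> list[str]:
    """Proteins exposed as feature columns: trusted internally, or an
    endpoint of a trusted linked relation."""
    from .enrichment import trusted_linked_partners

    trusted = network.trusted_proteins()
    linked = trusted_linked_partners(trusted, network)
    return sorted(trusted | linked)


def build_design_matrix(
    documents: Sequence[Mapping],
    network: IntegratedNetwork,
    ticf_table: TICFTable,
    use_composite: bool = True,
    use_network: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort-level design matrix over all TICF-defined patients.

    Rows are identical across the four ablation configurations so fold
    partitions can be shared; only the columns change.  Without the
    network the rows carry clinical features only — exactly the ring0
    population with no enrichment.
    """
    rows = sorted(ticf_table.values)
    data: dict[str, list[float]] = {}
    if use_composite:
        data["ticf"] = [ticf_table.values[sid].normalized for sid in rows]
    else:
        data["stage"] = [float(ticf_table.values[sid].stage) for sid in rows]
        data["size"] = [float(ticf_table.values[sid].size) for sid in rows]
        data["age"] = [float(ticf_table.values[sid].age) for sid in rows]
    if use_network:
        for protein in _indicator_proteins(network):
            carriers = patients_by_protein(network, protein)
            data[f"protein:{protein}"] = [1.0 if sid in carriers else 0.0 for sid in rows]

    survival: dict[str, float] = {}
    for doc in sorted(
        (d for d in documents if d.get("data_type") == "clinical"),
        key=lambda d: str(d.get("record_id")),
    ):
        sid = doc["sample_id"]
        if sid not in survival:
            months = extract_survival_months(doc)
            if months is not None:
                survival[sid] = months

    matrix = _zscore_columns(pd.DataFrame(data, index=rows))
    targets = pd.Series([survival.get(sid, np.nan) for sid in rows], index=rows,
                        name="survival_months")
    keep = targets.notna()
    return matrix.loc[keep], targets.loc[keep]


def run_ablation(
    documents: Sequence[Mapping],
    network: IntegratedNetwork,
    ticf_table: TICFTable,
    specs: Optional[Sequence[ModelSpec]] = None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, CVReport]:
    """The 2x2 grid: ±composite TICF × ±relation network.

    All four reports share the row set and the seeded fold partition, so
    the comparison is paired.
    """
    grid = {
        "ticf_network": (True, True),
        "separate_network": (False, True),
        "ticf_only": (True, False),
        "separate_only": (False, False),
    }
    reports: dict[str, CVReport] = {}
    for name in ABLATION_CONFIGS:
        use_composite, use_network = grid[name]
        X, y = build_design_matrix(
            documents, network, ticf_table,
            use_composite=use_composite, use_network=use_network,
        )
        reports[name] = cross_validate(X, y, specs=specs, k=k, seed=seed)
    return reports


def mean_r2_over_models(report: CVReport) -> float:
    """Mean held-out R² across model families — the ablation comparison scalar."""
    return float(np.mean([report.mean_test_r2(f) for f in sorted(report.models)]))


def sample_validation_subset(
    ticf_table: TICFTable,
    fraction: float = 0.25,
    seed: int = 0,
    n_subgroups: int = 5,
) -> tuple[list[str], dict[str, int]]:
    """A seeded ~25% validation subset, stratified into 5 subgroups.

    Uniform sample without replacement of ceil(fraction*n) TICF-defined
    patients, then contiguous TICF stratification of the subset.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    sids = sorted(ticf_table.values)
    size = math.ceil(fraction * len(sids))
    rng = np.random.default_rng(seed)
    subset = sorted(rng.choice(sids, size=size, replace=False).tolist())
    groups = stratify({sid: ticf_table.values[sid].normalized for sid in subset},
                      k=n_subgroups)
    return subset, groups
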