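"""Repeated-split benchmark of four classifiers on the feature table.

Protocol: the labelled feature table is split at random into training and
evaluation sets (70/30 by default); within each of the n_repeats runs all
four models receive the *identical* partition; features are min-max scaled
to [0, 1] with parameters fitted on the training set only (no clipping of
out-of-range evaluation values); accuracy is plain percent-correct on the
evaluation set, summarised per model as mean ± SD over runs.

Model defaults follow the common R implementations of each family: an RBF
support-vector machine with C = 1, a CART decision tree, a 500-tree random
forest with sqrt(p) features per split, and a single-hidden-layer neural
network (3 units, logistic activation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import PipelineConfig

MODEL_KINDS = ("svm", "tree", "random_forest", "nn")


def normalize_features(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Min-max scale both tables using the training columns' ranges.

    Constant training columns map to 0 (with a warning); evaluation values
    outside the training range scale to values outside [0, 1] and are left
    unclipped.
    """
    mins = train.min(axis=0)
    maxs = train.max(axis=0)
    span = maxs - mins
    const = span == 0
    if const.any():
        warnings.warn(
            f"constant feature columns mapped to 0: {list(train.columns[const])}",
            stacklevel=2,
        )
    safe_span = span.where(~const, 1.0)
    train_n = (train - mins) / safe_span
    test_n = (test - mins) / safe_span
    train_n.loc[:, const] = 0.0
    test_n.loc[:, const] = 0.0
    params = {"min": mins.to_dict(), "max": maxs.to_dict()}
    return train_n, test_n, params


def train_model(
    kind: str,
    train_x: np.ndarray,
    train_y: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
):
    """Fit one classifier of the requested family; returns the fitted model."""
    if config is None:
        config = PipelineConfig()
    if kind == "svm":
        model = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    elif kind == "tree":
        model = DecisionTreeClassifier(random_state=seed)
    elif kind == "random_forest":
        model = RandomForestClassifier(
            n_estimators=config.rf_n_trees, max_features="sqrt", random_state=seed
        )
    elif kind == "nn":
        model = MLPClassifier(
            hidden_layer_sizes=(config.nn_hidden,),
            activation="logistic",
            solver="lbfgs",
            max_iter=2000,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train_x, train_y)
    return model


@dataclass
class BenchmarkReport:
    per_model: dict[str, dict] = field(default_factory=dict)
    n_repeats: int = 0
    split_fraction: float = 0.7
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "per_model": self.per_model,
            "n_repeats": self.n_repeats,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Type": kind,
                "Result [%]": d["mean_accuracy_pct"],
                "Standard Deviation": d["sd_pct"],
            }
            for kind, d in self.per_model.items()
        ]
        return pd.DataFrame(rows)


def _split_indices(
    labels: np.ndarray,
    frac: float,
    stratified: bool,
    rng: np.random.Generator,
    max_retry: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    n = labels.size
    n_train = int(round(frac * n))
    classes = np.unique(labels)
    if stratified:
        train_parts = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            k = int(round(frac * idx.size))
            train_parts.append(idx[:k])
        train = np.sort(np.concatenate(train_parts))
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        for _ in range(max_retry):
            test = np.setdiff1d(np.arange(n), train)
            if (
                np.isin(classes, labels[train]).all()
                and np.isin(classes, labels[test]).all()
            ):
                break
            warnings.warn("a class was absent from one side of the split; resampling", stacklevel=3)
            perm = rng.permutation(n)
            train = np.sort(perm[:n_train])
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def run_benchmark(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    model_kinds: Sequence[str] = MODEL_KINDS,
) -> BenchmarkReport:
    """Repeated shared-split benchmark over the four model families.

    ``features`` holds only numeric feature columns (one row per subject);
    ``labels`` the binary class labels.  Deterministic in ``seed``.
    """
    if config is None:
        config = PipelineConfig()
    if seed is None:
        seed = config.rng_seed
    lab = np.asarray(labels)
    x_all = features.to_numpy(dtype=float)
    classes, counts = np.unique(lab, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("benchmark needs two classes with >= 2 samples each")

    rng = np.random.default_rng(seed)
    accuracies: dict[str, list[float]] = {k: [] for k in model_kinds}
    for run in range(config.n_repeats):
        train_idx, test_idx = _split_indices(
            lab, config.split_fraction, config.stratified_split, rng
        )
        train_df = pd.DataFrame(x_all[train_idx], columns=features.columns)
        test_df = pd.DataFrame(x_all[test_idx], columns=features.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_n, test_n, _ = normalize_features(train_df, test_df)
        model_seed = int(rng.integers(0, 2**31 - 1))
        for kind in model_kinds:
            model = train_model(
                kind, train_n.to_numpy(), lab[train_idx], config, seed=model_seed
            )
            pred = model.predict(test_n.to_numpy())
            accuracies[kind].append(100.0 * float(np.mean(pred == lab[test_idx])))

    report = BenchmarkReport(
        n_repeats=config.n_repeats, split_fraction=config.split_fraction, seed=seed
    )
    for kind in model_kinds:
        acc = np.asarray(accuracies[kind])
        report.per_model[kind] = {
            "mean_accuracy_pct": float(acc.mean()),
            "sd_pct": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
            "per_run": acc.tolist(),
        }
    return report
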