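"""Per-depth multivariate decoding with leave-one-run-out cross-validation.

Trial betas restricted to one depth bin's voxels are classified with a
linear soft-margin support vector machine (C-SVM, cost 1, termination
tolerance 0.001, equal class costs). Before classification, betas are
rescaled per voxel onto [-1, 1]; the rescaling parameters are learned on
the training folds only and applied to the held-out fold (test values may
therefore fall outside [-1, 1]; no clipping).

Provides colour decoding within a condition, cross-classification between
conditions (train on the two colours of one condition, test on another),
condition-pair decoding (e.g. illusory vs. mock within one colour), and
extraction of the fold-averaged primal weight vector for visual-field
back-projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .glm import BetaMatrix
from .laminar import DepthAssignment

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "WeightMap",
    "Rescaler",
    "rescale_betas",
    "decode_loro",
    "cross_classify",
    "decode_condition_pair",
    "extract_weight_map",
    "decode_subject_colours",
]


@dataclass(frozen=True)
class DecoderConfig:
    """Linear C-SVM settings (LIBSVM-style defaults)."""

    cost_c: float = 1.0
    kernel: str = "linear"
    termination_tolerance: float = 0.001

    def __post_init__(self) -> None:
        if self.cost_c <= 0:
            raise ValueError("cost_c must be positive")
        if self.termination_tolerance <= 0:
            raise ValueError("termination_tolerance must be positive")

    def make(self) -> SVC:
        # equal class costs: no class_weight
        return SVC(
            C=self.cost_c, kernel=self.kernel, tol=self.termination_tolerance
        )


@dataclass
class DecodingResult:
    """Fold accuracies for one (condition/pair, depth bin) analysis."""

    fold_accuracies: np.ndarray
    meta: dict = field(default_factory=dict)
    models: list = field(default_factory=list)
    voxel_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if np.any((self.fold_accuracies < 0) | (self.fold_accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


@dataclass
class WeightMap:
    """Fold-averaged primal SVM weights for one depth bin.

    Positive weight = evidence for the first-named class.
    """

    weights: np.ndarray
    bias: float
    voxel_indices: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.voxel_indices):
            raise ValueError("one weight per voxel required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


class Rescaler:
    """Per-voxel affine map of trial betas onto [-1, 1].

    Fitted on training trials only; applying to held-out trials can give
    values outside [-1, 1] by design.
    """

    def __init__(self) -> None:
        self.vmin: np.ndarray | None = None
        self.vmax: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "Rescaler":
        values = np.asarray(values, dtype=float)
        self.vmin = values.min(axis=0)
        self.vmax = values.max(axis=0)
        if np.any(self.vmax == self.vmin):
            raise ValueError("constant voxel in rescaling scope")
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.vmin is None:
            raise RuntimeError("Rescaler must be fitted first")
        return 2.0 * (values - self.vmin) / (self.vmax - self.vmin) - 1.0


def rescale_betas(betas: BetaMatrix) -> BetaMatrix:
    """Rescale each voxel's betas onto [-1, 1] over all trials.

    Convenience for non-cross-validated use; cross-validated decoding fits
    the rescaler on training folds internally.
    """
    scaled = Rescaler().fit(betas.values).transform(betas.values)
    return BetaMatrix(scaled, betas.labels.copy(), dict(betas.meta))


def _encode(labels: pd.Series, classes: tuple[str, str]) -> np.ndarray:
    y = np.full(len(labels), -1, dtype=int)
    y[labels.to_numpy() == classes[0]] = 0
    y[labels.to_numpy() == classes[1]] = 1
    if np.any(y < 0):
        raise ValueError(f"labels outside classes {classes}")
    return y


def decode_loro(
    betas: BetaMatrix,
    voxel_indices: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
    label_column: str = "colour",
    classes: tuple[str, str] = ("red", "green"),
) -> DecodingResult:
    """Leave-one-run-out decoding of a binary label within one depth bin.

    ``betas`` must already be restricted to the trials of interest (e.g.
    one condition's red/green trials). Each run serves once as the test
    fold; rescaling parameters and the SVM are fitted on the remaining
    runs' trials restricted to ``voxel_indices``.
    """
    runs = np.sort(betas.labels["run"].unique())
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs")
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    X_all = betas.values[:, voxel_indices]
    y_all = _encode(betas.labels[label_column], classes)
    run_of = betas.labels["run"].to_numpy()
    accs, models = [], []
    for test_run in runs:
        train = run_of != test_run
        y_train = y_all[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"class missing from training fold (test run {test_run})"
            )
        scaler = Rescaler().fit(X_all[train])
        clf = config.make()
        clf.fit(scaler.transform(X_all[train]), y_train)
        pred = clf.predict(scaler.transform(X_all[~train]))
        accs.append(np.mean(pred == y_all[~train]))
        models.append(clf)
    return DecodingResult(
        fold_accuracies=np.array(accs),
        meta={
            "scheme": f"{label_column}:{classes[0]}-vs-{classes[1]}",
            "n_voxels": len(voxel_indices),
            "runs": runs.tolist(),
        },
        models=models,
        voxel_indices=voxel_indices,
    )


def cross_classify(
    train_betas: BetaMatrix,
    train_condition: str,
    test_betas: BetaMatrix,
    test_condition: str,
    voxel_indices: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
    classes: tuple[str, str] = ("red", "green"),
) -> DecodingResult:
    """Train a colour classifier on one condition, test it on another.

    All runs of the training condition form the training set, all runs of
    the test condition the test set (no fold structure: the sets are
    disjoint by construction). Passing the same condition twice falls back
    to leave-one-run-out decoding.
    """
    if train_condition == test_condition:
        return decode_loro(train_betas, voxel_indices, config, classes=classes)
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    X_train = train_betas.values[:, voxel_indices]
    X_test = test_betas.values[:, voxel_indices]
    y_train = _encode(train_betas.labels["colour"], classes)
    y_test = _encode(test_betas.labels["colour"], classes)
    scaler = Rescaler().fit(X_train)
    clf = config.make()
    clf.fit(scaler.transform(X_train), y_train)
    acc = np.mean(clf.predict(scaler.transform(X_test)) == y_test)
    return DecodingResult(
        fold_accuracies=np.array([acc]),
        meta={
            "scheme": f"cross:{train_condition}->{test_condition}",
            "n_voxels": len(voxel_indices),
        },
        models=[clf],
        voxel_indices=voxel_indices,
    )


def decode_condition_pair(
    betas: BetaMatrix,
    condition_a: str,
    condition_b: str,
    voxel_indices: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
) -> dict[str, DecodingResult]:
    """Decode condition A vs. condition B separately per colour.

    Returns one leave-one-run-out result per colour (a built-in
    reliability check: both colour analyses should agree within sampling
    error for symmetric generators).
    """
    if condition_a == condition_b:
        raise ValueError("condition pair must be two distinct conditions")
    out = {}
    for colour in ("red", "green"):
        mask = (
            betas.labels["condition"].isin([condition_a, condition_b])
            & (betas.labels["colour"] == colour)
        ).to_numpy()
        sub = betas.select(mask)
        out[colour] = decode_loro(
            sub,
            voxel_indices,
            config,
            label_column="condition",
            classes=(condition_a, condition_b),
        )
    return out


def extract_weight_map(result: DecodingResult) -> WeightMap:
    """Fold-averaged primal weight vector of a linear decoding result.

    Sign convention: positive weight is evidence for the first-named
    class. Requires the linear kernel (the primal vector is undefined
    otherwise).
    """
    if not result.models:
        raise ValueError("result carries no trained models")
    for m in result.models:
        if m.kernel != "linear":
            raise ValueError("weight extraction requires a linear kernel")
    # sklearn's coef_ points towards class 1 (the second-named class);
    # flip so positive = first-named class
    w = -np.mean([m.coef_[0] for m in result.models], axis=0)
    b = -float(np.mean([m.intercept_[0] for m in result.models]))
    return WeightMap(
        weights=w, bias=b, voxel_indices=np.asarray(result.voxel_indices)
    )


def decode_subject_colours(
    betas: BetaMatrix,
    assignment: DepthAssignment,
    config: DecoderConfig = DecoderConfig(),
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Colour decoding for every (condition, depth bin): tidy fold table.

    Runs leave-one-run-out red-vs-green decoding per condition restricted
    to each depth bin's voxels. Returns rows (condition, depth, fold,
    accuracy, n_voxels).
    """
    if conditions is None:
        conditions = tuple(pd.unique(betas.labels["condition"]))
    rows = []
    for cond in conditions:
        sub = betas.select((betas.labels["condition"] == cond).to_numpy())
        for k, centre in enumerate(assignment.bin_centres):
            idx = assignment.indices(k)
            if len(idx) == 0:
                continue
            res = decode_loro(sub, idx, config)
            for fold, acc in enumerate(res.fold_accuracies):
                rows.append(
                    {
                        "condition": cond,
                        "depth": centre,
                        "fold": fold,
                        "accuracy": acc,
                        "n_voxels": len(idx),
                    }
                )
    return pd.DataFrame(rows)
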