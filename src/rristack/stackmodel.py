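"""Two-level stacked generalization for residue-pair classification.

Four heterogeneous base learners (decision tree, Gaussian naive Bayes,
one-hidden-layer neural network, random forest) are combined by a
gradient-boosted-tree meta-learner.  Meta-training data are produced by
out-of-fold prediction: the base learners are fit on the complement of each
of five stratified folds and score the held-out fold, so the meta-learner
never sees resubstitution probabilities.  The meta input is the four base
probabilities optionally concatenated with the primitive pair vector.

Evaluation follows leave-one-complex-out cross-validation: each complex's
pairs are scored by a stack trained on the similarity-filtered,
undersampled pairs of all remaining complexes, and ranked by ROC/AUROC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from lightgbm import LGBMClassifier, early_stopping
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .dataset import (
    FeaturizedComplex,
    complex_similarity,
    filter_training_complexes,
    undersample_indices,
)
from .errors import NonFiniteFeature, SchemaMismatch, SingleClass

BASE_LEARNER_NAMES = ["decision_tree", "naive_bayes", "neural_net",
                      "random_forest"]


@dataclass
class StackConfig:
    """Hyperparameters of the two-level stack.

    The learner settings are package defaults (none are dictated by the
    method itself): unlimited-depth tree with a minimum leaf of 5,
    Gaussian naive Bayes, a single 100-unit hidden layer with early
    stopping, a 200-tree forest, and up to 500 boosting rounds at learning
    rate 0.05 with early stopping on a 10% holdout.
    """

    oof_folds: int = 5
    include_primitive_in_meta: bool = True
    seed: int = 0
    tree_min_samples_leaf: int = 5
    nn_hidden_units: int = 100
    nn_max_iter: int = 150
    rf_trees: int = 200
    gbm_rounds: int = 500
    gbm_learning_rate: float = 0.05
    gbm_early_stopping_rounds: int = 20
    gbm_holdout_fraction: float = 0.1


def _make_base_learners(config: StackConfig) -> dict[str, object]:
    seed = config.seed
    return {
        "decision_tree": DecisionTreeClassifier(
            min_samples_leaf=config.tree_min_samples_leaf, random_state=seed
        ),
        "naive_bayes": GaussianNB(),
        "neural_net": MLPClassifier(
            hidden_layer_sizes=(config.nn_hidden_units,),
            early_stopping=True,
            max_iter=config.nn_max_iter,
            random_state=seed,
        ),
        "random_forest": RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=seed, n_jobs=1
        ),
    }


def _make_meta_learner(config: StackConfig) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=config.gbm_rounds,
        learning_rate=config.gbm_learning_rate,
        random_state=config.seed,
        n_jobs=1,
        verbose=-1,
    )


def _positive_proba(model, x: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(x)
    classes = list(model.classes_)
    if True in classes or 1 in classes:
        col = classes.index(True) if True in classes else classes.index(1)
        return proba[:, col]
    return np.zeros(len(x))


@dataclass
class TrainedStack:
    base_models: dict[str, object]
    meta_model: object
    config: StackConfig
    pair_width: int
    columns: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, model in self.base_models.items():
            joblib.dump(model, directory / f"base_{name}.joblib")
        joblib.dump(self.meta_model, directory / "meta.joblib")
        meta = {
            "config": asdict(self.config),
            "pair_width": self.pair_width,
            "columns": self.columns,
            "provenance": self.provenance,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedStack":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        base = {
            name: joblib.load(directory / f"base_{name}.joblib")
            for name in BASE_LEARNER_NAMES
        }
        return cls(
            base_models=base,
            meta_model=joblib.load(directory / "meta.joblib"),
            config=StackConfig(**meta["config"]),
            pair_width=meta["pair_width"],
            columns=meta.get("columns"),
            provenance=meta.get("provenance", {}),
        )


def _check_xy(x: np.ndarray, y: np.ndarray | None = None) -> None:
    if not np.isfinite(x).all():
        raise NonFiniteFeature("feature matrix contains NaN/inf")
    if y is not None and len(np.unique(y)) < 2:
        raise SingleClass("both classes required")


def train_stack(
    x: np.ndarray, y: np.ndarray, config: StackConfig | None = None,
    columns: list[str] | None = None, provenance: dict | None = None,
) -> TrainedStack:
    """Fit the two-level stack on labeled pair vectors.

    Out-of-fold base probabilities over ``config.oof_folds`` stratified
    folds form the meta-training matrix (concatenated with the primitive
    pair vectors when ``include_primitive_in_meta``); base learners are
    refit on all instances for inference.
    """
    config = config or StackConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(bool)
    _check_xy(x, y)

    min_class = int(min((y == True).sum(), (y == False).sum()))  # noqa: E712
    n_splits = min(config.oof_folds, min_class)
    if n_splits < 2:
        raise SingleClass(
            f"need >=2 instances of each class for out-of-fold stacking "
            f"(minority count {min_class})"
        )
    oof = np.zeros((len(y), len(BASE_LEARNER_NAMES)))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train_idx, held_idx in skf.split(x, y):
            fold_learners = _make_base_learners(config)
            for k, name in enumerate(BASE_LEARNER_NAMES):
                model = fold_learners[name]
                model.fit(x[train_idx], y[train_idx])
                oof[held_idx, k] = _positive_proba(model, x[held_idx])

        meta_x = np.hstack([oof, x]) if config.include_primitive_in_meta else oof
        meta = _make_meta_learner(config)
        if 0.0 < config.gbm_holdout_fraction < 1.0 and min_class >= 4:
            tr, va = train_test_split(
                np.arange(len(y)),
                test_size=config.gbm_holdout_fraction,
                stratify=y, random_state=config.seed,
            )
            meta.fit(
                meta_x[tr], y[tr],
                eval_set=[(meta_x[va], y[va])],
                callbacks=[early_stopping(
                    config.gbm_early_stopping_rounds, verbose=False)],
            )
        else:
            meta.fit(meta_x, y)

        base_models = _make_base_learners(config)
        for model in base_models.values():
            model.fit(x, y)

    return TrainedStack(
        base_models=base_models,
        meta_model=meta,
        config=config,
        pair_width=x.shape[1],
        columns=columns,
        provenance=provenance or {},
    )


def base_probabilities(stack: TrainedStack, x: np.ndarray) -> np.ndarray:
    return np.column_stack([
        _positive_proba(stack.base_models[name], x)
        for name in BASE_LEARNER_NAMES
    ])


def predict_stack(stack: TrainedStack, x: np.ndarray) -> np.ndarray:
    """Interaction probabilities for pair vectors matching the stack schema."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != stack.pair_width:
        raise SchemaMismatch(
            f"expected pair width {stack.pair_width}, got {x.shape}"
        )
    _check_xy(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probs = base_probabilities(stack, x)
        meta_x = (np.hstack([probs, x])
                  if stack.config.include_primitive_in_meta else probs)
        return np.clip(_positive_proba(stack.meta_model, meta_x), 0.0, 1.0)


# ---------------------------------------------------------------------------
# ROC / AUROC


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def roc_and_auroc(scores, labels) -> RocCurve:
    """ROC points over all distinct score thresholds plus trapezoidal AUROC.

    TPR = TP / (TP + FN) and FPR = FP / (FP + TN) are traced from the
    strictest threshold to the loosest; the area equals the probability
    that a random positive outscores a random negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    p = int(labels.sum())
    n = int((~labels).sum())
    if p == 0 or n == 0:
        raise SingleClass("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    tpr = np.r_[0.0, tp[distinct] / p]
    fpr = np.r_[0.0, fp[distinct] / n]
    auroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auroc=auroc)


# ---------------------------------------------------------------------------
# LOOCV driver


@dataclass
class LoocvFold:
    complex_id: str
    auroc: float | None
    n_train: int
    n_test_pairs: int
    filter_fallback: bool
    warning: str | None = None


@dataclass
class LoocvResult:
    folds: list[LoocvFold]
    mean_auroc: float
    warnings: list[str]

    @property
    def per_complex(self) -> dict[str, float | None]:
        return {f.complex_id: f.auroc for f in self.folds}

    def to_json(self) -> dict:
        return {
            "mean_auroc": self.mean_auroc,
            "per_complex": self.per_complex,
            "warnings": self.warnings,
            "folds": [
                {"complex_id": f.complex_id, "auroc": f.auroc,
                 "n_train": f.n_train, "n_test_pairs": f.n_test_pairs,
                 "filter_fallback": f.filter_fallback,
                 "warning": f.warning}
                for f in self.folds
            ],
        }


def pairwise_similarity(
    featurized: list[FeaturizedComplex],
) -> dict[tuple[str, str], float]:
    """Symmetric similarity scores between every pair of complexes."""
    scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(featurized):
        for b in featurized[i + 1:]:
            s = complex_similarity(a.record, b.record)
            scores[(a.complex_id, b.complex_id)] = s
            scores[(b.complex_id, a.complex_id)] = s
    return scores


def loocv(
    featurized: list[FeaturizedComplex],
    config: StackConfig | None = None,
    ratio_negatives_per_positive: int = 3,
    filter_threshold: float = 0.05,
    similarity: dict[tuple[str, str], float] | None = None,
    seed: int | None = None,
) -> LoocvResult:
    """Leave-one-complex-out evaluation of the full pipeline.

    For each held-out complex: filter the training pool by similarity,
    pool and undersample the remaining training pairs, train a stack, score
    every test pair (no test-side undersampling) and compute its AUROC.
    Folds whose test pairs are single-class are skipped with a warning.
    """
    if len(featurized) < 2:
        raise ValueError("LOOCV needs at least two complexes")
    config = config or StackConfig()
    seed = config.seed if seed is None else seed
    if similarity is None:
        similarity = pairwise_similarity(featurized)

    folds: list[LoocvFold] = []
    warns: list[str] = []
    for fold_idx, test_fc in enumerate(featurized):
        pool = [fc for fc in featurized if fc is not test_fc]
        sim_scores = {
            fc.complex_id: similarity[(test_fc.complex_id, fc.complex_id)]
            for fc in pool
        }
        kept, report = filter_training_complexes(
            test_fc.complex_id, pool, filter_threshold, scores=sim_scores
        )
        if report.fallback:
            warns.append(
                f"{test_fc.complex_id}: similarity filter removed all "
                f"training complexes; falling back to full pool"
            )

        rng = np.random.default_rng([seed, fold_idx])
        x_parts, y_parts = [], []
        for fc in kept:
            ri, lj, y = fc.all_pairs()
            idx = undersample_indices(y, ratio_negatives_per_positive, rng)
            x_parts.append(fc.pair_features(ri[idx], lj[idx]))
            y_parts.append(y[idx])
        x_train = np.vstack(x_parts)
        y_train = np.concatenate(y_parts)

        ri, lj, y_test = test_fc.all_pairs()
        fold = LoocvFold(
            complex_id=test_fc.complex_id,
            auroc=None,
            n_train=len(y_train),
            n_test_pairs=len(y_test),
            filter_fallback=report.fallback,
        )
        try:
            fold_config = StackConfig(**{**asdict(config), "seed": seed})
            stack = train_stack(x_train, y_train, fold_config)
            scores = predict_stack(stack, test_fc.pair_features(ri, lj))
            fold.auroc = roc_and_auroc(scores, y_test).auroc
        except SingleClass as exc:
            fold.warning = str(exc)
            warns.append(f"{test_fc.complex_id}: skipped ({exc})")
        folds.append(fold)

    valid = [f.auroc for f in folds if f.auroc is not None]
    mean = float(np.mean(valid)) if valid else float("nan")
    return LoocvResult(folds=folds, mean_auroc=mean, warnings=warns)
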