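"""Random-forest cancer classifier over end-motif profiles.

The modelling recipe: fit a forest on all 256 motif frequencies, rank
motifs by out-of-bag permutation importance (mean decrease accuracy),
keep the top-k motifs (13 for the cancer model, 6 for the immunotherapy
model), and refit on that subset. Performance is estimated by
stratified k-fold cross-validation in which ranking and selection are
re-run inside every training fold, so held-out scores never see the
fold's own labels through feature selection. A sample's cancer score is
the forest's positive-class vote fraction, in [0, 1].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, InputError, TrainingError

logger = logging.getLogger(__name__)

def _oob_indices(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag sample indices of one tree.

    Re-derives the tree's bootstrap draw from its stored random state
    (valid for forests fit with bootstrap=True, max_samples=None and no
    sample weights). Uses sklearn's own helper when its signature is
    recognisable, else replicates the identical draw.
    """
    try:  # signatures vary across sklearn versions
        from sklearn.ensemble._forest import _generate_unsampled_indices

        try:
            return _generate_unsampled_indices(tree.random_state, n_samples, n_samples)
        except TypeError:
            return _generate_unsampled_indices(
                tree.random_state, n_samples, n_samples, None
            )
    except ImportError:  # pragma: no cover - only if sklearn internals move
        sampled = np.random.RandomState(tree.random_state).randint(
            0, n_samples, n_samples
        )
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class RFConfig:
    """Forest and selection hyperparameters.

    Defaults are the canonical forest settings (500 trees, sqrt(p)
    candidate features per split, leaves grown pure) with 5-fold CV and
    top-13 motif selection.
    """

    n_trees: int = 500
    features_per_split: str | int = "sqrt"
    min_leaf: int = 1
    seed: int = 0
    n_folds: int = 5
    top_k: int = 13
    importance: str = "mda_oob"  # or "gini"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not 1 <= self.top_k <= 256:
            raise ConfigurationError("top_k must be in [1, 256]")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.importance not in ("mda_oob", "gini"):
            raise ConfigurationError("importance must be 'mda_oob' or 'gini'")


@dataclass(frozen=True)
class ImportanceRanking:
    """Motifs sorted by non-increasing importance (ties lexicographic)."""

    motifs: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.motifs) != len(self.scores):
            raise ValueError("motifs and scores must align")
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError("ranked motifs must be unique")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"motif": self.motifs, "mean_decrease_accuracy": self.scores})


@dataclass
class TrainedModel:
    """A fitted forest restricted to its selected motif subset."""

    forest: RandomForestClassifier
    selected_motifs: tuple[str, ...]
    ranking: ImportanceRanking
    config: RFConfig
    training_sample_ids: tuple[str, ...]
    positive_label: str

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "forest": self.forest,
                "selected_motifs": self.selected_motifs,
                "ranking": self.ranking,
                "config": self.config,
                "training_sample_ids": self.training_sample_ids,
                "positive_label": self.positive_label,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != 1:
            raise InputError(f"{path}: unknown model archive version")
        return cls(
            forest=blob["forest"],
            selected_motifs=blob["selected_motifs"],
            ranking=blob["ranking"],
            config=blob["config"],
            training_sample_ids=blob["training_sample_ids"],
            positive_label=blob["positive_label"],
        )


def infer_positive_label(labels: Sequence) -> str:
    classes = sorted({str(v) for v in labels})
    if set(classes) == {"cancer", "healthy"}:
        return "cancer"
    if set(classes) == {"response", "non_response"}:
        return "response"
    return classes[-1]


def _binarize(labels: Sequence, positive_label: str | None) -> tuple[np.ndarray, str]:
    labels = np.asarray([str(v) for v in labels])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise TrainingError("labels contain a single class; need both classes to train")
    if len(classes) > 2:
        raise TrainingError(f"expected binary labels, got {list(classes)}")
    pos = positive_label or infer_positive_label(labels)
    if pos not in classes:
        raise TrainingError(f"positive label {pos!r} absent from labels")
    return (labels == pos).astype(int), pos


def _fit_forest(X: np.ndarray, y: np.ndarray, config: RFConfig, seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _tree_predict(tree, X32: np.ndarray) -> np.ndarray:
    # bypass per-call input validation; X32 must be C-contiguous float32
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:  # (n_samples, n_outputs, n_classes) in some versions
        proba = proba[:, 0, :]
    return np.argmax(proba, axis=1)


def oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Mean decrease accuracy per feature, measured out of bag.

    For every tree: take its out-of-bag samples, record the tree's OOB
    accuracy, then for each feature the tree actually splits on, permute
    that feature's OOB values and record the accuracy drop. A feature a
    tree never uses cannot change that tree's predictions, so its drop
    is zero. The importance is the drop averaged over all trees.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    drops = np.zeros(p)
    for tree in forest.estimators_:
        oob = _oob_indices(tree, n)
        if oob.size == 0:
            continue
        Xo = X32[oob].copy()
        yo = y[oob]
        base = float(np.mean(_tree_predict(tree, Xo) == yo))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            col = Xo[:, j].copy()
            Xo[:, j] = col[rng.permutation(oob.size)]
            acc = float(np.mean(_tree_predict(tree, Xo) == yo))
            Xo[:, j] = col
            drops[j] += base - acc
    return drops / len(forest.estimators_)


def rank_importance(
    matrix: pd.DataFrame,
    labels: Sequence,
    config: RFConfig | None = None,
    positive_label: str | None = None,
) -> ImportanceRanking:
    """Fit a forest on all features and rank them by importance.

    Default importance is out-of-bag permutation mean decrease accuracy;
    Gini (impurity) importance is available as an option but is never
    the default. Deterministic for a fixed ``config.seed``.
    """
    config = config or RFConfig()
    y, _ = _binarize(labels, positive_label)
    if min(np.bincount(y)) < 2:
        raise TrainingError("need at least 2 samples per class")
    X = matrix.to_numpy(dtype=float)
    forest = _fit_forest(X, y, config, config.seed)
    if config.importance == "gini":
        scores = forest.feature_importances_
    else:
        scores = oob_permutation_importance(forest, X, y, seed=config.seed)
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], matrix.columns[j]))
    return ImportanceRanking(
        motifs=tuple(matrix.columns[j] for j in order),
        scores=tuple(float(scores[j]) for j in order),
    )


def select_top_k(ranking: ImportanceRanking, k: int) -> tuple[str, ...]:
    """First k motifs of the ranking; boundary ties resolve lexicographically."""
    if not 1 <= k <= len(ranking.motifs):
        raise ConfigurationError(f"k must be in [1, {len(ranking.motifs)}], got {k}")
    if k < len(ranking.motifs) and ranking.scores[k - 1] == ranking.scores[k]:
        logger.warning(
            "importance tie at rank %d (%.6g); keeping lexicographically smaller motif %s",
            k,
            ranking.scores[k - 1],
            ranking.motifs[k - 1],
        )
    return ranking.motifs[:k]


def importance_null_band(
    matrix: pd.DataFrame,
    labels: Sequence,
    config: RFConfig | None = None,
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Maximum importance under label permutation, one value per permutation.

    Permuting the labels severs any feature-label association, so these
    maxima describe what noise alone produces at this sample size and
    feature count; an observed maximum importance inside this band is
    indistinguishable from noise.
    """
    config = config or RFConfig()
    rng = np.random.default_rng(seed)
    labels = np.asarray([str(v) for v in labels])
    maxima = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted = labels[rng.permutation(len(labels))]
        cfg = replace(config, seed=int(rng.integers(0, 2**31)))
        maxima[b] = rank_importance(matrix, permuted, cfg).scores[0]
    return maxima


def _fold_seeds(config: RFConfig, n: int) -> list[int]:
    ss = np.random.SeedSequence(config.seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def cross_validate(
    matrix: pd.DataFrame,
    labels: Sequence,
    config: RFConfig | None = None,
    positive_label: str | None = None,
    selection_in_fold: bool = True,
) -> pd.Series:
    """Out-of-fold cancer scores from stratified k-fold CV.

    Importance ranking and top-k selection are re-run inside every
    training fold (``selection_in_fold=True``) so that scoring a
    held-out sample never uses its label, even indirectly through
    feature selection. ``selection_in_fold=False`` performs selection
    once on the full data and is provided only as an ablation that
    demonstrates the optimistic bias of leaking selection.
    """
    config = config or RFConfig()
    y, pos = _binarize(labels, positive_label)
    counts = np.bincount(y)
    if counts.min() < config.n_folds:
        raise TrainingError(
            f"smallest class has {counts.min()} samples; fewer than n_folds={config.n_folds}"
        )
    X = matrix.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    scores = pd.Series(np.nan, index=matrix.index, name="score", dtype=float)
    seeds = _fold_seeds(config, config.n_folds)
    leaky_selected: tuple[str, ...] | None = None
    if not selection_in_fold:
        leaky_selected = select_top_k(rank_importance(matrix, labels, config, pos), config.top_k)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = replace(config, seed=seeds[fold])
        if selection_in_fold:
            ranking = rank_importance(
                matrix.iloc[tr], np.asarray(labels)[tr], fold_cfg, pos
            )
            selected = select_top_k(ranking, config.top_k)
        else:
            selected = leaky_selected
        cols = [matrix.columns.get_loc(m) for m in selected]
        forest = _fit_forest(X[np.ix_(tr, cols)], y[tr], config, seeds[fold])
        scores.iloc[te] = forest.predict_proba(X[np.ix_(te, cols)])[:, 1]
    assert not scores.isna().any()
    return scores


def fit_final(
    matrix: pd.DataFrame,
    labels: Sequence,
    config: RFConfig | None = None,
    positive_label: str | None = None,
) -> TrainedModel:
    """Rank on the full training cohort, select top-k, refit on the subset."""
    config = config or RFConfig()
    y, pos = _binarize(labels, positive_label)
    ranking = rank_importance(matrix, labels, config, pos)
    selected = select_top_k(ranking, config.top_k)
    X = matrix[list(selected)].to_numpy(dtype=float)
    forest = _fit_forest(X, y, config, config.seed)
    return TrainedModel(
        forest=forest,
        selected_motifs=selected,
        ranking=ranking,
        config=config,
        training_sample_ids=tuple(matrix.index),
        positive_label=pos,
    )


def predict_scores(model: TrainedModel, matrix: pd.DataFrame) -> pd.Series:
    """Positive-class vote fraction per sample, in [0, 1]."""
    missing = [m for m in model.selected_motifs if m not in matrix.columns]
    if missing:
        raise InputError(f"matrix lacks selected motif columns: {missing}")
    X = matrix[list(model.selected_motifs)].to_numpy(dtype=float)
    return pd.Series(
        model.forest.predict_proba(X)[:, 1], index=matrix.index, name="score"
    )
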