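"""Five-learner majority-voting ensemble for 6mA window classification.

The ensemble combines five heterogeneous base classifiers — random
forest (RF), linear discriminant analysis (LDA), a one-hidden-layer
multi-layer perceptron (MLP), a linear SVM trained by stochastic
gradient descent (SGD), and gradient-boosted trees (XGB) — by hard
majority voting: a window is called 6mA-positive when at least 3 of the
5 base learners vote positive. Votes are hard labels, never
probabilities.

All base learners are scikit-learn estimators behind a uniform
fit/predict contract; the gradient-boosting member is scikit-learn's
histogram-based gradient boosting. The package's own computation is the
encoding, the voting rule, grid-search orchestration and evaluation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from methylvote.encoders import Encoder, encode_matrix, get_encoder
from methylvote.property_tables import PropertyTable
from methylvote.sequence_io import DnaWindow, LabeledDataset

logger = logging.getLogger(__name__)

#: The five base-learner algorithms, in canonical (voting/report) order.
ALGORITHMS = ("RF", "LDA", "MLP", "SGD", "XGB")

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BaseClassifierSpec:
    """One base learner: algorithm name, hyperparameters, and seed."""

    algorithm: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )

    def with_params(self, **updates) -> "BaseClassifierSpec":
        merged = dict(self.hyperparameters)
        merged.update(updates)
        return BaseClassifierSpec(self.algorithm, merged, self.seed)


def build_classifier(spec: BaseClassifierSpec):
    """Instantiate the scikit-learn estimator behind a spec.

    Seeds are threaded into every stochastic algorithm; LDA is
    deterministic and takes none.
    """
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "RF":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.algorithm == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.algorithm == "MLP":
        hp.setdefault("hidden_layer_sizes", (64,))
        hp.setdefault("max_iter", 200)
        return MLPClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "SGD":
        # hinge loss: a linear SVM fitted by stochastic gradient descent
        hp.setdefault("loss", "hinge")
        return SGDClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "XGB":
        return HistGradientBoostingClassifier(random_state=spec.seed, **hp)
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")  # pragma: no cover


def default_specs(seed: int = 0) -> list[BaseClassifierSpec]:
    """The five default base-learner specs with per-algorithm seeds."""
    return [
        BaseClassifierSpec(alg, {}, seed=seed + i)
        for i, alg in enumerate(ALGORITHMS)
    ]


def default_grids() -> dict[str, dict[str, list]]:
    """Documented default hyperparameter grids, one per algorithm.

    Grids are inputs, not constants: pass your own mapping to
    :func:`train_ensemble` or :func:`grid_search` to override.
    """
    return {
        "RF": {"n_estimators": [100, 300], "max_features": ["sqrt", 0.3]},
        "LDA": {"solver": ["svd", "lsqr"]},
        "MLP": {"hidden_layer_sizes": [(32,), (64,), (128,)],
                "alpha": [1e-4, 1e-3]},
        "SGD": {"alpha": [1e-5, 1e-4, 1e-3]},
        "XGB": {"learning_rate": [0.05, 0.1, 0.3], "max_iter": [100, 200]},
    }


def majority_vote(votes: Sequence[int], threshold: int = 3) -> int:
    """Label 1 iff at least ``threshold`` of the votes are 1.

    With 5 voters and the default threshold 3 this is strict majority and
    no tie is possible.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote list")
    if not 1 <= threshold <= len(votes):
        raise ValueError(
            f"threshold {threshold} out of range for {len(votes)} votes"
        )
    if any(v not in (0, 1) for v in votes):
        raise ValueError("votes must be 0 or 1")
    return int(sum(votes) >= threshold)


def train_base(spec: BaseClassifierSpec, X: np.ndarray, y: Sequence[int]):
    """Fit one base classifier on a feature matrix and binary labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature matrix has {X.shape[0] if X.ndim == 2 else '?'} rows "
            f"but {y.shape[0]} labels"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = build_classifier(spec)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        clf.fit(X, y)
    return clf


@dataclass
class GridSearchResult:
    """Outcome of an exhaustive grid search for one algorithm."""

    algorithm: str
    best_params: dict
    best_score: float
    results: list[tuple[dict, float]]  # (params, mean CV accuracy; NaN = failed)
    folds: int

    def __post_init__(self) -> None:
        finite = [s for _, s in self.results if np.isfinite(s)]
        assert not finite or self.best_score >= max(finite) - 1e-12


def grid_search(
    spec: BaseClassifierSpec,
    grid: Mapping[str, Sequence],
    X: np.ndarray,
    y: Sequence[int],
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive stratified-CV accuracy search over a hyperparameter grid.

    Every combination in the Cartesian product of ``grid`` is scored by
    stratified ``folds``-fold CV accuracy; ties break to the first
    combination in enumeration order. Combinations that fail to train are
    recorded with NaN and skipped; if all fail, an error is raised.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    names = list(grid)
    combos = [dict(zip(names, vals))
              for vals in itertools.product(*(grid[n] for n in names))]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    results: list[tuple[dict, float]] = []
    best: tuple[float, dict] | None = None
    for params in combos:
        trial = spec.with_params(**params)
        try:
            accs = []
            for tr, te in splits:
                clf = train_base(trial, X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
            score = float(np.mean(accs))
        except Exception as exc:  # noqa: BLE001 - record and skip per contract
            logger.warning("grid combination %s failed: %s", params, exc)
            results.append((params, float("nan")))
            continue
        results.append((params, score))
        if best is None or score > best[0]:
            best = (score, params)
    if best is None:
        raise RuntimeError(f"every {spec.algorithm} grid combination failed")
    return GridSearchResult(spec.algorithm, best[1], best[0], results, folds)


class EnsembleModel:
    """Five fitted base classifiers + encoder spec + majority-vote rule.

    Prediction re-encodes query windows with the recorded encoder, takes
    a hard 0/1 vote from each base learner, and labels the window by
    :func:`majority_vote`.
    """

    def __init__(
        self,
        models: Mapping[str, object],
        encoder_name: str,
        window_length: int,
        vote_threshold: int = 3,
        dinucleotide_table: PropertyTable | None = None,
        trinucleotide_table: PropertyTable | None = None,
        fused_components: tuple[str, ...] | None = None,
        metadata: dict | None = None,
    ):
        self.algorithms = tuple(models)
        if len(self.algorithms) < 1:
            raise ValueError("ensemble needs at least one base model")
        if not 1 <= vote_threshold <= len(self.algorithms):
            raise ValueError("vote_threshold out of range")
        if len(self.algorithms) % 2 == 0:
            warnings.warn(
                "even number of base classifiers: vote ties map to label 0",
                stacklevel=2,
            )
        self.models = dict(models)
        self.encoder_name = encoder_name
        self.window_length = int(window_length)
        self.vote_threshold = int(vote_threshold)
        self.dinucleotide_table = dinucleotide_table
        self.trinucleotide_table = trinucleotide_table
        self.fused_components = fused_components
        self.metadata = dict(metadata or {})
        self.format_version = _MODEL_FORMAT_VERSION

    def encoder(self) -> Encoder:
        return get_encoder(
            self.encoder_name,
            dinucleotide_table=self.dinucleotide_table,
            trinucleotide_table=self.trinucleotide_table,
            components=self.fused_components,
        )

    def _validate(self, windows: Sequence[DnaWindow]) -> None:
        bad = [
            w.id for w in windows
            if not w.is_model_ready(self.window_length)
        ]
        if bad:
            shown = ", ".join(bad[:10]) + (" ..." if len(bad) > 10 else "")
            raise ValueError(
                f"{len(bad)} windows are not valid {self.window_length}-nt "
                f"central-A windows: {shown}"
            )

    @staticmethod
    def _coerce_windows(data) -> list[DnaWindow]:
        if isinstance(data, LabeledDataset):
            return list(data.windows)
        out = []
        for i, item in enumerate(data):
            if isinstance(item, DnaWindow):
                out.append(item)
            else:
                out.append(DnaWindow(sequence=str(item), id=f"query_{i}"))
        if not out:
            raise ValueError("no query windows supplied")
        return out

    def predict_votes(self, data) -> tuple[np.ndarray, np.ndarray]:
        """Per-window base votes and ensemble labels.

        Returns ``(votes, labels)`` where ``votes`` is an (n, 5) 0/1
        array in ``self.algorithms`` order and ``labels`` the majority
        calls. Raises if any window is not a valid central-A window of
        the model's length.
        """
        windows = self._coerce_windows(data)
        self._validate(windows)
        ds = LabeledDataset(windows, [0] * len(windows), name="query")
        X = encode_matrix(ds, self.encoder())
        votes = np.column_stack(
            [np.asarray(self.models[a].predict(X), dtype=int)
             for a in self.algorithms]
        )
        labels = np.array(
            [majority_vote(row, self.vote_threshold) for row in votes],
            dtype=int,
        )
        return votes, labels

    def predict(self, data) -> np.ndarray:
        """Ensemble 0/1 labels for a dataset, window list, or sequences."""
        return self.predict_votes(data)[1]

    def predict_table(self, data):
        """Predictions as a DataFrame: id, ensemble_label, per-learner votes."""
        import pandas as pd

        windows = self._coerce_windows(data)
        votes, labels = self.predict_votes(windows)
        table = pd.DataFrame({"id": [w.id for w in windows],
                              "ensemble_label": labels})
        for j, alg in enumerate(self.algorithms):
            table[f"vote_{alg}"] = votes[:, j]
        return table


def train_ensemble(
    train: LabeledDataset,
    encoder,
    specs: Sequence[BaseClassifierSpec] | None = None,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    folds: int = 5,
    seed: int = 0,
    vote_threshold: int = 3,
    window_length: int | None = None,
) -> EnsembleModel:
    """Encode a cleaned training set once and fit the five base learners.

    ``grids`` maps algorithm name to a hyperparameter grid; when given,
    each listed algorithm is grid-searched by stratified CV before the
    final fit on the full training matrix. Fully deterministic for a
    given seed.
    """
    if specs is None:
        specs = default_specs(seed)
    if isinstance(encoder, str):
        encoder = get_encoder(encoder)
    if window_length is None:
        lengths = {w.length for w in train.windows}
        if len(lengths) != 1:
            raise ValueError("training windows have heterogeneous lengths; "
                             "clean the dataset first")
        window_length = lengths.pop()

    logger.info("encoding %d training windows with %s", len(train), encoder.name)
    X = encode_matrix(train, encoder)
    y = train.label_array()

    grid_results: dict[str, GridSearchResult] = {}
    models: dict[str, object] = {}
    for spec in specs:
        if grids and spec.algorithm in grids:
            result = grid_search(spec, grids[spec.algorithm], X, y,
                                 folds=folds, seed=seed)
            grid_results[spec.algorithm] = result
            spec = spec.with_params(**result.best_params)
            logger.info("%s grid search: best %s (CV ACC %.3f)",
                        spec.algorithm, result.best_params, result.best_score)
        models[spec.algorithm] = train_base(spec, X, y)
        logger.info("fitted %s", spec.algorithm)

    metadata = {
        "dataset": train.name,
        "n_train": len(train),
        "seed": seed,
        "encoder": encoder.name,
        "algorithms": [s.algorithm for s in specs],
        "grid_search": {
            alg: {"best_params": r.best_params, "best_score": r.best_score}
            for alg, r in grid_results.items()
        },
    }
    enc_spec = encoder.spec or {"name": encoder.name}
    return EnsembleModel(
        models,
        encoder_name=enc_spec["name"],
        window_length=window_length,
        vote_threshold=vote_threshold,
        dinucleotide_table=enc_spec.get("dinucleotide_table"),
        trinucleotide_table=enc_spec.get("trinucleotide_table"),
        fused_components=enc_spec.get("components"),
        metadata=metadata,
    )


def save_model(model: EnsembleModel, path) -> None:
    """Persist a fitted ensemble (joblib archive with a version stamp)."""
    from methylvote import __version__

    joblib.dump(
        {"format_version": _MODEL_FORMAT_VERSION,
         "package_version": __version__,
         "model": model},
        path,
    )


def load_model(path) -> EnsembleModel:
    """Load a persisted ensemble; round-trips predictions exactly."""
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {payload.get('format_version')}"
        )
    return payload["model"]
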