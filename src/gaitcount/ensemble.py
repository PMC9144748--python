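"""Classify-then-regress step counting.

The core model is a two-stage ensemble: a carrying-position classifier
routes each acceleration window to a bank of position-specific step-count
regressors, and the "ensemble" regressor is a weighted average of the
linear-kernel SVM, the MLP and the random forest trained for that
position.  Training the regressors per position lets each one specialise
on that position's signal pattern instead of averaging over all of them.

Seven learner families are available for either role: random forest,
1-D CNN, histogram gradient boosting, MLP, linear-kernel SVM, k-nearest
neighbours, and the weighted-average ensemble (regression only).  With
all of them requested the bank holds 3 positions x 7 regressors.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted

from .preprocess import preprocess_accel
from .traces import POSITIONS, AccelTrace
from .windows import WindowDataset, slide_features
from . import nn

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "random_forest",
    "cnn",
    "hist_gradient_boost",
    "mlp",
    "svm",
    "knn",
    "ensemble",
)
#: Components whose weighted average forms the ensemble regressor.
ENSEMBLE_COMPONENTS = ("svm", "mlp", "random_forest")

#: Four hidden layers totalling 920 units (any split summing to 920 is
#: an acceptable configuration; this one tapers).
MLP_HIDDEN_LAYERS = (460, 230, 150, 80)


class TrainingDataError(ValueError):
    """Raised when the training windows cannot support the requested bank."""


@dataclass(frozen=True)
class ModelSpec:
    """One learner request: algorithm, role and (optional) overrides.

    ``hyperparams`` are passed through to the underlying estimator and
    override the documented defaults (e.g. classifier random forest:
    200 trees, depth cap 200; regressor random forest: 500 trees;
    SVM: linear kernel; MLP: 4 hidden layers, 920 units total).
    """

    algorithm: str
    role: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if self.role not in ("classifier", "regressor"):
            raise ValueError(f"role must be 'classifier' or 'regressor', got {self.role!r}")
        if self.algorithm == "ensemble" and self.role != "regressor":
            raise ValueError("the ensemble model is a regressor (weighted average of SVM/MLP/RF)")


def _scaled(estimator):
    # distance- and gradient-based learners need standardised inputs;
    # magnitude windows sit around g = 9.81 m/s^2 with position-dependent spread
    return make_pipeline(StandardScaler(), estimator)


def make_estimator(spec: ModelSpec):
    """Instantiate the estimator for a spec (``ensemble`` has no single
    estimator; it is assembled from its components at prediction time)."""
    hp = dict(spec.hyperparams)
    alg, role, seed = spec.algorithm, spec.role, spec.seed
    if alg == "ensemble":
        raise ValueError("the ensemble regressor is derived from its components, not instantiated")
    if alg == "random_forest":
        if role == "classifier":
            defaults = dict(n_estimators=200, max_depth=200, random_state=seed, n_jobs=1)
            return RandomForestClassifier(**{**defaults, **hp})
        defaults = dict(n_estimators=500, random_state=seed, n_jobs=1)
        return RandomForestRegressor(**{**defaults, **hp})
    if alg == "hist_gradient_boost":
        cls = HistGradientBoostingClassifier if role == "classifier" else HistGradientBoostingRegressor
        return cls(**{**dict(random_state=seed), **hp})
    if alg == "svm":
        cls = SVC if role == "classifier" else SVR
        defaults = dict(kernel="linear")
        if role == "classifier":
            defaults["random_state"] = seed
        return _scaled(cls(**{**defaults, **hp}))
    if alg == "mlp":
        cls = MLPClassifier if role == "classifier" else MLPRegressor
        defaults = dict(
            hidden_layer_sizes=MLP_HIDDEN_LAYERS,
            max_iter=300,
            early_stopping=True,
            random_state=seed,
        )
        return _scaled(cls(**{**defaults, **hp}))
    if alg == "knn":
        cls = KNeighborsClassifier if role == "classifier" else KNeighborsRegressor
        return _scaled(cls(**hp))
    if alg == "cnn":
        cls = nn.Conv1dClassifier if role == "classifier" else nn.Conv1dRegressor
        return cls(**{**dict(random_state=seed), **hp})
    raise AssertionError(f"unhandled algorithm {alg!r}")


def default_specs(
    regressors: Sequence[str] = ("random_forest", "svm", "mlp", "ensemble"),
    classifier: str = "random_forest",
    seed: int = 0,
) -> list[ModelSpec]:
    """Classifier spec plus one regressor spec per requested algorithm."""
    specs = [ModelSpec(algorithm=classifier, role="classifier", seed=seed)]
    specs += [ModelSpec(algorithm=a, role="regressor", seed=seed) for a in regressors]
    return specs


def split_dataset(
    dataset: WindowDataset,
    train_frac: float = 0.7,
    mode: str = "chronological",
    seed: int = 0,
) -> tuple[WindowDataset, WindowDataset]:
    """7:3-style train/test partition of a window dataset.

    ``random`` mode shuffles windows and takes exact
    ``round(train_frac * n)`` for training.  ``chronological`` mode (the
    leakage-safe default) cuts each recording's windows by time: the cut
    falls at the start of window ``ceil(train_frac * n_rec)`` and any
    train-side window whose samples straddle the cut is dropped, so no
    test window shares samples with a train window.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if mode == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        return dataset.subset(np.sort(perm[:n_train])), dataset.subset(np.sort(perm[n_train:]))
    if mode != "chronological":
        raise ValueError(f"unknown split mode {mode!r}")
    window_len = dataset.window_len
    stride = dataset.stride
    overlap = window_len - stride
    train_idx, test_idx = [], []
    for rec in np.unique(dataset.recording_ids):
        rec_idx = np.flatnonzero(dataset.recording_ids == rec)
        rec_idx = rec_idx[np.argsort(dataset.window_starts[rec_idx])]
        n_rec = len(rec_idx)
        cut = int(np.ceil(train_frac * n_rec))
        cut = min(cut, n_rec)
        test_idx.extend(rec_idx[cut:])
        # drop train windows overlapping the first test window's samples
        keep = cut - int(np.ceil(overlap / stride)) if cut < n_rec and overlap > 0 else cut
        train_idx.extend(rec_idx[: max(keep, 0)])
    return dataset.subset(np.array(sorted(train_idx), dtype=int)), dataset.subset(
        np.array(sorted(test_idx), dtype=int)
    )


class EnsembleStepCounter(BaseEstimator):
    """Position-routed step-count estimator (sklearn-style).

    Parameters
    ----------
    classifier_algorithm : str
        Learner for the carrying-position classifier (default random
        forest, 200 trees, depth cap 200).
    regressor_algorithms : sequence of str
        Regressors to train per position.  ``"ensemble"`` requires its
        three components (SVM, MLP, random forest) and adds no estimator
        of its own.
    ensemble_weights : dict or None
        Weights over the ensemble components; ``None`` means uniform.
        Must be non-negative and sum to 1.
    window_s, overlap_frac, sample_rate_hz, maf_half_width :
        Windowing and preprocessing geometry used by
        :meth:`count_steps`; must match the training windows.
    routing : {"recording", "window"}
        Whole-recording counting either routes every window with the
        recording's majority-vote position (placement is fixed during a
        walk) or per window.
    random_state : int
        Seed forwarded to every learner.

    Attributes
    ----------
    classifier_ : fitted position classifier
    regressors_ : dict position -> dict algorithm -> fitted regressor
    ensemble_weights_ : dict algorithm -> float
    classes_ : positions seen during fit
    """

    def __init__(
        self,
        classifier_algorithm: str = "random_forest",
        regressor_algorithms: Sequence[str] = ("random_forest", "svm", "mlp", "ensemble"),
        ensemble_weights: Optional[dict] = None,
        window_s: float = 2.0,
        overlap_frac: float = 0.5,
        sample_rate_hz: float = 30.0,
        maf_half_width: int = 2,
        routing: str = "recording",
        random_state: int = 0,
        classifier_hyperparams: Optional[dict] = None,
        regressor_hyperparams: Optional[dict] = None,
    ):
        self.classifier_algorithm = classifier_algorithm
        self.regressor_algorithms = regressor_algorithms
        self.ensemble_weights = ensemble_weights
        self.window_s = window_s
        self.overlap_frac = overlap_frac
        self.sample_rate_hz = sample_rate_hz
        self.maf_half_width = maf_half_width
        self.routing = routing
        self.random_state = random_state
        self.classifier_hyperparams = classifier_hyperparams
        self.regressor_hyperparams = regressor_hyperparams

    # ------------------------------------------------------------- fitting

    def _resolve_weights(self) -> dict:
        if self.ensemble_weights is None:
            w = {a: 1.0 / len(ENSEMBLE_COMPONENTS) for a in ENSEMBLE_COMPONENTS}
        else:
            w = {a: float(v) for a, v in self.ensemble_weights.items()}
            if set(w) != set(ENSEMBLE_COMPONENTS):
                raise ValueError(f"ensemble_weights must cover exactly {ENSEMBLE_COMPONENTS}")
            if any(v < 0 for v in w.values()):
                raise ValueError("ensemble weights must be non-negative")
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("ensemble weights must sum to 1")
        return w

    def fit(self, X, y, positions=None):
        """Fit the classifier and the per-position regressor bank.

        Parameters
        ----------
        X : (n_windows, window_len) array
            Filtered magnitude windows.
        y : (n_windows,) array
            Per-window step-count labels.
        positions : (n_windows,) array of str
            Carrying-position label of each window (required).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if positions is None:
            raise ValueError("positions are required to fit the position classifier")
        positions = np.asarray(positions, dtype=object)
        if not (len(X) == len(y) == len(positions)):
            raise ValueError("X, y and positions must have equal lengths")
        uniq = [p for p in POSITIONS if p in set(positions)]
        extra = set(positions) - set(POSITIONS)
        if extra:
            raise ValueError(f"unknown positions in training data: {sorted(extra)}")
        if len(uniq) < 2:
            raise TrainingDataError(
                f"training data covers only {uniq}; at least two positions are needed "
                "to fit a position classifier"
            )

        algs = list(self.regressor_algorithms)
        for a in algs:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown regressor algorithm {a!r}")
        fit_algs = [a for a in algs if a != "ensemble"]
        if "ensemble" in algs:
            fit_algs += [a for a in ENSEMBLE_COMPONENTS if a not in fit_algs]

        self.ensemble_weights_ = self._resolve_weights()
        self.window_len_ = X.shape[1]

        clf_spec = ModelSpec(
            self.classifier_algorithm, "classifier",
            hyperparams=self.classifier_hyperparams or {}, seed=self.random_state,
        )
        self.classifier_ = make_estimator(clf_spec).fit(X, positions)
        self.classes_ = np.asarray(uniq, dtype=object)

        reg_hp = self.regressor_hyperparams or {}
        self.regressors_: dict[str, dict] = {}
        for pos in uniq:
            mask = positions == pos
            if not mask.any():
                raise TrainingDataError(f"no training windows for position {pos!r}")
            bank = {}
            for a in fit_algs:
                spec = ModelSpec(a, "regressor", hyperparams=reg_hp.get(a, {}), seed=self.random_state)
                bank[a] = make_estimator(spec).fit(X[mask], y[mask])
            self.regressors_[pos] = bank
        self.trained_algorithms_ = tuple(algs)
        return self

    def fit_dataset(self, dataset: WindowDataset) -> "EnsembleStepCounter":
        """Fit from a :class:`WindowDataset` (features, labels, positions)."""
        return self.fit(dataset.features, dataset.labels, positions=dataset.positions)

    def fit_ensemble_weights(self, X_val, y_val, positions_val) -> "EnsembleStepCounter":
        """Set ensemble weights proportional to validation step-count accuracy.

        For each component, the aggregate relative accuracy
        ``max(0, 1 - |sum(pred) - sum(label)| / sum(label))`` on the
        validation windows becomes its unnormalised weight.  Falls back
        to uniform weights if all components fail completely.
        """
        check_is_fitted(self, "regressors_")
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        positions_val = np.asarray(positions_val, dtype=object)
        scores = {}
        for a in ENSEMBLE_COMPONENTS:
            pred = self.predict(X_val, positions=positions_val, algorithm=a)
            nr = float(y_val.sum())
            scores[a] = max(0.0, 1.0 - abs(float(pred.sum()) - nr) / nr) if nr > 0 else 0.0
        total = sum(scores.values())
        if total <= 0:
            self.ensemble_weights_ = {a: 1.0 / len(ENSEMBLE_COMPONENTS) for a in ENSEMBLE_COMPONENTS}
        else:
            self.ensemble_weights_ = {a: s / total for a, s in scores.items()}
        return self

    # ---------------------------------------------------------- prediction

    def _check_features(self, X) -> np.ndarray:
        check_is_fitted(self, "regressors_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.window_len_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training window length {self.window_len_}"
            )
        return X

    def classify_position(self, X):
        """Predict the carrying position of one window or a batch."""
        X = self._check_features(X)
        return np.asarray(self.classifier_.predict(X), dtype=object)

    def _regress(self, X: np.ndarray, position: str, algorithm: str) -> np.ndarray:
        if position not in self.regressors_:
            raise KeyError(f"no regressors trained for position {position!r}")
        bank = self.regressors_[position]
        if algorithm == "ensemble":
            missing = [a for a in ENSEMBLE_COMPONENTS if a not in bank]
            if missing:
                raise KeyError(f"ensemble components not trained: {missing}")
            pred = np.zeros(len(X))
            for a, w in self.ensemble_weights_.items():
                pred += w * np.maximum(np.asarray(bank[a].predict(X), dtype=float), 0.0)
            return np.maximum(pred, 0.0)
        if algorithm not in bank:
            raise KeyError(f"algorithm {algorithm!r} not trained for position {position!r}")
        return np.maximum(np.asarray(bank[algorithm].predict(X), dtype=float), 0.0)

    def predict_window_steps(self, features, position: str, algorithm: str = "ensemble") -> float:
        """Step-count prediction for a single window, floored at 0."""
        X = self._check_features(features)
        return float(self._regress(X, position, algorithm)[0])

    def predict(self, X, positions=None, algorithm: str = "ensemble") -> np.ndarray:
        """Per-window step-count predictions.

        If ``positions`` is omitted the fitted classifier routes each
        window; otherwise the given labels route them (oracle routing).
        """
        X = self._check_features(X)
        if positions is None:
            positions = self.classify_position(X)
        positions = np.asarray(positions, dtype=object)
        pred = np.empty(len(X))
        for pos in np.unique(positions):
            mask = positions == pos
            pred[mask] = self._regress(X[mask], str(pos), algorithm)
        return pred

    def count_steps(self, accel: AccelTrace, algorithm: str = "ensemble"):
        """Whole-recording step count from raw tri-axial acceleration.

        Pipeline: magnitude -> moving average -> sliding windows ->
        position classification -> position-routed regression.  With 50 %
        overlap every interior step is covered by two windows, so the
        window-prediction sum is scaled by stride/window_len (=1/2); the
        recording's first and last ``window_len - stride`` samples are
        covered only once, so half their window's prediction is added
        back as an edge correction (for a single-window recording the
        total is then exactly that window's rounded prediction).

        Returns ``(total, position_votes)`` where ``position_votes`` is
        the classifier's per-window tally.
        """
        check_is_fitted(self, "regressors_")
        mag = preprocess_accel(accel, half_width=self.maf_half_width)
        feats, _, _ = slide_features(
            mag, window_s=self.window_s, overlap_frac=self.overlap_frac,
            sample_rate_hz=self.sample_rate_hz,
        )
        win_positions = self.classify_position(feats)
        votes = Counter(win_positions.tolist())
        if self.routing == "recording":
            # majority vote; deterministic tie-break by canonical position order
            best = max(votes.values())
            majority = next(p for p in POSITIONS if votes.get(p, 0) == best)
            routed = np.full(len(feats), majority, dtype=object)
        elif self.routing == "window":
            routed = win_positions
        else:
            raise ValueError(f"unknown routing mode {self.routing!r}")
        preds = self.predict(feats, positions=routed, algorithm=algorithm)
        window_len = int(round(self.window_s * self.sample_rate_hz))
        stride = int(round(window_len * (1.0 - self.overlap_frac)))
        core = preds.sum() * stride / window_len
        edge = (window_len - stride) / window_len * (preds[0] + preds[-1]) / 2.0
        total = int(round(core + edge))
        return total, dict(votes)


def train(train_set: WindowDataset, specs: Sequence[ModelSpec]) -> EnsembleStepCounter:
    """Functional wrapper: fit an :class:`EnsembleStepCounter` from specs.

    Exactly one classifier spec is required; each regressor spec adds its
    algorithm to the per-position bank.
    """
    specs = list(specs)
    clf_specs = [s for s in specs if s.role == "classifier"]
    reg_specs = [s for s in specs if s.role == "regressor"]
    if len(clf_specs) != 1:
        raise ValueError(f"need exactly one classifier spec, got {len(clf_specs)}")
    if not reg_specs:
        raise ValueError("need at least one regressor spec")
    model = EnsembleStepCounter(
        classifier_algorithm=clf_specs[0].algorithm,
        regressor_algorithms=tuple(s.algorithm for s in reg_specs),
        window_s=train_set.window_s,
        overlap_frac=train_set.overlap_frac,
        sample_rate_hz=train_set.sample_rate_hz,
        random_state=clf_specs[0].seed,
        classifier_hyperparams=clf_specs[0].hyperparams,
        regressor_hyperparams={s.algorithm: s.hyperparams for s in reg_specs},
    )
    return model.fit_dataset(train_set)
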