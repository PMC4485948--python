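"""Machine-learned move validation.

A proposed parent-to-child move between two cross sections is described
by a 66-value feature vector and classified into one of five classes:

    1  normal move between circular cross sections     -> valid
    2  normal move involving elongated cross sections  -> valid
    3  abnormal move (interstitial tissue / vessel)    -> invalid
    4  move involving a glomerulus cross section       -> terminate
    5  move in the inner medulla                       -> region signal

Two one-vs-all model families are provided: a feed-forward neural
network and an RBF-kernel SVM.  A voting (argmax) scheme over the five
per-class scores picks the winning class; for the neural network a
winning *valid* class must additionally clear a score threshold, which
sets the sensitivity of invalid-move rejection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import Node, N_PROFILE_ANGLES, ShapeFactors

__all__ = [
    "N_FEATURES",
    "CLASSES",
    "VALID_CLASSES",
    "MoveContext",
    "MoveDecision",
    "MoveClassifier",
    "extract_move_features",
    "train_classifiers",
    "classify_move",
    "capture_training_examples",
    "save_classifier",
    "load_classifier",
    "examples_to_dataframe",
]

N_FEATURES = 66
CLASSES = (1, 2, 3, 4, 5)
VALID_CLASSES = (1, 2)

# layout: 6 factor means | 6 factor differences | distance | relative z |
# image difference | dx | dy | 24 parent radii | 24 child radii | correlation
_SLICE_MEANS = slice(0, 6)
_SLICE_DIFFS = slice(6, 12)
IDX_DISTANCE = 12
IDX_REL_Z = 13
IDX_IMG_DIFF = 14
IDX_DX, IDX_DY = 15, 16
_SLICE_PROF_A = slice(17, 41)
_SLICE_PROF_B = slice(41, 65)
IDX_CORR = 65

FEATURE_LAYOUT = (
    tuple(f"mean_{n}" for n in ShapeFactors.NAMES)
    + tuple(f"diff_{n}" for n in ShapeFactors.NAMES)
    + ("distance", "relative_z", "image_difference", "offset_dx", "offset_dy")
    + tuple(f"parent_r{15 * i:03d}" for i in range(N_PROFILE_ANGLES))
    + tuple(f"child_r{15 * i:03d}" for i in range(N_PROFILE_ANGLES))
    + ("profile_correlation",)
)
assert len(FEATURE_LAYOUT) == N_FEATURES

LAYOUT_HASH = hashlib.sha256("|".join(FEATURE_LAYOUT).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class MoveContext:
    """Per-move context: depth, slices skipped and registration offset."""

    relative_z: float
    image_difference: int = 1
    offset: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class MoveDecision:
    """Outcome of classifying one move."""

    final: str  # valid | invalid | terminate | region_signal
    winning_class: int
    class_scores: np.ndarray = field(repr=False)


def _profile_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two shape profiles.

    Constant profiles (e.g. two circles) have zero variance; two constant
    profiles are deemed perfectly correlated, one constant against a
    varying one uncorrelated.
    """
    sa, sb = float(np.std(a)), float(np.std(b))
    if sa < 1e-12 or sb < 1e-12:
        return 1.0 if (sa < 1e-12 and sb < 1e-12) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def extract_move_features(parent: Node, child: Node, ctx: MoveContext) -> np.ndarray:
    """Build the 66-value move descriptor for a parent -> child move.

    Both nodes must carry shape factors (via their cross section) and a
    24-sample shape profile.  The xy distance uses the offset-corrected
    child position (child minus registration offset).
    """
    if parent.profile is None or child.profile is None:
        raise ValueError("both nodes must carry a shape profile")
    if parent.cross_section is None or child.cross_section is None:
        raise ValueError("both nodes must reference their cross section")
    fa = parent.cross_section.shape.as_array()
    fb = child.cross_section.shape.as_array()
    if not 1 <= ctx.image_difference <= 3:
        raise ValueError("image difference must be 1, 2 or 3")
    dx, dy = ctx.offset
    corrected = child.xy - [dx, dy]
    out = np.empty(N_FEATURES)
    out[_SLICE_MEANS] = (fa + fb) / 2.0
    out[_SLICE_DIFFS] = fa - fb
    out[IDX_DISTANCE] = np.linalg.norm(parent.xy - corrected)
    out[IDX_REL_Z] = ctx.relative_z
    out[IDX_IMG_DIFF] = ctx.image_difference
    out[IDX_DX] = dx
    out[IDX_DY] = dy
    out[_SLICE_PROF_A] = parent.profile
    out[_SLICE_PROF_B] = child.profile
    out[IDX_CORR] = _profile_correlation(parent.profile, child.profile)
    return out


class MoveClassifier:
    """One-vs-all multiclass move validator.

    Parameters
    ----------
    model : {"ann", "svm"}
        Feed-forward neural network (one hidden layer of ``hidden_units``)
        or support vector machine with an RBF kernel of width
        ``rbf_width`` (gamma = 1 / (2 * width^2)).
    threshold : float
        Minimum winning-class score for a *valid* verdict from the neural
        network; raising it rejects more moves.  Ignored by the SVM.
    """

    def __init__(
        self,
        model: str = "ann",
        threshold: float = 0.3,
        rbf_width: float = 5.0,
        hidden_units: int = 20,
        random_state: int = 0,
    ) -> None:
        if model not in ("ann", "svm"):
            raise ValueError("model must be 'ann' or 'svm'")
        self.model = model
        self.threshold = threshold
        self.rbf_width = rbf_width
        self.hidden_units = hidden_units
        self.random_state = random_state
        self.scaler_: StandardScaler | None = None
        self.learners_: dict[int, object] = {}
        self.layout_hash = LAYOUT_HASH

    def _new_learner(self):
        if self.model == "ann":
            return MLPClassifier(
                hidden_layer_sizes=(self.hidden_units,),
                activation="logistic",
                max_iter=800,
                random_state=self.random_state,
            )
        gamma = 1.0 / (2.0 * self.rbf_width**2)
        return SVC(kernel="rbf", gamma=gamma, C=10.0, random_state=self.random_state)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MoveClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        present = set(np.unique(y))
        missing = [c for c in CLASSES if c not in present]
        if missing:
            raise ValueError(f"class(es) {missing} absent from the training split")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.learners_ = {}
        for c in CLASSES:
            learner = self._new_learner()
            learner.fit(Xs, (y == c).astype(int))
            self.learners_[c] = learner
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 5) continuous one-vs-all scores, one column per class."""
        if self.scaler_ is None:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        Xs = self.scaler_.transform(X)
        cols = []
        for c in CLASSES:
            learner = self.learners_[c]
            if hasattr(learner, "predict_proba"):
                cols.append(learner.predict_proba(Xs)[:, 1])
            else:
                cols.append(learner.decision_function(Xs))
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Winning class per row (argmax vote over one-vs-all scores)."""
        return np.asarray(CLASSES)[np.argmax(self.scores(X), axis=1)]

    def decide(self, features: np.ndarray, threshold: float | None = None) -> MoveDecision:
        return classify_move(features, self, threshold)


def classify_move(
    features: np.ndarray, classifier: MoveClassifier, threshold: float | None = None
) -> MoveDecision:
    """Vote over the one-vs-all scores and derive the final verdict.

    Winning classes 1-2 give ``valid`` (for the neural network only when
    the winning score clears the threshold, else ``invalid``); class 3
    gives ``invalid``; class 4 ``terminate`` (glomerulus reached); class 5
    ``region_signal`` (inner medulla; a tracking-mode change, not a
    validity verdict).
    """
    scores = classifier.scores(features)[0]
    winner = int(np.asarray(CLASSES)[int(np.argmax(scores))])
    if winner in VALID_CLASSES:
        thr = classifier.threshold if threshold is None else threshold
        if classifier.model == "ann" and scores[winner - 1] < thr:
            final = "invalid"
        else:
            final = "valid"
    elif winner == 3:
        final = "invalid"
    elif winner == 4:
        final = "terminate"
    else:
        final = "region_signal"
    return MoveDecision(final=final, winning_class=winner, class_scores=scores)


def split_examples(
    X: np.ndarray,
    y: np.ndarray,
    split: tuple[float, float, float] = (0.7, 0.15, 0.15),
    random_state: int = 0,
) -> tuple:
    """Deterministic shuffled train/validation/test split by ratio."""
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split ratios must sum to 1")
    n = len(X)
    rng = np.random.default_rng(random_state)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    tr, va, te = order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]
    return (X[tr], y[tr]), (X[va], y[va]), (X[te], y[te])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t - 1, p - 1] += 1
    return cm


def _valid_invalid_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Condense 5-class predictions into valid/invalid performance.

    Class 5 is a region label, not a validity verdict, and is excluded
    here (reported separately in the confusion matrices).
    """
    keep = y_true != 5
    t = np.isin(y_true[keep], VALID_CLASSES)
    p = np.isin(y_pred[keep], VALID_CLASSES)
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    total = tp + tn + fp + fn
    return {
        "accuracy": 100.0 * (tp + tn) / total if total else float("nan"),
        "precision": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "sensitivity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def train_classifiers(
    examples: Sequence[tuple[np.ndarray, int]],
    split: tuple[float, float, float] = (0.7, 0.15, 0.15),
    model_params: dict | None = None,
    random_state: int = 0,
) -> tuple[MoveClassifier, MoveClassifier, dict]:
    """Train the neural-network and SVM move validators.

    Features are standardised with statistics of the training split only.
    Returns both fitted classifiers and a report with per-split 5-class
    confusion matrices, multiclass accuracy, and condensed valid/invalid
    accuracy/precision/sensitivity per model family.  ``sensitivity`` here
    is the invalid-move rejection rate (true-negative rate).
    """
    params = model_params or {}
    X = np.array([e[0] for e in examples], dtype=float)
    y = np.array([e[1] for e in examples], dtype=int)
    for c in CLASSES:
        if np.sum(y == c) < 2:
            raise ValueError(f"need at least 2 examples of class {c}")
    (Xtr, ytr), (Xva, yva), (Xte, yte) = split_examples(X, y, split, random_state)

    ann = MoveClassifier(model="ann", random_state=random_state, **params.get("ann", {}))
    svm = MoveClassifier(model="svm", random_state=random_state, **params.get("svm", {}))
    ann.fit(Xtr, ytr)
    svm.fit(Xtr, ytr)

    report: dict = {"split_sizes": {"train": len(Xtr), "validation": len(Xva), "test": len(Xte)}}
    for name, clf in (("ann", ann), ("svm", svm)):
        entry: dict = {}
        for split_name, (Xs, ys) in (
            ("train", (Xtr, ytr)),
            ("validation", (Xva, yva)),
            ("test", (Xte, yte)),
        ):
            if len(Xs) == 0:
                continue
            pred = clf.predict(Xs)
            entry[split_name] = {
                "confusion_5class": _confusion(ys, pred).tolist(),
                "accuracy_5class": 100.0 * float(np.mean(pred == ys)),
                **_valid_invalid_metrics(ys, pred),
            }
        report[name] = entry
    return ann, svm, report


# ---------------------------------------------------------------------------
# training-example capture


def capture_training_examples(
    stack,
    feats,
    seeds,
    labeller: Callable,
    config=None,
    capture_all: bool = False,
) -> list[tuple[np.ndarray, int]]:
    """Capture labelled move examples from unregulated tracker runs.

    Runs the tracker without ML validation over each seed and emits every
    attempted parent -> child move (with ``capture_all=True``, every
    in-radius candidate, so abnormal neighbours are seen too) as a feature vector
    plus the label assigned by ``labeller(parent, child, ctx)``; a labeller
    returning ``None`` drops the move.  Class balance is up to the caller
    (regenerate, don't duplicate).
    """
    from .tracker import track  # deferred: tracker depends on this module

    captured: list[tuple[np.ndarray, int]] = []
    seen: set[tuple] = set()

    def recorder(parent: Node, child: Node, ctx: MoveContext) -> None:
        key = (parent.node_id, child.node_id)
        if key in seen:
            return
        seen.add(key)
        label = labeller(parent, child, ctx)
        if label is not None:
            captured.append((extract_move_features(parent, child, ctx), int(label)))

    for seed in seeds:
        track(
            stack,
            feats,
            seed,
            config=config,
            classifier=None,
            move_recorder=recorder,
            capture_all=capture_all,
        )
    return captured


def class_counts(examples: Sequence[tuple[np.ndarray, int]]) -> dict[int, int]:
    counts = {c: 0 for c in CLASSES}
    for _, label in examples:
        counts[label] = counts.get(label, 0) + 1
    return counts


def examples_to_dataframe(examples: Sequence[tuple[np.ndarray, int]]) -> pd.DataFrame:
    """Training examples as a DataFrame (66 feature columns + label)."""
    X = np.array([e[0] for e in examples])
    df = pd.DataFrame(X, columns=list(FEATURE_LAYOUT))
    df["label"] = [e[1] for e in examples]
    return df


# ---------------------------------------------------------------------------
# persistence


def save_classifier(clf: MoveClassifier, path) -> None:
    """Persist a fitted classifier (versioned archive via joblib)."""
    joblib.dump(
        {
            "format_version": 1,
            "layout_hash": clf.layout_hash,
            "model": clf.model,
            "threshold": clf.threshold,
            "rbf_width": clf.rbf_width,
            "hidden_units": clf.hidden_units,
            "random_state": clf.random_state,
            "scaler": clf.scaler_,
            "learners": clf.learners_,
        },
        path,
    )


def load_classifier(path) -> MoveClassifier:
    blob = joblib.load(path)
    if blob.get("layout_hash") != LAYOUT_HASH:
        raise ValueError("model archive was trained on a different feature layout")
    clf = MoveClassifier(
        model=blob["model"],
        threshold=blob["threshold"],
        rbf_width=blob["rbf_width"],
        hidden_units=blob["hidden_units"],
        random_state=blob["random_state"],
    )
    clf.scaler_ = blob["scaler"]
    clf.learners_ = blob["learners"]
    return clf
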