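"""Diagnostic-group classification: evaluation, pairwise AUC, bootstrap,
and the leave-one-participant-out triangle characterisation.

The unit of classification is the 20-observation bucket; a participant is
characterised by the proportions of their buckets assigned to each of the
three diagnostic groups, a point in the 2-simplex ("the triangle").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .estimators import (
    MeanScoreFeaturizer,
    MoodGroupClassifier,
    RandomQuadraticFeaturizer,
    SignatureFeaturizer,
)
from .streams import GROUPS, Bucket, NormalisationSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TrianglePoint",
    "ClassifierReport",
    "signature_features",
    "mean_score_features",
    "random_quadratic_features",
    "train_group_classifier",
    "evaluate_classifier",
    "confusion_report",
    "pairwise_auc",
    "pairwise_table",
    "bootstrap_accuracy",
    "split_buckets",
    "loo_triangle",
    "triangle_all",
    "participant_accuracy",
]


# ---------------------------------------------------------------- features


def signature_features(
    bucket: Bucket, n: int = 2, spec: NormalisationSpec | None = None
) -> np.ndarray:
    """Order-n signature feature vector of one bucket (length sig_dim(7, n))."""
    spec = spec or NormalisationSpec()
    f = SignatureFeaturizer(
        order=n, centring=spec.centring, divisor=spec.divisor, time_mode=spec.time_mode
    ).fit([bucket])
    return f.transform([bucket])[0]


def mean_score_features(bucket: Bucket) -> np.ndarray:
    """Per-category mean raw score of one bucket (length 6)."""
    return MeanScoreFeaturizer().fit([bucket]).transform([bucket])[0]


def random_quadratic_features(bucket: Bucket, k: int = 57, seed: int = 0) -> np.ndarray:
    """k random quadratic monomials of the bucket's raw 7L-coordinate stream."""
    f = RandomQuadraticFeaturizer(k=k, random_state=seed).fit([bucket])
    return f.transform([bucket])[0]


# ------------------------------------------------------------- evaluation


@dataclass
class TrianglePoint:
    """Barycentric proportions of a participant's buckets per group."""

    participant_id: str
    p_healthy: float
    p_bipolar: float
    p_borderline: float
    n_buckets: int

    def __post_init__(self) -> None:
        props = (self.p_healthy, self.p_bipolar, self.p_borderline)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_healthy, self.p_bipolar, self.p_borderline)

    def to_xy(self) -> tuple[float, float]:
        """Planar projection: healthy at (0,0), bipolar at (1,0),
        borderline at (1/2, sqrt(3)/2)."""
        return (
            self.p_bipolar + 0.5 * self.p_borderline,
            (np.sqrt(3) / 2) * self.p_borderline,
        )


@dataclass
class ClassifierReport:
    """Overall accuracy plus one-vs-rest rates per class."""

    accuracy: float
    per_class: pd.DataFrame  # index: class; columns sensitivity/specificity/ppv
    confusion: pd.DataFrame  # rows: true class, columns: predicted class
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n": self.n,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


def confusion_report(y_true, y_pred) -> ClassifierReport:
    """Accuracy, sensitivity, specificity and PPV from labels alone."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    labels = [g for g in GROUPS if g in set(y_true) | set(y_pred)]
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    total = cm.sum()
    rows = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows[lab] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "ppv": tp / (tp + fp) if tp + fp else np.nan,
        }
    return ClassifierReport(
        accuracy=float(np.trace(cm) / total),
        per_class=pd.DataFrame.from_dict(rows, orient="index"),
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        n=int(total),
    )


def train_group_classifier(X, y, **settings) -> MoodGroupClassifier:
    """Fit the default random-forest group classifier (see MoodGroupClassifier)."""
    return MoodGroupClassifier(**settings).fit(X, y)


def evaluate_classifier(model, X, y) -> ClassifierReport:
    """Evaluate a fitted classifier on held-out buckets."""
    if len(X) == 0:
        raise ValueError("empty test set")
    return confusion_report(y, model.predict(X))


# ------------------------------------------------------------------ splits


def split_buckets(
    buckets: list[Bucket],
    mode: str = "bucket",
    test_size: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test index split, by bucket or by participant.

    ``"bucket"`` splits buckets independently (the original protocol, which
    risks within-participant leakage because one person's buckets can land
    on both sides); ``"participant"`` keeps each participant wholly on one
    side and is the recommended mode.
    """
    if mode not in ("bucket", "participant"):
        raise ValueError(f"unknown split mode {mode!r}")
    if not 0 < test_size < 1:
        raise ValueError("test_size must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(buckets)
    if mode == "bucket":
        perm = rng.permutation(n)
        n_test = max(1, int(round(test_size * n)))
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    pids = np.array([b.participant_id for b in buckets], dtype=object)
    unique = np.array(sorted(set(pids)), dtype=object)
    perm = rng.permutation(len(unique))
    n_test = max(1, int(round(test_size * len(unique))))
    test_pids = set(unique[perm[:n_test]])
    test_mask = np.array([p in test_pids for p in pids])
    return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


# ------------------------------------------------------- pairwise accuracy


def pairwise_auc(
    X_train, y_train, X_test, y_test, pair: tuple[str, str], **settings
) -> dict:
    """Binary accuracy and ROC AUC for one pair of diagnostic groups.

    Trains on the pair's training buckets only; AUC is computed from the
    probability of the second group of the pair (equivalently, the
    normalised Mann-Whitney U statistic of the two score samples).
    """
    a, b = pair
    if a == b or a not in GROUPS or b not in GROUPS:
        raise ValueError(f"invalid group pair {pair!r}")
    y_train = np.asarray(y_train, dtype=object)
    y_test = np.asarray(y_test, dtype=object)
    tr = np.isin(y_train, list(pair))
    te = np.isin(y_test, list(pair))
    if len(set(y_train[tr])) < 2 or len(set(y_test[te])) < 2:
        raise ValueError(f"both groups of {pair!r} must appear in train and test")
    model = MoodGroupClassifier(**settings).fit(
        [X_train[i] for i in np.flatnonzero(tr)], y_train[tr]
    )
    Xte = [X_test[i] for i in np.flatnonzero(te)]
    yte = y_test[te]
    pred = model.predict(Xte)
    score_b = model.predict_proba(Xte)[:, list(model.classes_).index(b)]
    return {
        "pair": pair,
        "accuracy": float(np.mean(pred == yte)),
        "auc": float(roc_auc_score((yte == b).astype(int), score_b)),
        "n_test": int(te.sum()),
    }


def pairwise_table(X_train, y_train, X_test, y_test, **settings) -> pd.DataFrame:
    """Accuracy/AUC matrix over the three unordered group pairs."""
    rows = []
    for i in range(len(GROUPS)):
        for j in range(i + 1, len(GROUPS)):
            res = pairwise_auc(
                X_train, y_train, X_test, y_test, (GROUPS[i], GROUPS[j]), **settings
            )
            rows.append(
                {
                    "group_a": GROUPS[i],
                    "group_b": GROUPS[j],
                    "accuracy": res["accuracy"],
                    "auc": res["auc"],
                    "n_test": res["n_test"],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- bootstrap


def bootstrap_accuracy(
    X_train, y_train, X_test, y_test, reps: int = 200, seed: int = 0, **settings
) -> tuple[float, float]:
    """Mean and standard deviation of test accuracy over bootstrap refits.

    Each rep resamples the training buckets with replacement, refits and
    evaluates on the untouched test set; gauges the stability of the
    reported accuracy.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    y_train = np.asarray(y_train, dtype=object)
    y_test = np.asarray(y_test, dtype=object)
    rng = np.random.default_rng(seed)
    accs = np.empty(reps)
    n = len(X_train)
    for r in range(reps):
        while True:  # redraw in the (rare) event of a single-class resample
            idx = rng.integers(0, n, size=n)
            if len(set(y_train[idx])) >= 2:
                break
        model = MoodGroupClassifier(**settings).fit(
            [X_train[i] for i in idx], y_train[idx]
        )
        accs[r] = np.mean(model.predict(X_test) == y_test)
    return float(accs.mean()), float(accs.std(ddof=1))


# ---------------------------------------------------------------- triangle


def _bucket_labels(buckets: list[Bucket]) -> np.ndarray:
    labels = np.array([b.group for b in buckets], dtype=object)
    if any(l is None for l in labels):
        raise ValueError("all buckets need a group label")
    return labels


def loo_triangle(
    buckets: list[Bucket],
    participant_id: str,
    min_buckets: int = 5,
    **settings,
) -> TrianglePoint | None:
    """Leave-one-participant-out barycentric point for one participant.

    The classifier is trained on every other participant's buckets and
    applied to the held-out participant's buckets; the proportions of
    buckets assigned to each group locate the participant in the triangle.
    Participants contributing fewer than ``min_buckets`` buckets are
    excluded (returns None) to avoid extreme proportions from tiny counts.
    """
    pids = np.array([b.participant_id for b in buckets], dtype=object)
    mask = pids == participant_id
    if not mask.any():
        raise ValueError(f"participant {participant_id!r} has no buckets")
    if mask.sum() < min_buckets:
        logger.info(
            "participant %s excluded: %d < %d buckets",
            participant_id,
            mask.sum(),
            min_buckets,
        )
        return None
    labels = _bucket_labels(buckets)
    model = MoodGroupClassifier(**settings).fit(
        [b for b, m in zip(buckets, mask) if not m], labels[~mask]
    )
    pred = model.predict([b for b, m in zip(buckets, mask) if m])
    counts = {g: int(np.sum(pred == g)) for g in GROUPS}
    total = int(mask.sum())
    return TrianglePoint(
        participant_id=participant_id,
        p_healthy=counts["healthy"] / total,
        p_bipolar=counts["bipolar"] / total,
        p_borderline=counts["borderline"] / total,
        n_buckets=total,
    )


def triangle_all(
    buckets: list[Bucket], min_buckets: int = 5, **settings
) -> pd.DataFrame:
    """Triangle coordinates for every participant (one LOO fit each).

    Returns one row per participant: the group label, bucket count,
    barycentric proportions, the planar (x, y) projection, and whether the
    participant was excluded by the minimum-bucket rule.
    """
    pids = sorted(set(b.participant_id for b in buckets))
    rows = []
    for pid in pids:
        point = loo_triangle(buckets, pid, min_buckets=min_buckets, **settings)
        group = next(b.group for b in buckets if b.participant_id == pid)
        n = sum(b.participant_id == pid for b in buckets)
        if point is None:
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "n_buckets": n,
                    "excluded": True,
                    "p_healthy": np.nan,
                    "p_bipolar": np.nan,
                    "p_borderline": np.nan,
                    "x": np.nan,
                    "y": np.nan,
                }
            )
        else:
            x, y = point.to_xy()
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "n_buckets": n,
                    "excluded": False,
                    "p_healthy": point.p_healthy,
                    "p_bipolar": point.p_bipolar,
                    "p_borderline": point.p_borderline,
                    "x": x,
                    "y": y,
                }
            )
    return pd.DataFrame(rows)


def participant_accuracy(triangle: pd.DataFrame) -> float:
    """Fraction of included participants whose modal bucket assignment
    matches their diagnosis (majority-vote aggregation of the triangle)."""
    inc = triangle[~triangle["excluded"]]
    if inc.empty:
        raise ValueError("no included participants")
    cols = {"healthy": "p_healthy", "bipolar": "p_bipolar", "borderline": "p_borderline"}
    modal = inc[[cols[g] for g in GROUPS]].to_numpy().argmax(axis=1)
    predicted = np.array(GROUPS, dtype=object)[modal]
    return float(np.mean(predicted == inc["group"].to_numpy()))
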