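"""Scikit-learn estimators: featurizers and the mood models.

The featurizers are transformers from lists of :class:`~moodsig.streams.Bucket`
(or pre-built paths / raw score windows) to flat feature matrices; the
classifier and regressor wrap a random forest behind them. All compose with
sklearn pipelines and model selection, expose ``get_params``/``set_params``
and keep fitted state in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .signature import path_signature, sig_dim, word_manifest
from .streams import (
    CATEGORIES,
    GROUPS,
    LIKERT_MAX,
    LIKERT_MIN,
    Bucket,
    NormalisationSpec,
    normalise_bucket,
)

__all__ = [
    "SignatureFeaturizer",
    "MeanScoreFeaturizer",
    "RandomQuadraticFeaturizer",
    "MoodGroupClassifier",
    "MoodRegressor",
]

PATH_DIM = 1 + len(CATEGORIES)  # time + six mood channels


def _bucket_scores(x) -> np.ndarray:
    """Raw (L, 6) integer scores from a Bucket or array-like window."""
    if isinstance(x, Bucket):
        return x.scores
    arr = np.asarray(x)
    if arr.ndim != 2 or arr.shape[1] != len(CATEGORIES):
        raise ValueError(f"expected a Bucket or (L, 6) array, got shape {arr.shape}")
    return arr


def _bucket_path(x, spec: NormalisationSpec) -> np.ndarray:
    """Normalised (L+1, 7) path from a Bucket, raw window or ready path."""
    if isinstance(x, Bucket):
        return normalise_bucket(x, spec)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == PATH_DIM:
        return arr  # already a seven-dimensional path
    if arr.ndim == 2 and arr.shape[1] == len(CATEGORIES):
        # raw score window without timestamps: index-time normalisation
        fake_ts = np.arange(len(arr)).astype("datetime64[D]")
        return normalise_bucket(Bucket("_", arr, fake_ts), spec)
    raise ValueError(f"cannot interpret shape {arr.shape} as a bucket or path")


class SignatureFeaturizer(TransformerMixin, BaseEstimator):
    """Truncated path-signature features of normalised mood buckets.

    Parameters
    ----------
    order : int, default 2
        Signature truncation order; 2 gives the 57-dimensional feature set
        (1 + 7 + 49 words over the seven-letter alphabet).
    centring, divisor, time_mode
        Forwarded to :class:`~moodsig.streams.NormalisationSpec`.
    """

    def __init__(
        self,
        order: int = 2,
        centring: str = "mean",
        divisor: float = 6.0,
        time_mode: str = "index",
    ):
        self.order = order
        self.centring = centring
        self.divisor = divisor
        self.time_mode = time_mode

    def _spec(self) -> NormalisationSpec:
        return NormalisationSpec(
            centring=self.centring, divisor=self.divisor, time_mode=self.time_mode
        )

    def fit(self, X, y=None):
        if self.order not in (1, 2, 3, 4):
            raise ValueError(f"order must be in 1..4, got {self.order}")
        self.n_features_out_ = sig_dim(PATH_DIM, self.order)
        self.words_ = word_manifest(PATH_DIM, self.order)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        spec = self._spec()
        out = np.empty((len(X), self.n_features_out_))
        for i, x in enumerate(X):
            out[i] = path_signature(_bucket_path(x, spec), self.order).coeffs
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "words_")
        return np.asarray(
            ["sig_" + (w if w else "e") for w in self.words_], dtype=object
        )


class MeanScoreFeaturizer(TransformerMixin, BaseEstimator):
    """Per-category mean raw score over the bucket (the level baseline).

    Captures *how much* of each mood was reported but none of the order
    information; the comparison baseline for the signature features.
    """

    def fit(self, X, y=None):
        self.n_features_out_ = len(CATEGORIES)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        return np.stack([_bucket_scores(x).mean(axis=0) for x in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"mean_{c}" for c in CATEGORIES], dtype=object)


class RandomQuadraticFeaturizer(TransformerMixin, BaseEstimator):
    """Random degree-<=2 monomials of the raw flattened stream.

    The raw stream of an L-observation bucket has 7L coordinates (normalised
    time plus the six raw score channels at each observation; 140 for
    L = 20). Capturing all second-order effects of those coordinates would
    need every degree-<=2 monomial — over 10,000 features — so this baseline
    draws ``k`` of them at random (uniform coordinate choices, random +/-
    sign, degree 1 or 2), reproducibly from ``random_state``. Default
    k = 57 matches the order-2 signature dimension.
    """

    def __init__(self, k: int = 57, random_state: int = 0):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        L = len(_bucket_scores(X[0]))
        self.n_raw_ = (1 + len(CATEGORIES)) * L
        self.window_length_ = L
        rng = np.random.default_rng(self.random_state)
        self.degrees_ = rng.integers(1, 3, size=self.k)
        self.idx1_ = rng.integers(0, self.n_raw_, size=self.k)
        self.idx2_ = rng.integers(0, self.n_raw_, size=self.k)
        self.signs_ = rng.choice([-1.0, 1.0], size=self.k)
        return self

    def _flatten(self, x) -> np.ndarray:
        scores = _bucket_scores(x).astype(float)
        L = len(scores)
        if L != self.window_length_:
            raise ValueError(
                f"bucket length {L} differs from fitted length {self.window_length_}"
            )
        time = np.arange(L) / (L - 1)
        return np.concatenate([time, scores.T.ravel()])

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "idx1_")
        raw = np.stack([self._flatten(x) for x in X])
        feats = raw[:, self.idx1_].copy()
        quad = self.degrees_ == 2
        feats[:, quad] *= raw[:, self.idx2_[quad]]
        return feats * self.signs_


_FEATURIZERS = {
    "signature": SignatureFeaturizer,
    "mean": MeanScoreFeaturizer,
    "quadratic": RandomQuadraticFeaturizer,
}


class MoodGroupClassifier(ClassifierMixin, BaseEstimator):
    """Diagnostic-group classifier: featurizer + random forest.

    Fits on a list of buckets and their group labels. ``features`` selects
    the representation: ``"signature"`` (truncated path signature, the
    method under study), ``"mean"`` (per-category means) or ``"quadratic"``
    (random quadratic monomials of the raw stream). Class-probability ties
    are broken in the fixed order healthy < bipolar < borderline.
    """

    def __init__(
        self,
        features: str = "signature",
        order: int = 2,
        centring: str = "mean",
        divisor: float = 6.0,
        time_mode: str = "index",
        k: int = 57,
        n_estimators: int = 500,
        random_state: int = 0,
    ):
        self.features = features
        self.order = order
        self.centring = centring
        self.divisor = divisor
        self.time_mode = time_mode
        self.k = k
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _make_featurizer(self):
        if self.features == "signature":
            return SignatureFeaturizer(
                order=self.order,
                centring=self.centring,
                divisor=self.divisor,
                time_mode=self.time_mode,
            )
        if self.features == "mean":
            return MeanScoreFeaturizer()
        if self.features == "quadratic":
            return RandomQuadraticFeaturizer(k=self.k, random_state=self.random_state)
        raise ValueError(f"unknown features {self.features!r}")

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        present = set(y)
        if len(present) < 2:
            raise ValueError("training set contains a single class")
        unknown = present - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        # canonical label order for deterministic argmax tie-breaks
        self.classes_ = np.array([g for g in GROUPS if g in present], dtype=object)
        self.featurizer_ = self._make_featurizer().fit(X)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(self.featurizer_.transform(X), y)
        self._proba_order_ = np.array(
            [list(self.forest_.classes_).index(g) for g in self.classes_]
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        proba = self.forest_.predict_proba(self.featurizer_.transform(X))
        return proba[:, self._proba_order_]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class MoodRegressor(RegressorMixin, BaseEstimator):
    """Next-observation mood regressor on signature features.

    Maps the signature of the preceding window to the six next scores.
    Midpoint centring is the default normalisation here — unlike per-bucket
    mean centring it retains the absolute score level, which the 1-7 target
    lives on. Predictions are real-valued, clipped to [1, 7]; with
    ``separate_outputs`` one forest is fitted per category instead of a
    single multi-output forest.
    """

    def __init__(
        self,
        order: int = 2,
        centring: str = "midpoint",
        divisor: float = 6.0,
        time_mode: str = "index",
        n_estimators: int = 200,
        separate_outputs: bool = False,
        random_state: int = 0,
    ):
        self.order = order
        self.centring = centring
        self.divisor = divisor
        self.time_mode = time_mode
        self.n_estimators = n_estimators
        self.separate_outputs = separate_outputs
        self.random_state = random_state

    def fit(self, X, Y):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != len(CATEGORIES):
            raise ValueError(f"Y must be (n, 6), got {Y.shape}")
        if len(X) != len(Y):
            raise ValueError("X and Y lengths differ")
        self.featurizer_ = SignatureFeaturizer(
            order=self.order,
            centring=self.centring,
            divisor=self.divisor,
            time_mode=self.time_mode,
        ).fit(X)
        feats = self.featurizer_.transform(X)

        def make_forest():
            return RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=self.random_state,
                n_jobs=1,
            )

        if self.separate_outputs:
            self.forests_ = [
                make_forest().fit(feats, Y[:, j]) for j in range(len(CATEGORIES))
            ]
        else:
            self.forests_ = [make_forest().fit(feats, Y)]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forests_")
        feats = self.featurizer_.transform(X)
        if len(self.forests_) == 1:
            pred = self.forests_[0].predict(feats)
        else:
            pred = np.column_stack([f.predict(feats) for f in self.forests_])
        return np.clip(pred, LIKERT_MIN, LIKERT_MAX)
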