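"""Next-observation mood prediction and multi-horizon decay curves.

Each prediction pair is a sliding window of L observations plus the scores
recorded ``horizon`` observations after the window's end. A random-forest
regressor on the window's signature features is trained per clinical group
and compared against the naive benchmark that repeats the last observed
score. A prediction is *correct* for a category when it lies within one
Likert point of the actual score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MoodRegressor
from .streams import CATEGORIES

__all__ = [
    "PredictionPair",
    "build_prediction_pairs",
    "train_mood_regressor",
    "is_correct",
    "evaluate_predictions",
    "naive_benchmark",
    "horizon_decay",
]


@dataclass
class PredictionPair:
    """One L-observation window and its target ``horizon`` steps ahead."""

    participant_id: str
    scores: np.ndarray  # (L, 6) raw Likert window
    target: np.ndarray  # (6,) raw scores at the horizon
    horizon: int
    group: str | None = None


def build_prediction_pairs(
    reports: pd.DataFrame, L: int = 20, horizon: int = 1
) -> list[PredictionPair]:
    """Sliding windows (stride 1) with an existing observation at the horizon.

    Horizons count observations ahead, not calendar days, consistent with
    the gap-tolerant bucketing. Records shorter than L + horizon yield no
    pairs.
    """
    if L < 2:
        raise ValueError("window length L must be >= 2")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    has_group = "group" in reports.columns
    pairs: list[PredictionPair] = []
    for pid, sub in reports.groupby("participant_id", sort=True):
        scores = sub[list(CATEGORIES)].to_numpy()
        group = str(sub["group"].iloc[0]) if has_group else None
        for start in range(0, len(scores) - L - horizon + 1):
            pairs.append(
                PredictionPair(
                    participant_id=str(pid),
                    scores=scores[start : start + L],
                    target=scores[start + L + horizon - 1],
                    horizon=horizon,
                    group=group,
                )
            )
    return pairs


def train_mood_regressor(pairs: list[PredictionPair], n: int = 2, **settings) -> MoodRegressor:
    """Fit the signature regressor on pairs from a single clinical group."""
    if not pairs:
        raise ValueError("no training pairs")
    groups = {p.group for p in pairs}
    if len(groups) > 1:
        raise ValueError(f"training pairs span multiple groups: {sorted(groups)}")
    X = [p.scores for p in pairs]
    Y = np.stack([p.target for p in pairs])
    return MoodRegressor(order=n, **settings).fit(X, Y)


def is_correct(predicted: float, actual: int, tol: float = 1.0, rounding: bool = False) -> bool:
    """Correctness rule |predicted - actual| <= tol (default tol 1).

    Predictions are real-valued forest averages; by default the raw
    difference is compared, with ``rounding`` available to snap the
    prediction to the nearest integer score first.
    """
    if not 1 <= actual <= 7:
        raise ValueError("actual score must be in 1..7")
    p = float(np.round(predicted)) if rounding else float(predicted)
    return abs(p - actual) <= tol


def _report(
    pred: np.ndarray, actual: np.ndarray, group, horizon: int, tol: float, rounding: bool
) -> pd.DataFrame:
    if rounding:
        pred = np.round(pred)
    err = np.abs(pred - actual)
    rows = []
    for j, cat in enumerate(CATEGORIES):
        rows.append(
            {
                "group": group,
                "category": cat,
                "horizon": horizon,
                "mae": float(err[:, j].mean()),
                "percent_correct": float(100.0 * np.mean(err[:, j] <= tol)),
                "n": len(err),
            }
        )
    return pd.DataFrame(rows)


def evaluate_predictions(
    model, pairs: list[PredictionPair], tol: float = 1.0, rounding: bool = False
) -> pd.DataFrame:
    """Per-category MAE and percent-correct of a fitted regressor.

    Tidy output: one row per category with columns group, category,
    horizon, mae, percent_correct, n.
    """
    if not pairs:
        raise ValueError("no evaluation pairs")
    pred = model.predict([p.scores for p in pairs])
    actual = np.stack([p.target for p in pairs]).astype(float)
    return _report(
        pred, actual, pairs[0].group, pairs[0].horizon, tol, rounding
    )


def naive_benchmark(
    pairs: list[PredictionPair], tol: float = 1.0
) -> pd.DataFrame:
    """Last-value benchmark: predict that the next score equals the last
    observed score of the window; evaluated identically to the model."""
    if not pairs:
        raise ValueError("no evaluation pairs")
    pred = np.stack([p.scores[-1] for p in pairs]).astype(float)
    actual = np.stack([p.target for p in pairs]).astype(float)
    return _report(pred, actual, pairs[0].group, pairs[0].horizon, tol, False)


def _split_participants(pids: list[str], test_size: float, seed: int) -> set[str]:
    rng = np.random.default_rng(seed)
    unique = sorted(set(pids))
    perm = rng.permutation(len(unique))
    n_test = max(1, int(round(test_size * len(unique))))
    return {unique[i] for i in perm[:n_test]}


def horizon_decay(
    reports: pd.DataFrame,
    L: int = 20,
    horizons=range(1, 6),
    test_size: float = 0.3,
    seed: int = 0,
    tol: float = 1.0,
    include_naive: bool = True,
    **settings,
) -> pd.DataFrame:
    """Accuracy and MAE curves per group over increasing horizons.

    Participants are split once into train/test (common split across all
    horizons, no within-person leakage); at each horizon the per-group
    regressor is refitted and evaluated. Rows carry a ``model`` column
    ("signature" or "naive") for direct comparison.
    """
    if "group" not in reports.columns:
        raise ValueError("reports need a group column")
    test_pids = _split_participants(list(reports["participant_id"].astype(str)), test_size, seed)
    frames = []
    for group, sub in reports.groupby("group", sort=True):
        tr = sub[~sub["participant_id"].astype(str).isin(test_pids)]
        te = sub[sub["participant_id"].astype(str).isin(test_pids)]
        for h in horizons:
            train_pairs = build_prediction_pairs(tr, L=L, horizon=h)
            test_pairs = build_prediction_pairs(te, L=L, horizon=h)
            if not train_pairs or not test_pairs:
                continue
            model = train_mood_regressor(train_pairs, **settings)
            rep = evaluate_predictions(model, test_pairs, tol=tol)
            rep["model"] = "signature"
            frames.append(rep)
            if include_naive:
                nb = naive_benchmark(test_pairs, tol=tol)
                nb["model"] = "naive"
                frames.append(nb)
    if not frames:
        raise ValueError("no prediction pairs could be built at any horizon")
    return pd.concat(frames, ignore_index=True)
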