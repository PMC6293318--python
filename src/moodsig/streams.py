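"""Turn raw mood-report tables into buckets and normalised 7-d paths.

A *report* is one timestamped observation of six mood categories (anxiety,
elation, sadness, anger, irritability, energy), each rated 1-7 on a Likert
scale. Reports are grouped per participant into *buckets* of exactly
``L`` consecutive observations (default 20) — consecutive by observation
order, so calendar gaps and several-reports-per-day are both tolerated.

Each bucket becomes a seven-dimensional piecewise-linear path on the unit
interval: coordinate 1 is normalised time, coordinates 2..7 are the
cumulative sums of the centred, rescaled category scores, prepended with an
origin point so the path starts at 0. High scores become upward trends,
low scores downward trends, and oscillating scores oscillating paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "GROUPS",
    "LIKERT_MIN",
    "LIKERT_MAX",
    "LIKERT_MIDPOINT",
    "Bucket",
    "NormalisationSpec",
    "read_reports",
    "bucketize",
    "normalise_bucket",
    "pairwise_panel",
]

#: the six mood categories, in fixed column order
CATEGORIES = ("anxiety", "elation", "sadness", "anger", "irritability", "energy")

#: canonical diagnostic-group order (also the deterministic tie-break order)
GROUPS = ("healthy", "bipolar", "borderline")

LIKERT_MIN = 1
LIKERT_MAX = 7
LIKERT_MIDPOINT = 4.0
#: width of the Likert range, the default score divisor
LIKERT_RANGE = float(LIKERT_MAX - LIKERT_MIN)

REQUIRED_COLUMNS = ("participant_id", "timestamp") + CATEGORIES


@dataclass
class Bucket:
    """Exactly L consecutive reports from one participant."""

    participant_id: str
    scores: np.ndarray  # (L, 6) integer Likert scores, CATEGORIES order
    timestamps: np.ndarray  # (L,) datetime64, non-decreasing
    group: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(CATEGORIES):
            raise ValueError(f"scores must be (L, 6), got {self.scores.shape}")
        if self.scores.shape[0] < 2:
            raise ValueError("a bucket needs at least 2 reports")
        if self.scores.min() < LIKERT_MIN or self.scores.max() > LIKERT_MAX:
            raise ValueError("scores must lie in 1..7")
        self.timestamps = np.asarray(self.timestamps)
        if len(self.timestamps) != len(self.scores):
            raise ValueError("timestamps and scores lengths differ")
        if np.any(np.diff(self.timestamps) < np.timedelta64(0, "s")):
            raise ValueError("timestamps must be non-decreasing")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class NormalisationSpec:
    """How a bucket's scores become a path.

    centring
        ``"mean"`` subtracts each channel's per-bucket mean (the default —
        translation-invariant per bucket, so the representation does not
        depend on a participant's idiosyncratic baseline), ``"midpoint"``
        subtracts the fixed scale midpoint 4 (retains absolute level, which
        next-observation prediction needs).
    divisor
        positive scale divisor for the centred scores; default 6.0, the
        width of the 1-7 Likert range, keeping centred increments in [-1, 1].
    time_mode
        ``"index"`` spaces observations evenly on [0, 1] (gap-robust, the
        default); ``"timestamp"`` maps actual report times affinely onto
        (0, 1], with the prepended origin one median inter-report gap before
        the first observation.
    """

    centring: str = "mean"
    divisor: float = LIKERT_RANGE
    time_mode: str = "index"

    def __post_init__(self) -> None:
        if self.centring not in ("mean", "midpoint"):
            raise ValueError(f"unknown centring {self.centring!r}")
        if not self.divisor > 0:
            raise ValueError("divisor must be positive")
        if self.time_mode not in ("index", "timestamp"):
            raise ValueError(f"unknown time_mode {self.time_mode!r}")


def read_reports(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load and validate a long-format mood-report table.

    Expects columns ``participant_id, timestamp`` (ISO-8601), the six
    category scores, and optionally ``group``. Unknown columns are ignored;
    rows with any missing score are dropped with a logged count; scores
    outside 1..7 raise. Returns a frame sorted stably by participant and
    timestamp.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    keep = list(REQUIRED_COLUMNS) + (["group"] if "group" in df.columns else [])
    df = df[keep]
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    n0 = len(df)
    df = df.dropna(subset=list(CATEGORIES) + ["timestamp", "participant_id"])
    if len(df) < n0:
        logger.info("dropped %d rows with missing values", n0 - len(df))
    scores = df[list(CATEGORIES)].to_numpy()
    if scores.size and (scores.min() < LIKERT_MIN or scores.max() > LIKERT_MAX):
        raise ValueError("scores outside the 1..7 Likert range")
    df[list(CATEGORIES)] = scores.astype(int)
    df = df.sort_values(["participant_id", "timestamp"], kind="mergesort")
    return df.reset_index(drop=True)


def bucketize(
    reports: pd.DataFrame, L: int = 20, offset: int | None = None
) -> list[Bucket]:
    """Cut each participant's report sequence into windows of L observations.

    Consecutiveness is by observation order, not calendar day, so streams
    survive missed days and same-day repeats. Windows start every ``offset``
    observations (default ``L``: non-overlapping); trailing partial windows
    are discarded. Participants with fewer than L reports yield no buckets.
    """
    if L < 2:
        raise ValueError("bucket length L must be >= 2")
    offset = L if offset is None else int(offset)
    if offset < 1:
        raise ValueError("offset must be >= 1")
    has_group = "group" in reports.columns
    buckets: list[Bucket] = []
    for pid, sub in reports.groupby("participant_id", sort=True):
        scores = sub[list(CATEGORIES)].to_numpy()
        ts = sub["timestamp"].to_numpy()
        group = sub["group"].iloc[0] if has_group else None
        for start in range(0, len(sub) - L + 1, offset):
            buckets.append(
                Bucket(
                    participant_id=str(pid),
                    scores=scores[start : start + L],
                    timestamps=ts[start : start + L],
                    group=None if group is None or pd.isna(group) else str(group),
                )
            )
    logger.info("formed %d buckets of length %d", len(buckets), L)
    return buckets


def _time_coordinate(bucket: Bucket, spec: NormalisationSpec) -> np.ndarray:
    L = len(bucket)
    if spec.time_mode == "index":
        return np.arange(L + 1) / L
    # timestamp mode: seconds since first report, strictly increasing
    t = (bucket.timestamps - bucket.timestamps[0]) / np.timedelta64(1, "s")
    t = t.astype(float)
    # break exact ties (same-second repeats) by a cumulative 1s bump
    for i in range(1, L):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1.0
    gaps = np.diff(t)
    origin_gap = float(np.median(gaps)) if len(gaps) else 1.0
    t = np.concatenate(([-origin_gap], t))
    t -= t[0]
    return t / t[-1]


def normalise_bucket(
    bucket: Bucket, spec: NormalisationSpec | None = None
) -> np.ndarray:
    """Normalise one bucket into its (L+1, 7) piecewise-linear path.

    Per channel: centre, divide by the score divisor, cumulatively sum, and
    prepend a zero so the path starts at the origin. Column 0 is normalised
    time spanning exactly [0, 1]; columns 1..6 are the aggregated channels
    in CATEGORIES order. Constant channels centred by the mean become
    identically zero — a valid path.
    """
    spec = spec or NormalisationSpec()
    scores = bucket.scores.astype(float)
    if spec.centring == "mean":
        centred = scores - scores.mean(axis=0, keepdims=True)
    else:
        centred = scores - LIKERT_MIDPOINT
    agg = np.cumsum(centred / spec.divisor, axis=0)
    L = len(bucket)
    path = np.zeros((L + 1, 1 + len(CATEGORIES)))
    path[:, 0] = _time_coordinate(bucket, spec)
    path[1:, 1:] = agg
    return path


def pairwise_panel(path: np.ndarray) -> pd.DataFrame:
    """Tidy table of the 15 unordered channel-pair trajectories of a path.

    Each row is one point of one pair trajectory; columns ``channel_x``,
    ``channel_y`` name the categories, ``step`` indexes the path point, and
    ``x``, ``y`` are the aggregated normalised scores. Intended for export
    and plotting (identical channels trace the diagonal).
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 1 + len(CATEGORIES):
        raise ValueError(f"expected an (m, 7) path, got {path.shape}")
    frames = []
    m = len(path)
    for i in range(len(CATEGORIES)):
        for j in range(i + 1, len(CATEGORIES)):
            frames.append(
                pd.DataFrame(
                    {
                        "channel_x": CATEGORIES[i],
                        "channel_y": CATEGORIES[j],
                        "step": np.arange(m),
                        "x": path[:, 1 + i],
                        "y": path[:, 1 + j],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
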