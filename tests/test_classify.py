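"""Classification evaluation: confusion-matrix rates, AUC/Mann-Whitney
equivalence, splits, bootstrap and the leave-one-participant-out triangle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from helpers import make_bucket

import moodsig as ms
from moodsig.classify import TrianglePoint, confusion_report


def separable_buckets(n_per_group=8, L=20, seed=0):
    """Three groups with constant, well-separated score levels — trivially
    classifiable from mean-score features (levels are invisible to the
    mean-centred signature by design), for exercising evaluation plumbing."""
    rng = np.random.default_rng(seed)
    buckets = []
    levels = {"healthy": 2, "bipolar": 4, "borderline": 6}
    for g, level in levels.items():
        for i in range(n_per_group):
            scores = np.clip(
                level + rng.integers(-1, 2, size=(L, 6)), 1, 7
            )
            buckets.append(make_bucket(scores, pid=f"{g}{i}", group=g))
    return buckets


def test_confusion_report_hand_fixture():
    """Rates from a printed 3x3 confusion table match hand arithmetic."""
    y_true = (["healthy"] * 10) + (["bipolar"] * 10) + (["borderline"] * 10)
    y_pred = (
        ["healthy"] * 8 + ["bipolar"] * 2
        + ["bipolar"] * 7 + ["borderline"] * 3
        + ["borderline"] * 9 + ["healthy"] * 1
    )
    rep = confusion_report(y_true, y_pred)
    assert rep.accuracy == pytest.approx(24 / 30)
    assert rep.per_class.loc["healthy", "sensitivity"] == pytest.approx(0.8)
    assert rep.per_class.loc["healthy", "specificity"] == pytest.approx(19 / 20)
    assert rep.per_class.loc["healthy", "ppv"] == pytest.approx(8 / 9)
    assert rep.per_class.loc["bipolar", "ppv"] == pytest.approx(7 / 9)
    assert rep.confusion.loc["bipolar", "borderline"] == 3


def test_perfect_and_majority_class_accuracy():
    y = ["healthy", "bipolar", "borderline"] * 4
    assert confusion_report(y, y).accuracy == 1.0
    assert confusion_report(y, ["healthy"] * 12).accuracy == pytest.approx(1 / 3)


def test_auc_equals_normalised_mann_whitney():
    """The trapezoidal ROC area of the model's scores equals U/(n1*n2)."""
    buckets = separable_buckets(n_per_group=10, seed=3)
    y = np.array([b.group for b in buckets], dtype=object)
    res = ms.pairwise_auc(
        buckets, y, buckets, y, ("healthy", "bipolar"), features="mean",
        n_estimators=30, random_state=0,
    )
    model = ms.MoodGroupClassifier(features="mean", n_estimators=30, random_state=0).fit(
        [b for b in buckets if b.group in ("healthy", "bipolar")],
        [b.group for b in buckets if b.group in ("healthy", "bipolar")],
    )
    sub = [b for b in buckets if b.group in ("healthy", "bipolar")]
    labels = np.array([b.group for b in sub], dtype=object)
    scores = model.predict_proba(sub)[:, list(model.classes_).index("bipolar")]
    u = stats.mannwhitneyu(scores[labels == "bipolar"], scores[labels == "healthy"]).statistic
    n1 = (labels == "bipolar").sum()
    n0 = (labels == "healthy").sum()
    assert roc_auc_score((labels == "bipolar").astype(int), scores) == pytest.approx(
        u / (n1 * n0), abs=1e-12
    )
    assert res["auc"] == pytest.approx(1.0)  # separable pair


def test_shuffled_labels_give_chance_auc():
    """With labels shuffled uniformly at random, held-out AUC sits at 0.5
    within Monte-Carlo error."""
    rng = np.random.default_rng(0)
    buckets = separable_buckets(n_per_group=60, seed=1)
    y = np.array([b.group for b in buckets], dtype=object)
    y_shuffled = y.copy()
    rng.shuffle(y_shuffled)
    half = len(buckets) // 2
    res = ms.pairwise_auc(
        buckets[:half], y_shuffled[:half], buckets[half:], y_shuffled[half:],
        ("healthy", "borderline"), features="mean", n_estimators=50,
        random_state=0,
    )
    assert res["auc"] == pytest.approx(0.5, abs=0.15)


def test_split_modes_disjoint_and_covering(tiny_buckets):
    for mode in ("bucket", "participant"):
        tr, te = ms.split_buckets(tiny_buckets, mode=mode, seed=4)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == len(tiny_buckets)
    tr, te = ms.split_buckets(tiny_buckets, mode="participant", seed=4)
    tr_pids = {tiny_buckets[i].participant_id for i in tr}
    te_pids = {tiny_buckets[i].participant_id for i in te}
    assert not tr_pids & te_pids


def test_bootstrap_on_separable_data_is_degenerate():
    buckets = separable_buckets(n_per_group=6)
    y = np.array([b.group for b in buckets], dtype=object)
    mean, sd = ms.bootstrap_accuracy(
        buckets, y, buckets, y, reps=5, seed=0, features="mean", n_estimators=20
    )
    assert mean == 1.0 and sd == 0.0
    again = ms.bootstrap_accuracy(
        buckets, y, buckets, y, reps=5, seed=0, features="mean", n_estimators=20
    )
    assert (mean, sd) == again


def test_triangle_point_validation_and_projection():
    p = TrianglePoint("p", 0.625, 0.25, 0.125, 8)
    assert sum(p.as_tuple()) == pytest.approx(1.0, abs=1e-12)
    x, y = p.to_xy()
    assert x == pytest.approx(0.25 + 0.0625)
    assert y == pytest.approx(0.125 * np.sqrt(3) / 2)
    with pytest.raises(ValueError):
        TrianglePoint("p", 0.7, 0.2, 0.2, 5)


def test_loo_triangle_exclusion_and_proportions():
    buckets = separable_buckets(n_per_group=4, seed=2)
    # give one participant many buckets, another too few
    rich = [b for b in buckets if b.participant_id != "healthy0"]
    rich += [
        make_bucket(np.full((20, 6), 2), pid="healthy9", group="healthy")
        for _ in range(6)
    ]
    point = ms.loo_triangle(rich, "healthy9", min_buckets=5, features="mean",
                            n_estimators=20)
    assert point.n_buckets == 6
    assert sum(point.as_tuple()) == pytest.approx(1.0, abs=1e-12)
    assert point.p_healthy == 1.0  # separable: all buckets go to its group
    assert ms.loo_triangle(
        rich, "bipolar0", min_buckets=5, features="mean", n_estimators=20
    ) is None
    with pytest.raises(ValueError):
        ms.loo_triangle(rich, "nobody", features="mean", n_estimators=20)


def test_triangle_all_and_participant_accuracy():
    buckets = []
    for g in ("healthy", "bipolar", "borderline"):
        for i in range(2):
            buckets += [
                make_bucket(
                    np.full((20, 6), {"healthy": 2, "bipolar": 4, "borderline": 6}[g]),
                    pid=f"{g}{i}",
                    group=g,
                )
                for _ in range(5)
            ]
    tri = ms.triangle_all(buckets, min_buckets=5, features="mean", n_estimators=20)
    assert len(tri) == 6
    assert not tri["excluded"].any()
    included = tri[~tri.excluded]
    np.testing.assert_allclose(
        included[["p_healthy", "p_bipolar", "p_borderline"]].sum(axis=1), 1.0
    )
    assert ms.participant_accuracy(tri) == 1.0


def test_participant_split_limits_leakage():
    """With stable participant traits, a by-bucket split (same person on
    both sides) scores at least as high as an honest by-participant split."""
    spec = ms.CohortSpec(
        groups=ms.default_cohort_spec().groups,
        n_per_group=(12, 12, 12),
        days_per_group=(150, 150, 150),
        seed=5,
    )
    buckets = ms.bucketize(ms.read_reports(ms.generate_cohort(spec)))
    y = np.array([b.group for b in buckets], dtype=object)
    accs = {}
    for mode in ("bucket", "participant"):
        tr, te = ms.split_buckets(buckets, mode=mode, seed=2)
        model = ms.MoodGroupClassifier(n_estimators=150, random_state=2).fit(
            [buckets[i] for i in tr], y[tr]
        )
        accs[mode] = np.mean(model.predict([buckets[i] for i in te]) == y[te])
    assert accs["participant"] <= accs["bucket"]
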