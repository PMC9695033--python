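import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbscreen import nbayes, synthdata
from nbscreen.evalmetrics import (
    ConfusionMatrix,
    confusion,
    crossval,
    metrics_from_confusion,
    roc_auc,
)


def test_confusion_all_correct_and_all_inverted():
    labels = ["active"] * 10 + ["inactive"] * 10
    cm = confusion(labels, labels)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 10)
    inverted = ["inactive" if l == "active" else "active" for l in labels]
    cm2 = confusion(inverted, labels)
    assert (cm2.tp, cm2.fn, cm2.fp, cm2.tn) == (0, 10, 10, 0)


def test_confusion_hand_tally():
    labels = ["active", "active", "active", "inactive", "inactive", "inactive"]
    calls = ["active", "inactive", "active", "active", "inactive", "inactive"]
    cm = confusion(calls, labels)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)
    assert cm.total == 6


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion(["active"], ["active", "inactive"])


def test_perfect_classifier_metrics():
    rep = metrics_from_confusion(ConfusionMatrix(tp=7, fn=0, fp=0, tn=13))
    assert rep.active.precision == rep.active.recall == rep.active.f_measure == 1.0
    assert rep.inactive.precision == rep.inactive.recall == 1.0
    assert rep.specificity == 1.0 and rep.mcc == 1.0


def test_undefined_metrics_reported_as_nan():
    rep = metrics_from_confusion(ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
    assert math.isnan(rep.active.precision)
    assert rep.inactive.recall == 1.0


def _oracle_metrics(tp, fn, fp, tn):
    """First-principles recomputation in exact rational arithmetic."""
    out = {}
    out["recall"] = Fraction(tp, tp + fn) if tp + fn else None
    out["precision"] = Fraction(tp, tp + fp) if tp + fp else None
    out["specificity"] = Fraction(tn, fp + tn) if fp + tn else None
    p, r = out["precision"], out["recall"]
    out["f"] = 2 * p * r / (p + r) if p is not None and r is not None and p + r else None
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc_num"] = tp * tn - fp * fn
    out["mcc_den2"] = den
    return out


def test_metrics_match_exact_oracle_on_random_matrices():
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(1000):
        tp, fn, fp, tn = (int(x) for x in rng.integers(0, 40, size=4))
        if tp + fn + fp + tn == 0:
            continue
        cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
        rep = metrics_from_confusion(cm)
        o = _oracle_metrics(tp, fn, fp, tn)
        if o["recall"] is not None:
            assert rep.active.recall == pytest.approx(float(o["recall"]), rel=1e-12)
        if o["precision"] is not None:
            assert rep.active.precision == pytest.approx(float(o["precision"]), rel=1e-12)
        if o["specificity"] is not None:
            assert rep.specificity == pytest.approx(float(o["specificity"]), rel=1e-12)
        if o["f"] is not None:
            assert rep.active.f_measure == pytest.approx(float(o["f"]), rel=1e-12)
        if o["mcc_den2"] > 0:
            assert rep.mcc == pytest.approx(o["mcc_num"] / math.sqrt(o["mcc_den2"]), rel=1e-12)
        checked += 1
    assert checked > 900


@settings(deadline=None, max_examples=150)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_mcc_invariant_under_class_swap(tp, fn, fp, tn):
    if tp + fn + fp + tn == 0:
        return
    a = metrics_from_confusion(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)).mcc
    b = metrics_from_confusion(ConfusionMatrix(tp=tn, fn=fp, fp=fn, tn=tp)).mcc
    assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, rel=1e-12, abs=1e-12)


@settings(deadline=None, max_examples=150)
@given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50))
def test_weighted_f_between_class_f_values(tp, fn, fp, tn):
    rep = metrics_from_confusion(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
    fs = [rep.active.f_measure, rep.inactive.f_measure]
    if any(math.isnan(x) for x in fs):
        return
    assert min(fs) - 1e-12 <= rep.weighted.f_measure <= max(fs) + 1e-12


def test_f_measure_alpha_parameter():
    cm = ConfusionMatrix(tp=8, fn=2, fp=4, tn=6)
    rep2 = metrics_from_confusion(cm, alpha=2.0)
    p, r = 8 / 12, 8 / 10
    assert rep2.active.f_measure == pytest.approx(5 * p * r / (4 * p + r))


def test_auc_perfect_and_tied():
    auc, _ = roc_auc([5.0, 4.0, 1.0, 0.0], ["active", "active", "inactive", "inactive"])
    assert auc == 1.0
    auc_t, _ = roc_auc([1.0, 1.0, 1.0, 1.0], ["active", "inactive", "active", "inactive"])
    assert auc_t == 0.5


def test_auc_hand_derived_half():
    # pairs: (3,2) concordant, (1,2) discordant -> 1/2
    auc, _ = roc_auc([3.0, 2.0, 1.0], ["active", "inactive", "active"])
    assert auc == pytest.approx(0.5)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], ["active", "active"])


def _mann_whitney_auc(scores, labels):
    """Independent oracle: normalized U with half credit for ties."""
    act = [s for s, l in zip(scores, labels) if l == "active"]
    inact = [s for s, l in zip(scores, labels) if l == "inactive"]
    u = 0.0
    for a in act:
        for b in inact:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u / (len(act) * len(inact))


@settings(deadline=None, max_examples=100)
@given(st.lists(st.integers(0, 8), min_size=2, max_size=30), st.data())
def test_auc_equals_normalized_mann_whitney(scores, data):
    labels = data.draw(
        st.lists(st.sampled_from(["active", "inactive"]), min_size=len(scores), max_size=len(scores))
    )
    if "active" not in labels or "inactive" not in labels:
        return
    scores = [float(s) for s in scores]
    auc, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(_mann_whitney_auc(scores, labels), rel=1e-12, abs=1e-12)


def test_roc_curve_endpoints_and_monotone():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=50).tolist()
    labels = ["active" if rng.random() < 0.5 else "inactive" for _ in range(50)]
    if "active" not in labels:
        labels[0] = "active"
    if "inactive" not in labels:
        labels[1] = "inactive"
    _, points = roc_auc(scores, labels)
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    assert xs == sorted(xs) and ys == sorted(ys)


@pytest.fixture(scope="module")
def small_library():
    spec = synthdata.LibrarySpec(n_active=40, n_inactive=80, seed=11)
    lib = synthdata.generate_library(spec)
    feats = nbayes.featurize(lib, diameter=6)
    return lib, feats


def test_crossval_partitions_every_sample_once(small_library):
    lib, feats = small_library
    res = crossval(feats, lib.labels(), k=5, seed=0)
    assert res.confusion.total == len(lib)
    assert sorted(set(res.fold_of)) == list(range(5))
    fold_sizes = [res.fold_of.count(f) for f in range(5)]
    assert max(fold_sizes) - min(fold_sizes) <= 2  # stratified within each class


def test_crossval_deterministic_per_seed(small_library):
    lib, feats = small_library
    a = crossval(feats, lib.labels(), k=5, seed=3)
    b = crossval(feats, lib.labels(), k=5, seed=3)
    assert a.confusion == b.confusion
    assert a.scores == b.scores
    c = crossval(feats, lib.labels(), k=5, seed=4)
    assert a.fold_of != c.fold_of


def test_crossval_strong_signal_recall(full_signal_library):
    feats = nbayes.featurize(full_signal_library, diameter=6)
    res = crossval(feats, full_signal_library.labels(), k=10, seed=7)
    assert res.metrics.active.recall >= 0.9


def test_crossval_k_exceeding_n_rejected(small_library):
    lib, feats = small_library
    with pytest.raises(ValueError):
        crossval(feats, lib.labels(), k=len(lib) + 1, seed=0)
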