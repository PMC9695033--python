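import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nbscreen import chemio, evalmetrics, nbayes, synthdata
from nbscreen.chemspace import DescriptorTable
from nbscreen.nbayes import FeatureVectorSet, featurize, fit, laplacian_weight, score


def _fvs(feature_sets, ids=None):
    ids = ids or [f"c{i}" for i in range(len(feature_sets))]
    return FeatureVectorSet(ids=ids, features=[frozenset(f) for f in feature_sets])


def test_laplacian_weight_worked_example():
    # prior 1/2, feature in 5 of 5 actives and no inactives: log(6/3.5)
    assert laplacian_weight(5, 5, 0.5) == pytest.approx(math.log(6 / 3.5))
    assert laplacian_weight(5, 5, 0.5) == pytest.approx(0.539, abs=5e-4)


def test_feature_at_prior_frequency_has_near_zero_weight():
    # active fraction equals the prior: weight -> 0 as counts grow
    prior = 0.25
    w = laplacian_weight(250, 1000, prior)
    assert abs(w) < 5e-4


def test_prior_matches_class_counts():
    n_active, n_total = 1835, 5360
    feats = _fvs([{"f"}] * n_total)
    labels = ["active"] * n_active + ["inactive"] * (n_total - n_active)
    model = fit(feats, labels)
    assert model.prior_active == pytest.approx(n_active / n_total)
    assert model.prior_active == pytest.approx(0.3424, abs=5e-5)


def test_fit_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        fit(_fvs([{"a"}, {"b"}]), ["active", "active"])


def test_empty_feature_set_scores_zero(fitted_model):
    model, _ = fitted_model
    assert score(model, frozenset()).score == 0.0


def test_single_feature_score_is_its_weight():
    feats = _fvs([{"f"}] * 5 + [set()] * 5)
    labels = ["active"] * 5 + ["inactive"] * 5
    model = fit(feats, labels)
    expected = math.log(6 / 3.5)
    assert model.weights["f"] == pytest.approx(expected)
    assert score(model, {"f"}).score == pytest.approx(expected)


def test_score_additive_monotone(fitted_model):
    model, feats = fitted_model
    base = feats.features[0]
    positive = [f for f, w in model.weights.items() if w > 0 and f not in base][:5]
    s = score(model, base).score
    for f in positive:
        s2 = score(model, base | {f}).score
        assert s2 > s


def test_two_feature_ranking_matches_posterior_enumeration():
    """Additive scores rank the 4 feature combinations exactly as the
    brute-force Bayes posterior P(active | features) does."""
    rng = np.random.default_rng(0)
    # build a training set over two features with asymmetric class association
    rows = []
    labels = []
    for _ in range(400):
        active = rng.random() < 0.4
        f = set()
        if rng.random() < (0.8 if active else 0.2):
            f.add("A")
        if rng.random() < (0.6 if active else 0.35):
            f.add("B")
        rows.append(f)
        labels.append("active" if active else "inactive")
    model = fit(_fvs(rows), labels)

    # oracle: naive Bayes posterior over presence-only likelihoods, estimated
    # with the same Laplacian correction, enumerated per combination
    n_act = sum(1 for l in labels if l == "active")
    n_tot = len(labels)
    prior = n_act / n_tot

    def likelihood_ratio(fset):
        # product over present features of P_laplace(F|active)/P_laplace(F)
        acc = 1.0
        for f in fset:
            a = sum(1 for r, l in zip(rows, labels) if f in r and l == "active")
            t = sum(1 for r in rows if f in r)
            acc *= (a + 1.0) / ((t * prior + 1.0))
        return acc

    combos = [frozenset(), frozenset("A"), frozenset("B"), frozenset("AB")]
    oracle = sorted(combos, key=likelihood_ratio)
    additive = sorted(combos, key=lambda c: score(model, c).score)
    assert oracle == additive


def test_ranking_stable_under_training_duplication():
    """Duplicating the training set scales all counts; the Laplacian term's
    influence shrinks, so weights converge to log(A/(T*p)) and the score
    ranking of probe compounds is essentially unchanged."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(1)
    rows = [set(np.flatnonzero(rng.random(8) < 0.3).astype(str)) for _ in range(60)]
    labels = ["active" if rng.random() < 0.4 else "inactive" for _ in range(60)]
    labels[0], labels[1] = "active", "inactive"
    m1 = fit(_fvs(rows), labels)

    def dup(k):
        return fit(
            _fvs(rows * k, ids=[f"c{i}" for i in range(60 * k)]), labels * k
        )

    m10, m20 = dup(10), dup(20)
    prior = m1.prior_active
    for f, (a, t) in m1.feature_counts.items():
        limit = math.log((a + 1 / 10) / (t * prior + 1 / 10))  # k=10 exact form
        assert m10.weights[f] == pytest.approx(
            math.log((10 * a + 1) / (10 * t * prior + 1)), rel=1e-12
        )
        # convergence: k=20 weight is closer to the asymptote log(A/(T*p))
        if a > 0:
            asym = math.log(a / (t * prior))
            assert abs(m20.weights[f] - asym) <= abs(m10.weights[f] - asym) + 1e-12
    s1 = [score(m1, r).score for r in map(frozenset, rows)]
    s10 = [score(m10, r).score for r in map(frozenset, rows)]
    rho = spearmanr(s1, s10).statistic
    assert rho > 0.99


def test_featurize_descriptor_free_is_ecfp_only(full_signal_library):
    feats = featurize(full_signal_library, diameter=6)
    assert all(f.startswith("ecfp:") for fs in feats.features for f in fs)
    feats2 = featurize(full_signal_library, diameter=6)
    assert feats.features == feats2.features


def test_featurize_equal_frequency_binning():
    cset = chemio.CompoundSet(
        compounds=[chemio.Compound(id=f"c{i}", smiles="C") for i in range(4)]
    )
    table = DescriptorTable(
        pd.DataFrame({"d": [1.0, 2.0, 3.0, 4.0]}, index=[f"c{i}" for i in range(4)])
    )
    feats = featurize(cset, diameter=0, descriptors=table, bins=2)
    bins = [next(f for f in fs if f.startswith("desc:")) for fs in feats.features]
    # median split: {1,2} lower bin, {3,4} upper bin
    assert bins[0] == bins[1] and bins[2] == bins[3] and bins[0] != bins[2]


def test_featurize_binary_descriptor_passthrough():
    cset = chemio.CompoundSet(
        compounds=[chemio.Compound(id="a", smiles="C"), chemio.Compound(id="b", smiles="CC")]
    )
    table = DescriptorTable(pd.DataFrame({"IsChiral": [1.0, 0.0]}, index=["a", "b"]))
    feats = featurize(cset, diameter=0, descriptors=table)
    assert "desc:IsChiral:on" in feats.features[0]
    assert not any(f.startswith("desc:") for f in feats.features[1])


def test_featurize_rejects_single_bin():
    cset = chemio.CompoundSet(compounds=[chemio.Compound(id="a", smiles="C")])
    table = DescriptorTable(pd.DataFrame({"d": [1.0]}, index=["a"]))
    with pytest.raises(ValueError, match="bins"):
        featurize(cset, diameter=0, descriptors=table, bins=1)


def test_label_permutation_gives_chance_auc(full_signal_library):
    """Cross-validated AUC collapses to ~0.5 once labels are shuffled."""
    feats = featurize(full_signal_library, diameter=6)
    labels = full_signal_library.labels()
    rng = np.random.default_rng(123)
    aucs = []
    for _ in range(20):
        perm = list(rng.permutation(labels))
        res = evalmetrics.crossval(feats, perm, k=5, seed=0)
        aucs.append(res.metrics.auc)
    assert abs(float(np.mean(aucs)) - 0.5) < 0.05


def test_implanted_signal_recovered(full_signal_library, fitted_model):
    """Full-signal library: near-perfect CV AUC, and implant-motif
    identifiers carry the largest positive weights."""
    model, feats = fitted_model
    res = evalmetrics.crossval(feats, full_signal_library.labels(), k=10, seed=7)
    assert res.metrics.auc >= 0.95

    # identifiers of the bare implant motifs (their interior environments
    # reappear unchanged inside decorated molecules)
    from nbscreen.fingerprints import ecfp

    implant_ids = set()
    for motif in synthdata.DEFAULT_IMPLANTS:
        frag = motif.fragment.replace("8", "1")
        for ident in ecfp(frag, 6).identifiers:
            implant_ids.add(f"ecfp:{ident}")
    top = sorted(model.weights, key=model.weights.get, reverse=True)[:20]
    assert implant_ids & set(top)
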