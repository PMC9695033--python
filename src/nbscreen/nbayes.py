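"""Laplacian-corrected naive Bayesian activity classifier.

The model scores a compound as a sum of per-feature log weights.  For a
feature F seen in ``A_F`` actives out of ``T_F`` training compounds, with
class prior ``p = n_active / n_total`` and Laplacian stabilizer ``K = 1/p``,

    weight(F) = log[(A_F + p*K) / (T_F*p + p*K)] = log[(A_F + 1) / (T_F*p + 1)]

so a feature whose active fraction equals the prior gets weight ~0, and a
feature never seen among actives gets a finite negative weight.  Features
are ECFP identifiers plus (optionally) equal-frequency-binned molecular
descriptors.  A compound is called active when its score reaches the model's
activity cut-off, chosen on the training ROC by maximizing Youden's J
(sensitivity + specificity - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemio import CompoundSet
from .chemspace import DescriptorTable
from .fingerprints import ecfp

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass
class FeatureVectorSet:
    """Sparse binary feature sets, one per compound, in set order."""

    ids: list[str]
    features: list[frozenset[str]]
    bin_edges: dict[str, list[float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class BayesModel:
    """Fitted Laplacian-corrected naive Bayes classifier."""

    prior_active: float
    weights: dict[str, float]
    cutoff: float
    feature_counts: dict[str, tuple[int, int]]  # feature -> (n_active_with, n_total_with)
    n_active: int
    n_total: int
    bin_edges: dict[str, list[float]] = field(default_factory=dict)
    unseen_weight: float = 0.0
    penalize_unseen: bool = False

    def to_dict(self) -> dict:
        return {
            "prior_active": self.prior_active,
            "weights": self.weights,
            "cutoff": self.cutoff,
            "feature_counts": {k: list(v) for k, v in self.feature_counts.items()},
            "n_active": self.n_active,
            "n_total": self.n_total,
            "bin_edges": self.bin_edges,
            "unseen_weight": self.unseen_weight,
            "penalize_unseen": self.penalize_unseen,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BayesModel":
        return cls(
            prior_active=float(d["prior_active"]),
            weights={k: float(v) for k, v in d["weights"].items()},
            cutoff=float(d["cutoff"]),
            feature_counts={k: (int(v[0]), int(v[1])) for k, v in d["feature_counts"].items()},
            n_active=int(d["n_active"]),
            n_total=int(d["n_total"]),
            bin_edges={k: [float(x) for x in v] for k, v in d.get("bin_edges", {}).items()},
            unseen_weight=float(d.get("unseen_weight", 0.0)),
            penalize_unseen=bool(d.get("penalize_unseen", False)),
        )


@dataclass(frozen=True)
class ScoredCompound:
    compound_id: str
    score: float
    call: str  # "active" | "inactive"


def laplacian_weight(n_active_with: int, n_total_with: int, prior: float) -> float:
    """log[(A_F + p*K) / (T_F*p + p*K)] with K = 1/p, i.e. p*K = 1."""
    return math.log((n_active_with + 1.0) / (n_total_with * prior + 1.0))


def _bin_feature_names(name: str, edges: Sequence[float]) -> list[str]:
    return [f"desc:{name}:bin{i}" for i in range(len(edges) + 1)]


def _assign_bin(value: float, edges: Sequence[float]) -> int:
    # edges are interior quantile cut points; right-closed bins
    return int(np.searchsorted(edges, value, side="left"))


def featurize(
    cset: CompoundSet,
    diameter: int = 6,
    descriptors: Optional[DescriptorTable] = None,
    bins: int = 5,
    bin_edges: Optional[dict[str, list[float]]] = None,
) -> FeatureVectorSet:
    """Binary feature sets: ECFP identifiers plus binned-descriptor indicators.

    ECFP identifiers are encoded as ``ecfp:<id>``.  Each continuous descriptor
    becomes one-of-*bins* equal-frequency indicator features with edges
    computed here (or taken from *bin_edges*, e.g. a fitted model's, at
    prediction time).  Binary descriptors (only values 0/1) pass through as a
    single on/off indicator.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    fps = {c.id: ecfp(c, diameter) for c in cset}
    edges_out: dict[str, list[float]] = {}
    desc_features: dict[str, set[str]] = {c.id: set() for c in cset}
    if descriptors is not None:
        missing = [c.id for c in cset if c.id not in descriptors.frame.index]
        if missing:
            raise ValueError(f"descriptor rows missing for compounds: {missing[:5]}")
        for name in descriptors.descriptor_names:
            col = descriptors.frame[name]
            values = {c.id: float(col.loc[c.id]) for c in cset}
            uniq = set(values.values())
            if uniq <= {0.0, 1.0}:
                for cid, v in values.items():
                    if v == 1.0:
                        desc_features[cid].add(f"desc:{name}:on")
                continue
            if bin_edges is not None and name in bin_edges:
                edges = list(bin_edges[name])
            else:
                qs = np.linspace(0, 1, bins + 1)[1:-1]
                edges = sorted(set(np.quantile(list(values.values()), qs).tolist()))
            edges_out[name] = edges
            for cid, v in values.items():
                desc_features[cid].add(f"desc:{name}:bin{_assign_bin(v, edges)}")
    ids, feats = [], []
    for c in cset:
        ids.append(c.id)
        fset = {f"ecfp:{i}" for i in fps[c.id].identifiers} | desc_features[c.id]
        feats.append(frozenset(fset))
    if bin_edges is not None:
        edges_out = {**bin_edges, **edges_out}
    return FeatureVectorSet(ids=ids, features=feats, bin_edges=edges_out)


def fit(
    features: FeatureVectorSet,
    labels: Sequence[str],
    penalize_unseen: bool = False,
) -> BayesModel:
    """Fit the classifier from binary feature sets and active/inactive labels.

    The activity cut-off is set at the training-score threshold maximizing
    Youden's J; override via ``model.cutoff`` if an external cut-off is to be
    honored.
    """
    if len(labels) != len(features):
        raise ValueError("labels do not align with feature vectors")
    labels = list(labels)
    n_total = len(labels)
    n_active = sum(1 for l in labels if l == ACTIVE)
    if n_active == 0 or n_active == n_total:
        raise ValueError("training data must contain both classes")
    prior = n_active / n_total

    counts: dict[str, list[int]] = {}
    for fset, label in zip(features.features, labels):
        is_active = label == ACTIVE
        for f in fset:
            c = counts.setdefault(f, [0, 0])
            c[1] += 1
            if is_active:
                c[0] += 1
    weights = {f: laplacian_weight(a, t, prior) for f, (a, t) in counts.items()}
    unseen = laplacian_weight(0, 1, prior) if penalize_unseen else 0.0

    model = BayesModel(
        prior_active=prior,
        weights=weights,
        cutoff=0.0,
        feature_counts={f: (a, t) for f, (a, t) in counts.items()},
        n_active=n_active,
        n_total=n_total,
        bin_edges=dict(features.bin_edges),
        unseen_weight=unseen,
        penalize_unseen=penalize_unseen,
    )
    scores = np.array([_raw_score(model, fset) for fset in features.features])
    y = np.array([1 if l == ACTIVE else 0 for l in labels])
    model.cutoff = _youden_cutoff(scores, y)
    return model


def _youden_cutoff(scores: np.ndarray, y: np.ndarray) -> float:
    """Score threshold (call active iff score >= t) maximizing J.

    The returned cut-off is the midpoint between the J-optimal score and the
    next distinct score below it: training calls are unchanged, but the
    decision boundary sits mid-margin instead of exactly on a training
    compound, which generalizes better to unseen chemistry.
    """
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    P, N = int(y.sum()), int((1 - y).sum())
    # candidate thresholds: each distinct score value
    best_j, best_t = -np.inf, float(s[0])
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            tp += int(yy[j])
            fp += int(1 - yy[j])
            j += 1
        jstat = tp / P + (N - fp) / N - 1.0
        if jstat > best_j:
            best_j, best_t = jstat, float(s[i])
        i = j
    below = s[s < best_t]
    if below.size:
        return (best_t + float(below[0])) / 2.0
    return best_t


def _raw_score(model: BayesModel, fset: frozenset[str]) -> float:
    w = model.weights
    u = model.unseen_weight
    return sum(w.get(f, u) for f in fset)


def score(model: BayesModel, features: frozenset[str] | set[str], compound_id: str = "") -> ScoredCompound:
    """Score one compound's feature set; call active iff score >= cutoff.

    An empty feature set scores 0.  Features never seen in training
    contribute the model's unseen-feature weight (a small negative constant,
    or 0 when ``penalize_unseen`` is off).
    """
    s = _raw_score(model, frozenset(features))
    return ScoredCompound(compound_id=compound_id, score=s, call=ACTIVE if s >= model.cutoff else INACTIVE)


def score_set(model: BayesModel, features: FeatureVectorSet) -> list[ScoredCompound]:
    return [score(model, fset, cid) for cid, fset in zip(features.ids, features.features)]


def export_scores(scored: Sequence[ScoredCompound], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tscore\tcall\n")
        for s in scored:
            fh.write(f"{s.compound_id}\t{s.score!r}\t{s.call}\n")
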