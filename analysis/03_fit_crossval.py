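"""Fit the Laplacian-corrected naive Bayes classifier and cross-validate it.

Writes the serialized model, the training-set metrics and the pooled 10-fold
cross-validation metrics.
"""

from _common import DIAMETER, RESULTS, SEED, library

from nbscreen import chemio, evalmetrics, nbayes


def main() -> None:
    lib = library()
    labels = lib.labels()
    feats = nbayes.featurize(lib, diameter=DIAMETER)

    model = nbayes.fit(feats, labels)
    chemio.save_model(model, RESULTS / "bayes_model.json")

    scored = nbayes.score_set(model, feats)
    calls = ["active" if s.score >= model.cutoff else "inactive" for s in scored]
    cm = evalmetrics.confusion(calls, labels)
    auc, _ = evalmetrics.roc_auc([s.score for s in scored], labels)
    train_rep = evalmetrics.metrics_from_confusion(cm, auc=auc)
    evalmetrics.export_metrics(train_rep, RESULTS / "metrics_training.tsv")

    cv = evalmetrics.crossval(feats, labels, k=10, seed=SEED)
    evalmetrics.export_metrics(cv.metrics, RESULTS / "metrics_crossval.tsv")

    print(f"training: recall {train_rep.active.recall:.3f}, "
          f"precision {train_rep.active.precision:.3f}, AUC {auc:.3f}")
    print(f"10-fold:  recall {cv.metrics.active.recall:.3f}, "
          f"precision {cv.metrics.active.precision:.3f}, AUC {cv.metrics.auc:.3f}")


if __name__ == "__main__":
    main()
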