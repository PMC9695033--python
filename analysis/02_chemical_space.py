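"""Descriptor table, activity-correlation filter and PCA of the library.

Writes the raw descriptor table, the retained descriptor list and a PCA
summary (explained variance and loadings of the retained components).
"""

import json

import pandas as pd

from _common import RESULTS, library

from nbscreen import chemspace


def main() -> None:
    lib = library()
    table = chemspace.compute_descriptors(lib, names=sorted(chemspace.DESCRIPTOR_REGISTRY))
    table.to_csv(RESULTS / "descriptors.tsv")

    activity = [1 if l == "active" else 0 for l in lib.labels()]
    retained = chemspace.correlation_filter(table, activity, min_abs_r=0.1)
    (RESULTS / "descriptors_retained.txt").write_text("\n".join(retained) + "\n")

    filtered = chemspace.DescriptorTable(table.frame[retained])
    model = chemspace.fit_pca(filtered, n_components=min(5, len(retained)))
    k = chemspace.choose_n_components(model)
    loadings = pd.DataFrame(
        model.component_loadings[:, :k],
        index=model.descriptor_names,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings.to_csv(RESULTS / "pca_loadings.tsv", sep="\t", index_label="descriptor")
    scores = chemspace.project(model, filtered).iloc[:, :k]
    scores.to_csv(RESULTS / "pca_scores.tsv", sep="\t", index_label="compound_id")

    summary = {
        "n_descriptors_computed": len(table.descriptor_names),
        "n_descriptors_retained": len(retained),
        "n_components_kept": k,
        "explained_variance_fraction": [
            round(float(v), 4) for v in model.explained_variance_fraction[:k]
        ],
    }
    (RESULTS / "pca_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"retained {len(retained)}/{len(table.descriptor_names)} descriptors; "
          f"{k} PCs explain "
          f"{sum(model.explained_variance_fraction[:k]):.2%} of variance")


if __name__ == "__main__":
    main()
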