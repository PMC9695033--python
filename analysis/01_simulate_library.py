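"""Generate the study library and characterize its structural diversity.

Writes the library as SMILES with activity flags plus a diversity summary.
"""

import json

from _common import DIAMETER, LIBRARY_SPEC, RESULTS, library

from nbscreen import chemio
from nbscreen.fingerprints import dataset_diversity


def main() -> None:
    lib = library()
    chemio.write_compounds(lib, RESULTS / "library.smi")
    with open(RESULTS / "library_flags.tsv", "w") as fh:
        fh.write("compound_id\tsmiles\tpxc50\tactivity_flag\n")
        for c in lib:
            fh.write(f"{c.id}\t{c.smiles}\t{c.pxc50:.3f}\t{c.activity_flag}\n")

    div = dataset_diversity(lib, diameter=2)
    summary = {
        "n_active": LIBRARY_SPEC.n_active,
        "n_inactive": LIBRARY_SPEC.n_inactive,
        "seed": LIBRARY_SPEC.seed,
        "ecfp_diameter_for_model": DIAMETER,
        "mean_pairwise_tanimoto_ecfp2": round(div.mean_pairwise_tc, 4),
        "n_pairs": div.n_pairs,
    }
    (RESULTS / "library_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"library: {len(lib)} compounds, mean pairwise Tc "
          f"{div.mean_pairwise_tc:.3f} over {div.n_pairs} pairs")


if __name__ == "__main__":
    main()
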