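"""Rank fragment environments by their Bayes weight (GF/BF analysis).

Writes the full fragment table and the top good/bad fragment lists.
"""

from _common import DIAMETER, RESULTS, library

from nbscreen import nbayes
from nbscreen.fragments import export_fragment_table, fragment_table, top_fragments


def main() -> None:
    lib = library()
    feats = nbayes.featurize(lib, diameter=DIAMETER)
    model = nbayes.fit(feats, lib.labels())

    table = fragment_table(lib, diameter=DIAMETER, model=model)
    export_fragment_table(table, RESULTS / "fragments_all.tsv")
    for direction in ("good", "bad"):
        top = top_fragments(table, n=20, direction=direction)
        export_fragment_table(top, RESULTS / f"fragments_top_{direction}.tsv")

    best = top_fragments(table, n=5, direction="good")
    print("top good fragments (identifier, weight, exemplar):")
    for f in best:
        print(f"  {f.identifier}\t{f.bayes_weight:+.3f}\t{f.exemplar}")


if __name__ == "__main__":
    main()
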