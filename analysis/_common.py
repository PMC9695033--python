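"""Shared study configuration for the numbered analysis drivers.

All drivers regenerate the same seeded library, so each script can be run
independently and in any order; outputs land in ``results/``.
"""

from pathlib import Path

from nbscreen import synthdata

RESULTS = Path(__file__).resolve().parent.parent / "results"

SEED = 7
DIAMETER = 6
LIBRARY_SPEC = synthdata.LibrarySpec(n_active=167, n_inactive=333, seed=SEED)


def library():
    RESULTS.mkdir(exist_ok=True)
    return synthdata.generate_library(LIBRARY_SPEC)
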