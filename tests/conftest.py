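import pytest

from nbscreen import chemio, nbayes, synthdata


@pytest.fixture()
def tiny_set():
    """Three small alcohols/aromatics with pXC50 annotations."""
    return chemio.CompoundSet(
        compounds=[
            chemio.Compound(id="ethanol", smiles="CCO", pxc50=4.9),
            chemio.Compound(id="propanol", smiles="CCCO", pxc50=5.1),
            chemio.Compound(id="benzene", smiles="c1ccccc1", pxc50=6.0),
        ],
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def full_signal_library():
    """500-compound library, implant rate 1 vs 0, 1:2 active:inactive."""
    spec = synthdata.LibrarySpec(n_active=167, n_inactive=333, seed=7)
    return synthdata.generate_library(spec)


@pytest.fixture(scope="session")
def fitted_model(full_signal_library):
    feats = nbayes.featurize(full_signal_library, diameter=6)
    return nbayes.fit(feats, full_signal_library.labels()), feats
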