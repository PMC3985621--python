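import pytest

from riscload import mirref, synth


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated experiment shared across tests (12 miRNAs)."""
    matures, hairpins = synth.simulate_reference(12, seed=11)
    manifest = synth.default_manifest(matures, seed=11, depth=6000)
    sim = synth.simulate_libraries(matures, hairpins, manifest)
    return matures, hairpins, manifest, sim


@pytest.fixture(scope="session")
def linked_small_sim(small_sim):
    matures, hairpins, manifest, sim = small_sim
    return mirref.link_matures(matures, hairpins), hairpins, manifest, sim
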