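import pytest

from scatyper import clustering, digest, synthetic

K = 20
SEED = 7


@pytest.fixture(scope="session")
def community():
    """A default 20-type community over the full 36-sample design."""
    return synthetic.simulate_community(K, seed=SEED)


@pytest.fixture(scope="session")
def type_model():
    return synthetic.default_type_model(seed=SEED)


@pytest.fixture(scope="session")
def type_sequences(type_model):
    return synthetic.simulate_type_sequences(type_model, K, seed=SEED)


@pytest.fixture(scope="session")
def clone_library(community, type_sequences, type_model):
    return synthetic.simulate_clone_library(
        community, type_sequences, depth=17, seed=SEED, model=type_model
    )


@pytest.fixture(scope="session")
def scac_trfs(type_sequences):
    """Per-enzyme TRF predictions for every type sequence."""
    fwd, rev = digest.PRIMERS["scaC"]
    out = {}
    for enz_name in digest.ENZYME_PANELS["scaC"]:
        enz = digest.ENZYMES[enz_name]
        out[enz_name] = {
            t: digest.predict_trf(digest.extract_amplicon(s, fwd, rev), enz, t)
            for t, s in type_sequences.items()
        }
    return out


def to_records(clones):
    return [
        clustering.SeqRecord(c.clone_id, c.sequence, c.sample_id) for c in clones
    ]
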