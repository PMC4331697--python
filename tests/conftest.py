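import pytest

from chemner.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-document synthetic corpus shared by read-only tests."""
    return generate_corpus(GeneratorConfig(n_docs=30, seed=11))


@pytest.fixture(scope="session")
def toy_sequences():
    """A tiny hand-built training set: 'tested <chem>' contexts."""
    seqs = []
    for i in range(20):
        chem = f"chem{i % 5}ol"
        seqs.append((
            [["W=we"], ["W=tested"], [f"W={chem}", "SUF2=ol"], ["W=."]],
            ["O", "O", "B", "O"],
        ))
    seqs.append((
        [["W=acetylsalicylic", "SUF2=ic"], ["W=acid"]],
        ["B", "I"],
    ))
    seqs.append((
        [["W=no"], ["W=drugs"], ["W=here"]],
        ["O", "O", "O"],
    ))
    return seqs


@pytest.fixture(scope="session")
def toy_model(toy_sequences):
    from chemner.crf import train_crf

    return train_crf(toy_sequences, order=1, max_iter=200)
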