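import numpy as np
import pytest

from ionbind.core import AnnotatedChain, LigandProfile, Residue
from ionbind.simulate import SimConfig, generate_corpus, strong_signal_config


def make_chain(seq, labels=None, ss=None, rsa=None, chain_id="c1"):
    """Hand-build a small annotated chain with simple defaults."""
    n = len(seq)
    labels = labels or [0] * n
    ss = ss or "C" * n
    rsa = rsa if rsa is not None else [0.3] * n
    return AnnotatedChain(
        chain_id=chain_id,
        residues=[
            Residue(aa=seq[i], ss=ss[i], rsa=float(rsa[i]), label=int(labels[i]))
            for i in range(n)
        ],
    )


@pytest.fixture
def zn_profile():
    return LigandProfile.default("Zn2+")


@pytest.fixture
def small_chains():
    """A small synthetic corpus for fast structural tests."""
    return generate_corpus(
        SimConfig(n_chains=6, length_range=(30, 40), binding_fraction=0.1, seed=3)
    )


@pytest.fixture(scope="session")
def strong_chains():
    """The standard strong-signal benchmark corpus (shared across tests)."""
    return generate_corpus(strong_signal_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
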