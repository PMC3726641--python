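import numpy as np
import pytest

from cleftscope import synthetic_data as syn


@pytest.fixture(scope="session")
def toy_complex():
    return syn.make_toy_complex(n_waters=6)


@pytest.fixture(scope="session")
def dry_complex():
    return syn.make_toy_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def find(structure, name, **kw):
    return structure.atom_id(name, **kw)


@pytest.fixture(scope="session")
def planted_hbond_ids(toy_complex):
    structure, _ = toy_complex
    return dict(
        donor=find(structure, "NZ", residue_name="LYS"),
        hydrogen=find(structure, "HZ1", residue_name="LYS"),
        acceptor=find(structure, "OE2", residue_name="GLU"),
    )
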