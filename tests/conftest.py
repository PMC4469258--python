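import pytest

from molscreen import default_catalogue, make_fixture_set, parse_smiles


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def bench_set():
    return make_fixture_set("mixed_bench", 19, rng_seed=7)


@pytest.fixture()
def alkane_set():
    return make_fixture_set("alkanes", 8)


def record(smiles: str, name: str = "X"):
    return parse_smiles(f"{smiles} {name}", auto_name=name)


@pytest.fixture(scope="session")
def molecules():
    """Small, structurally varied molecules used across property tests."""
    smiles = {
        "methane": "C",
        "ethane": "CC",
        "ethanol": "CCO",
        "benzene": "c1ccccc1",
        "toluene": "Cc1ccccc1",
        "cyclohexane": "C1CCCCC1",
        "glycine": "NCC(=O)O",
        "pyridine": "c1ccncc1",
        "butanediol": "OCCCCO",
        "acetamide": "CC(=O)NC",
        "benzoquinone": "O=C1C=CC(=O)C=C1",
        "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    }
    return {name: record(smi, name) for name, smi in smiles.items()}
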