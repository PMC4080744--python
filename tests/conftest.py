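import logging

import pytest
from rdkit import Chem

from molblocks.chem_io import MoleculeRecord
from molblocks.fixtures import golden_records, toy_rules

logging.getLogger("molblocks").setLevel(logging.WARNING)


def record(smiles: str, mol_id: str = "m") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"bad test SMILES {smiles!r}"
    return MoleculeRecord(id=mol_id, smiles=smiles, mol=mol)


@pytest.fixture(scope="session")
def rules():
    return toy_rules()


@pytest.fixture(scope="session")
def ester_rule(rules):
    return [r for r in rules if r.name == "ester"]


@pytest.fixture(scope="session")
def golden():
    return golden_records()


@pytest.fixture
def ethyl_acetate():
    return record("CC(=O)OCC", "ethyl_acetate")


@pytest.fixture
def diethyl_succinate():
    return record("CCOC(=O)CCC(=O)OCC", "diethyl_succinate")
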