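import pytest

from classrt.chemio import DatasetTable, MoleculeRecord
from classrt.synthkit import SynthConfig, generate_library
from classrt.taxonomy import default_ruleset


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def small_library():
    """Six-class synthetic library, 30 molecules per class, sigma 10 s."""
    table, truth = generate_library(SynthConfig(per_class=30, noise_sd=10.0, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def noiseless_library():
    table, truth = generate_library(SynthConfig(per_class=25, noise_sd=0.0, seed=7))
    return table, truth


def make_table(smiles_rt, prefix="m"):
    """Tiny helper: build a DatasetTable from (smiles, rt) pairs."""
    recs = [
        MoleculeRecord.from_smiles(f"{prefix}{i}", smi, rt)
        for i, (smi, rt) in enumerate(smiles_rt)
    ]
    return DatasetTable(recs)
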