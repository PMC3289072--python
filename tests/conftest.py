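import numpy as np
import pytest

from dnagroove import fixtures as fx
from dnagroove import knowledgebase as kbm
from dnagroove.structio import AtomRecord, ResidueRecord, StructureModel

DBU_TYPES = ["ARG", "LYS", "ASN", "SER", "ARG"]


@pytest.fixture(scope="session")
def helix16():
    return fx.HelixParams(n_bp=16)


@pytest.fixture(scope="session")
def duplex16(helix16):
    return fx.build_bdna(helix16)


@pytest.fixture(scope="session")
def planted():
    """(complex model, ground truth) with one major-groove DBU, no jitter."""
    dna = fx.build_bdna(fx.HelixParams(n_bp=16))
    spec = fx.PlantedDBUSpec(residue_types=DBU_TYPES, groove="major",
                             center_bp=8, seed=1)
    return fx.plant_dbu(dna, spec)


@pytest.fixture(scope="session")
def trained_kb(planted):
    model, _ = planted
    return kbm.build_knowledgebase([model])


def make_structure(residue_specs, struct_id="synthetic"):
    """Build a StructureModel from (chain, seq, res_type, [(name, elem, xyz)])."""
    residues = []
    serial = 0
    for chain, seq, res_type, atoms in residue_specs:
        recs = []
        for name, elem, xyz in atoms:
            serial += 1
            recs.append(AtomRecord(serial, name, elem, np.asarray(xyz, float)))
        residues.append(ResidueRecord(chain, seq, res_type, "", recs))
    return StructureModel(id=struct_id, residues=residues)


@pytest.fixture
def make_struct():
    return make_structure
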