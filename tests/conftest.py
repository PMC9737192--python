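import warnings

import numpy as np
import pytest

from contactprof import synthgen
from contactprof.bonds import infer_bonds
from contactprof.perception import perceive
from contactprof.structure import Atom, Frame, classify_entities


@pytest.fixture(scope="session")
def toy_frame():
    return synthgen.make_toy_complex()


@pytest.fixture(scope="session")
def toy_entities(toy_frame):
    return classify_entities(toy_frame, {synthgen.LIGAND_RESNAME})


@pytest.fixture(scope="session")
def toy_bonds(toy_frame):
    return infer_bonds(toy_frame)


@pytest.fixture(scope="session")
def toy_perception(toy_frame, toy_bonds, toy_entities):
    return perceive(toy_frame, toy_bonds, toy_entities)


@pytest.fixture(scope="session")
def crystal_frame():
    return synthgen.make_crystal_site_synthetic()


def make_frame(spec, res_name="UNK", chain="A", res_seq=1):
    """Tiny frame helper: spec = [(name, element, (x, y, z)), ...]."""
    atoms = [Atom(serial=i + 1, name=nm, element=el, res_name=res_name,
                  res_seq=res_seq, chain_id=chain, coords=np.asarray(xyz, float))
             for i, (nm, el, xyz) in enumerate(spec)]
    return Frame(atoms)


@pytest.fixture(autouse=True)
def _quiet_bond_warnings():
    """Randomized stress frames legitimately detach the odd hydrogen."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no bonded heavy atom.*")
        warnings.filterwarnings("ignore", message=".*no covalent neighbors.*")
        yield
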