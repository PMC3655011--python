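import numpy as np
import pytest

from gtusc.structio import AtomRecord, Frame


def make_atom(serial, chain, resnum, name="CA", element="C", resname="ALA",
              pos=(0.0, 0.0, 0.0)):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_number=resnum,
                      chain_id=chain, position=np.asarray(pos, dtype=float))


def two_chain_frame(coords_a, coords_b, index=0):
    """Frame with chain A atoms at coords_a and chain B atoms at coords_b."""
    atoms = []
    serial = 1
    for chain, coords in (("A", coords_a), ("B", coords_b)):
        for i, pos in enumerate(coords):
            atoms.append(make_atom(serial, chain, i + 1, pos=pos))
            serial += 1
    return Frame(index=index, atoms=tuple(atoms))


@pytest.fixture
def rng():
    return np.random.default_rng(20130515)
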