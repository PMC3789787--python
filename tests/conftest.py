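import logging

import numpy as np
import pytest

import cbsvar
from cbsvar import structure_features as sf
from cbsvar.synthetic_data import helix_coordinates, simulate_structure

# the in-window warning about dropped zero-OD reads fires constantly on
# noisy low-OD synthetic curves; keep test output readable
logging.getLogger("cbsvar.growth_kinetics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def table1():
    return cbsvar.load_table1()


@pytest.fixture(scope="session")
def table2():
    return cbsvar.load_table2()


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    """60-residue synthetic helix with one heme and one PLP group.

    The heme is planted exactly 7.3 A (+x) from the dummy side-chain atom
    of the residue whose side chain points closest to +x, so the written
    (3-decimal) coordinates realize the distance exactly.
    """
    coords = helix_coordinates(60)
    target = min(coords, key=lambda s: abs(np.arctan2(coords[s]["CB"][1],
                                                      coords[s]["CB"][0])))
    heme = coords[target]["CB"] + np.array([7.3, 0.0, 0.0])
    plp = np.array([-12.0, 0.0, 40.0])
    path = tmp_path_factory.mktemp("structs") / "helix.pdb"
    simulate_structure(path, 60, ligand_positions=[("heme", heme), ("plp", plp)])
    return {"path": path, "heme": heme, "plp": plp, "target": target}


@pytest.fixture(scope="session")
def helix_model(helix_pdb):
    return sf.load_structure(helix_pdb["path"])
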