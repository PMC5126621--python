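import numpy as np
import pytest

import pocketmc as pm
from pocketmc.energy import default_params
from pocketmc.refine import RefinementConfig


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def pocket12():
    """A 12-residue synthetic pocket shared across read-only tests."""
    return pm.make_mini_pocket(seed=7, n_residues=12)


@pytest.fixture(scope="session")
def pocket15():
    return pm.make_mini_pocket(seed=3, n_residues=15)


@pytest.fixture()
def tiny_cfg():
    """A deliberately small refinement protocol for fast trajectory tests."""
    return RefinementConfig(outer_cycles=2, mid_blocks=2, inner_steps=2,
                            n_decoys=3, max_K=3, convergence_tol=0.05, seed=11)


def make_atom(name="C1", element="C", pos=(0.0, 0.0, 0.0), q=0.0,
              radius=1.9, hb_role="none", is_h=False):
    return pm.Atom(name=name, element=element, position=np.array(pos, float),
                   partial_charge=q, vdw_radius=radius, hb_role=hb_role,
                   is_hydrogen=is_h)
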