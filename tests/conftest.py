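"""Shared fixtures: parametric oracle meshes and a synthetic training corpus.

Session scope keeps the expensive objects (descriptor assembly over a corpus
of toy complexes) computed once for the whole run.
"""

import numpy as np
import pytest

from locsurf import fixtures as fx
from locsurf.chemistry import Atom, Structure
from locsurf.descriptor import apply_normalization
from locsurf.training import MoietySpec, TrainingExample, build_ligand_model

SPACING_RANGE = (3.5, 4.5)   # generative ligand inter-atom jitter window, Å


@pytest.fixture(scope="session")
def unit_sphere():
    return fx.sphere_mesh(1.0)


@pytest.fixture(scope="session")
def sphere_r2():
    return fx.sphere_mesh(2.0)


@pytest.fixture(scope="session")
def sphere_r5():
    return fx.sphere_mesh(5.0)


@pytest.fixture(scope="session")
def plane():
    return fx.plane_mesh(extent=10.0)


@pytest.fixture(scope="session")
def cylinder():
    return fx.cylinder_mesh(1.0, height=10.0)


@pytest.fixture(scope="session")
def pocket():
    return fx.pocket_mesh(4.0, extent=16.0)


@pytest.fixture(scope="session")
def toy_complex():
    return fx.make_synthetic_complex(seed=11)


@pytest.fixture(scope="session")
def corpus_split():
    """20 training + 5 test complexes, +2σ signature on 5 features per atom."""
    cs = fx.make_synthetic_corpus(25, seed=42, template={"spacing_range": SPACING_RANGE})
    return cs[:20], cs[20:]


@pytest.fixture(scope="session")
def toy_spec():
    return MoietySpec("toy", ["L1", "L2"], ["LIG"])


@pytest.fixture(scope="session")
def toy_model(corpus_split, toy_spec):
    train, _ = corpus_split
    examples = [
        TrainingExample(c.surface, c.ligand_pose, f"train{i}")
        for i, c in enumerate(train)
    ]
    return build_ligand_model("LIG", [toy_spec], {"toy": examples}, seed=5)


@pytest.fixture(scope="session")
def normalized_test_surfaces(corpus_split, toy_model):
    _, test = corpus_split
    return [apply_normalization(c.surface, toy_model.stats) for c in test]


@pytest.fixture()
def tiny_structure():
    """Hand-built 5-atom structure covering several categories."""
    mk = lambda serial, name, el, res, seq, pos: Atom(
        serial=serial, name=name, element=el, residue_name=res,
        chain="A", residue_seq=seq, position=np.array(pos, float),
    )
    return Structure(
        atoms=[
            mk(1, "N", "N", "ALA", 1, (0.0, 0.0, 0.0)),
            mk(2, "CA", "C", "ALA", 1, (1.5, 0.0, 0.0)),
            mk(3, "OG", "O", "SER", 2, (0.0, 3.0, 0.0)),
            mk(4, "SG", "S", "CYS", 3, (5.0, 0.0, 0.0)),
            mk(5, "OD1", "O", "ASP", 4, (0.0, 0.0, 2.0)),
        ]
    )
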