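import numpy as np
import pytest

from crydimer import (
    Ensemble,
    FixtureSpec,
    RadiiSet,
    Structure,
    compute_msa_reference,
    make_dimer_pose,
    make_helix_monomer,
    make_tripeptide,
)


def single_atom_structure(element="C", position=(0.0, 0.0, 0.0)):
    return Structure.from_arrays([position], [element])


def two_chain_points(positions_a, positions_b, elements="S", atom_name="SG",
                     res_name="CYS"):
    """Minimal two-chain structure with one named atom per residue."""
    pa = np.atleast_2d(positions_a)
    pb = np.atleast_2d(positions_b)
    coords = np.vstack([pa, pb])
    n_a, n_b = len(pa), len(pb)
    el = [elements] * (n_a + n_b) if isinstance(elements, str) else elements
    return Structure.from_arrays(
        coords,
        el,
        atom_names=[atom_name] * (n_a + n_b),
        res_names=[res_name] * (n_a + n_b),
        res_ids=list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
        chain_ids=["A"] * n_a + ["B"] * n_b,
    )


@pytest.fixture(scope="session")
def radii960():
    return RadiiSet(n_sphere_points=960)


@pytest.fixture(scope="session")
def monomer_spec():
    # helix twist 100°/residue: Cys10 faces 180°, partners on the far face
    return FixtureSpec(
        helix_length=20,
        cys_positions=(10,),
        lys_positions=(4, 15),
        asp_positions=(17,),
        seed=0,
    )


@pytest.fixture(scope="session")
def monomer(monomer_spec):
    return make_helix_monomer(monomer_spec)


@pytest.fixture(scope="session")
def pose5(monomer):
    return make_dimer_pose(monomer, 5.0, c2=True, seed=0)


@pytest.fixture(scope="session")
def msa_small(radii960):
    trips = {
        r: Ensemble([make_tripeptide(r)])
        for r in ("ALA", "CYS", "LYS", "ASP", "GLY")
    }
    return compute_msa_reference(trips, radii960)
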